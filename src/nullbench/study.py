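"""End-to-end study driver: negatives, synthetic families, scoring, reports.

``run_study`` reproduces the full evaluation loop at desk scale:

1. generate the GC-stratified random negatives (default: 50 per mark,
   length 70, AG consensus at positions 49-50 — the acceptor-site
   geometry);
2. build three synthetic ground-truth acceptor WAMs at low / medium /
   high average GC (default 38% / 50% / 65%), sample a training set from
   each and fit a WAM to it;
3. score the negatives under every requested null (default the six of
   the study: 5%GC, 25%GC, uniform, 75%GC, 95%GC, target);
4. write per-family score tables and the per-family specificity table.

Everything is deterministic given the single config seed: per-stage
seeds are spawned from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .evaluation import specificity_table
from .null_models import make_fixed_gc, make_uniform
from .scoring import TARGET, NullSpec, score_dataset
from .seqgen import (
    ConsensusSpec,
    GCMarkDataset,
    generate_gc_stratified,
    make_synthetic_acceptor_wam,
    sample_family,
)
from .wam import WAMModel, fit_wam

logger = logging.getLogger(__name__)

DEFAULT_NULL_SPECS = ("gc:0.05", "gc:0.25", "uniform", "gc:0.75", "gc:0.95", "target")


def parse_null_spec(spec: str) -> NullSpec:
    """Parse a null-model spec string: ``uniform``, ``gc:<frac>``, ``target``."""
    spec = spec.strip()
    if spec == "uniform":
        return make_uniform()
    if spec == "target":
        return TARGET
    if spec.startswith("gc:"):
        return make_fixed_gc(float(spec[3:]))
    raise ValueError(f"unrecognised null spec {spec!r}")


@dataclass
class RunConfig:
    """Parameters of one full study run."""

    seed: int = 0
    n_per_mark: int = 50
    length: int = 70
    consensus_motif: str = "AG"
    consensus_pos: int = 49  # 1-based; 0 disables the consensus
    family_gcs: tuple[float, ...] = (0.38, 0.50, 0.65)
    train_n: int = 1000
    order: int = 1
    pseudocount: float = 1.0
    nulls: tuple[str, ...] = DEFAULT_NULL_SPECS
    outdir: str = "results/study"
    log_level: str = "INFO"

    def consensus(self) -> ConsensusSpec | None:
        if self.consensus_pos <= 0 or not self.consensus_motif:
            return None
        return ConsensusSpec(self.consensus_pos, self.consensus_motif)

    def null_models(self) -> list[NullSpec]:
        if not self.nulls:
            raise ValueError("null list must be non-empty")
        return [parse_null_spec(s) for s in self.nulls]


@dataclass
class StudyReport:
    """In-memory bundle of everything a study run produced."""

    negatives: GCMarkDataset
    true_families: dict[str, WAMModel]
    fitted_families: dict[str, WAMModel]
    scores: dict[str, pd.DataFrame]
    specificity: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def family_label(gc: float) -> str:
    return f"WAM_{round(100 * gc)}GC"


def run_study(config: RunConfig) -> StudyReport:
    """Run the full negatives / families / scoring / specificity pipeline."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # independent per-stage streams derived from the one config seed
    seedseq = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s) % (2**31) for s in seedseq.generate_state(16)]

    consensus = config.consensus()
    logger.info(
        "generating negatives: N=%d L=%d consensus=%s",
        config.n_per_mark,
        config.length,
        consensus,
    )
    negatives = generate_gc_stratified(
        config.n_per_mark, config.length, seed=stage_seeds[0], consensus=consensus
    )
    logger.info(
        "negatives: %d sequences over %d marks",
        len(negatives),
        negatives.occupied_marks.size,
    )
    paths: dict[str, Path] = {}
    io.write_dataset_fasta(negatives, outdir / "negatives.fasta")
    io.write_dataset_manifest(negatives, outdir / "negatives.tsv")
    paths["negatives"] = outdir / "negatives.fasta"

    nulls = config.null_models()
    true_families: dict[str, WAMModel] = {}
    fitted: dict[str, WAMModel] = {}
    scores: dict[str, pd.DataFrame] = {}
    spec_rows = []
    for i, gc in enumerate(config.family_gcs):
        label = family_label(gc)
        truth = make_synthetic_acceptor_wam(
            gc,
            length=config.length,
            consensus=consensus,
            order=config.order,
            seed=stage_seeds[1 + 2 * i],
        )
        training = sample_family(
            truth, config.train_n, seed=stage_seeds[2 + 2 * i], prefix=label
        )
        model = fit_wam(training, order=config.order, pseudocount=config.pseudocount)
        true_families[label] = truth
        fitted[label] = model
        logger.info(
            "family %s: trained on %d sequences, average GC %.3f",
            label,
            config.train_n,
            model.average_gc(),
        )
        table = score_dataset(negatives, model, nulls)
        scores[label] = table
        path = outdir / f"scores_{label}.tsv"
        io.write_scores(table, path)
        paths[f"scores_{label}"] = path
        spec = specificity_table(table, n_total=len(negatives))
        spec.insert(0, "family", label)
        spec_rows.append(spec)

    specificity = pd.concat(spec_rows, ignore_index=True)
    spec_path = outdir / "specificity.tsv"
    specificity.to_csv(spec_path, sep="\t", index=False, lineterminator="\n")
    paths["specificity"] = spec_path
    logger.info("specificity table written to %s", spec_path)

    return StudyReport(
        negatives=negatives,
        true_families=true_families,
        fitted_families=fitted,
        scores=scores,
        specificity=specificity,
        paths=paths,
    )
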