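"""Position-independent (i.i.d.) sequence models and raw log-probability scores.

An i.i.d. model assigns each base a fixed probability, so the probability
of a sequence depends only on its base counts:

    log2 P(x | N) = sum_i c_i * log2 P_N(i),   i in {A, C, G, T}

("raw score", in bits).  Four constructions cover the null-model classes
studied here:

* :func:`make_fixed_gc` — the symmetric fixed-GC family, P(G)=P(C)=gc/2,
  P(A)=P(T)=(1-gc)/2; ``gc=0.5`` is the uniform model.
* :func:`fit_target` — the target model: maximum-likelihood base
  frequencies of the very sequence being scored.
* :func:`fit_background` — pooled ML frequencies of a sequence
  collection (genomic-background or training-set null).

Zero probabilities are representable; a raw score may be ``-inf`` (a base
present in the sequence but impossible under the model) and is treated as
a valid minimal score, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence import ALPHABET, NucleotideSequence

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class IIDModel:
    """Fixed per-base probability distribution ``(P_A, P_C, P_G, P_T)``."""

    probs: tuple[float, float, float, float]
    label: str = "iid"
    _log2: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("an i.i.d. model needs exactly 4 probabilities (A, C, G, T)")
        if (p < 0).any():
            raise ValueError(f"model {self.label!r}: negative probability")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"model {self.label!r}: probabilities sum to {p.sum()!r}, not 1"
            )
        object.__setattr__(self, "probs", tuple(float(v) for v in p))
        with np.errstate(divide="ignore"):
            object.__setattr__(self, "_log2", np.log2(p))

    @property
    def probs_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @property
    def log2_probs(self) -> np.ndarray:
        """log2 probabilities; zeros map to ``-inf``."""
        return self._log2

    @property
    def gc(self) -> float:
        return self.probs[1] + self.probs[2]

    def __str__(self) -> str:
        body = ", ".join(f"{b}={p:.4g}" for b, p in zip(ALPHABET, self.probs))
        return f"IIDModel({self.label}: {body})"


def make_fixed_gc(gc: float, label: str | None = None) -> IIDModel:
    """Symmetric fixed-GC model: P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    if label is None:
        label = f"{100 * gc:g}%GC"
    s, w = gc / 2.0, (1.0 - gc) / 2.0
    return IIDModel((w, s, s, w), label=label)


def make_uniform() -> IIDModel:
    """The uniform model, P(i) = 1/4 for every base."""
    return IIDModel((0.25, 0.25, 0.25, 0.25), label="uniform")


def fit_target(x: NucleotideSequence) -> IIDModel:
    """Target model of ``x``: its own ML base frequencies c_i / L."""
    c = x.counts
    return IIDModel(tuple(c / len(x)), label="target")


def fit_background(seqs: Sequence[NucleotideSequence], label: str = "background") -> IIDModel:
    """Pooled ML base frequencies over a collection of sequences."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("background fit needs at least one sequence")
    total = np.zeros(4, dtype=np.int64)
    n = 0
    for s in seqs:
        total += s.counts
        n += len(s)
    return IIDModel(tuple(total / n), label=label)


def _counts_dot_log2(counts: np.ndarray, log2p: np.ndarray) -> np.ndarray:
    """``counts @ log2p`` with the convention 0 * (-inf) = 0."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(invalid="ignore"):
        terms = np.where(counts > 0, counts * log2p, 0.0)
    return terms.sum(axis=-1)


def raw_score(x: NucleotideSequence, model: IIDModel) -> float:
    """log2 P(x | model) in bits; ``-inf`` if x contains an impossible base."""
    return float(_counts_dot_log2(x.counts, model.log2_probs))


def raw_score_counts(counts: np.ndarray, model: IIDModel) -> np.ndarray:
    """Vectorised :func:`raw_score` on an ``(n, 4)`` count matrix."""
    return _counts_dot_log2(counts, model.log2_probs)


def target_raw_score_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised raw score of each row under its own target model.

    For row counts ``c`` of total ``L`` this is ``sum_i c_i log2(c_i/L)``,
    which is always finite and non-positive.
    """
    counts = np.asarray(counts, dtype=float)
    L = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log2(counts / L), 0.0)
    return terms.sum(axis=-1)
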