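"""GC-stratified random sequence generation and motif-bearing sample sets.

The stratified generator produces the all-negative test sets used
throughout the study.  For each GC percentage W = j/100, j = 0..100, it
builds N sequences of length L by concatenating a GC-only subsequence of
length K1 = floor(L_free * W) (bases uniform over {G, C}) with an AT-only
subsequence of length K2 = L_free - K1 (uniform over {A, T}) and
shuffling the result uniformly.  When a consensus motif is requested
(e.g. the canonical AG of an acceptor splice site), the motif occupies
fixed positions excluded from the random construction (L_free = L minus
the motif length) and is spliced back in after the shuffle.

Each sequence is then assigned to the integer mark
``round(100 * gc_count / L)`` recomputed on the full sequence, consensus
included.  Distinct W batches can collide on the same mark, so every
occupied mark is pruned to exactly N sequences (the first N in generation
order); marks reached by no batch are absent.  The total dataset size is
therefore N times the number of occupied marks — e.g. 50 per mark gives
3150 sequences at L=62, 5050 at L=100 and 3450 at L=70 with an AG
dinucleotide fixed at positions 49-50.

:func:`sample_family` and :func:`make_synthetic_acceptor_wam` provide the
positive side: training/test sets drawn from a known position-specific
model with controllable average GC, standing in for curated splice-site
and RNA-family collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .sequence import (
    A,
    C,
    G,
    T,
    NucleotideSequence,
    counts_matrix,
    decode,
    encode,
    gc_mark,
)
from .wam import WAMModel

__all__ = [
    "ConsensusSpec",
    "GCMarkDataset",
    "generate_gc_stratified",
    "sample_family",
    "make_synthetic_acceptor_wam",
]


@dataclass(frozen=True)
class ConsensusSpec:
    """A short motif pinned at a fixed 1-based position.

    ``ConsensusSpec(49, "AG")`` places the canonical acceptor-site AG at
    positions 49-50 of every generated sequence.
    """

    start: int
    motif: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"consensus start must be >= 1 (1-based), got {self.start}")
        if len(self.motif) < 1:
            raise ValueError("consensus motif must be non-empty")
        encode(self.motif, name="<consensus>")

    def __len__(self) -> int:
        return len(self.motif)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.motif, name="<consensus>")

    @property
    def gc_count(self) -> int:
        return int(np.isin(self.codes, (C, G)).sum())

    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.motif) - 1

    def check_fits(self, length: int) -> None:
        if self.end() > length:
            raise ValueError(
                f"consensus {self.motif!r} at position {self.start} does not fit "
                f"in length {length}"
            )


@dataclass
class GCMarkDataset:
    """Sequences grouped by integer GC percentage mark.

    Rows of ``codes`` are in generation order (batch W ascending, then
    within-batch index); ``marks[i]`` is the recomputed mark of row i.
    Every occupied mark holds exactly ``n_per_mark`` sequences.
    """

    codes: np.ndarray
    ids: list[str]
    marks: np.ndarray
    n_per_mark: int
    length: int
    consensus: ConsensusSpec | None
    seed: int

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def occupied_marks(self) -> np.ndarray:
        """Sorted distinct marks present in the dataset."""
        return np.unique(self.marks)

    def counts(self) -> np.ndarray:
        """Per-sequence base counts, shape ``(n, 4)``."""
        return counts_matrix(self.codes)

    def rows_for_mark(self, mark: int) -> np.ndarray:
        return np.flatnonzero(self.marks == mark)

    def sequences(self) -> Iterator[NucleotideSequence]:
        for i in range(len(self)):
            yield NucleotideSequence(id=self.ids[i], residues=decode(self.codes[i]))


def _random_batch(
    rng: np.random.Generator,
    n: int,
    length: int,
    k1: int,
    consensus: ConsensusSpec | None,
) -> np.ndarray:
    """One batch of n sequences with exactly k1 G/C bases among the free positions."""
    l_free = length - (len(consensus) if consensus else 0)
    free = np.empty((n, l_free), dtype=np.uint8)
    # GC half: uniform over {C, G}; AT half: uniform over {A, T}
    free[:, :k1] = np.where(rng.integers(0, 2, size=(n, k1)) == 0, C, G)
    free[:, k1:] = np.where(rng.integers(0, 2, size=(n, l_free - k1)) == 0, A, T)
    rng.permuted(free, axis=1, out=free)
    if consensus is None:
        return free
    out = np.empty((n, length), dtype=np.uint8)
    lo = consensus.start - 1
    hi = consensus.end()
    out[:, :lo] = free[:, :lo]
    out[:, lo:hi] = consensus.codes
    out[:, hi:] = free[:, lo:]
    return out


def generate_gc_stratified(
    n_per_mark: int,
    length: int,
    seed: int = 0,
    consensus: ConsensusSpec | None = None,
) -> GCMarkDataset:
    """Generate the GC-stratified random dataset.

    Parameters
    ----------
    n_per_mark
        N, the number of sequences per GC percentage mark.
    length
        L, the full sequence length (consensus included).
    seed
        Seed for the single generator threaded through all draws and
        shuffles; identical parameters and seed reproduce the dataset
        byte for byte.
    consensus
        Optional motif pinned at a fixed position and excluded from the
        random-composition construction.

    Returns
    -------
    GCMarkDataset
        Exactly ``n_per_mark`` sequences at every occupied mark.
    """
    if n_per_mark < 1:
        raise ValueError(f"n_per_mark must be >= 1, got {n_per_mark}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if consensus is not None:
        consensus.check_fits(length)

    rng = np.random.default_rng(seed)
    cons_len = len(consensus) if consensus else 0
    cons_gc = consensus.gc_count if consensus else 0
    l_free = length - cons_len

    kept_codes: list[np.ndarray] = []
    kept_ids: list[str] = []
    kept_marks: list[int] = []
    fill: dict[int, int] = {}  # mark -> sequences already retained

    for j in range(101):
        k1 = (l_free * j) // 100  # floor(L_free * W)
        batch = _random_batch(rng, n_per_mark, length, k1, consensus)
        # composition of every batch sequence is fixed by construction
        mark = gc_mark(k1 + cons_gc, length)
        have = fill.get(mark, 0)
        take = min(n_per_mark - have, n_per_mark)
        if take > 0:
            kept_codes.append(batch[:take])
            kept_ids.extend(f"seq_{j}_{k}" for k in range(take))
            kept_marks.extend([mark] * take)
            fill[mark] = have + take

    codes = np.concatenate(kept_codes, axis=0)
    return GCMarkDataset(
        codes=codes,
        ids=kept_ids,
        marks=np.asarray(kept_marks, dtype=np.int64),
        n_per_mark=n_per_mark,
        length=length,
        consensus=consensus,
        seed=seed,
    )


def sample_family(
    model: WAMModel, n: int, seed: int = 0, prefix: str = "fam"
) -> list[NucleotideSequence]:
    """Draw n sequences from a position-specific family model.

    Each sequence is sampled position by position from the model's
    conditional distributions; deterministic given the seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    codes = model.sample_codes(n, rng)
    return [
        NucleotideSequence(id=f"{prefix}_{i}", residues=decode(codes[i]))
        for i in range(n)
    ]


def make_synthetic_acceptor_wam(
    gc: float,
    length: int = 70,
    consensus: ConsensusSpec | None = None,
    order: int = 1,
    concentration: float = 10.0,
    seed: int = 0,
) -> WAMModel:
    """Construct a known acceptor-site-like WAM with average GC ``gc``.

    Every non-consensus conditional distribution is drawn from a
    Dirichlet centred on the symmetric fixed-GC distribution
    (P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2) with the given concentration,
    so sampled sequences have average GC content close to ``gc`` while
    individual positions carry motif-like preferences.  Consensus
    positions (e.g. the acceptor AG) are point masses.

    Used as the ground-truth generator for synthetic training and
    positive test sets; it is a model to sample from and to recover by
    fitting, not a fitted object itself.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in (0, 1) for a synthetic family, got {gc}")
    if consensus is not None:
        consensus.check_fits(length)
    rng = np.random.default_rng(seed)
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cons_cols: dict[int, int] = {}
    if consensus is not None:
        for off, code in enumerate(consensus.codes):
            cons_cols[consensus.start - 1 + off] = int(code)

    dists: list[np.ndarray] = []
    for p in range(length):
        n_ctx = 4 ** min(p, order)
        if p in cons_cols:
            d = np.zeros((n_ctx, 4))
            d[:, cons_cols[p]] = 1.0
        else:
            d = rng.dirichlet(concentration * base, size=n_ctx)
        dists.append(d)
    return WAMModel(dists=dists, order=order, pseudocount=0.0)
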