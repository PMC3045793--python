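"""Weight Array Matrices: position-specific Markov models of fixed-length motifs.

A WAM of order k stores, for each position p, the conditional
distribution of the base at p given the k preceding bases (marginal
distributions for the first k positions).  Order 1 is the classic weight
array matrix capturing adjacent-dinucleotide dependencies; order 0
degenerates to a position weight matrix.

Estimation uses additive (pseudocount) smoothing:

    P_p(b | ctx) = (count(ctx, b at p) + alpha) / (count(ctx at p) + 4*alpha)

With ``alpha = 0``, contexts never observed in training have no defined
conditional; they are marked unusable and scoring a sequence through one
raises :class:`UnusableContextError` — deliberately distinct from a
zero-probability event at an observed context, which scores ``-inf``.

All scores are in bits (log base 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence import NucleotideSequence

_ROW_TOL = 1e-9


class UnusableContextError(ValueError):
    """Scoring required a conditional for a context never seen at fit time."""


class LengthMismatchError(ValueError):
    """Sequence length does not match the model length."""


@dataclass
class WAMModel:
    """Position-specific conditional base distributions.

    ``dists[p]`` has shape ``(4**min(p, order), 4)``; row indices encode
    the context string read left to right as a base-4 number (A=0, C=1,
    G=2, T=3).  ``usable[p]`` flags contexts with a defined conditional.
    """

    dists: list[np.ndarray]
    order: int = 1
    pseudocount: float = 1.0
    usable: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.dists:
            raise ValueError("a WAM needs at least one position")
        if self.order < 0:
            raise ValueError(f"order must be >= 0, got {self.order}")
        if self.usable is None:
            self.usable = [np.ones(d.shape[0], dtype=bool) for d in self.dists]
        for p, (d, u) in enumerate(zip(self.dists, self.usable)):
            expected = 4 ** min(p, self.order)
            if d.shape != (expected, 4):
                raise ValueError(
                    f"position {p + 1}: distribution shape {d.shape}, "
                    f"expected ({expected}, 4)"
                )
            if (d[u] < 0).any():
                raise ValueError(f"position {p + 1}: negative probability")
            sums = d[u].sum(axis=1)
            if sums.size and np.abs(sums - 1.0).max() > _ROW_TOL:
                raise ValueError(
                    f"position {p + 1}: conditional distributions do not sum to 1"
                )

    @property
    def length(self) -> int:
        return len(self.dists)

    def _check_length(self, L: int) -> None:
        if L != self.length:
            raise LengthMismatchError(
                f"sequence length {L} does not match model length {self.length}"
            )

    def _context_index(self, codes: np.ndarray, p: int) -> np.ndarray:
        """Base-4 context row index at position p for each row of ``codes``."""
        cp = min(p, self.order)
        idx = np.zeros(codes.shape[0], dtype=np.int64)
        for t in range(cp):
            idx = idx * 4 + codes[:, p - cp + t]
        return idx

    def log_prob_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised log2 P(x | WAM) over the rows of a code matrix."""
        codes = np.atleast_2d(np.asarray(codes))
        self._check_length(codes.shape[1])
        total = np.zeros(codes.shape[0])
        with np.errstate(divide="ignore"):
            for p in range(self.length):
                ctx = self._context_index(codes, p)
                bad = ~self.usable[p][ctx]
                if bad.any():
                    raise UnusableContextError(
                        f"position {p + 1}: context never observed at fit time "
                        f"(alpha=0); cannot score"
                    )
                total += np.log2(self.dists[p][ctx, codes[:, p]])
        return total

    def log_prob(self, x: NucleotideSequence) -> float:
        """log2 P(x | WAM) in bits; ``-inf`` on a zero-probability base."""
        return float(self.log_prob_codes(x.codes[None, :])[0])

    def sample_codes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n sequences position by position; shape ``(n, L)``."""
        out = np.empty((n, self.length), dtype=np.uint8)
        u = rng.random((n, self.length))
        for p in range(self.length):
            ctx = self._context_index(out, p)
            if not self.usable[p][ctx].all():
                raise UnusableContextError(
                    f"position {p + 1}: sampling reached an unusable context"
                )
            cdf = np.cumsum(self.dists[p][ctx], axis=1)
            out[:, p] = (u[:, p : p + 1] > cdf[:, :3]).sum(axis=1)
        return out

    def marginal_base_probs(self) -> np.ndarray:
        """Exact marginal base distribution at each position, shape ``(L, 4)``.

        Propagates context probabilities through the chain; useful for
        checking the average composition a model induces.
        """
        out = np.empty((self.length, 4))
        ctx_prob = np.ones(1)
        for p in range(self.length):
            cond = np.where(self.usable[p][:, None], self.dists[p], 0.0)
            out[p] = ctx_prob @ cond
            if self.order == 0:
                continue
            joint = ctx_prob[:, None] * cond  # (n_ctx, 4)
            n_next = 4 ** min(p + 1, self.order)
            if joint.size == n_next:
                ctx_prob = joint.reshape(n_next)
            else:
                # context window slides: drop the oldest base
                ctx_prob = joint.reshape(4, -1, 4).sum(axis=0).reshape(n_next)
        return out

    def average_gc(self) -> float:
        """Expected GC fraction of sequences drawn from the model."""
        marg = self.marginal_base_probs()
        return float(marg[:, [1, 2]].sum() / self.length)


def fit_wam(
    training: Sequence[NucleotideSequence],
    order: int = 1,
    pseudocount: float = 1.0,
) -> WAMModel:
    """Estimate a WAM from aligned fixed-length training sequences.

    Raises on an empty training set, ragged lengths, or a negative
    pseudocount.  With ``pseudocount = 0``, unobserved contexts are
    marked unusable rather than silently uniform.
    """
    training = list(training)
    if not training:
        raise ValueError("training set is empty")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    L = len(training[0])
    for s in training:
        if len(s) != L:
            raise ValueError(
                f"ragged training set: record {s.id!r} has length {len(s)}, "
                f"expected {L}"
            )
    codes = np.stack([s.codes for s in training])

    dists: list[np.ndarray] = []
    usable: list[np.ndarray] = []
    for p in range(L):
        cp = min(p, order)
        n_ctx = 4**cp
        ctx = np.zeros(codes.shape[0], dtype=np.int64)
        for t in range(cp):
            ctx = ctx * 4 + codes[:, p - cp + t]
        counts = np.zeros((n_ctx, 4))
        np.add.at(counts, (ctx, codes[:, p]), 1.0)
        ctx_tot = counts.sum(axis=1)
        if pseudocount > 0:
            d = (counts + pseudocount) / (ctx_tot[:, None] + 4 * pseudocount)
            u = np.ones(n_ctx, dtype=bool)
        else:
            u = ctx_tot > 0
            d = np.zeros((n_ctx, 4))
            d[u] = counts[u] / ctx_tot[u, None]
        dists.append(d)
        usable.append(u)
    return WAMModel(dists=dists, order=order, pseudocount=pseudocount, usable=usable)
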