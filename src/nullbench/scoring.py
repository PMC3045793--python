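"""Log-odds classification: family model vs null model.

The log-odds score of a sequence x under family model F and null model N
(equal priors assumed) is

    S(x) = log2 P(x | F) - log2 P(x | N)    [bits]

and x is classified positive iff S > 0 strictly; S = 0 counts as
negative.  The family model may be a WAM or any i.i.d. model; the null
is an i.i.d. model or the per-sequence target rule (the null refitted to
each scored sequence's own base frequencies).

:func:`swap_null` re-expresses a log-odds score computed against the
uniform null under any other null without rescoring the family model:

    S_N(x) = S_U(x) + log2 P(x | U) - log2 P(x | N)

This is how scores from an external scorer that hard-wires a uniform
null (e.g. a covariance-model search whose best path must not depend on
the null) are adapted to the nulls studied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .null_models import (
    IIDModel,
    fit_target,
    raw_score,
    raw_score_counts,
    target_raw_score_counts,
)
from .seqgen import GCMarkDataset
from .sequence import NucleotideSequence
from .wam import WAMModel

FamilyModel = Union[WAMModel, IIDModel]


class UndefinedScoreError(ArithmeticError):
    """Both family and null assign probability zero: the log-odds is -inf - -inf."""


class _TargetRule:
    """Sentinel null: refit the i.i.d. model to each target sequence."""

    label = "target"

    def __repr__(self) -> str:  # pragma: no cover
        return "TARGET"


TARGET = _TargetRule()
NullSpec = Union[IIDModel, _TargetRule]

SCORE_COLUMNS = [
    "id",
    "mark",
    "null_label",
    "family_bits",
    "null_bits",
    "log_odds",
    "positive",
]


@dataclass(frozen=True)
class ScoreRecord:
    """One scored (sequence, null) pair."""

    id: str
    mark: int
    null_label: str
    family_bits: float
    null_bits: float
    log_odds: float
    positive: bool


def _family_bits(x: NucleotideSequence, family: FamilyModel) -> float:
    if isinstance(family, WAMModel):
        return family.log_prob(x)
    return raw_score(x, family)


def _null_bits(x: NucleotideSequence, null: NullSpec) -> float:
    if isinstance(null, _TargetRule):
        return raw_score(x, fit_target(x))
    return raw_score(x, null)


def _combine(family_bits: float, null_bits: float) -> float:
    if np.isneginf(family_bits) and np.isneginf(null_bits):
        raise UndefinedScoreError(
            "family and null both assign probability zero; the log-odds is undefined"
        )
    return family_bits - null_bits


def log_odds(
    x: NucleotideSequence, family: FamilyModel, null: NullSpec
) -> ScoreRecord:
    """Score one sequence: S = log2 P(x|F) - log2 P(x|N), threshold at 0."""
    fb = _family_bits(x, family)
    nb = _null_bits(x, null)
    s = _combine(fb, nb)
    return ScoreRecord(
        id=x.id,
        mark=x.mark,
        null_label=null.label,
        family_bits=fb,
        null_bits=nb,
        log_odds=s,
        positive=bool(s > 0),
    )


def swap_null(s_uniform: float, x: NucleotideSequence, new_null: NullSpec) -> float:
    """Adapt a uniform-null log-odds score to another null.

    ``s_uniform`` must have been computed against the uniform null for
    this exact sequence.  A null assigning x probability zero yields
    ``+inf``, flagged with a warning (the score is degenerate: the null
    rules x out entirely).
    """
    log_p_uniform = -2.0 * len(x)  # log2 (1/4)^L
    log_p_new = _null_bits(x, new_null)
    if np.isneginf(log_p_new):
        warnings.warn(
            f"record {x.id!r}: null {new_null.label!r} assigns probability zero; "
            "swapped score is +inf (degenerate)",
            RuntimeWarning,
            stacklevel=2,
        )
    return s_uniform + log_p_uniform - log_p_new


def _family_bits_matrix(codes: np.ndarray, family: FamilyModel) -> np.ndarray:
    from .sequence import counts_matrix

    if isinstance(family, WAMModel):
        return family.log_prob_codes(codes)
    return raw_score_counts(counts_matrix(codes), family)


def score_dataset(
    data: GCMarkDataset,
    family: FamilyModel,
    nulls: Sequence[NullSpec],
) -> pd.DataFrame:
    """Score every sequence of a stratified dataset under each null.

    Returns one row per (sequence, null), sorted by (mark, id,
    null_label), with both log-probability terms, the log-odds score and
    the positive/negative call.
    """
    from .sequence import counts_matrix

    nulls = list(nulls)
    if not nulls:
        raise ValueError("at least one null model is required")
    counts = counts_matrix(data.codes)
    fam = _family_bits_matrix(data.codes, family)

    frames = []
    for null in nulls:
        if isinstance(null, _TargetRule):
            nb = target_raw_score_counts(counts)
        else:
            nb = raw_score_counts(counts, null)
        both_inf = np.isneginf(fam) & np.isneginf(nb)
        if both_inf.any():
            i = int(np.argmax(both_inf))
            raise UndefinedScoreError(
                f"record {data.ids[i]!r} under null {null.label!r}: family and "
                "null both assign probability zero"
            )
        s = fam - nb
        frames.append(
            pd.DataFrame(
                {
                    "id": data.ids,
                    "mark": data.marks,
                    "null_label": null.label,
                    "family_bits": fam,
                    "null_bits": nb,
                    "log_odds": s,
                    "positive": s > 0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["mark", "id", "null_label"], kind="mergesort")
    return out.reset_index(drop=True)


def per_mark_mean(scores: pd.DataFrame, null_label: str | None = None) -> pd.Series:
    """Mean log-odds per GC mark (optionally for a single null label)."""
    df = scores if null_label is None else scores[scores["null_label"] == null_label]
    return df.groupby("mark")["log_odds"].mean()
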