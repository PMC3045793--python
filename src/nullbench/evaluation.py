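"""Study-level evaluation: specificity counts, confusion metrics, PR by GC mark.

All-negative random test sets measure specificity directly: a good null
model leaves few (ideally no) random sequences with positive log-odds
scores.  Labeled sets additionally support precision / recall /
specificity / F-score at the fixed S > 0 threshold, and per-GC-mark
precision-recall series (one point per mark holding strictly more than
five positive samples — sparser marks are omitted, not zero-filled).

Percentages in count tables are rounded half-away-from-zero to integers;
the denominator is always reported alongside, since it differs between
experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the derived metrics at the S > 0 threshold.

    ``precision`` and ``f_score`` are ``None`` (absent) when undefined
    (no positive predictions), never coerced to zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d > 0 else None

    @property
    def recall(self) -> float:
        return self.tp / self.n_pos

    sensitivity = recall

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg

    @property
    def f_score(self) -> float | None:
        p = self.precision
        if p is None or p + self.recall == 0:
            return None
        return 2 * p * self.recall / (p + self.recall)


def specificity_table(
    scores: pd.DataFrame, n_total: int | None = None
) -> pd.DataFrame:
    """Positive-score counts per null on an all-negative random set.

    Parameters
    ----------
    scores
        Long-format score table with at least ``null_label`` and
        ``log_odds`` columns (one row per sequence-null pair); every row
        must come from label-free random sequences, so each positive
        score is a false positive.
    n_total
        Denominator for the percentage; defaults to the number of
        sequences scored under each null.

    Returns
    -------
    DataFrame with one row per null label: ``n_positive``, integer
    ``percent`` and the ``denominator`` used.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    rows = []
    for label, grp in scores.groupby("null_label", sort=False):
        denom = n_total if n_total is not None else len(grp)
        n_pos = int((grp["log_odds"] > 0).sum())
        rows.append(
            {
                "null_label": label,
                "n_positive": n_pos,
                "percent": round_half_away(100.0 * n_pos / denom),
                "denominator": denom,
            }
        )
        logger.info(
            "specificity: null=%s positives=%d/%d", label, n_pos, denom
        )
    return pd.DataFrame(rows)


def confusion_metrics(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> EvalReport:
    """Confusion counts and metrics at the S > 0 threshold.

    ``pos_scores`` are log-odds of true family members, ``neg_scores``
    of non-members; both classes must be non-empty.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both a positive and a negative class are required")
    tp = int((pos > 0).sum())
    fp = int((neg > 0).sum())
    return EvalReport(tp=tp, fp=fp, tn=int(neg.size - fp), fn=int(pos.size - tp))


def pr_by_gc(records: pd.DataFrame, min_positives: int = 5) -> pd.DataFrame:
    """Per-GC-mark precision/recall series from a labeled score table.

    ``records`` needs columns ``mark``, ``label`` (boolean truth) and
    ``log_odds``.  A mark contributes a point only when it holds
    strictly more than ``min_positives`` true-positive samples; other
    marks are omitted.  Undefined precision (no positive prediction at a
    mark) is reported as NaN, not zero.
    """
    required = {"mark", "label", "log_odds"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for mark, grp in records.groupby("mark", sort=True):
        truth = grp["label"].to_numpy(dtype=bool)
        n_pos = int(truth.sum())
        if n_pos <= min_positives:
            continue
        pred = grp["log_odds"].to_numpy(dtype=float) > 0
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        fn = n_pos - tp
        rows.append(
            {
                "mark": int(mark),
                "precision": tp / (tp + fp) if tp + fp > 0 else float("nan"),
                "recall": tp / (tp + fn),
                "n_pos": n_pos,
                "n_neg": int((~truth).sum()),
            }
        )
    if not rows:
        logger.warning(
            "no GC mark holds more than %d positive samples; empty series",
            min_positives,
        )
        return pd.DataFrame(columns=["mark", "precision", "recall", "n_pos", "n_neg"])
    return pd.DataFrame(rows)


def roc_points(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> pd.DataFrame:
    """Score-threshold sweep: (false-positive rate, true-positive rate) points.

    Convenience output only; thresholds are the distinct observed scores.
    """
    pos = np.sort(np.asarray(list(pos_scores), dtype=float))
    neg = np.sort(np.asarray(list(neg_scores), dtype=float))
    thresholds = np.unique(np.concatenate([pos, neg]))
    rows = []
    for t in thresholds[::-1]:
        tpr = float((pos > t).sum() / pos.size)
        fpr = float((neg > t).sum() / neg.size)
        rows.append({"threshold": t, "fpr": fpr, "tpr": tpr})
    rows.append({"threshold": -np.inf, "fpr": 1.0, "tpr": 1.0})
    return pd.DataFrame(rows)
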