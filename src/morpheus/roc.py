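"""ROC-AUC evaluation of binding models (the "ROC" tool).

Discriminative power of a model is measured by comparing a per-sequence
statistic (best-site score or predicted occupancy) between a bound
(positive) and an unbound (negative) sequence set. Thresholds sweep the
distinct pooled statistic values from +inf down with the rule
"statistic >= threshold -> predicted bound"; the curve runs from (0,0)
to (1,1) and the AUC is its trapezoidal area, which equals the
Mann-Whitney probability P(pos > neg) + 0.5*P(pos = neg). Ties connect
blocks with a diagonal segment. The direction is fixed as "higher =
bound": a degenerate model shows up as AUC < 0.5 rather than being
silently flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .mpwm import MPWM, MPWMError, Calibration
from .occupancy import region_occupancy
from .scanner import SequenceRecord, best_hit, scan_record

__all__ = ["RocResult", "roc_points", "roc_table", "auc", "evaluate_model"]

logger = logging.getLogger(__name__)

STATISTICS = ("best_score", "occupancy")


@dataclass
class RocResult:
    """An ROC curve with its AUC and the per-class statistic values."""

    points: list[tuple[float, float]]
    auc: float
    statistic: str
    n_pos: int
    n_neg: int
    n_dropped: int = 0
    pos_values: list[float] = field(default_factory=list)
    neg_values: list[float] = field(default_factory=list)


def roc_points(
    pos: Sequence[float], neg: Sequence[float]
) -> list[tuple[float, float]]:
    """Ordered (FPR, TPR) points from threshold sweep over pooled values.

    Includes the endpoints (0,0) and (1,1); FPR and TPR are
    non-decreasing along the curve.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise MPWMError("ROC requires at least one positive and one negative value")
    points = [(0.0, 0.0)]
    for t in sorted(set(pos.tolist()) | set(neg.tolist()), reverse=True):
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        if (fpr, tpr) != points[-1]:
            points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def roc_table(
    pos: Sequence[float], neg: Sequence[float]
) -> list[tuple[float, float, float]]:
    """(threshold, FPR, TPR) rows for every swept threshold, +inf first."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise MPWMError("ROC requires at least one positive and one negative value")
    rows = [(float("inf"), 0.0, 0.0)]
    for t in sorted(set(pos.tolist()) | set(neg.tolist()), reverse=True):
        rows.append((t, float(np.mean(neg >= t)), float(np.mean(pos >= t))))
    return rows


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC curve."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate_model(
    model: MPWM,
    pos_records: Iterable[SequenceRecord],
    neg_records: Iterable[SequenceRecord],
    statistic: str = "best_score",
    limit: Optional[float] = None,
    calib: Optional[Calibration] = None,
) -> RocResult:
    """Compute the per-sequence statistic for both sets and their ROC.

    ``statistic`` is ``best_score`` (score of the top site) or
    ``occupancy`` (sum of site binding probabilities, optionally
    restricted to scores >= limit). Records shorter than the model
    contribute no statistic and are dropped with a logged count.
    """
    if statistic not in STATISTICS:
        raise MPWMError(
            f"unknown statistic {statistic!r}; expected one of {STATISTICS}"
        )
    if calib is None:
        calib = model.calibration or Calibration()

    def stat_of(rec: SequenceRecord) -> Optional[float]:
        hits = scan_record(model, rec, mode="all")
        if not hits:
            return None
        if statistic == "best_score":
            return max(h.score for h in hits)
        return region_occupancy(hits, calib, limit, seq_id=rec.id).occupancy

    dropped = 0
    pos_values: list[float] = []
    neg_values: list[float] = []
    for records, values in ((pos_records, pos_values), (neg_records, neg_values)):
        for rec in records:
            s = stat_of(rec)
            if s is None:
                dropped += 1
                logger.warning(
                    "record %s has no scorable window (length < %d); dropped",
                    rec.id,
                    model.length,
                )
            else:
                values.append(s)
    points = roc_points(pos_values, neg_values)
    return RocResult(
        points=points,
        auc=auc(points),
        statistic=statistic,
        n_pos=len(pos_values),
        n_neg=len(neg_values),
        n_dropped=dropped,
        pos_values=pos_values,
        neg_values=neg_values,
    )
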