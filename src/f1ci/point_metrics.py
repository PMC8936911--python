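"""Per-class rates and aggregate F1 scores from a probability table.

For an r x r table of cell probabilities p_ij (rows predicted, columns
true) the per-class rates are

    TP_i = p_ii,   FP_i = sum_{j != i} p_ij,   FN_i = sum_{j != i} p_ji,

so TP_i + FP_i = p_i. and TP_i + FN_i = p_.i.  Precision and recall are
P_i = p_ii / p_i. and R_i = p_ii / p_.i, and the per-class F1 is their
harmonic mean, F1_i = 2 p_ii / (p_i. + p_.i).

Three single-number summaries are supported:

* micro-averaged F1 (miF1): pooled over samples; for single-label
  multi-class data miP = miR = miF1 = trace(p), the overall accuracy;
* macro-averaged F1 (maF1): arithmetic mean of the F1_i, weighting
  classes equally;
* alternative macro-averaged F1 (maF1*): harmonic mean of the macro
  precision maP = mean(P_i) and macro recall maR = mean(R_i).

Degenerate classes (absent from both margins) make maF1 a 0/0 and raise
:class:`~f1ci.errors.DegenerateClassError` unless dropped explicitly; a
zero margin makes maF1* undefined and raises
:class:`~f1ci.errors.UndefinedEstimatorError`.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .confusion_io import ProbabilityTable
from .errors import DegenerateClassError, UndefinedEstimatorError

__all__ = [
    "ClasswiseMetrics",
    "AggregateScores",
    "classwise_rates",
    "precision_recall",
    "micro_f1",
    "macro_f1",
    "macro_f1_star",
    "aggregate_scores",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ClasswiseMetrics:
    """Per-class rates; undefined precision/recall entries are NaN."""

    class_labels: tuple
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray


@dataclasses.dataclass(frozen=True)
class AggregateScores:
    mi_f1: float
    ma_f1: float
    ma_f1_star: float
    ma_precision: float
    ma_recall: float

    @property
    def mi_precision(self) -> float:
        # micro precision = micro recall = micro F1 for single-label data
        return self.mi_f1

    @property
    def mi_recall(self) -> float:
        return self.mi_f1


def _with_nan(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with NaN where den == 0."""
    out = np.full_like(num, np.nan, dtype=np.float64)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def classwise_rates(pt: ProbabilityTable) -> ClasswiseMetrics:
    """TP/FP/FN rates plus per-class precision, recall and F1."""
    p = pt.p
    tp = np.diag(p).astype(np.float64)
    fp = pt.row_margins - tp
    fn = pt.col_margins - tp
    precision = _with_nan(tp, pt.row_margins)
    recall = _with_nan(tp, pt.col_margins)
    f1 = _with_nan(2.0 * tp, pt.row_margins + pt.col_margins)
    return ClasswiseMetrics(pt.class_labels, tp, fp, fn, precision, recall, f1)


# precision_recall is the same computation viewed from the P/R side;
# kept as a separate name for discoverability.
precision_recall = classwise_rates


def micro_f1(pt: ProbabilityTable) -> float:
    """miF1 = trace of the probability table (= miP = miR)."""
    return float(np.trace(pt.p))


def _empty_classes(pt: ProbabilityTable) -> np.ndarray:
    return np.flatnonzero(pt.row_margins + pt.col_margins == 0)


def macro_f1(pt: ProbabilityTable, drop_empty_classes: bool = False) -> float:
    """maF1 = (1/r) sum_i F1_i = (2/r) sum_i p_ii / (p_i. + p_.i).

    A class absent from both margins leaves its F1_i undefined (0/0).
    By default that raises :class:`DegenerateClassError`;
    ``drop_empty_classes=True`` averages over the non-empty classes
    instead, with a logged warning (this changes r and hence the score).
    """
    empty = _empty_classes(pt)
    if empty.size:
        names = [pt.class_labels[i] for i in empty]
        if not drop_empty_classes:
            raise DegenerateClassError(
                f"class(es) {names} absent from both margins: per-class F1 "
                "is 0/0; pass drop_empty_classes=True to average over the "
                "remaining classes",
                classes=names,
            )
        logger.warning(
            "dropping %d empty class(es) %s from maF1 (averaging over r'=%d)",
            empty.size, names, pt.r - empty.size,
        )
    cw = classwise_rates(pt)
    f1 = np.delete(cw.f1, empty) if empty.size else cw.f1
    return float(np.mean(f1))


def macro_f1_star(pt: ProbabilityTable) -> tuple[float, float, float]:
    """maF1* with its components.

    Returns ``(ma_f1_star, ma_precision, ma_recall)`` where
    maP = (1/r) sum_i p_ii / p_i., maR = (1/r) sum_i p_ii / p_.i and
    maF1* = 2 maP maR / (maP + maR).  Requires every row and column
    margin to be positive; otherwise the estimator is undefined.
    """
    zero_rows = np.flatnonzero(pt.row_margins == 0)
    zero_cols = np.flatnonzero(pt.col_margins == 0)
    if zero_rows.size or zero_cols.size:
        names = sorted(
            {pt.class_labels[i] for i in zero_rows}
            | {pt.class_labels[i] for i in zero_cols},
            key=str,
        )
        raise UndefinedEstimatorError(
            f"maF1* undefined: zero margin for class(es) {names}; "
            "all row and column margins must be non-zero",
            classes=names,
        )
    cw = classwise_rates(pt)
    ma_p = float(np.mean(cw.precision))
    ma_r = float(np.mean(cw.recall))
    if ma_p + ma_r == 0:
        return 0.0, ma_p, ma_r
    return 2.0 * ma_p * ma_r / (ma_p + ma_r), ma_p, ma_r


def aggregate_scores(
    pt: ProbabilityTable, drop_empty_classes: bool = False
) -> AggregateScores:
    """All five aggregate scores in one pass.

    maF1* (and its components) are NaN when a margin is zero while the
    other scores remain computable.
    """
    mi = micro_f1(pt)
    ma = macro_f1(pt, drop_empty_classes=drop_empty_classes)
    try:
        star, ma_p, ma_r = macro_f1_star(pt)
    except UndefinedEstimatorError:
        star = ma_p = ma_r = float("nan")
    return AggregateScores(mi, ma, star, ma_p, ma_r)
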