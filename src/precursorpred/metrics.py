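"""Per-label and macro classification metrics, and label-wise Wilcoxon
signed-rank model comparison.

Multi-label precursor prediction is strongly imbalanced, so evaluation uses
macro averages: precision, recall and F1 are computed per label from that
label's confusion counts and then averaged with equal weight across labels
(mPrecision, mRecall, mF1).  Labels with a zero denominator score 0 and are
flagged as degenerate, but still enter the macro average so that the reported
number is the literal unweighted mean.

Model comparison uses the Wilcoxon signed-rank (WSR) test on paired per-label
metric values: differences d_i = m1_i − m2_i, zeros dropped, absolute
differences ranked with average ranks for ties, W⁺ and W⁻ the rank sums of
positive and negative differences, test statistic W = min(W⁺, W⁻).  The
two-sided p-value comes from exact sign-flip enumeration for small effective
sample sizes and from a continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DataError

#: Largest effective sample size for which the exact sign-flip null is used.
EXACT_CROSSOVER = 25


@dataclass(frozen=True)
class LabelMetrics:
    """Confusion counts and derived metrics for one label."""

    label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool  # a zero denominator forced the 0 convention

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MacroReport:
    """Unweighted means of the per-label metrics."""

    m_precision: float
    m_recall: float
    m_f1: float
    n_labels: int

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def label_confusion(
    Y_true: np.ndarray, Y_pred: np.ndarray, labels: Sequence[str] | None = None
) -> list[LabelMetrics]:
    """Per-label confusion counts and precision/recall/F1.

    Each label column is scored independently.  Precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 their harmonic mean; a zero denominator gives 0
    and sets the ``degenerate`` flag.
    """
    Y_true = np.asarray(Y_true)
    Y_pred = np.asarray(Y_pred)
    if Y_true.shape != Y_pred.shape:
        raise DataError(f"shape mismatch: {Y_true.shape} vs {Y_pred.shape}")
    if Y_true.ndim == 1:
        Y_true = Y_true[:, None]
        Y_pred = Y_pred[:, None]
    L = Y_true.shape[1]
    names = list(labels) if labels is not None else [str(i) for i in range(L)]
    if len(names) != L:
        raise DataError(f"{L} label columns but {len(names)} label names")
    out = []
    for j, name in enumerate(names):
        t = Y_true[:, j].astype(bool)
        p = Y_pred[:, j].astype(bool)
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        prec, d1 = _safe_div(tp, tp + fp)
        rec, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * prec * rec, prec + rec)
        out.append(
            LabelMetrics(
                label=name, tp=tp, fp=fp, fn=fn,
                precision=prec, recall=rec, f1=f1,
                degenerate=d1 or d2 or d3,
            )
        )
    return out


def macro_metrics(per_label: Sequence[LabelMetrics]) -> MacroReport:
    """mPrecision / mRecall / mF1: unweighted arithmetic means over all labels,
    degenerate labels included."""
    if len(per_label) == 0:
        raise DataError("macro metrics need at least one label")
    return MacroReport(
        m_precision=float(np.mean([m.precision for m in per_label])),
        m_recall=float(np.mean([m.recall for m in per_label])),
        m_f1=float(np.mean([m.f1 for m in per_label])),
        n_labels=len(per_label),
    )


def evaluate(
    Y_true: np.ndarray, Y_pred: np.ndarray, labels: Sequence[str] | None = None
) -> dict:
    """Full metrics report: per-label block plus macro block, JSON-ready."""
    per = label_confusion(Y_true, Y_pred, labels)
    macro = macro_metrics(per)
    return {"per_label": [m.to_dict() for m in per], "macro": macro.to_dict()}


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WSRResult:
    """Outcome of a Wilcoxon signed-rank comparison of two models."""

    w_plus: float
    w_minus: float
    w: float
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal_approx"
    sidedness: str = "two_sided"
    all_zero: bool = False  # every paired difference was zero

    def to_dict(self) -> dict:
        return asdict(self)


def _exact_cdf_leq(ranks2: np.ndarray, w2: int) -> float:
    """P(2·W⁺ ≤ w2) under the sign-flip null, by dynamic programming.

    Ranks are doubled so tie-averaged (half-integer) ranks become integers.
    Each of the 2^n sign assignments is equally likely; the DP accumulates
    the distribution of the doubled positive-rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = min(w2, total)
    return float(counts[: w2 + 1].sum())


def wsr_test(m1: Sequence[float], m2: Sequence[float]) -> WSRResult:
    """Wilcoxon signed-rank test on paired per-label metric values.

    Zero differences are dropped; ties in |d| get average ranks.  Exact
    two-sided p by sign-flip enumeration for n_effective ≤ 25, otherwise a
    normal approximation with continuity and tie corrections.  When every
    difference is zero the result is p = 1 with the ``all_zero`` flag set
    (no error).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise DataError(f"shape mismatch: {m1.shape} vs {m2.shape}")
    if m1.ndim != 1 or m1.size < 1:
        raise DataError("inputs must be 1-D with at least one pair")
    d = m1 - m2
    nz = d != 0
    d = d[nz]
    n = int(d.size)
    if n == 0:
        return WSRResult(0.0, 0.0, 0.0, 0, 1.0, "exact", all_zero=True)
    ranks = rankdata(np.abs(d))  # average ranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= EXACT_CROSSOVER:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = min(1.0, 2.0 * _exact_cdf_leq(ranks2, int(round(2 * w))))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: each group of t tied |d| values reduces the variance
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        z = (w - mu + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.cdf(z)))
        method = "normal_approx"
    return WSRResult(w_plus, w_minus, w, n, max(p, np.finfo(float).tiny), method)


def wsr_cv_test(metrics_A: np.ndarray, metrics_B: np.ndarray) -> WSRResult:
    """Cross-validation variant: pool differences over all (label, fold) pairs,
    then run the identical signed-rank procedure."""
    A = np.asarray(metrics_A, dtype=float)
    B = np.asarray(metrics_B, dtype=float)
    if A.shape != B.shape:
        raise DataError(f"shape mismatch: {A.shape} vs {B.shape}")
    return wsr_test(A.ravel(), B.ravel())
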