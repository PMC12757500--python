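"""Discrimination, calibration and group-fairness metrics.

Everything here operates on out-of-fold predicted risks.  Discrimination is
the Mann-Whitney AUC (ties counted one half) with DeLong variance for tests
and confidence intervals.  Calibration covers calibration-in-the-large
(mean predicted minus observed, in percentage points; negative means
under-prediction), the logistic recalibration slope, expected calibration
error over equal-frequency bins, the Brier score, and reliability bins for
plotting.  Group fairness at an operating threshold (default 30% five-year
risk) is summarized through confusion counts, TPR / FPR / PPV / flag-rate,
their Black-White gaps (statistical parity, equalized odds, predictive
parity), Pearson chi-square tests for rate differences, and DeLong's test
for AUC differences.  Flagging uses the boundary-inclusive convention
``score >= threshold`` throughout, including decision-curve analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "GroupMetrics",
    "ReliabilityBin",
    "CalibrationReport",
    "FairnessGaps",
    "auc",
    "auc_ci",
    "delong_auc_difference",
    "brier",
    "reliability_bins",
    "calibration_in_the_large",
    "calibration_slope",
    "ece",
    "confusion_at_threshold",
    "classification_rates",
    "fairness_gaps",
    "chi2_2x2",
    "threshold_sweep",
    "calibration_report",
]


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel().astype(int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    return s, y


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted half.

    Rank-based, O(n log n); equals the brute-force mean over all
    positive-negative pairs.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # midranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(scores, labels):
    """DeLong structural components; returns (auc, V10, V01)."""
    s, y = _check_scores_labels(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = all_ranks[:m], all_ranks[m:]
    a = float((pos_ranks.sum() - m * (m + 1) / 2) / (m * n))
    v10 = (pos_ranks - rankdata(pos)) / n          # per-positive placement
    v01 = 1.0 - (neg_ranks - rankdata(neg)) / m    # per-negative placement
    return a, v10, v01


def auc_variance(scores, labels) -> float:
    """DeLong variance estimate of the AUC."""
    a, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95):
    """AUC with a DeLong normal-approximation confidence interval."""
    a = auc(scores, labels)
    se = math.sqrt(auc_variance(scores, labels))
    zq = norm.ppf(0.5 + level / 2)
    return a, max(a - zq * se, 0.0), min(a + zq * se, 1.0)


def delong_auc_difference(scores_g1, labels_g1, scores_g2, labels_g2):
    """DeLong test for the AUC difference between two disjoint groups.

    The groups are independent samples (e.g. Black vs White patients), so the
    z statistic divides the AUC difference by the root of the summed DeLong
    variances.  Returns ``(z, two_sided_p)``; swapping the groups flips the
    sign of z and leaves p unchanged.
    """
    a1 = auc(scores_g1, labels_g1)
    a2 = auc(scores_g2, labels_g2)
    var = auc_variance(scores_g1, labels_g1) + auc_variance(scores_g2, labels_g2)
    if var <= 0:
        raise ValueError("degenerate groups: zero AUC variance")
    z = (a1 - a2) / math.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def brier(scores, labels) -> float:
    """Mean squared error of the predicted probabilities."""
    s, y = _check_scores_labels(scores, labels)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean((s - y) ** 2))


@dataclass
class ReliabilityBin:
    """One equal-frequency reliability bin."""

    index: int
    n: int
    mean_predicted: float
    observed_rate: float


def reliability_bins(scores, labels, n_bins: int = 10, ids=None):
    """Equal-frequency reliability bins (risk deciles by default).

    Ties are broken by a stable sort on (score, id); bin sizes differ by at
    most one and sum to n.
    """
    s, y = _check_scores_labels(scores, labels)
    if s.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} points, got {s.size}")
    tie_break = np.arange(s.size) if ids is None else np.asarray(ids)
    order = np.lexsort((tie_break, s))  # stable: score first, then id
    chunks = np.array_split(order, n_bins)
    return [
        ReliabilityBin(
            index=i,
            n=len(chunk),
            mean_predicted=float(s[chunk].mean()),
            observed_rate=float(y[chunk].mean()),
        )
        for i, chunk in enumerate(chunks)
    ]


def calibration_in_the_large(scores, labels) -> float:
    """Mean predicted risk minus observed event rate, in percentage points.

    Negative values mean the model under-predicts risk for this group.
    """
    s, y = _check_scores_labels(scores, labels)
    return float(100.0 * (s.mean() - y.mean()))


def calibration_slope(scores, labels, level: float = 0.95):
    """Logistic recalibration slope with a Wald confidence interval.

    Fits outcome ~ intercept + slope * logit(score) by maximum likelihood
    (IRLS, convergence tolerance 1e-8); the CI comes from the observed
    information.  A slope of 1 is ideal; < 1 indicates overfitted /
    too-extreme predictions.  Returns ``(slope, lo, hi)``.
    """
    s, y = _check_scores_labels(scores, labels)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("scores must lie strictly inside (0, 1)")
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    x = logit(s)
    if np.ptp(x) < 1e-12:
        raise ValueError("constant scores: calibration slope unidentifiable")
    design = sm.add_constant(x)
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(tol=1e-8)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    zq = norm.ppf(0.5 + level / 2)
    return slope, slope - zq * se, slope + zq * se


def ece(bins) -> float:
    """Expected calibration error over reliability bins.

    Frequency-weighted mean absolute gap between bin-wise observed and
    predicted rates; zero iff every bin sits on the diagonal.
    """
    bins = list(bins)
    if not bins:
        raise ValueError("bins must be non-empty")
    total = sum(b.n for b in bins)
    return float(
        sum(b.n * abs(b.observed_rate - b.mean_predicted) for b in bins) / total
    )


@dataclass
class CalibrationReport:
    """Calibration summary for one (model, group) pair."""

    citl_pp: float
    slope: float
    slope_ci: tuple
    ece: float
    brier: float
    bins: list = field(default_factory=list)
    n: int = 0


def calibration_report(scores, labels, n_bins: int = 10, folds=None,
                       ids=None) -> CalibrationReport:
    """Full calibration report for one (model, group) pair.

    When fold labels are given, calibration-in-the-large, slope and ECE are
    computed within each cross-validation fold and averaged (the slope CI is
    then a normal interval from the between-fold spread); reliability bins
    and the Brier score are computed on the pooled out-of-fold predictions.
    """
    s, y = _check_scores_labels(scores, labels)
    bins = reliability_bins(s, y, n_bins=n_bins, ids=ids)
    if folds is None:
        citl = calibration_in_the_large(s, y)
        slope, lo, hi = calibration_slope(s, y)
        e = ece(bins)
    else:
        f = np.asarray(folds)
        citls, slopes, eces = [], [], []
        for fold in np.unique(f):
            mask = f == fold
            citls.append(calibration_in_the_large(s[mask], y[mask]))
            slopes.append(calibration_slope(s[mask], y[mask])[0])
            eces.append(ece(reliability_bins(s[mask], y[mask], n_bins=n_bins)))
        citl, e = float(np.mean(citls)), float(np.mean(eces))
        slope = float(np.mean(slopes))
        kf = len(slopes)
        se = float(np.std(slopes, ddof=1) / math.sqrt(kf)) if kf > 1 else 0.0
        lo, hi = slope - 1.96 * se, slope + 1.96 * se
    return CalibrationReport(
        citl_pp=citl, slope=slope, slope_ci=(lo, hi), ece=e,
        brier=brier(s, y), bins=bins, n=s.size,
    )


# ---------------------------------------------------------------------------
# Classification at a threshold
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN at one threshold, for one group or overall."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    group: str | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("total count must be positive")


@dataclass
class GroupMetrics:
    """Classification rates for one group at one threshold (fractions).

    ``ppv`` is ``None`` when no patient was flagged (undefined, never
    silently zero).
    """

    tpr: float | None
    fpr: float | None
    ppv: float | None
    flag_rate: float
    threshold: float
    counts: ConfusionCounts | None = None
    group: str | None = None


def confusion_at_threshold(scores, labels, p_t: float,
                           group: str | None = None) -> ConfusionCounts:
    """Confusion counts flagging ``score >= p_t`` (boundary inclusive)."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    s, y = _check_scores_labels(scores, labels)
    flagged = s >= p_t
    return ConfusionCounts(
        tp=int((flagged & (y == 1)).sum()),
        fp=int((flagged & (y == 0)).sum()),
        tn=int((~flagged & (y == 0)).sum()),
        fn=int((~flagged & (y == 1)).sum()),
        threshold=p_t,
        group=group,
    )


def classification_rates(counts: ConfusionCounts) -> GroupMetrics:
    """TPR / FPR / PPV / flag-rate from confusion counts.

    Zero denominators yield explicit ``None`` markers rather than exceptions.
    """
    pos = counts.tp + counts.fn
    neg = counts.fp + counts.tn
    flagged = counts.tp + counts.fp
    return GroupMetrics(
        tpr=counts.tp / pos if pos > 0 else None,
        fpr=counts.fp / neg if neg > 0 else None,
        ppv=counts.tp / flagged if flagged > 0 else None,
        flag_rate=flagged / counts.n,
        threshold=counts.threshold,
        counts=counts,
        group=counts.group,
    )


@dataclass
class FairnessGaps:
    """Black minus White differences, in percentage points.

    ``tpr_gap_pp`` / ``fpr_gap_pp`` are the equalized-odds gaps,
    ``ppv_gap_pp`` the predictive-parity gap (``None`` when PPV is undefined
    in either group), ``flag_rate_gap_pp`` statistical parity, and
    ``auc_gap`` the per-group AUC difference on its natural scale.
    """

    tpr_gap_pp: float | None
    fpr_gap_pp: float | None
    ppv_gap_pp: float | None
    flag_rate_gap_pp: float
    threshold: float
    auc_gap: float | None = None
    delong_z: float | None = None
    delong_p: float | None = None
    chi2_event_rate: float | None = None
    chi2_event_rate_p: float | None = None


def fairness_gaps(metrics_black: GroupMetrics, metrics_white: GroupMetrics,
                  aucs: tuple | None = None,
                  delong: tuple | None = None,
                  event_chi2: tuple | None = None) -> FairnessGaps:
    """Elementwise Black-White metric gaps at a common threshold."""
    if abs(metrics_black.threshold - metrics_white.threshold) > 1e-12:
        raise ValueError(
            "group metrics were computed at different thresholds: "
            f"{metrics_black.threshold} vs {metrics_white.threshold}"
        )

    def gap(a, b):
        return None if a is None or b is None else 100.0 * (a - b)

    return FairnessGaps(
        tpr_gap_pp=gap(metrics_black.tpr, metrics_white.tpr),
        fpr_gap_pp=gap(metrics_black.fpr, metrics_white.fpr),
        ppv_gap_pp=gap(metrics_black.ppv, metrics_white.ppv),
        flag_rate_gap_pp=100.0 * (metrics_black.flag_rate - metrics_white.flag_rate),
        threshold=metrics_black.threshold,
        auc_gap=None if aucs is None else float(aucs[0] - aucs[1]),
        delong_z=None if delong is None else delong[0],
        delong_p=None if delong is None else delong[1],
        chi2_event_rate=None if event_chi2 is None else event_chi2[0],
        chi2_event_rate_p=None if event_chi2 is None else event_chi2[1],
    )


def chi2_2x2(counts_a, counts_b):
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table.

    ``counts_a`` / ``counts_b`` are ``(events, non_events)`` per group.
    Symmetric in group order.
    """
    table = np.asarray([counts_a, counts_b], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in the 2x2 table")
    expected = np.outer(row, col) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def threshold_sweep(scores, labels, groups, grid) -> pd.DataFrame:
    """Per-group classification rates across a grid of thresholds.

    Returns a tidy frame (group, threshold, tpr, fpr, ppv, flag_rate); TPR
    and FPR are non-increasing in the threshold.
    """
    s, y = _check_scores_labels(scores, labels)
    g = np.asarray(groups)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    rows = []
    for group in np.unique(g):
        mask = g == group
        for p_t in grid:
            metrics = classification_rates(
                confusion_at_threshold(s[mask], y[mask], float(p_t), group=str(group))
            )
            rows.append({
                "group": group,
                "threshold": float(p_t),
                "tpr": metrics.tpr,
                "fpr": metrics.fpr,
                "ppv": metrics.ppv,
                "flag_rate": metrics.flag_rate,
            })
    return pd.DataFrame(rows)
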