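"""Metric implementations against independent oracles and printed counts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from ckdfair import (
    ConfusionCounts,
    auc,
    brier,
    calibration_in_the_large,
    calibration_report,
    calibration_slope,
    chi2_2x2,
    classification_rates,
    confusion_at_threshold,
    delong_auc_difference,
    ece,
    fairness_gaps,
    reliability_bins,
    threshold_sweep,
)
from ckdfair.fairness_eval import auc_variance


def _auc_bruteforce(scores, labels):
    """All-pairs oracle: ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_half(self):
        assert auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_all_pairs_oracle(self, data):
        n = data.draw(st.integers(min_value=4, max_value=60))
        scores = data.draw(
            st.lists(st.sampled_from([0.1, 0.2, 0.2, 0.5, 0.7, 0.9]),
                     min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12
        )


class TestDelong:
    def test_identical_groups_give_zero_z(self):
        s = [0.2, 0.6, 0.4, 0.8, 0.5, 0.3]
        y = [0, 0, 1, 1, 0, 1]
        z, p = delong_auc_difference(s, y, s, y)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(2)
        s1, y1 = rng.uniform(size=50), rng.integers(0, 2, 50)
        s2, y2 = rng.uniform(size=60), rng.integers(0, 2, 60)
        z12, p12 = delong_auc_difference(s1, y1, s2, y2)
        z21, p21 = delong_auc_difference(s2, y2, s1, y1)
        assert z12 == pytest.approx(-z21)
        assert p12 == pytest.approx(p21)

    def test_variance_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.integers(0, 2, n)
        s = np.clip(0.3 * y + rng.normal(0.4, 0.25, n), 0, 1)
        v_delong = auc_variance(s, y)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            boot.append(auc(s[idx], y[idx]))
        v_boot = np.var(boot, ddof=1)
        assert abs(v_delong - v_boot) / v_boot < 0.15


class TestBrier:
    def test_perfect_predictions(self):
        assert brier([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 4, [0, 1, 0, 1]) == 0.25

    def test_hand_arithmetic(self):
        assert brier([0.8, 0.2], [1, 0]) == pytest.approx(0.04)


class TestReliabilityAndEce:
    def test_equal_frequency_bins(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=100)
        y = rng.integers(0, 2, 100)
        bins = reliability_bins(s, y, 10)
        assert [b.n for b in bins] == [10] * 10
        assert sum(b.n for b in bins) == 100

    def test_calibrated_bins_on_diagonal(self):
        # score exactly equals each bin's event rate
        s = np.repeat([0.2, 0.6], 10)
        y = np.concatenate([[1, 0, 0, 0, 0] * 2, [1, 1, 1, 0, 0] * 2])
        bins = reliability_bins(s, y, 2)
        for b in bins:
            assert b.observed_rate == pytest.approx(b.mean_predicted)
        assert ece(bins) == pytest.approx(0.0, abs=1e-12)

    def test_ece_hand_arithmetic(self):
        s = np.repeat([0.2, 0.6], 10)
        y = np.concatenate([
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],   # observed 0.3 vs predicted 0.2
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],   # observed 0.5 vs predicted 0.6
        ])
        bins = reliability_bins(s, y, 2)
        # equal-weight bins with |gap| 0.1 each
        assert ece(bins) == pytest.approx(0.1)

    def test_two_equal_bins_weighted_mean(self):
        from ckdfair import ReliabilityBin
        bins = [
            ReliabilityBin(0, 50, 0.2, 0.3),
            ReliabilityBin(1, 50, 0.6, 0.5),
        ]
        assert ece(bins) == pytest.approx(0.1)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="n_bins"):
            reliability_bins([0.5] * 5, [1] * 5, 10)

    def test_empty_bins_raise(self):
        with pytest.raises(ValueError, match="non-empty"):
            ece([])


class TestCalibrationInTheLarge:
    def test_printed_pooled_black_means(self):
        # mean predicted 30.7% vs observed 34.5% -> -3.8 pp exactly
        scores = np.full(1000, 0.307)
        labels = np.concatenate([np.ones(345), np.zeros(655)])
        assert calibration_in_the_large(scores, labels) == pytest.approx(-3.8)

    def test_matched_means_give_zero(self):
        scores = np.array([0.2, 0.4])
        labels = np.array([0, 1])  # mean 0.5? no: use matching means
        scores = np.array([0.5, 0.5])
        assert calibration_in_the_large(scores, labels) == pytest.approx(0.0)

    def test_printed_pooled_white_means(self):
        scores = np.full(1000, 0.218)
        labels = np.concatenate([np.ones(183), np.zeros(817)])
        assert calibration_in_the_large(scores, labels) == pytest.approx(3.5)


class TestCalibrationSlope:
    def test_recovers_unit_slope_on_bernoulli_scores(self):
        rng = np.random.default_rng(11)
        s = rng.uniform(0.02, 0.95, 20_000)
        y = rng.uniform(size=s.size) < s
        slope, lo, hi = calibration_slope(s, y.astype(int))
        assert slope == pytest.approx(1.0, abs=0.05)
        assert lo < 1.0 < hi

    def test_doubled_logits_give_half_slope(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(0.05, 0.95, 20_000)
        y = (rng.uniform(size=base.size) < base).astype(int)
        logits = np.log(base / (1 - base))
        s_overconfident = expit(2.0 * logits)
        slope, _, _ = calibration_slope(s_overconfident, y)
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_constant_scores_raise(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_slope([0.3] * 20, [0, 1] * 10)


class TestClassificationRates:
    def test_boundary_inclusive_flagging(self):
        counts = confusion_at_threshold([0.2, 0.3, 0.35], [0, 1, 1], 0.3)
        assert counts.tp + counts.fp == 2

    def test_threshold_above_max_flags_none(self):
        counts = confusion_at_threshold([0.2, 0.3], [1, 0], 0.9)
        assert counts.tp == 0 and counts.fp == 0
        assert classification_rates(counts).ppv is None

    def test_complement_identity(self):
        rng = np.random.default_rng(3)
        s, y = rng.uniform(size=50), rng.integers(0, 2, 50)
        c = confusion_at_threshold(s, y, 0.4)
        assert c.fn == y.sum() - c.tp
        assert c.tn == (1 - y).sum() - c.fp

    def test_printed_modular_confusion_counts(self):
        # Black modular: 510 TP of 840 events; 365 FP of 2,160 non-events;
        # White modular: 294/900 and 144/3,600.
        black = classification_rates(
            ConfusionCounts(tp=510, fn=330, fp=365, tn=1795, threshold=0.30)
        )
        white = classification_rates(
            ConfusionCounts(tp=294, fn=606, fp=144, tn=3456, threshold=0.30)
        )
        assert round(100 * black.tpr, 1) == 60.7
        assert round(100 * white.tpr, 1) == 32.7
        assert round(100 * black.fpr, 1) == 16.9
        assert round(100 * white.fpr, 1) == 4.0
        gaps = fairness_gaps(black, white, aucs=(0.794, 0.821))
        assert gaps.fpr_gap_pp == pytest.approx(16.9 - 4.0, abs=0.05)

    def test_pooled_tpr_gap(self):
        # pooled TPR 52.4% (Black) vs 46.3% (White) -> +6.1 pp
        black = classification_rates(
            ConfusionCounts(tp=440, fn=400, fp=460, tn=1700, threshold=0.30)
        )
        white = classification_rates(
            ConfusionCounts(tp=417, fn=483, fp=256, tn=3344, threshold=0.30)
        )
        assert round(100 * black.tpr, 1) == 52.4
        assert round(100 * white.tpr, 1) == 46.3
        gaps = fairness_gaps(black, white)
        assert gaps.tpr_gap_pp == pytest.approx(6.1, abs=0.1)

    def test_identical_metrics_zero_gaps(self):
        m = classification_rates(
            ConfusionCounts(tp=10, fp=5, tn=80, fn=5, threshold=0.3)
        )
        gaps = fairness_gaps(m, m)
        assert gaps.tpr_gap_pp == 0 and gaps.fpr_gap_pp == 0
        assert gaps.ppv_gap_pp == 0 and gaps.flag_rate_gap_pp == 0

    def test_threshold_mismatch_raises(self):
        a = classification_rates(ConfusionCounts(1, 1, 1, 1, threshold=0.3))
        b = classification_rates(ConfusionCounts(1, 1, 1, 1, threshold=0.2))
        with pytest.raises(ValueError, match="threshold"):
            fairness_gaps(a, b)


class TestChi2:
    def test_printed_event_rate_comparison(self):
        # Black 840/2,160 vs White 900/3,600
        stat, p = chi2_2x2((840, 2160), (900, 3600))
        assert stat == pytest.approx(64.65, abs=0.05)
        assert p < 0.01

    def test_equal_rates_zero_statistic(self):
        stat, _ = chi2_2x2((30, 70), (60, 140))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_group_order(self):
        a, b = (25, 75), (40, 160)
        assert chi2_2x2(a, b)[0] == pytest.approx(chi2_2x2(b, a)[0])

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_2x2((0, 0), (10, 20))


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.2, 0.8, 100)
        y = rng.integers(0, 2, 100)
        g = np.array(["Black"] * 50 + ["White"] * 50)
        sweep = threshold_sweep(s, y, g, [0.01, 0.99])
        lo = sweep[sweep["threshold"] == 0.01]
        hi = sweep[sweep["threshold"] == 0.99]
        assert (lo["tpr"] == 1.0).all() and (lo["fpr"] == 1.0).all()
        assert (hi["flag_rate"] == 0.0).all()

    def test_monotone_against_bruteforce(self):
        rng = np.random.default_rng(5)
        n = 200
        s = rng.uniform(size=n)
        y = rng.integers(0, 2, n)
        g = np.array(["A"] * n)
        grid = np.linspace(0.05, 0.95, 19)
        sweep = threshold_sweep(s, y, g, grid)
        # brute-force recomputation and monotonicity
        for _, row in sweep.iterrows():
            flagged = s >= row["threshold"]
            assert row["tpr"] == pytest.approx(
                (flagged & (y == 1)).sum() / (y == 1).sum()
            )
        assert (np.diff(sweep["tpr"]) <= 1e-12).all()
        assert (np.diff(sweep["fpr"]) <= 1e-12).all()


class TestCalibrationReport:
    def test_fold_averaged_close_to_pooled_on_homogeneous_data(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0.05, 0.9, 4000)
        y = (rng.uniform(size=4000) < s).astype(int)
        folds = np.repeat(np.arange(5), 800)
        pooled = calibration_report(s, y)
        averaged = calibration_report(s, y, folds=folds)
        assert averaged.citl_pp == pytest.approx(pooled.citl_pp, abs=0.5)
        assert averaged.slope == pytest.approx(pooled.slope, abs=0.1)
        assert pooled.ece < 0.03  # calibrated by construction
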