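"""Distributional statistics, random intercepts, and the three feature spaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ptsdgps.features as fe
from ptsdgps.synthetic import CohortConfig, generate_cohort


class TestSlopeAndRmssd:
    @pytest.mark.parametrize(
        "values,days,expected",
        [([5, 5, 5], [1, 2, 3], 0.0), ([0, 1, 2], [1, 2, 3], 1.0), ([1, 2, 4], [1, 2, 3], 1.5)],
    )
    def test_slope(self, values, days, expected):
        assert fe.slope(values, days) == pytest.approx(expected)

    def test_slope_degenerate_indices(self):
        assert fe.slope([1.0, 2.0], [3, 3]) == 0.0

    @pytest.mark.parametrize(
        "values,expected",
        [([3, 3, 3, 3], 0.0), ([1, 2, 4], np.sqrt(2.5)), ([7.0, 7.0 - 4.2], 4.2)],
    )
    def test_rmssd(self, values, expected):
        assert fe.rmssd(values) == pytest.approx(expected)

    def test_translation_invariance_scale_equivariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=6)
        d = np.arange(1, 7)
        assert fe.rmssd(y + 10.0) == pytest.approx(fe.rmssd(y))
        assert np.var(y + 10.0, ddof=1) == pytest.approx(np.var(y, ddof=1))
        assert fe.slope(3.0 * y, d) == pytest.approx(3.0 * fe.slope(y, d))


def quantile_oracle(values, q):
    """Linear interpolation between order statistics (type-7), from scratch."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestSummarizeSeries:
    def test_constant_series(self):
        s = fe.summarize_series([0.7] * 5)
        d = s.to_dict()
        assert len(d) == 15
        for name in ["mean", "median"] + fe.QUANTILE_NAMES:
            assert d[name] == pytest.approx(0.7)
        assert s.variance == s.slope == s.rmssd == 0.0

    def test_quantiles_match_oracle(self):
        s = fe.summarize_series([1, 2, 4], [1, 2, 3]).to_dict()
        for q, name in zip(fe.QUANTILE_GRID, fe.QUANTILE_NAMES):
            assert s[name] == pytest.approx(quantile_oracle([1, 2, 4], q))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fe.summarize_series([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=9))
    @settings(max_examples=1000, deadline=None)
    def test_quantile_monotonicity(self, values):
        s = fe.summarize_series(values).to_dict()
        qs = [s[name] for name in fe.QUANTILE_NAMES]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert s["variance"] >= 0 and s["rmssd"] >= 0


def balanced_blup_oracle(y_by_group):
    """Closed-form REML BLUPs for a balanced one-way random-effects layout.

    For a groups of n observations each, the REML variance components are the
    ANOVA estimators sigma2 = MSW, tau2 = (MSB - MSW)/n, and the BLUP is
    shrinkage n*tau2/(n*tau2 + sigma2) times the centered group mean.
    """
    a = len(y_by_group)
    n = len(y_by_group[0])
    means = np.array([np.mean(g) for g in y_by_group])
    grand = means.mean()
    ssw = sum(((np.asarray(g) - m) ** 2).sum() for g, m in zip(y_by_group, means))
    msw = ssw / (a * (n - 1))
    msb = n * ((means - grand) ** 2).sum() / (a - 1)
    tau2 = max(0.0, (msb - msw) / n)
    shrink = n * tau2 / (n * tau2 + msw)
    return shrink * (means - grand)


class TestRandomIntercepts:
    def _stack(self, y_by_group, col="dma_minutes"):
        rows = []
        for i, g in enumerate(y_by_group):
            for d, v in enumerate(g, start=1):
                rows.append((f"S{i:03d}", d, False, v, v))
        return pd.DataFrame(
            rows, columns=["subject_id", "day_index", "is_weekend", "dma_minutes", "mdr_km"]
        )

    def test_matches_closed_form_balanced_oracle(self):
        rng = np.random.default_rng(4)
        y = [list(rng.normal(5.0 * i, 1.0, size=5)) for i in range(8)]
        stacked = self._stack(y)
        got = fe.random_intercepts(stacked, "DMA")
        expected = balanced_blup_oracle(y)
        assert np.allclose(got.to_numpy(), expected, atol=1e-6)

    def test_zero_between_variance_shrinks_to_zero(self):
        # identical subject means: between-subject variance estimated ~0
        base = [1.0, 2.0, 3.0, 4.0]
        y = [base, base[::-1], [2.0, 1.0, 4.0, 3.0], [3.0, 4.0, 1.0, 2.0]]
        got = fe.random_intercepts(self._stack(y), "DMA")
        assert np.allclose(got.to_numpy(), 0.0, atol=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        y = [list(rng.normal(3.0 * i, 1.0, size=4)) for i in range(6)]
        shifted = [[v + 100.0 for v in g] for g in y]
        a = fe.random_intercepts(self._stack(y), "DMA")
        b = fe.random_intercepts(self._stack(shifted), "DMA")
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)


class TestToWide:
    def test_counts(self, small_cohort):
        stacked, _ = small_cohort
        wide = fe.to_wide(stacked)
        assert list(wide.columns) == fe.WIDE_COLUMNS
        assert len(wide) == stacked["subject_id"].nunique()

    def test_missing_cell_count(self):
        stacked = pd.DataFrame(
            {
                "subject_id": ["A"] * 3,
                "day_index": [1, 2, 3],
                "is_weekend": [False] * 3,
                "dma_minutes": [10.0, 20.0, 30.0],
                "mdr_km": [1.0, 2.0, 3.0],
            }
        )
        wide = fe.to_wide(stacked)
        assert wide.isna().sum().sum() == 8  # 2 variables x 4 unobserved days

    def test_duplicate_day_errors(self):
        stacked = pd.DataFrame(
            {
                "subject_id": ["A", "A"],
                "day_index": [1, 1],
                "is_weekend": [False, False],
                "dma_minutes": [1.0, 2.0],
                "mdr_km": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            fe.to_wide(stacked)

    def test_empty_table(self):
        assert list(fe.to_wide(pd.DataFrame(columns=fe.WIDE_COLUMNS)).columns) == fe.WIDE_COLUMNS


class TestArm3:
    def test_feature_count_and_summary_consistency(self, small_cohort):
        stacked, _ = small_cohort
        arm3 = fe.engineer_arm3(stacked)
        assert arm3.shape[1] == 39
        # the 15-summary block must equal summarize_series applied per subject
        sid = arm3.index[0]
        grp = stacked[stacked["subject_id"] == sid].sort_values("day_index")
        s = fe.summarize_series(grp["mdr_km"].to_numpy(), grp["day_index"].to_numpy()).to_dict()
        for name, val in s.items():
            assert arm3.loc[sid, f"arm3_mdr_{name}"] == pytest.approx(val)
        pct = arm3["arm3_weekend_away_pct"].dropna()
        assert pct.between(0, 100).all()

    def test_constant_subject(self):
        stacked = pd.DataFrame(
            {
                "subject_id": ["A"] * 4 + ["B"] * 4,
                "day_index": [1, 2, 6, 7] * 2,
                "is_weekend": [False, False, True, True] * 2,
                "dma_minutes": [100.0] * 4 + [200.0] * 4,
                "mdr_km": [2.0] * 4 + [3.0] * 4,
            }
        )
        arm3 = fe.engineer_arm3(stacked)
        row = arm3.loc["A"]
        assert row["arm3_mdr_variance"] == row["arm3_mdr_slope"] == row["arm3_mdr_rmssd"] == 0.0
        assert row["arm3_mdr_weekday_weekend_ratio"] == pytest.approx(1.0)
        assert row["arm3_mdr_max_weekend_minus_max_weekday"] == pytest.approx(0.0)
        # 2 weekend days at 100 + 2 weekdays at 100 -> half the time away is weekend
        assert row["arm3_weekend_away_pct"] == pytest.approx(50.0)


class TestPredictionFeatures:
    def test_count_and_oracle(self):
        probs = pd.DataFrame(
            {"subject_id": ["A"] * 3, "day_index": [1, 2, 3], "prob_group1": [0.2, 0.4, 0.9]}
        )
        out = fe.engineer_prediction_features(probs)
        assert out.shape == (1, 15)
        oracle = fe.summarize_series([0.2, 0.4, 0.9], [1, 2, 3]).to_dict()
        for name, val in oracle.items():
            assert out.loc["A", f"pred_{name}"] == pytest.approx(val)

    def test_constant_probability(self):
        probs = pd.DataFrame(
            {"subject_id": ["A"] * 4, "day_index": [1, 2, 3, 4], "prob_group1": [0.5] * 4}
        )
        out = fe.engineer_prediction_features(probs)
        assert out.loc["A", "pred_mean"] == pytest.approx(0.5)
        assert out.loc["A", "pred_variance"] == 0.0

    def test_out_of_range_probability_errors(self):
        probs = pd.DataFrame({"subject_id": ["A"], "day_index": [1], "prob_group1": [1.2]})
        with pytest.raises(ValueError):
            fe.engineer_prediction_features(probs)


class TestImputeStandardize:
    def test_standardize_two_point_column(self):
        train = pd.DataFrame({"x": [2.0, 4.0]})
        stats = fe.ScalingStats.fit(train)
        z = fe.standardize(train, stats)
        assert np.allclose(z["x"], [-0.70710678, 0.70710678])

    def test_constant_column_maps_to_zero(self):
        train = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        stats = fe.ScalingStats.fit(train)
        assert (fe.standardize(train, stats)["x"] == 0.0).all()

    def test_impute_uses_training_means_only(self):
        train = pd.DataFrame({"x": [1.0, 3.0]})
        stats = fe.ScalingStats.fit(train)
        test = pd.DataFrame({"x": [np.nan, 10.0]})
        out = fe.impute_column_means(test, stats)
        assert out["x"].tolist() == [2.0, 10.0]
        # imputed column mean is the stated mix of observed and training means
        assert out["x"].mean() == pytest.approx((2.0 + 10.0) / 2)

    def test_entirely_missing_training_column_errors(self):
        with pytest.raises(ValueError, match="missing"):
            fe.ScalingStats.fit(pd.DataFrame({"x": [np.nan, np.nan]}))


def test_feature_counts_on_generated_cohort():
    stacked, _ = generate_cohort(CohortConfig(n_group1=6, n_group2=3, seed=2))
    assert fe.to_wide(stacked).shape[1] == 14
    assert fe.engineer_arm3(stacked).shape[1] == 39
    probs = stacked[["subject_id", "day_index"]].assign(prob_group1=0.5)
    assert fe.engineer_prediction_features(probs).shape[1] == 15
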