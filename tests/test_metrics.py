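"""Evaluation statistics: R^2 / RMSE / RPD, bias & SEP, intervals,
interpretation bands, ANOVA + Tukey, residual diagnostics."""

import numpy as np
import pytest
from scipy import stats

from tanninspec.metrics import (
    PredictionSet,
    anova_tukey,
    bias_and_sep,
    confidence_intervals,
    evaluate,
    interpret,
    r_squared,
    residual_summary,
    rmse,
    rpd_from_r2,
)


class TestRSquared:
    def test_perfect_predictions(self):
        ps = PredictionSet(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r_squared(ps) == 1.0

    def test_constant_prediction_at_mean_scores_zero(self):
        y = np.array([1.0, 2, 3, 4])
        ps = PredictionSet(y, np.full(4, y.mean()))
        assert r_squared(ps) == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic(self):
        ps = PredictionSet(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert r_squared(ps) == pytest.approx(0.5, abs=1e-15)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(PredictionSet(np.ones(3), np.array([1.0, 2, 3])))


class TestRMSE:
    def test_identical_vectors(self):
        assert rmse(PredictionSet(np.arange(3.0), np.arange(3.0))) == 0.0

    def test_unit_residuals(self):
        ps = PredictionSet(np.array([0.0, 0.0]), np.array([1.0, -1.0]))
        assert rmse(ps) == pytest.approx(1.0, abs=1e-15)

    def test_matches_stepwise_definition(self):
        rng = np.random.default_rng(0)
        y, yp = rng.uniform(size=10), rng.uniform(size=10)
        acc = 0.0
        for a, b in zip(y, yp):
            acc += (b - a) ** 2
        assert rmse(PredictionSet(y, yp)) == pytest.approx(
            np.sqrt(acc / 10), abs=1e-12)


class TestRPD:
    def test_zero_r2_gives_one(self):
        assert rpd_from_r2(0.0) == 1.0

    @pytest.mark.parametrize("r2,expected", [(0.80, 2.24), (0.79, 2.18),
                                             (0.60, 1.58), (0.74, 1.96)])
    def test_reproduces_printed_pairs(self, r2, expected):
        assert round(rpd_from_r2(r2), 2) == expected

    def test_identity_and_monotonicity(self):
        grid = np.linspace(-1, 0.99, 50)
        vals = [rpd_from_r2(r) for r in grid]
        np.testing.assert_allclose(
            [v * np.sqrt(1 - r) for v, r in zip(vals, grid)], 1.0, atol=1e-12)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_unbounded_region_rejected(self):
        with pytest.raises(ValueError):
            rpd_from_r2(1.0)


class TestBiasSep:
    def test_zero_residuals(self):
        assert bias_and_sep(PredictionSet(np.arange(4.0), np.arange(4.0))) == (0, 0)

    def test_constant_offset(self):
        y = np.arange(4.0)
        bias, sep = bias_and_sep(PredictionSet(y, y + 0.25))
        assert bias == pytest.approx(0.25, abs=1e-15)
        assert sep == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic(self):
        y = np.zeros(4)
        yp = np.array([0.1, -0.1, 0.3, -0.3])
        bias, sep = bias_and_sep(PredictionSet(y, yp))
        assert bias == pytest.approx(0.0, abs=1e-15)
        assert sep == pytest.approx(np.sqrt(0.2 / 3), abs=1e-12)


class TestConfidenceIntervals:
    def test_degenerate_when_sep_zero(self):
        y = np.arange(5.0)
        ci_mean, ci_single = confidence_intervals(PredictionSet(y, y))
        assert ci_mean[0] == ci_mean[1] == ci_single[0] == ci_single[1] == y.mean()

    def test_mean_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(1)
        resid = rng.normal(size=400)
        y = np.zeros(400)
        half = {}
        for n in (100, 400):
            ci_mean, ci_single = confidence_intervals(
                PredictionSet(y[:n], resid[:n]))
            half[n] = ((ci_mean[1] - ci_mean[0]) / 2, (ci_single[1] - ci_single[0]) / 2)
        ratio_mean = half[100][0] / half[400][0]
        ratio_single = half[100][1] / half[400][1]
        sd_ratio = resid[:100].std(ddof=1) / resid[:400].std(ddof=1)
        assert ratio_mean == pytest.approx(2 * sd_ratio, rel=0.02)
        assert ratio_single == pytest.approx(sd_ratio, rel=0.02)

    def test_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(2)
        y = np.full(60, 1.2)
        resid = rng.normal(scale=0.3, size=60)
        ps = PredictionSet(y, y + resid)
        ci_mean, _ = confidence_intervals(ps)
        half = (ci_mean[1] - ci_mean[0]) / 2
        boots = np.array([
            rng.choice(resid, size=60, replace=True).mean()
            for _ in range(10_000)
        ])
        boot_half = (np.percentile(boots, 97.5) - np.percentile(boots, 2.5)) / 2
        assert abs(half - boot_half) / boot_half < 0.10


class TestInterpretation:
    def test_abstract_level_performance_is_excellent_outstanding(self):
        assert interpret(0.83, 2.42) == "excellent / outstanding"

    def test_low_r2_is_poor(self):
        assert interpret(0.59, 1.2).startswith("poor")

    def test_band_boundaries_closed_on_left(self):
        assert interpret(0.6, 1.5) == "good / acceptable"
        assert interpret(0.8, 2.0) == "excellent / outstanding"


class TestAnovaTukey:
    def test_textbook_sums_of_squares(self):
        rep = anova_tukey({"a": np.array([2.0, 4.0]), "b": np.array([6.0, 8.0])})
        assert rep.f_statistic == pytest.approx(8.0, abs=1e-12)
        assert rep.df == (1, 2)

    def test_null_p_values_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rep = anova_tukey({g: rng.normal(size=10) for g in "abc"})
            ps.append(rep.p_value)
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_large_shift_is_detected(self):
        base = np.array([1.0, 2.0, 3.0])
        rep = anova_tukey({"a": base, "b": base + 10})
        crit = stats.f.ppf(0.999, 1, 4)
        assert rep.f_statistic > crit

    def test_tukey_flags_the_shifted_group(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(size=10) * 0.1 for g in ("pls", "svr")}
        groups["cnn"] = rng.normal(size=10) * 0.1 + 5.0
        rep = anova_tukey(groups)
        flagged = rep.tukey[rep.tukey["reject"] == True]  # noqa: E712
        pairs = {frozenset((r["group1"], r["group2"])) for _, r in flagged.iterrows()}
        assert frozenset(("cnn", "pls")) in pairs
        assert frozenset(("cnn", "svr")) in pairs

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": np.ones(3), "b": np.ones(3)})


class TestResidualSummary:
    def test_standard_normal_shape(self):
        rng = np.random.default_rng(4)
        y = np.zeros(1000)
        rs = residual_summary(PredictionSet(y, rng.normal(size=1000)))
        assert abs(rs.skewness) < 0.2
        assert abs(rs.excess_kurtosis) < 0.5
        assert not rs.degenerate

    def test_constant_residuals_flagged(self):
        y = np.arange(10.0)
        rs = residual_summary(PredictionSet(y, y + 0.5))
        assert rs.degenerate
        assert rs.skewness == 0.0

    def test_mean_equals_bias(self):
        rng = np.random.default_rng(5)
        ps = PredictionSet(rng.uniform(size=20), rng.uniform(size=20))
        rs = residual_summary(ps)
        assert rs.mean == pytest.approx(bias_and_sep(ps)[0], abs=1e-15)


def test_evaluate_produces_consistent_report():
    rng = np.random.default_rng(6)
    y = rng.uniform(0.1, 2.5, size=60)
    ps = PredictionSet(y, y + rng.normal(scale=0.2, size=60))
    rep = evaluate(ps)
    assert rep.r2 == pytest.approx(r_squared(ps))
    assert rep.rpd == pytest.approx(rpd_from_r2(rep.r2))
    # calibration-set identity: R^2 = 1 - RMSE^2 * n / SS_tot
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert rep.r2 == pytest.approx(1 - rep.rmse**2 * 60 / ss_tot, abs=1e-12)
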