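import numpy as np
import pytest

from socnetlong.errors import ConfigError, DegenerateInputError, DomainError
from socnetlong.longevity import (
    LifeRecord,
    aggression_rate,
    average_adult_metrics,
    fit_ols,
    group_effect_model,
    randomization_regression,
    residual_control,
)


def make_record(values_by_year, age=4.0):
    rec = LifeRecord(individual_id="x", sex="female", age_at_death_years=age)
    for (year, age_y), value in values_by_year.items():
        if value is not None:
            rec.yearly[year] = {"sd": value}
        rec.adult_years.append((year, age_y))
    return rec


class TestAverageAdultMetrics:
    def test_mean_over_adult_years(self):
        rec = make_record({(2002, 2): 0.2, (2003, 3): 0.3, (2004, 4): 0.4})
        assert average_adult_metrics(rec, "sd") == pytest.approx(0.3)

    def test_single_adult_year(self):
        rec = make_record({(2002, 2): 0.7}, age=2.0)
        assert average_adult_metrics(rec, "sd") == pytest.approx(0.7)

    def test_missing_year_skipped_with_warning(self):
        rec = make_record({(2002, 2): 0.2, (2003, 3): None, (2004, 4): 0.4})
        with pytest.warns(UserWarning, match="missing"):
            assert average_adult_metrics(rec, "sd") == pytest.approx(0.3)

    def test_no_adult_years_excluded(self):
        rec = make_record({(2002, 2): None})
        with pytest.raises(DegenerateInputError):
            average_adult_metrics(rec, "sd")


class TestFitOls:
    def test_hand_slope(self):
        slopes, r2 = fit_ols([1, 2, 2, 3], [1, 2, 3, 4])
        assert slopes[0] == pytest.approx(0.6)

    def test_exact_line_r2_one(self):
        _, r2 = fit_ols([2, 4, 6, 8], [1, 2, 3, 4])
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        slopes, r2 = fit_ols([3, 3, 3, 3], [1, 2, 3, 4])
        assert slopes[0] == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_collinear_design_named(self):
        x = np.arange(6.0)
        with pytest.raises(DomainError, match="collinear"):
            fit_ols(np.ones(6), np.column_stack([x, 2 * x]))


class TestRandomizationRegression:
    def test_perfect_line_minimal_p(self):
        x = np.arange(10.0)
        res = randomization_regression(x, x, n_perm=999, rng=0)
        assert res.p_randomization == pytest.approx(1 / 1000)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_identical_y_gives_p_one(self):
        res = randomization_regression(np.ones(8), np.arange(8.0), n_perm=199, rng=0)
        assert res.p_randomization == 1.0

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(60):
            y = rng.normal(size=20)
            x = rng.normal(size=20)
            res = randomization_regression(y, x, n_perm=199, rng=rng)
            rejections += res.p_randomization < 0.05
        assert rejections <= 9  # exact binomial 95% upper bound for p=0.05, n=60

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            randomization_regression([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], n_perm=10)
        with pytest.raises(DegenerateInputError):
            randomization_regression([1, 2], [1, 2], n_perm=200)


class TestResidualControl:
    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        resid = residual_control(rng.normal(size=20), rng.normal(size=(20, 2)))
        assert abs(resid.sum()) < 1e-10

    def test_y_in_span_gives_zero(self):
        x = np.arange(10.0)
        resid = residual_control(3 * x + 2, x)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_frisch_waugh_identity(self):
        rng = np.random.default_rng(2)
        n = 40
        controls = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        ry = residual_control(y, controls)
        rx = residual_control(x, controls)
        partial_slope, _ = fit_ols(ry, rx)
        joint, _ = fit_ols(y, np.column_stack([x, controls]))
        assert partial_slope[0] == pytest.approx(joint[0], abs=1e-10)

    def test_orthogonal_controls_leave_slope_unchanged(self):
        n = 48  # even half-blocks make x and the control exactly orthogonal
        x = np.tile([1.0, -1.0], n // 2)
        control = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(3)
        y = 2.0 * x + rng.normal(size=n)
        raw_slope, _ = fit_ols(y, x)
        adj_slope, _ = fit_ols(residual_control(y, control), residual_control(x, control))
        assert adj_slope[0] == pytest.approx(raw_slope[0], abs=1e-10)


class TestGroupEffectModel:
    def test_detects_predictor_not_group(self):
        detections_pred, detections_grp = 0, 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            groups = np.repeat(np.arange(6), 6)[:34]
            x = rng.normal(size=34)
            y = 1.2 * x + rng.normal(size=34)  # predictor effect, no group effect
            res = group_effect_model(y, x, groups)
            detections_pred += res.p_predictor < 0.05
            detections_grp += res.p_group < 0.05
        assert detections_pred >= 48  # >= 80 percent power
        assert detections_grp <= 9    # near-nominal false positives

    def test_null_f_near_one(self):
        fs = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            groups = np.repeat(np.arange(5), 6)
            y = rng.normal(size=30)
            res = group_effect_model(y, rng.normal(size=30), groups)
            fs.append(res.f_group)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(6), 6)[:34]
        res = group_effect_model(rng.normal(size=34), rng.normal(size=34), groups)
        assert res.df_group == (5, 27)
        assert res.df_predictor == (1, 27)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_effect_model(np.arange(10.0), np.arange(10.0), np.zeros(10))

    def test_singleton_group_warned_but_kept(self):
        rng = np.random.default_rng(4)
        groups = np.array([0] * 10 + [1] * 10 + [2])
        with pytest.warns(UserWarning, match="single member"):
            group_effect_model(rng.normal(size=21), rng.normal(size=21), groups)


class TestAggressionRate:
    def test_counts_linear_in_controls_all_zero(self):
        size = np.array([5, 10, 15, 20, 25.0])
        days = np.array([12, 18, 35, 41, 50.0])
        counts = 2 * size + 0.5 * days + 3
        np.testing.assert_allclose(aggression_rate(counts, size, days), 0, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(5)
        rates = aggression_rate(rng.poisson(5, size=20).astype(float),
                                rng.uniform(5, 20, 20), rng.uniform(10, 60, 20))
        assert abs(rates.sum()) < 1e-8

    def test_excess_aggressor_positive(self):
        size = np.array([8, 10, 12, 14, 9, 11, 13, 10.0])
        days = np.array([20, 30, 25, 40, 35, 22, 28, 30.0])
        counts = 0.2 * size + 0.1 * days
        counts[-1] += 6.0  # same size/effort as row 1, far more agonistic days
        rates = aggression_rate(counts, size, days)
        assert rates[-1] > 0
        assert rates[-1] == rates.max()

    def test_all_zero_counts_valid(self):
        out = aggression_rate(np.zeros(5), np.ones(5), np.ones(5))
        np.testing.assert_array_equal(out, np.zeros(5))
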