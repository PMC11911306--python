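"""Comparison-layer statistics: correlations, agreement, MINQUE, Bayes factors."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from eegage.stats import (
    bland_altman,
    compare_dependent_correlations,
    jzs_regression_bf01,
    linreg_rmse,
    minque_components,
    paired_t,
    partial_correlation,
    pearson,
)


class TestPearson:
    def test_perfect_lines(self, rng):
        x = rng.standard_normal(30)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, _ = pearson(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10))


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        assert partial_correlation(x, y) == pytest.approx(pearson(x, y))

    def test_controlling_for_y_itself_gives_zero(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, _ = partial_correlation(x, y, y)
        assert abs(r) < 1e-10

    def test_matches_inverse_correlation_matrix_oracle(self, rng):
        data = rng.standard_normal((60, 4)) @ rng.standard_normal((4, 4))
        x, y, z = data[:, 0], data[:, 1], data[:, 2:]
        r, _ = partial_correlation(x, y, z)
        prec = np.linalg.inv(np.corrcoef(data.T))
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["x", "y", "z"])
        r, p = partial_correlation(df["x"], df["y"], df["z"])
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_collinear_controls_error(self, rng):
        x, y = rng.standard_normal((2, 30))
        z = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            partial_correlation(rng.standard_normal(30), y, z)


class TestDependentCorrelationComparison:
    def test_equal_correlations_give_zero_t(self):
        res = compare_dependent_correlations(0.5, 0.5, 0.3, 40)
        assert res.t_stat == 0.0 and res.p == pytest.approx(1.0)
        assert res.df == 37

    def test_sign_flip_negates_t(self):
        a = compare_dependent_correlations(0.6, 0.4, 0.3, 40)
        b = compare_dependent_correlations(0.4, 0.6, 0.3, 40)
        assert a.t_stat == pytest.approx(-b.t_stat)

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(0.95, -0.95, 0.9, 30)


class TestBlandAltman:
    def test_identical_methods_collapse(self, rng):
        a = rng.standard_normal(20)
        res = bland_altman(a, a)
        assert res.bias == 0 and res.sd_diff == 0
        assert res.loa_low == res.loa_high == 0

    def test_constant_shift(self, rng):
        a = rng.standard_normal(20)
        res = bland_altman(a, a - 0.5)
        assert res.bias == pytest.approx(0.5)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_limits_match_direct_formula(self, rng):
        a, b = rng.standard_normal((2, 50))
        res = bland_altman(a, b)
        d = a - b
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)
        slope_oracle = np.polyfit((a + b) / 2, d, 1)[0]
        assert res.proportional_slope == pytest.approx(slope_oracle)


class TestLinregRmse:
    def test_exact_line_has_zero_rmse(self):
        x = np.arange(10.0)
        fit = linreg_rmse(x, 2 * x - 1)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.r == pytest.approx(1.0)

    def test_two_predictor_coefficients_recovered_exactly(self, rng):
        x = rng.standard_normal((40, 2))
        y = 68.8 - 22.5 * x[:, 0] + 44.1 * x[:, 1]
        fit = linreg_rmse(x, y)
        assert fit.intercept == pytest.approx(68.8)
        assert fit.coefficients == pytest.approx([-22.5, 44.1])

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        fit = linreg_rmse(x, y)
        design = np.column_stack([np.ones(30), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.intercept == pytest.approx(oracle[0], abs=1e-10)
        assert np.allclose(fit.coefficients, oracle[1:], atol=1e-10)
        resid = y - design @ oracle
        assert fit.rmse == pytest.approx(np.sqrt(np.mean(resid**2)))

    def test_singular_design_errors(self, rng):
        x = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError):
            linreg_rmse(x, rng.standard_normal(20))


class TestPairedT:
    def test_identical_samples(self, rng):
        a = rng.standard_normal(15)
        t, df, p = paired_t(a, a)
        assert t == 0.0 and p == 1.0 and df == 14

    def test_constant_shift_degenerate(self, rng):
        a = rng.standard_normal(15)
        t, _, p = paired_t(a, a - 1.0)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy(self, rng):
        a, b = rng.standard_normal((2, 25))
        t, df, p = paired_t(a, b)
        ref = sp_stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


def anova_components_balanced(grid):
    """Method-of-moments (EMS) oracle for a balanced two-way crossed layout."""
    p, c = grid.shape
    grand = grid.mean()
    msa = c * np.sum((grid.mean(axis=1) - grand) ** 2) / (p - 1)
    msb = p * np.sum((grid.mean(axis=0) - grand) ** 2) / (c - 1)
    resid = grid - grid.mean(axis=1, keepdims=True) - grid.mean(axis=0) + grand
    mse = np.sum(resid**2) / ((p - 1) * (c - 1))
    return (msa - mse) / c, (msb - mse) / p, mse


class TestMinque:
    def test_equals_anova_on_balanced_layouts(self, rng):
        for _ in range(5):
            grid = (rng.standard_normal((8, 6)) + 2 * rng.standard_normal((8, 1))
                    + 0.5 * rng.standard_normal((1, 6)))
            vc = minque_components(grid)
            sa, sb, se = anova_components_balanced(grid)
            assert vc.between_subject == pytest.approx(sa, abs=1e-8)
            assert vc.within_subject == pytest.approx(sb, abs=1e-8)
            assert vc.error == pytest.approx(se, abs=1e-8)

    def test_pure_participant_shifts(self, rng):
        shifts = rng.standard_normal(10) * 3
        grid = np.tile(shifts[:, None], (1, 8)) + 1e-6 * rng.standard_normal((10, 8))
        vc = minque_components(grid)
        assert vc.proportions["between_subject"] > 0.999

    def test_proportions_sum_to_one_with_missing_cells(self, rng):
        grid = rng.standard_normal((10, 6)) + rng.standard_normal((10, 1))
        grid[rng.random((10, 6)) < 0.15] = np.nan
        vc = minque_components(grid)
        assert sum(vc.proportions.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in vc.proportions.values())

    def test_recovers_known_components(self, rng):
        """sigma^2 = (4, 1, 2) planted; mean estimate over replicates unbiased."""
        sa2, sb2, se2 = 4.0, 1.0, 2.0
        est = []
        for _ in range(100):
            a = np.sqrt(sa2) * rng.standard_normal((20, 1))
            b = np.sqrt(sb2) * rng.standard_normal((1, 10))
            e = np.sqrt(se2) * rng.standard_normal((20, 10))
            vc = minque_components(a + b + e)
            est.append([vc.between_subject, vc.within_subject, vc.error])
        mean = np.mean(est, axis=0)
        se = np.std(est, axis=0, ddof=1) / np.sqrt(len(est))
        for m, s, truth in zip(mean, se, (sa2, sb2, se2)):
            assert abs(m - truth) < 4 * s


class TestJzsBayesFactor:
    def test_identical_models_give_unit_bf(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 2))
        assert jzs_regression_bf01(y, x, x).bf01 == pytest.approx(1.0)

    def test_occam_penalty_for_noise_covariate(self, rng):
        wins = 0
        for _ in range(40):
            n = 100
            x1 = rng.standard_normal(n)
            y = 0.5 * x1 + rng.standard_normal(n)
            noise = rng.standard_normal(n)
            res = jzs_regression_bf01(y, x1, np.column_stack([x1, noise]))
            wins += res.bf01 > 1
        assert wins / 40 >= 0.9

    def test_quadrature_matches_monte_carlo_importance_sampling(self, rng):
        n = 60
        x = rng.standard_normal((n, 2))
        y = x @ np.array([0.4, -0.2]) + rng.standard_normal(n)
        res = jzs_regression_bf01(y, None, x)
        # oracle: average the likelihood-ratio factor over prior draws of g
        design = np.column_stack([np.ones(n), x])
        resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        g = sp_stats.invgamma(0.5, scale=n * 0.354**2 / 2).rvs(400_000, random_state=1)
        p = 2
        logs = ((n - 1 - p) / 2) * np.log1p(g) - ((n - 1) / 2) * np.log1p(g * (1 - r2))
        bf10_mc = np.exp(logs).mean()
        assert res.bf_alt_vs_intercept == pytest.approx(bf10_mc, rel=0.02)

    def test_non_nested_models_error(self, rng):
        y = rng.standard_normal(30)
        with pytest.raises(ValueError):
            jzs_regression_bf01(y, rng.standard_normal(30), rng.standard_normal(30))


class TestTypeOneErrorCalibration:
    """Null-simulation calibration at moderate replicate counts; the
    acceptance suite reruns these at >= 2000 replicates."""

    def test_dependent_correlation_test_holds_level(self, rng):
        hits = 0
        runs = 2000
        for _ in range(runs):
            z = rng.standard_normal((30, 3)) + 0.6 * rng.standard_normal((30, 1))
            c = np.corrcoef(z.T)
            res = compare_dependent_correlations(c[0, 2], c[1, 2], c[0, 1], 30)
            hits += res.p < 0.05
        assert abs(hits / runs - 0.05) < 0.015

    def test_paired_t_holds_level(self, rng):
        hits = 0
        runs = 2000
        for _ in range(runs):
            a, b = rng.standard_normal((2, 20))
            hits += paired_t(a, b)[2] < 0.05
        assert abs(hits / runs - 0.05) < 0.015
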