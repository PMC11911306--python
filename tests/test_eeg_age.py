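"""PLS1, permutation factor selection, VIP, R-PLS, PARAFAC, tri-PLS."""

import numpy as np
import pytest

from eegage.age_models import (
    corcondia,
    diagnose_parafac,
    fit_parafac,
    fit_pls,
    fit_tripls,
    predict_age,
    rpls_select,
    select_factors_by_permutation,
    vip_scores,
)


def planted_two_factor_data(rng, n=40, p=30, noise=0.02):
    """y is a noiseless function of two orthogonal latent directions in X."""
    t = rng.standard_normal((n, 2))
    loadings = np.linalg.qr(rng.standard_normal((p, 2)))[0].T
    loadings = loadings * np.array([[1.0], [3.0]])  # distinct direction scales
    x = t @ loadings + noise * rng.standard_normal((n, p))
    y = t[:, 0] + t[:, 1]
    return x, y


class TestFitPls:
    def test_exact_two_column_relationship(self, rng):
        # centred orthogonal predictors with distinct norms: the 2-dimensional
        # Krylov space of PLS1 then contains the true coefficient vector exactly
        g = rng.standard_normal((25, 6))
        q, _ = np.linalg.qr(g - g.mean(axis=0))
        x = q * np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 3.0 * x[:, 1] - 2.0 * x[:, 4] + 5.0
        model = fit_pls(x, y, n_factors=2)
        pred = model.predict(x)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-8
        assert np.corrcoef(pred, y)[0, 1] == pytest.approx(1.0)

    def test_constant_response_gives_zero_beta(self, rng):
        x = rng.standard_normal((20, 5))
        y = np.full(20, 47.0)
        model = fit_pls(x, y, n_factors=3)
        assert np.allclose(model.beta, 0.0)
        assert np.allclose(model.predict(x), 47.0)

    def test_matches_sklearn_pls_predictions(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(5):
            x = rng.standard_normal((30, 12))
            y = rng.standard_normal(30)
            for k in (1, 2, 4):
                ours = fit_pls(x, y, k).predict(x)
                ref = PLSRegression(n_components=k, scale=False).fit(x, y)
                assert np.allclose(ours, ref.predict(x).ravel(), atol=1e-8)

    def test_excessive_factors_error(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.standard_normal((5, 3)), rng.standard_normal(5), 4)

    def test_explained_variance_nondecreasing_in_factors(self, rng):
        x, y = planted_two_factor_data(rng)
        cum = [fit_pls(x, y, k).explained_y_variance.sum() for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(cum, cum[1:]))
        assert cum[-1] <= 1.0 + 1e-12


class TestPermutationSelection:
    def test_null_data_rarely_selects_factors(self, rng):
        hits = 0
        runs = 100
        for i in range(runs):
            x = rng.standard_normal((24, 15))
            y = rng.standard_normal(24)
            k, _ = select_factors_by_permutation(x, y, max_factors=1, n_perm=199,
                                                 seed=1000 + i)
            hits += k > 0
        assert hits / runs <= 0.10  # nominal level 0.05

    def test_planted_structure_is_detected(self, rng):
        found = 0
        runs = 20
        for i in range(runs):
            x, y = planted_two_factor_data(rng)
            k, _ = select_factors_by_permutation(x, y, max_factors=4, n_perm=199,
                                                 seed=2000 + i)
            found += k >= 2
        assert found / runs >= 0.9

    def test_deterministic_under_seed(self, rng):
        x, y = planted_two_factor_data(rng)
        a = select_factors_by_permutation(x, y, 3, n_perm=199, seed=7)
        b = select_factors_by_permutation(x, y, 3, n_perm=199, seed=7)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestVip:
    def test_single_active_frequency_gets_sqrt_p(self, rng):
        p = 9
        x = np.zeros((30, p))
        x[:, 3] = rng.standard_normal(30)
        y = 2.0 * x[:, 3]
        model = fit_pls(x, y, 1)
        vip = vip_scores(model)
        assert vip[3] == pytest.approx(np.sqrt(p))
        assert np.allclose(np.delete(vip, 3), 0.0)

    def test_mean_squared_vip_is_one(self, rng):
        x, y = planted_two_factor_data(rng)
        vip = vip_scores(fit_pls(x, y, 3))
        assert np.mean(vip**2) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self, rng):
        x, y = planted_two_factor_data(rng)
        model = fit_pls(x, y, 3)
        vip = vip_scores(model)
        p = x.shape[1]
        ssy = model.explained_y_variance
        brute = np.empty(p)
        for j in range(p):
            acc = 0.0
            for a in range(model.n_factors):
                w = model.x_weights[:, a]
                acc += ssy[a] * (w[j] / np.linalg.norm(w)) ** 2
            brute[j] = np.sqrt(p * acc / ssy.sum())
        assert np.allclose(vip, brute, atol=1e-12)


class TestRpls:
    def test_recovers_planted_two_frequency_contrast(self, rng):
        n, p = 50, 40
        x = rng.standard_normal((n, p))
        y = -22.5 * x[:, 10] + 44.1 * x[:, 25]
        res = rpls_select(x, y, n_factors=2)
        support = np.flatnonzero(res.selected)
        assert set(support) == {10, 25}

    def test_noise_only_terminates(self, rng):
        x = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        res = rpls_select(x, y, max_iter=50)
        assert res.iterations <= 50
        assert res.selected.any()

    def test_duplicated_informative_column_survives(self, rng):
        n = 50
        x = rng.standard_normal((n, 10))
        x[:, 7] = x[:, 3]  # exact duplicate of the informative column
        y = 5.0 * x[:, 3]
        res = rpls_select(x, y, n_factors=1)
        assert res.selected[3] or res.selected[7]


class TestPredictAge:
    def test_in_sample_definition(self, rng):
        x, y = planted_two_factor_data(rng)
        model = fit_pls(x, y, 2)
        assert np.allclose(predict_age(model, x), model.predict(x))

    def test_shift_equivariance(self, rng):
        x, y = planted_two_factor_data(rng)
        a = fit_pls(x, y, 2).predict(x)
        b = fit_pls(x, y + 100.0, 2).predict(x)
        assert np.allclose(b - a, 100.0, atol=1e-8)

    def test_grid_mismatch_errors(self, rng):
        x, y = planted_two_factor_data(rng)
        model = fit_pls(x, y, 2)
        with pytest.raises(ValueError):
            model.predict(rng.standard_normal((4, x.shape[1] + 1)))

    def test_recovers_planted_age_signal_from_spectra(self, grid):
        from eegage.simulate import CohortSpec, generate_cohort, synthesize_spectrum

        cohort60 = generate_cohort(CohortSpec(n_participants=60, seed=5))
        ages = np.array([p.age for p in cohort60])
        x = np.vstack([
            synthesize_spectrum(p, "O1", grid, noise_sd=0.1, seed=i)
            for i, p in enumerate(cohort60)
        ])
        model = fit_pls(x, ages, 5)
        assert np.corrcoef(model.predict(x), ages)[0, 1] > 0.6


def rank_r_tensor(rng, shape, r):
    a = rng.standard_normal((shape[0], r))
    b = rng.standard_normal((shape[1], r))
    c = rng.standard_normal((shape[2], r))
    return np.einsum("ir,jr,kr->ijk", a, b, c), (a, b, c)


class TestParafac:
    def test_exact_rank_one_tensor(self, rng):
        x, _ = rank_r_tensor(rng, (6, 5, 7), 1)
        fit = fit_parafac(x, 1, n_replications=5, seed=0)
        assert fit.sse < 1e-16 * np.sum(x**2) + 1e-12
        assert fit.corcondia == pytest.approx(100.0, abs=1e-6)

    def test_overfactoring_degrades_core_consistency(self, rng):
        x, _ = rank_r_tensor(rng, (8, 6, 7), 2)
        fit = fit_parafac(x, 3, n_replications=10, seed=1)
        assert fit.corcondia < 80.0

    def test_deterministic_diagnostics(self, rng):
        x, _ = rank_r_tensor(rng, (6, 5, 5), 2)
        x += 0.01 * rng.standard_normal(x.shape)
        d1, _ = diagnose_parafac(x, max_factors=2, n_replications=4, seed=3)
        d2, _ = diagnose_parafac(x, max_factors=2, n_replications=4, seed=3)
        assert d1.equals(d2)

    def test_sse_nonincreasing_in_factor_count(self, rng):
        x, _ = rank_r_tensor(rng, (7, 6, 8), 3)
        x += 0.05 * rng.standard_normal(x.shape)
        diag, _ = diagnose_parafac(x, max_factors=4, n_replications=6, seed=5)
        sse = diag["sse"].to_numpy()
        assert all(b <= a * (1 + 1e-8) for a, b in zip(sse, sse[1:]))

    def test_compression_preserves_solution(self, rng):
        x, _ = rank_r_tensor(rng, (10, 8, 30), 2)
        full = fit_parafac(x, 2, n_replications=4, seed=2)
        comp = fit_parafac(x, 2, n_replications=4, seed=2, compress_rank=6)
        assert comp.sse == pytest.approx(full.sse, abs=1e-6 * np.sum(x**2) + 1e-9)
        assert comp.corcondia == pytest.approx(full.corcondia, abs=1.0)


class TestTriPls:
    def test_planted_trilinear_signal_recovered(self, rng):
        n, j, k = 30, 8, 20
        ages = rng.uniform(20, 80, n)
        wj = rng.standard_normal(j)
        wk = rng.standard_normal(k)
        x = (ages - ages.mean())[:, None, None] * np.outer(wj, wk)[None]
        model = fit_tripls(x, ages, 1)
        assert abs(model.score_age_corr[0]) > 0.99
        assert np.corrcoef(model.fitted, ages)[0, 1] > 0.99
        assert np.linalg.norm(model.channel_weights[:, 0]) == pytest.approx(1.0)
        assert np.linalg.norm(model.frequency_weights[:, 0]) == pytest.approx(1.0)

    def test_constant_response_predicts_mean(self, rng):
        x = rng.standard_normal((10, 4, 6))
        y = np.full(10, 50.0)
        model = fit_tripls(x, y, 2)
        assert np.allclose(model.fitted, 50.0)

    def test_fitted_mean_equals_mean_age(self, rng):
        """In-sample OLS on scores keeps the predicted mean at the true mean."""
        x = rng.standard_normal((20, 5, 10))
        y = rng.uniform(20, 80, 20)
        model = fit_tripls(x, y, 3)
        assert model.fitted.mean() == pytest.approx(y.mean())

    def test_predict_reproduces_training_scores(self, rng):
        x = rng.standard_normal((15, 4, 8))
        y = rng.uniform(20, 80, 15)
        model = fit_tripls(x, y, 2)
        assert np.allclose(model.predict(x), model.fitted, atol=1e-10)
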