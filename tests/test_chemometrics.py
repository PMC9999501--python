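"""NIPALS PCA/PLS against independent oracles; correlation statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from numpy.linalg import lstsq, svd

from pymbms import (
    InputError,
    SpectraMatrix,
    cross_validate_pls,
    cross_validate_pls_repeated,
    fit_pls_nipals,
    ion_trait_correlations,
    pca_nipals,
    pearson,
    pls_predict,
    r_squared_linfit,
    select_ions,
    spearman,
)


def _spectra(X, mz_lo=50):
    """Wrap a nonnegative matrix as spectra (intensities cannot be negative)."""
    X = np.asarray(X, dtype=float)
    assert np.all(X >= 0), "test matrices must be nonnegative"
    mz = np.arange(mz_lo, mz_lo + X.shape[1])
    return SpectraMatrix([f"s{i}" for i in range(X.shape[0])], mz, X)


def _rank_k_spectra(rng, n, p, k):
    """Nonnegative rank-k matrix T @ P with uniform positive factors,
    returned with the latent scores T for building exact linear traits."""
    T = rng.uniform(0.5, 2.0, size=(n, k))
    P = rng.uniform(0.1, 1.0, size=(k, p))
    return _spectra(T @ P), T


# ---------------------------------------------------------------------------
# PCA

class TestPCA:
    def test_rank_one_matrix_fully_explained_by_pc1(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        m = pca_nipals(X, 2)
        assert m.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("shape,seed", [((6, 5), 0), ((10, 8), 42)])
    def test_matches_svd_oracle_up_to_sign(self, shape, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=shape)
        k = 3
        m = pca_nipals(X, k)
        Xc = X - X.mean(axis=0)
        U, S, Vt = svd(Xc, full_matrices=False)
        for j in range(k):
            v = Vt[j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            t = Xc @ v
            np.testing.assert_allclose(m.loadings[j], v, atol=1e-6)
            np.testing.assert_allclose(m.scores[:, j], t, atol=1e-6)
            assert m.explained_variance_fraction[j] == pytest.approx(
                S[j] ** 2 / np.sum(S**2), abs=1e-8
            )

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(InputError, match="zero-variance"):
            pca_nipals(np.ones((5, 4)), 1)

    def test_too_many_components_rejected(self):
        with pytest.raises(InputError, match="exceeds"):
            pca_nipals(np.random.default_rng(0).normal(size=(4, 6)), 4)

    def test_loadings_unit_norm_and_evf_nonincreasing(self):
        rng = np.random.default_rng(7)
        m = pca_nipals(rng.normal(size=(12, 6)), 4)
        np.testing.assert_allclose(np.linalg.norm(m.loadings, axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(m.explained_variance_fraction) <= 1e-10)
        assert m.cumulative_explained() <= 1 + 1e-8

    def test_full_extraction_explains_all_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 5))
        m = pca_nipals(X, 5)
        assert m.cumulative_explained() == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# PLS

class TestPLS:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(0)
        m, T = _rank_k_spectra(rng, 30, 12, 3)
        y = T @ np.array([1.0, -2.0, 0.5])
        model = fit_pls_nipals(m, y, 3, mz_window=(50, 61))
        yhat = pls_predict(model, m)
        np.testing.assert_allclose(yhat, y, atol=1e-8)

    def test_full_factor_model_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.1, 5.0, size=(20, 6))
        y = rng.normal(size=20)
        m = _spectra(X)
        model = fit_pls_nipals(m, y, 6, mz_window=(50, 55))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ols = lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(model.coefficients, b_ols, atol=1e-6)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(9)
        X = rng.uniform(0.1, 5.0, size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=25)
        model = fit_pls_nipals(_spectra(X), y, 3, mz_window=(50, 59))
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.coefficients, sk.coef_.ravel(), atol=1e-8
        )

    def test_constant_trait_gives_zero_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.1, 5.0, size=(10, 4))
        y = np.full(10, 3.5)
        model = fit_pls_nipals(_spectra(X), y, 2, mz_window=(50, 53))
        np.testing.assert_array_equal(model.coefficients, 0.0)
        np.testing.assert_allclose(pls_predict(model, _spectra(X)), 3.5)

    def test_n_factors_beyond_rank_rejected(self):
        rng = np.random.default_rng(4)
        m, _ = _rank_k_spectra(rng, 10, 6, 2)
        with pytest.raises(InputError, match="rank"):
            fit_pls_nipals(m, rng.normal(size=10), 5, mz_window=(50, 55))

    def test_predicting_x_mean_returns_y_mean(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(5.0, 15.0, size=(15, 5))
        y = rng.normal(size=15) + 4
        model = fit_pls_nipals(_spectra(X), y, 2, mz_window=(50, 54))
        mean_row = _spectra(model.x_mean[None, :])
        assert pls_predict(model, mean_row)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_missing_window_bins_warn_and_count_zero(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.1, 5.0, size=(12, 6))
        y = rng.normal(size=12)
        model = fit_pls_nipals(_spectra(X), y, 2, mz_window=(50, 55))
        narrower = SpectraMatrix(
            [f"n{i}" for i in range(3)], np.arange(50, 54),
            np.abs(rng.normal(size=(3, 4))),
        )
        with pytest.warns(UserWarning, match="missing"):
            out = pls_predict(model, narrower)
        assert out.shape == (3,)


class TestCrossValidation:
    def test_seeded_holdout_is_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 5.0, size=(40, 8))
        y = rng.normal(size=40)
        m = _spectra(X)
        a = cross_validate_pls(m, y, 2, n_holdout=10, seed=7, mz_window=(50, 57))
        b = cross_validate_pls(m, y, 2, n_holdout=10, seed=7, mz_window=(50, 57))
        assert a == b

    def test_holdout_too_large_rejected(self):
        rng = np.random.default_rng(0)
        m = _spectra(rng.uniform(0.1, 5.0, size=(10, 4)))
        with pytest.raises(InputError, match="n_holdout"):
            cross_validate_pls(m, rng.normal(size=10), 2, n_holdout=10, seed=0,
                               mz_window=(50, 53))

    def test_noiseless_linear_data_validates_perfectly(self):
        rng = np.random.default_rng(1)
        m, T = _rank_k_spectra(rng, 50, 10, 3)
        y = T @ np.array([2.0, -1.0, 0.3])
        stats = cross_validate_pls(m, y, 3, n_holdout=20, seed=3,
                                   mz_window=(50, 59))
        assert stats["r2_validation"] >= 0.999

    def test_pure_noise_trait_centres_at_or_below_zero_skill(self):
        """With y independent of X, validation R^2 (squared correlation)
        should concentrate near zero: its mean over 100 seeded splits stays
        below the small-sample chance level."""
        rng = np.random.default_rng(12)
        X = rng.uniform(0.1, 5.0, size=(30, 10))
        m = _spectra(X)
        r2s = []
        for seed in range(100):
            y = np.random.default_rng(1000 + seed).normal(size=30)
            stats = cross_validate_pls(m, y, 2, n_holdout=10, seed=seed,
                                       mz_window=(50, 59))
            r2s.append(stats["r2_validation"])
        # squared-r of 10 unrelated points has expectation ~1/(n-1) ≈ 0.11
        assert np.mean(r2s) < 0.25

    def test_repeated_mode_reports_mean_and_sd(self):
        rng = np.random.default_rng(2)
        m, T = _rank_k_spectra(rng, 40, 8, 2)
        y = T @ np.array([1.0, 0.5]) + 0.05 * rng.normal(size=40)
        out = cross_validate_pls_repeated(m, y, 2, n_holdout=10,
                                          n_repeats=10, seed=0, mz_window=(50, 57))
        assert out["n_repeats"] == 10
        assert 0.9 <= out["r2_validation_mean"] <= 1.0
        assert out["r2_validation_sd"] >= 0.0


# ---------------------------------------------------------------------------
# statistics

class TestStatistics:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert r_squared_linfit(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_spearman_hand_oracle(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert pearson(3 * x + 2, 0.5 * y - 7) == pytest.approx(pearson(x, y), abs=1e-12)

    def test_spearman_one_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, x**3) == pytest.approx(1.0)

    def test_matches_scipy_oracle_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-10
            )
            assert spearman(x, y) == pytest.approx(
                scipy.stats.spearmanr(x, y).statistic, abs=1e-10
            )

    def test_spearman_with_ties_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 4, size=15).astype(float)
            y = rng.integers(0, 4, size=15).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(
                scipy.stats.spearmanr(x, y).statistic, abs=1e-10
            )

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_short_vectors_rejected(self):
        with pytest.raises(InputError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestIonDiscovery:
    def test_planted_informative_ions_selected(self, ions):
        from pymbms import (
            SyntheticConfig, generate_dataset, aromatic_sum,
            average_replicates, tic_normalize,
        )
        sp, tab, truth = generate_dataset(SyntheticConfig(n_samples=100, seed=21))
        tic = average_replicates(tic_normalize(sp))
        trait = aromatic_sum(tab)
        r = ion_trait_correlations(tic, trait)
        selected = set(select_ions(r, 0.5))
        planted = set(ions.aromatic_ions) - ions.confounded_ions
        assert planted <= selected

    def test_threshold_above_one_selects_nothing(self):
        r = pd.Series([0.9, 1.0], index=[77, 122])
        assert select_ions(r, 1.01) == []

    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 5.0, size=(10, 3))
        X[:, 1] = 5.0
        m = _spectra(X)
        r = ion_trait_correlations(m, X[:, 0])
        assert np.isnan(r.iloc[1])
        assert 51 not in select_ions(r, -2.0)

    def test_misaligned_samples_listed(self):
        rng = np.random.default_rng(0)
        m = _spectra(rng.uniform(0.1, 5.0, size=(4, 3)))
        trait = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "zzz"])
        with pytest.raises(InputError, match="zzz"):
            ion_trait_correlations(m, trait)
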