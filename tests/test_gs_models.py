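"""Model checks: closed-form identities, REML recovery, treatment semantics."""

import numpy as np
import pytest

from gslens import (
    ConfigurationError,
    DegenerateInputError,
    GBlupModel,
    InputError,
    LassoModel,
    RidgeModel,
    SimulationConfig,
    delete_treat,
    fit_gblup,
    fit_lasso_predictor,
    fit_ridge,
    fit_rrblup,
    make_model,
    msom_treat,
    simulate_dataset,
    simulate_genotypes,
    vanraden_G,
)

FAST_LASSO = dict(n_lambda=25, eps_ratio=1e-2, k_folds=4, tol=1e-3)


def _standardized(X):
    sd = X.std(0)
    return (X - X.mean(0)) / np.where(sd > 0, sd, 1)


class TestLassoPredictor:
    def test_noise_free_signal_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 10))
        y = 2.0 * X[:, 0]
        model = fit_lasso_predictor(X[:70], y[:70], **FAST_LASSO)
        r = np.corrcoef(model.predict(X[70:]), y[70:])[0, 1]
        assert r > 0.99

    def test_pure_noise_has_no_held_out_accuracy(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 30))
            y = rng.normal(size=100)
            model = fit_lasso_predictor(X[:70], y[:70], seed=seed, **FAST_LASSO)
            rs.append(abs(np.corrcoef(model.predict(X[70:]), y[70:])[0, 1]))
        assert np.mean(rs) < 0.2

    def test_deterministic_given_seed(self, toy_dataset):
        ds, _ = toy_dataset
        m1 = fit_lasso_predictor(ds.genotypes, ds.phenotype, seed=5, **FAST_LASSO)
        m2 = fit_lasso_predictor(ds.genotypes, ds.phenotype, seed=5, **FAST_LASSO)
        assert np.array_equal(m1.predict(ds.genotypes), m2.predict(ds.genotypes))

    def test_empty_training_set_rejected(self):
        with pytest.raises(InputError):
            fit_lasso_predictor(np.empty((0, 3)), np.empty(0))


class TestRidge:
    def test_shrinkage_constant_from_heritability(self, toy_dataset):
        ds, _ = toy_dataset
        model = fit_ridge(ds.genotypes, ds.phenotype, h2=0.5)
        assert model.fit_result.extras["lambda_r"] == pytest.approx(ds.n_markers)
        with pytest.raises(ConfigurationError):
            fit_ridge(ds.genotypes, ds.phenotype, h2=1.5)

    def test_h2_to_one_limit_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))  # n > p toy
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 2.0]) + 0.1 * rng.normal(size=40)
        model = fit_ridge(X, y, h2=1 - 1e-12)
        Z = _standardized(X)
        ols = np.linalg.lstsq(Z, y - y.mean(), rcond=None)[0]
        assert np.allclose(model.fit_result.marker_effects, ols, atol=1e-5)

    def test_ridge_equals_gblup_with_matched_ratio(self):
        """Ridge and GBLUP agree when G = ZZ'/m and the variance ratio is lambda_r/m."""
        rng = np.random.default_rng(2)
        n, m = 30, 50
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        h2 = 0.4
        lam = m * (1 - h2) / h2
        ridge = fit_ridge(X, y, h2=h2)
        Z = _standardized(X)
        G = Z @ Z.T / m
        gfit = fit_gblup(y, G, np.arange(n), var_ratio=lam / m)
        assert np.allclose(
            ridge.predict(X), gfit.extras["predictions"], atol=1e-6
        )


class TestRRBlup:
    def test_equals_ridge_at_reml_optimum(self, toy_dataset):
        """RR-BLUP effects equal ridge effects with lambda = sigma2_e/sigma2_u."""
        ds, _ = toy_dataset
        rb = fit_rrblup(ds.genotypes, ds.phenotype)
        lam = rb.fit_result.extras["delta"]
        rd = fit_ridge(ds.genotypes, ds.phenotype, h2=0.5, lambda_override=lam)
        assert np.allclose(
            rb.fit_result.marker_effects, rd.fit_result.marker_effects, atol=1e-6
        )

    def test_heritability_recovery_at_study_scale(self):
        """sigma2_u m / (sigma2_u m + sigma2_e) near the simulated h2=0.5 (20 seeds)."""
        h2_hats = []
        for seed in range(20):
            cfg = SimulationConfig(heritability=0.5, outlier_fraction=0.0, seed=seed)
            ds, _ = simulate_dataset(cfg)
            rb = fit_rrblup(ds.genotypes, ds.phenotype)
            h2_hats.append(rb.fit_result.extras["h2_hat"])
        assert abs(np.mean(h2_hats) - 0.5) < 0.15

    def test_pure_noise_gives_near_zero_heritability(self):
        h2_hats = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, size=(60, 100)).astype(float)
            y = rng.normal(size=60)
            rb = fit_rrblup(X, y)
            h2_hats.append(rb.fit_result.extras["h2_hat"])
        assert np.median(h2_hats) < 0.1

    def test_variance_components_nonnegative(self, toy_dataset):
        ds, _ = toy_dataset
        rb = fit_rrblup(ds.genotypes, ds.phenotype)
        assert rb.fit_result.sigma2_u >= 0
        assert rb.fit_result.sigma2_e >= 0


class TestVanRadenG:
    def test_identical_individuals_share_diagonal(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(10, 40)).astype(float)
        X[1] = X[0]
        rel = vanraden_G(X)
        assert rel.G[0, 1] == pytest.approx(rel.G[0, 0])

    def test_symmetric_psd(self, toy_dataset):
        ds, _ = toy_dataset
        rel = vanraden_G(ds.genotypes)
        assert np.allclose(rel.G, rel.G.T)
        ev = np.linalg.eigvalsh(rel.G + 1e-8 * np.eye(len(rel.G)))
        assert ev.min() > -1e-10

    def test_mean_diagonal_near_one_at_equilibrium(self):
        cfg = SimulationConfig(
            n_individuals=500, n_chromosomes=2, markers_per_chromosome=100,
            n_qtl=2, seed=4,
        )
        G_mat, _ = simulate_genotypes(cfg)
        rel = vanraden_G(G_mat.astype(float))
        assert np.mean(np.diag(rel.G)) == pytest.approx(1.0, abs=0.1)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(DegenerateInputError):
            vanraden_G(np.ones((5, 4)))


class TestGBlup:
    def test_matches_rrblup_predictions(self, toy_dataset):
        """GBLUP with G = ZZ'/m reproduces RR-BLUP predictions (1e-6)."""
        ds, _ = toy_dataset
        rb = fit_rrblup(ds.genotypes, ds.phenotype)
        Z = _standardized(ds.genotypes)
        m = ds.n_markers
        G = Z @ Z.T / m
        gfit = fit_gblup(
            ds.phenotype, G, np.arange(ds.n_individuals),
            var_ratio=rb.fit_result.extras["delta"] / m,
        )
        assert np.allclose(
            gfit.extras["predictions"], rb.predict(ds.genotypes), atol=1e-6
        )

    def test_noiseless_response_is_interpolated(self):
        """With a genetic response the training predictions approach the data."""
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(40, 60)).astype(float)
        rel = vanraden_G(X)
        L = np.linalg.cholesky(rel.G + 1e-6 * np.eye(40))
        y = L @ rng.normal(size=40)  # exactly G-structured, no noise
        gfit = fit_gblup(y, rel.G, np.arange(40))
        assert np.corrcoef(gfit.extras["predictions"], y)[0, 1] > 0.99

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(25, 50)).astype(float)
        y = rng.normal(size=25)
        rel = vanraden_G(X)
        fit = fit_gblup(y, rel.G, np.arange(25))
        perm = rng.permutation(25)
        rel_p = vanraden_G(X[perm])
        fit_p = fit_gblup(y[perm], rel_p.G, np.arange(25))
        assert np.allclose(
            fit_p.extras["predictions"], fit.extras["predictions"][perm], atol=1e-8
        )

    def test_model_interface_predicts_unseen_individuals(self, toy_dataset):
        ds, _ = toy_dataset
        model = GBlupModel().fit(ds.genotypes[:45], ds.phenotype[:45])
        pred = model.predict(ds.genotypes[45:])
        assert pred.shape == (ds.n_individuals - 45,)
        assert np.all(np.isfinite(pred))


class TestTreatments:
    def test_msom_indicator_structure(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        treated = msom_treat(X, y, [3, 7], mode="indicator")
        D = treated.X[:, 4:]
        assert D.shape == (12, 2)
        assert np.all(D.sum(axis=0) == 1)
        assert set(np.flatnonzero(D.sum(axis=1))) == {3, 7}
        assert np.array_equal(treated.y, y)

    def test_msom_indicator_equals_deletion_for_least_squares(self, rng):
        """Classical identity: shift-augmented OLS == OLS after row deletion (1e-10)."""
        n, p = 40, 6
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        flagged = np.array([0, 13, 29])
        aug = msom_treat(X, y, flagged, mode="indicator")
        A = np.column_stack([np.ones(n), aug.X])
        coef_aug = np.linalg.lstsq(A, aug.y, rcond=None)[0][: p + 1]
        dele = delete_treat(X, y, flagged)
        B = np.column_stack([np.ones(len(dele.y)), dele.X])
        coef_del = np.linalg.lstsq(B, dele.y, rcond=None)[0]
        assert np.allclose(coef_aug, coef_del, atol=1e-10)

    def test_msom_replace_moves_only_flagged(self, toy_dataset):
        ds, truth = toy_dataset
        flagged = truth.outlier_indices
        treated = msom_treat(ds.genotypes, ds.phenotype, flagged, mode="replace")
        clean = np.setdiff1d(np.arange(ds.n_individuals), flagged)
        assert np.array_equal(treated.y[clean], ds.phenotype[clean])
        assert not np.array_equal(treated.y[flagged], ds.phenotype[flagged])
        # replacements are less extreme than the contaminated values
        mu = ds.phenotype.mean()
        assert np.all(
            np.abs(treated.y[flagged] - mu) < np.abs(ds.phenotype[flagged] - mu)
        )

    def test_empty_flag_set_is_identity(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        for mode in ("indicator", "replace"):
            treated = msom_treat(X, y, [], mode=mode)
            assert np.array_equal(treated.X[:, :3], X)
            assert np.array_equal(treated.y, y)
        dele = delete_treat(X, y, [])
        assert np.array_equal(dele.X, X)

    def test_delete_counts(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        dele = delete_treat(X, y, np.arange(10))
        assert dele.X.shape == (190, 5) and len(dele.y) == 190

    def test_degenerate_flag_sets_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        with pytest.raises(DegenerateInputError):
            msom_treat(X, y, np.arange(5))
        with pytest.raises(InputError):
            delete_treat(X, y, np.arange(5))
        with pytest.raises(InputError):
            msom_treat(X, y, [99])


def test_make_model_rejects_unknown_kind():
    with pytest.raises(ConfigurationError):
        make_model("bayeslasso")
    assert isinstance(make_model("ridge", h2=0.3), RidgeModel)
    assert isinstance(make_model("lasso"), LassoModel)
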