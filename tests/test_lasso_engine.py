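"""Engine checks: grid structure, KKT optimality, closed forms, CV behaviour."""

import itertools

import numpy as np
import pytest

from gslens import (
    ConfigurationError,
    DegenerateInputError,
    cross_validate_path,
    fit_lasso_path,
    fold_assignments,
    lambda_grid,
)


def _orthonormal_design(n, p, seed=0):
    """Columns with X'X/n = I and zero means, so the lasso has a closed form."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p + 1))
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:] * np.sqrt(n)  # orthogonal to the intercept, unit variance


class TestLambdaGrid:
    def test_structure(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        grid = lambda_grid(X, y, n_lambda=25, eps_ratio=1e-3)
        assert len(grid) == 25
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(grid[0] * 1e-3)

    def test_lambda_max_formula(self):
        # single standardized predictor with x'y/n = 2 -> lambda_max = 2
        n = 64
        x = _orthonormal_design(n, 1, seed=3)
        y = 2.0 * x[:, 0]
        grid = lambda_grid(x, y, n_lambda=5)
        assert grid[0] == pytest.approx(2.0)

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(DegenerateInputError):
            lambda_grid(X, np.zeros(20))


class TestFitPath:
    def test_all_zero_at_lambda_max(self, rng):
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        grid = lambda_grid(X, y, n_lambda=30)
        path = fit_lasso_path(X, y, grid, tol=1e-8)
        assert np.all(path.coefs[:, 0] == 0)

    def test_soft_threshold_closed_form(self):
        """Orthonormal design: beta_j(lambda) = S(OLS beta_j, lambda), to 1e-8."""
        n, p = 128, 6
        X = _orthonormal_design(n, p, seed=1)
        beta_true = np.array([2.0, -1.5, 0.8, 0.3, -0.1, 0.0])
        y = X @ beta_true
        ols = X.T @ (y - y.mean()) / n
        grid = np.array([2.5, 1.0, 0.5, 0.1, 0.01])
        path = fit_lasso_path(X, y, grid, tol=1e-14)
        for j, lam in enumerate(grid):
            expect = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            assert np.allclose(path.coefs[:, j], expect, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_conditions_small_instances(self, seed):
        """|x_j'r/n| <= lambda for inactive j and == lambda for active j (tol 1e-6)."""
        rng = np.random.default_rng(seed)
        n, p = 20, 30
        X = rng.normal(size=(n, p))
        y = X[:, :3] @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=n)
        grid = lambda_grid(X, y, n_lambda=20, eps_ratio=1e-2)
        path = fit_lasso_path(X, y, grid, tol=1e-12)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        for j, lam in enumerate(grid):
            b = path.coefs[:, j]
            g = Xs.T @ (yc - Xs @ b) / n
            active = b != 0
            assert np.all(np.abs(g[~active]) <= lam + 1e-6)
            if active.any():
                assert np.allclose(np.abs(g[active]), lam, atol=1e-6)

    def test_matches_brute_force_on_tiny_instance(self):
        """Objective at the solution <= brute-force search over sign patterns (1e-6)."""
        rng = np.random.default_rng(7)
        n, p = 10, 5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        lam = 0.15

        def objective(b):
            r = yc - Xs @ b
            return 0.5 * r @ r / n + lam * np.abs(b).sum()

        # enumerate all sign patterns; solve the equality-constrained problem
        best = objective(np.zeros(p))
        for signs in itertools.product([-1, 0, 1], repeat=p):
            s = np.array(signs, dtype=float)
            A = np.flatnonzero(s)
            if len(A) == 0:
                continue
            XA = Xs[:, A]
            b_A = np.linalg.solve(XA.T @ XA / n, XA.T @ yc / n - lam * s[A])
            if np.any(np.sign(b_A) * s[A] < 0):
                continue  # inconsistent pattern
            b = np.zeros(p)
            b[A] = b_A
            best = min(best, objective(b))
        path = fit_lasso_path(X, y, np.array([lam]), tol=1e-14)
        assert objective(path.coefs[:, 0]) <= best + 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_independent_solver(self, seed):
        """Coefficient paths match scikit-learn's coordinate descent (1e-5)."""
        from sklearn.linear_model import lasso_path as sk_lasso_path

        rng = np.random.default_rng(seed)
        n, p = 40, 25
        X = rng.normal(size=(n, p))
        y = X[:, :4] @ rng.normal(size=4) + rng.normal(size=n)
        grid = lambda_grid(X, y, n_lambda=25, eps_ratio=1e-2)
        path = fit_lasso_path(X, y, grid, tol=1e-12)
        Xs = (X - X.mean(0)) / X.std(0)
        _, sk_coefs, _ = sk_lasso_path(
            np.asfortranarray(Xs), y - y.mean(), alphas=grid, tol=1e-12, max_iter=100000
        )
        assert np.allclose(path.coefs, sk_coefs, atol=1e-5)

    def test_path_continuity_under_refinement(self, rng):
        X = rng.normal(size=(30, 12))
        y = X[:, 0] * 2 + rng.normal(size=30)
        grid = lambda_grid(X, y, n_lambda=200, eps_ratio=1e-2)
        path = fit_lasso_path(X, y, grid, tol=1e-10)
        jumps = np.abs(np.diff(path.coefs, axis=1)).max(axis=0)
        assert jumps.max() < 0.2  # fine grid: no large coefficient jumps

    def test_original_scale_predictions_include_intercept(self, rng):
        X = rng.normal(loc=5.0, size=(50, 8))
        y = 3.0 + X[:, 0] + rng.normal(scale=0.1, size=50)
        path = fit_lasso_path(X, y, n_lambda=30, eps_ratio=1e-4, tol=1e-10)
        pred = path.predict(X, path.n_lambda - 1)
        assert np.corrcoef(pred, y)[0, 1] > 0.99


class TestCrossValidation:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 20))
        y = rng.normal(size=40)
        grid = lambda_grid(X, y, n_lambda=15, eps_ratio=1e-2)
        cv1 = cross_validate_path(X, y, grid, k_folds=5, seed=3)
        cv2 = cross_validate_path(X, y, grid, k_folds=5, seed=3)
        assert np.array_equal(cv1.mean_error, cv2.mean_error)
        assert cv1.lambda_best == cv2.lambda_best

    def test_curve_nonnegative_and_best_on_grid(self, rng):
        X = rng.normal(size=(40, 20))
        y = X[:, 0] + rng.normal(size=40)
        grid = lambda_grid(X, y, n_lambda=15, eps_ratio=1e-2)
        cv = cross_validate_path(X, y, grid, k_folds=4, seed=0)
        assert np.all(cv.mean_error >= 0)
        assert cv.lambda_best in grid

    def test_pure_noise_selects_sparse_model(self):
        """Under a pure-noise response the CV-selected model stays small."""
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(50, 30))
            y = rng.normal(size=50)
            grid = lambda_grid(X, y, n_lambda=30, eps_ratio=1e-2)
            path = fit_lasso_path(X, y, grid, tol=1e-8)
            cv = cross_validate_path(X, y, grid, k_folds=5, seed=seed)
            sizes.append(len(path.active_set(cv.best_index)))
        assert np.median(sizes) <= 2

    def test_one_se_rule_picks_larger_lambda(self, rng):
        X = rng.normal(size=(60, 10))
        y = X[:, 0] * 2 + rng.normal(size=60)
        grid = lambda_grid(X, y, n_lambda=40, eps_ratio=1e-3)
        cv_min = cross_validate_path(X, y, grid, k_folds=5, seed=1, rule="min")
        cv_1se = cross_validate_path(X, y, grid, k_folds=5, seed=1, rule="1se")
        assert cv_1se.lambda_best >= cv_min.lambda_best

    def test_fold_assignment_balance(self):
        labels = fold_assignments(23, 5, seed=0)
        counts = np.bincount(labels)
        assert counts.max() - counts.min() <= 1

    def test_too_few_observations_for_folds(self, rng):
        with pytest.raises(ConfigurationError):
            fold_assignments(3, 5, seed=0)
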