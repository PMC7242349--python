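"""L1-penalized regression core: solution paths and cross-validation curves.

The LASSO estimate minimizes (1/2n) ||y - X beta||^2 + lambda ||beta||_1 on
internally standardized data (columns centered and scaled to unit variance,
response centered).  Solutions over a decreasing lambda grid are obtained by
warm-started cyclic coordinate descent (scikit-learn's solver) with a
duality-gap stopping rule; coefficients are reported on the original scale.
Both the influence diagnostics and the prediction models build on these
objects, so the grid and fold bookkeeping live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solver import cd_path
from .exceptions import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "Standardization",
    "LassoPath",
    "CVCurve",
    "lambda_grid",
    "fit_lasso_path",
    "cross_validate_path",
    "fold_assignments",
]

DEFAULT_N_LAMBDA = 100
DEFAULT_EPS_RATIO = 1e-3
DEFAULT_K_FOLDS = 10
DEFAULT_TOL = 1e-4


@dataclass(frozen=True)
class Standardization:
    """Column means/scales and response mean used to standardize a fit."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float


@dataclass
class LassoPath:
    """Coefficient paths over a strictly decreasing lambda grid.

    ``coefs`` holds standardized-scale coefficients (p x L); original-scale
    coefficients and per-lambda intercepts are derived properties so that
    predictions can be formed directly from raw genotype matrices.
    """

    lambdas: np.ndarray
    coefs: np.ndarray  # (p, L), standardized scale
    standardization: Standardization

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    @property
    def coefs_original(self) -> np.ndarray:
        return self.coefs / self.standardization.x_scale[:, None]

    @property
    def intercepts(self) -> np.ndarray:
        s = self.standardization
        return s.y_mean - s.x_mean @ self.coefs_original

    def active_set(self, index: int) -> frozenset[int]:
        """Support of the coefficient vector at grid position ``index``."""
        return frozenset(np.flatnonzero(self.coefs[:, index]).tolist())

    def predict(self, X: np.ndarray, index: int) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefs_original[:, index] + self.intercepts[index]


@dataclass
class CVCurve:
    """K-fold CV prediction-error curve over a lambda grid with the selected point."""

    lambdas: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray
    k_folds: int
    seed: int
    rule: str = "min"

    def __post_init__(self) -> None:
        if self.rule not in ("min", "1se"):
            raise ConfigurationError("selection rule must be 'min' or '1se'")

    @property
    def best_index(self) -> int:
        imin = int(np.argmin(self.mean_error))
        if self.rule == "min":
            return imin
        threshold = self.mean_error[imin] + self.se_error[imin]
        ok = np.flatnonzero(self.mean_error <= threshold)
        return int(ok[0])  # grid is decreasing: first qualifying point is largest lambda

    @property
    def lambda_best(self) -> float:
        return float(self.lambdas[self.best_index])


def _standardize(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, Standardization]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-D matrix")
    if len(y) != X.shape[0]:
        raise InputError("X and y disagree on the number of observations")
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("missing values are not allowed here; see the imputation policy")
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant; the lasso problem is degenerate")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)  # monomorphic columns stay zero
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    return np.asfortranarray(Xs), y - y_mean, Standardization(x_mean, x_scale, y_mean)


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    eps_ratio: float = DEFAULT_EPS_RATIO,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max = max_j |x_j' y| / n.

    At lambda_max every coefficient is exactly zero; the grid descends to
    ``eps_ratio * lambda_max``.
    """
    if n_lambda < 2:
        raise ConfigurationError("n_lambda must be >= 2")
    if not 0 < eps_ratio < 1:
        raise ConfigurationError("eps_ratio must lie in (0, 1)")
    Xs, yc, _ = _standardize(X, y)
    n = Xs.shape[0]
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if lam_max == 0:
        raise DegenerateInputError("all predictors are uncorrelated with y at machine precision")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps_ratio), n_lambda)


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    *,
    n_lambda: int = DEFAULT_N_LAMBDA,
    eps_ratio: float = DEFAULT_EPS_RATIO,
    tol: float = DEFAULT_TOL,
    max_iter: int = 1000,
    init_path: "LassoPath | None" = None,
) -> LassoPath:
    """Solve the penalized problem at every grid point, warm-started downward.

    ``init_path`` supplies per-lambda starting coefficients from a reference
    fit on nearly identical data (e.g. the full-data path when refitting
    after one deletion), which typically cuts the solve to a few sweeps.
    """
    Xs, yc, std = _standardize(X, y)
    if grid is None:
        n = Xs.shape[0]
        lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
        if lam_max == 0:
            raise DegenerateInputError("all predictors are uncorrelated with y")
        grid = np.logspace(np.log10(lam_max), np.log10(lam_max * eps_ratio), n_lambda)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) >= 0):
        raise ConfigurationError("lambda grid must be strictly decreasing")
    if init_path is not None:
        if init_path.coefs.shape != (Xs.shape[1], len(grid)):
            raise ConfigurationError("init_path does not match the design/grid shape")
        init = np.asarray(init_path.coefs, dtype=float)
        use_init = True
    else:
        init = np.zeros((Xs.shape[1], len(grid)))
        use_init = False
    coefs = cd_path(Xs, yc, grid, init, use_init, tol, max_iter)
    return LassoPath(lambdas=grid, coefs=coefs, standardization=std)


def fold_assignments(n: int, k_folds: int, seed: int) -> np.ndarray:
    """Balanced fold labels in {0..k-1} from a seeded permutation."""
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    if n < k_folds:
        raise ConfigurationError("cannot split fewer observations than folds")
    rng = np.random.default_rng(seed)
    labels = np.resize(np.arange(k_folds), n)
    return labels[rng.permutation(n)]


def cross_validate_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    k_folds: int = DEFAULT_K_FOLDS,
    seed: int = 0,
    *,
    tol: float = DEFAULT_TOL,
    rule: str = "min",
    fold_labels: np.ndarray | None = None,
    init_path: LassoPath | None = None,
) -> CVCurve:
    """Per-lambda mean squared prediction error across folds, with SE.

    ``fold_labels`` lets callers supply an externally derived assignment
    (the leave-one-out diagnostics drop one observation from the full-data
    assignment so curve differences reflect the deletion, not fold churn).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if fold_labels is None:
        fold_labels = fold_assignments(n, k_folds, seed)
    fold_labels = np.asarray(fold_labels)
    if len(fold_labels) != n:
        raise ConfigurationError("fold labels must cover every observation")
    fold_mse = []
    for f in np.unique(fold_labels):
        test = fold_labels == f
        train = ~test
        if train.sum() < 2 or test.sum() < 1:
            raise ConfigurationError(f"fold {f} leaves fewer than 2 training observations")
        path = fit_lasso_path(X[train], y[train], grid, tol=tol, init_path=init_path)
        pred = X[test] @ path.coefs_original + path.intercepts  # (n_test, L)
        fold_mse.append(((y[test, None] - pred) ** 2).mean(axis=0))
    fold_mse = np.asarray(fold_mse)
    mean_error = fold_mse.mean(axis=0)
    se_error = fold_mse.std(axis=0, ddof=1) / np.sqrt(fold_mse.shape[0])
    return CVCurve(
        lambdas=grid,
        mean_error=mean_error,
        se_error=se_error,
        k_folds=int(len(np.unique(fold_labels))),
        seed=seed,
        rule=rule,
    )
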