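"""Leave-one-out influence diagnostics for LASSO fits.

Case-deletion diagnostics ask how much the fitted object moves when a single
observation is removed.  For a penalized path fit there are four natural
"objects" to watch, and each yields one per-observation measure:

``df_model``
    change in the selected variable set: |A symdiff A_(i)| where A is the
    support of the coefficient vector at the CV-selected lambda.
``df_lambda``
    movement of the CV-selected penalty: |ln lambda_(i) - ln lambda|.
``df_regpath``
    mean normalized Euclidean distance between the two coefficient paths
    along the shared lambda grid.
``df_cvpath``
    mean normalized absolute distance between the two CV error curves.

All four are zero when deleting the observation changes nothing.  Each
measure is converted to a per-observation p-value (empirical rank calibration
by default, a robust-z alternative for continuous measures); the combination
of the four p-values into a single decision lives in :mod:`gslens.combine`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ContractError, InputError
from .lasso_engine import (
    DEFAULT_EPS_RATIO,
    DEFAULT_K_FOLDS,
    DEFAULT_N_LAMBDA,
    DEFAULT_TOL,
    CVCurve,
    LassoPath,
    fit_lasso_path,
    fold_assignments,
    lambda_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InfluenceConfig",
    "InfluenceTable",
    "ALL_MEASURES",
    "loo_refits",
    "df_model",
    "df_lambda",
    "df_regpath",
    "df_cvpath",
    "measure_pvalues",
    "influence_table",
    "detect_outliers",
]

ALL_MEASURES = ("df_model", "df_lambda", "df_regpath", "df_cvpath")


@dataclass(frozen=True)
class InfluenceConfig:
    """Tunables of the diagnostic pass.

    The defaults match the engine defaults (100-point grid down to 1e-3 of
    lambda_max, 10 folds).  ``measures`` may be a subset: when neither
    ``df_lambda``, ``df_model`` nor ``df_cvpath`` is requested the CV stage
    is skipped entirely, which makes a pure ``df_regpath`` pass much cheaper.
    """

    n_lambda: int = DEFAULT_N_LAMBDA
    eps_ratio: float = DEFAULT_EPS_RATIO
    k_folds: int = DEFAULT_K_FOLDS
    seed: int = 0
    tol: float = DEFAULT_TOL
    measures: tuple[str, ...] = ALL_MEASURES
    pvalue_method: str = "empirical_mid"

    def __post_init__(self) -> None:
        unknown = set(self.measures) - set(ALL_MEASURES)
        if unknown:
            raise ConfigurationError(f"unknown influence measures: {sorted(unknown)}")
        if not self.measures:
            raise ConfigurationError("at least one influence measure must be requested")
        if self.pvalue_method not in ("empirical", "empirical_mid", "robust_z"):
            raise ConfigurationError(
                "pvalue_method must be 'empirical', 'empirical_mid' or 'robust_z'"
            )

    @property
    def needs_cv(self) -> bool:
        return bool({"df_model", "df_lambda", "df_cvpath"} & set(self.measures))


@dataclass
class InfluenceTable:
    """Per-observation diagnostic values and p-values plus run metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def pvalue_matrix(self, measures: tuple[str, ...] = ALL_MEASURES) -> np.ndarray:
        """n x K matrix of per-measure p-values, ready for combination."""
        cols = [f"p_{m}" for m in measures if f"p_{m}" in self.frame.columns]
        if not cols:
            raise ContractError("no p-value columns present for the requested measures")
        return self.frame[cols].to_numpy()


class LooWorkspace:
    """Shared state for the n leave-one-out refits.

    Holds the full-data path, the per-fold reference paths and per-test-
    observation squared-error curves.  Each LOO refit is warm-started from
    the matching reference fit (the solutions sit a single deletion apart),
    and the fold whose test split contains the deleted observation needs no
    refit at all: its training rows are unchanged, so only that
    observation's residuals drop out of the curve.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        grid: np.ndarray,
        fold_labels: np.ndarray | None,
        tol: float = DEFAULT_TOL,
        seed: int = 0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.grid = np.asarray(grid, dtype=float)
        self.tol = tol
        self.seed = seed
        self.n = len(self.y)
        self.full_path = fit_lasso_path(self.X, self.y, self.grid, tol=tol)
        self.fold_labels = fold_labels
        self.folds: list[dict] = []
        self.full_cv: CVCurve | None = None
        if fold_labels is not None:
            for f in np.unique(fold_labels):
                test = np.flatnonzero(fold_labels == f)
                train = np.flatnonzero(fold_labels != f)
                path_f = fit_lasso_path(
                    self.X[train], self.y[train], self.grid,
                    tol=tol, init_path=self.full_path,
                )
                pred = self.X[test] @ path_f.coefs_original + path_f.intercepts
                sqerr = (self.y[test, None] - pred) ** 2  # (n_test, L)
                self.folds.append(
                    {"test": test, "train": train, "path": path_f, "sqerr": sqerr}
                )
            self.full_cv = self._curve([fold["sqerr"].mean(axis=0) for fold in self.folds])

    def _curve(self, fold_mse: list[np.ndarray]) -> CVCurve:
        fm = np.asarray(fold_mse)
        return CVCurve(
            lambdas=self.grid,
            mean_error=fm.mean(axis=0),
            se_error=fm.std(axis=0, ddof=1) / np.sqrt(fm.shape[0]),
            k_folds=fm.shape[0],
            seed=self.seed,
        )

    def loo(self, i: int) -> tuple[LassoPath, CVCurve | None]:
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        path_i = fit_lasso_path(
            self.X[keep], self.y[keep], self.grid, tol=self.tol,
            init_path=self.full_path,
        )
        if self.fold_labels is None:
            return path_i, None
        fold_mse = []
        for fold in self.folds:
            if i in fold["test"]:
                # training rows untouched: reuse the reference fit, drop the
                # deleted observation's residuals from the curve
                mask = fold["test"] != i
                if not mask.any():
                    continue
                fold_mse.append(fold["sqerr"][mask].mean(axis=0))
            else:
                train = fold["train"][fold["train"] != i]
                path_f = fit_lasso_path(
                    self.X[train], self.y[train], self.grid,
                    tol=self.tol, init_path=fold["path"],
                )
                pred = self.X[fold["test"]] @ path_f.coefs_original + path_f.intercepts
                fold_mse.append(((self.y[fold["test"], None] - pred) ** 2).mean(axis=0))
        return path_i, self._curve(fold_mse)


def loo_refits(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    k_folds: int = DEFAULT_K_FOLDS,
    seed: int = 0,
    *,
    tol: float = DEFAULT_TOL,
    with_cv: bool = True,
    full_fold_labels: np.ndarray | None = None,
):
    """Yield (path_i, cv_i) for every left-out observation i, on the shared grid.

    Fold labels for the reduced data are the full-data labels with entry i
    dropped, so the i-th CV curve differs from the full curve only through
    the deletion.  Results are independent of evaluation order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise InputError("leave-one-out diagnostics need at least 3 observations")
    if full_fold_labels is None and with_cv:
        full_fold_labels = fold_assignments(n, k_folds, seed)
    ws = LooWorkspace(X, y, grid, full_fold_labels if with_cv else None, tol=tol, seed=seed)
    for i in range(n):
        yield ws.loo(i)


def df_model(
    full_path: LassoPath,
    full_cv: CVCurve,
    loo_path: LassoPath,
    loo_cv: CVCurve,
) -> int:
    """Size of the symmetric difference between the two selected variable sets.

    Each fit contributes the support of its coefficient vector at its own
    CV-selected lambda; lambda movement itself is df_lambda's job.
    """
    a_full = full_path.active_set(full_cv.best_index)
    a_loo = loo_path.active_set(loo_cv.best_index)
    return len(a_full ^ a_loo)


def df_lambda(lambda_full: float, lambda_loo: float) -> float:
    """Absolute log-ratio |ln lambda_(i) - ln lambda| of the selected penalties."""
    if lambda_full <= 0 or lambda_loo <= 0:
        raise InputError("selected penalties must be positive")
    return abs(np.log(lambda_loo) - np.log(lambda_full))


def df_regpath(full_path: LassoPath, loo_path: LassoPath) -> float:
    """Mean normalized Euclidean distance between coefficient paths.

    (1/L) sum_l ||beta(l) - beta_(i)(l)||_2 / (1 + ||beta(l)||_2), computed on
    original-scale coefficients so the two fits' (slightly different)
    standardizations cannot masquerade as influence.
    """
    if full_path.n_lambda != loo_path.n_lambda or not np.allclose(
        full_path.lambdas, loo_path.lambdas
    ):
        raise ContractError("paths must share the lambda grid")
    b_full = full_path.coefs_original
    b_loo = loo_path.coefs_original
    num = np.linalg.norm(b_full - b_loo, axis=0)
    den = 1.0 + np.linalg.norm(b_full, axis=0)
    return float(np.mean(num / den))


def df_cvpath(full_cv: CVCurve, loo_cv: CVCurve) -> float:
    """Mean normalized absolute distance between CV error curves.

    (1/L) sum_l |CV(l) - CV_(i)(l)| / (1 + CV(l)).
    """
    if len(full_cv.lambdas) != len(loo_cv.lambdas) or not np.allclose(
        full_cv.lambdas, loo_cv.lambdas
    ):
        raise ContractError("CV curves must share the lambda grid")
    num = np.abs(full_cv.mean_error - loo_cv.mean_error)
    den = 1.0 + full_cv.mean_error
    return float(np.mean(num / den))


def measure_pvalues(values: np.ndarray, method: str = "empirical") -> np.ndarray:
    """Per-observation p-values for one influence measure (large = influential).

    empirical
        p_i = (1 + #{j != i : m_j >= m_i}) / n — distribution-free, based on
        exchangeability of uncontaminated observations; ties share a p-value.
    empirical_mid
        mid-rank variant p_i = (0.5 + #{j != i : m_j > m_i}
        + 0.5 #{j != i : m_j = m_i}) / n.  The strict variant maps the modal
        value of a tie-heavy discrete measure to exactly 1, which after
        clamping turns into a large negative z in the Stouffer/logit
        combiners and drowns observations that are influential on only a
        subset of measures; the mid-p correction keeps the discrete null
        centered at 1/2 (this is the detector default).
    robust_z
        upper-tail normal probability of (m_i - median) / (1.4826 MAD); falls
        back to the empirical rule with a warning when the MAD is zero.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise InputError("need at least 3 values to calibrate p-values")
    if method == "empirical":
        ge = (values[None, :] >= values[:, None]).sum(axis=1) - 1  # exclude self
        return (1.0 + ge) / n
    if method == "empirical_mid":
        gt = (values[None, :] > values[:, None]).sum(axis=1)
        eq = (values[None, :] == values[:, None]).sum(axis=1) - 1  # exclude self
        return (0.5 + gt + 0.5 * eq) / n
    if method == "robust_z":
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        if mad == 0:
            logger.warning("robust_z calibration: MAD is zero, falling back to empirical")
            return measure_pvalues(values, "empirical")
        z = (values - med) / (1.4826 * mad)
        p = stats.norm.sf(z)
        return np.clip(p, np.finfo(float).tiny, 1.0)
    raise ConfigurationError("method must be 'empirical', 'empirical_mid' or 'robust_z'")


def influence_table(
    X: np.ndarray,
    y: np.ndarray,
    config: InfluenceConfig = InfluenceConfig(),
    observation_ids: list[str] | None = None,
) -> InfluenceTable:
    """Full diagnostic pass: full fit, n leave-one-out refits, measures, p-values.

    Deterministic given ``config.seed``; the same seed drives the full-data
    fold assignment from which every leave-one-out assignment is derived.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    grid = lambda_grid(X, y, config.n_lambda, config.eps_ratio)
    full_labels = None
    if config.needs_cv:
        full_labels = fold_assignments(n, config.k_folds, config.seed)
    ws = LooWorkspace(X, y, grid, full_labels, tol=config.tol, seed=config.seed)
    full_path, full_cv = ws.full_path, ws.full_cv

    values: dict[str, list[float]] = {m: [] for m in config.measures}
    for i in range(n):
        path_i, cv_i = ws.loo(i)
        if "df_model" in values:
            values["df_model"].append(df_model(full_path, full_cv, path_i, cv_i))
        if "df_lambda" in values:
            values["df_lambda"].append(df_lambda(full_cv.lambda_best, cv_i.lambda_best))
        if "df_regpath" in values:
            values["df_regpath"].append(df_regpath(full_path, path_i))
        if "df_cvpath" in values:
            values["df_cvpath"].append(df_cvpath(full_cv, cv_i))

    if observation_ids is None:
        observation_ids = [str(i) for i in range(n)]
    data: dict[str, np.ndarray | list] = {"observation": observation_ids}
    for m in config.measures:
        arr = np.asarray(values[m], dtype=float)
        data[m] = arr
        data[f"p_{m}"] = measure_pvalues(arr, config.pvalue_method)
    frame = pd.DataFrame(data)
    metadata = {
        "n_lambda": config.n_lambda,
        "eps_ratio": config.eps_ratio,
        "k_folds": config.k_folds,
        "seed": config.seed,
        "tol": config.tol,
        "measures": list(config.measures),
        "pvalue_method": config.pvalue_method,
        "lambda_max": float(grid[0]),
        "lambda_best_full": None if full_cv is None else full_cv.lambda_best,
    }
    return InfluenceTable(frame=frame, metadata=metadata)


def detect_outliers(
    X: np.ndarray,
    y: np.ndarray,
    config: InfluenceConfig = InfluenceConfig(),
    methods: tuple[str, ...] | None = None,
    alpha: float = 0.05,
):
    """One-call detector: diagnostics, p-value combination, flagged sets.

    Returns (InfluenceTable, CombinedResult); the flagged set of combination
    method ``m`` is ``result.flagged_set(m)``.
    """
    from .combine import ALL_METHODS, combine_pvalues

    table = influence_table(X, y, config)
    combined = combine_pvalues(
        table.pvalue_matrix(config.measures),
        methods=methods or ALL_METHODS,
        alpha=alpha,
    )
    return table, combined
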