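"""P-value combination (meta-analysis) and outlier flagging.

Four per-observation diagnostic p-values p_1..p_K are fused into one overall
significance value under the classical independent-uniform null:

=====================  =============================================  ==========
method                 statistic                                      null
=====================  =============================================  ==========
fisher (inverse chi2)  L = sum_k -2 ln p_k                            chi2_{2K}
logit                  T = -(sum_k ln[p_k/(1-p_k)]) / C               t_{5K+4}
meanp                  W = (0.5 - pbar) sqrt(12 K)                    N(0, 1)
sumz (Stouffer)        Z = sum_k w_k z(p_k) / sqrt(sum_k w_k^2)       N(0, 1)
=====================  =============================================  ==========

with C = sqrt(K pi^2 (5K + 2) / (3 (5K + 4))) (the Mudholkar–George scaling
that makes the t_{5K+4} reference correct) and z(p) the upper-tail standard
normal quantile.  Small p_k push every combined p toward zero.  Observations
are flagged when the combined p-value falls strictly below the cut-off
(default 0.05).  The four diagnostics are not independent in practice; the
combiners implement the stated nulls as-is and the calibration under
dependence is a matter for the test suite, not a correction applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_METHODS",
    "CombinedResult",
    "combine_fisher",
    "combine_logit",
    "combine_meanp",
    "combine_sumz",
    "combine_pvalues",
    "flag_outliers",
]

ALL_METHODS = ("fisher", "logit", "meanp", "sumz")


def _check_open_unit(p: np.ndarray, allow_one: bool) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    hi_ok = p <= 1.0 if allow_one else p < 1.0
    if not np.all((p > 0.0) & hi_ok):
        bound = "(0, 1]" if allow_one else "(0, 1)"
        raise InputError(f"p-values must lie in {bound}")
    return p


def combine_fisher(pvalues: np.ndarray) -> tuple[float, float]:
    """Fisher's inverse chi-square method: (L, upper-tail chi2_{2K} p-value)."""
    p = _check_open_unit(pvalues, allow_one=True)
    L = float(np.sum(-2.0 * np.log(p)))
    return L, float(stats.chi2.sf(L, 2 * len(p)))


def combine_logit(pvalues: np.ndarray) -> tuple[float, float]:
    """Logit (Mudholkar–George) method: (T, upper-tail t_{5K+4} p-value)."""
    p = _check_open_unit(pvalues, allow_one=False)
    k = len(p)
    c = np.sqrt(k * np.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
    T = float(-np.sum(np.log(p / (1.0 - p))) / c)
    return T, float(stats.t.sf(T, 5 * k + 4))


def combine_meanp(pvalues: np.ndarray) -> tuple[float, float]:
    """Mean-p method: (W, upper-tail N(0,1) p-value); needs K >= 4."""
    p = _check_open_unit(pvalues, allow_one=True)
    k = len(p)
    if k < 4:
        raise ConfigurationError("meanp's normal approximation needs at least 4 p-values")
    W = float((0.5 - p.mean()) * np.sqrt(12.0 * k))
    return W, float(stats.norm.sf(W))


def combine_sumz(pvalues: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Stouffer's weighted-z method: (Z, upper-tail N(0,1) p-value).

    z(p) is the upper-tail quantile, so small p_k give large Z and a small
    combined p, in the same direction as the other combiners.  Default
    weights are 1; rescaling all weights leaves Z unchanged.
    """
    p = _check_open_unit(pvalues, allow_one=False)
    if weights is None:
        w = np.ones(len(p))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(p):
            raise InputError("weights and p-values differ in length")
        if np.any(w <= 0):
            raise InputError("weights must be positive")
    Z = float(w @ stats.norm.isf(p) / np.sqrt(w @ w))
    return Z, float(stats.norm.sf(Z))


_COMBINERS = {
    "fisher": combine_fisher,
    "logit": combine_logit,
    "meanp": combine_meanp,
    "sumz": combine_sumz,
}

# combiners whose transform diverges at p = 1 and therefore need clamping
_NEEDS_CLAMP = {"logit", "sumz"}


def flag_outliers(combined_p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Indices with combined p strictly below the cut-off (p = alpha is kept)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    p = np.asarray(combined_p, dtype=float)
    return np.flatnonzero(p < alpha)


@dataclass
class CombinedResult:
    """Per-observation combined statistics/p-values and the flagged sets."""

    frame: pd.DataFrame
    alpha: float
    flagged: dict[str, np.ndarray] = field(default_factory=dict)
    n_combined: int = 0

    def flagged_set(self, method: str) -> np.ndarray:
        return self.flagged[method]


def combine_pvalues(
    pmatrix: np.ndarray,
    methods: tuple[str, ...] = ALL_METHODS,
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
    observation_ids: list[str] | None = None,
) -> CombinedResult:
    """Combine an n x K matrix of per-measure p-values, one row per observation.

    Empirical rank calibration produces p = 1 for the least extreme
    observation; for the logit and sumz transforms (undefined at 1) such
    values are clamped to 1 - 1/(2n) with a logged warning.
    """
    P = np.asarray(pmatrix, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise InputError("expected an n x K matrix with K >= 2 p-values per observation")
    if np.any((P <= 0) | (P > 1)):
        raise InputError("p-values must lie in (0, 1]")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ConfigurationError(f"unknown combination methods: {sorted(unknown)}")
    n, k = P.shape
    clamp_hi = 1.0 - 1.0 / (2.0 * n)
    n_clamped = int(np.sum(P >= 1.0))
    if n_clamped and (_NEEDS_CLAMP & set(methods)):
        logger.warning(
            "clamping %d p-value(s) equal to 1 to %.6g for logit/sumz", n_clamped, clamp_hi
        )
    P_clamped = np.minimum(P, clamp_hi)

    if observation_ids is None:
        observation_ids = [str(i) for i in range(n)]
    data: dict[str, list | np.ndarray] = {"observation": observation_ids}
    flagged: dict[str, np.ndarray] = {}
    for method in methods:
        fn = _COMBINERS[method]
        use = P_clamped if method in _NEEDS_CLAMP else P
        if method == "sumz":
            out = [fn(use[i], weights) for i in range(n)]
        else:
            out = [fn(use[i]) for i in range(n)]
        stat = np.array([s for s, _ in out])
        pc = np.array([p for _, p in out])
        data[f"stat_{method}"] = stat
        data[f"p_{method}"] = pc
        flagged[method] = flag_outliers(pc, alpha)
        data[f"flag_{method}"] = np.isin(np.arange(n), flagged[method])
    return CombinedResult(frame=pd.DataFrame(data), alpha=alpha, flagged=flagged, n_combined=k)
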