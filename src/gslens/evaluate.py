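"""Cross-validated prediction evaluation, detector scoring and TOPSIS ranking.

Prediction quality is summarized by the accuracy r — the Pearson correlation
between observed and predicted phenotype on held-out individuals — and the
prediction error PE/MSE, averaged over repeated random 70/30 train/test
splits with standard errors.  Methods are compared to a named baseline as a
percentage gain in accuracy and percentage reduction in MSE.  Detector
output is scored against the simulation ground truth with precision, recall
and the F1 score; the headline F1 is the geometric mean sqrt(P * R) (the
harmonic-mean variant is also emitted).  TOPSIS turns a methods x criteria
table into a single ranking by closeness to the ideal solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "PredictionReport",
    "ConfusionCounts",
    "accuracy",
    "mse",
    "cv_protocol",
    "pct_change",
    "score_detector",
    "topsis",
]


@dataclass
class PredictionReport:
    """Per-replicate accuracy/MSE with aggregates."""

    replicates: pd.DataFrame  # columns: replicate, accuracy, mse
    n_rep: int
    train_frac: float
    model: str = ""
    treatment: str = "none"

    @property
    def mean_accuracy(self) -> float:
        return float(self.replicates["accuracy"].mean())

    @property
    def se_accuracy(self) -> float:
        return float(self.replicates["accuracy"].std(ddof=1) / np.sqrt(self.n_rep))

    @property
    def mean_mse(self) -> float:
        return float(self.replicates["mse"].mean())

    @property
    def se_mse(self) -> float:
        return float(self.replicates["mse"].std(ddof=1) / np.sqrt(self.n_rep))

    def summary(self) -> dict:
        return {
            "model": self.model,
            "treatment": self.treatment,
            "accuracy": self.mean_accuracy,
            "mse": self.mean_mse,
            "accuracy_se": self.se_accuracy,
            "mse_se": self.se_mse,
            "n_rep": self.n_rep,
            "train_frac": self.train_frac,
        }


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def accuracy(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted phenotypes."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise InputError("observed and predicted vectors differ in length")
    if len(y_obs) < 3:
        raise InputError("need at least 3 pairs for a correlation")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(y_obs, y_pred).statistic)


def mse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared difference (the prediction error PE)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise InputError("observed and predicted vectors differ in length")
    if len(y_obs) == 0:
        raise InputError("empty vectors")
    return float(np.mean((y_obs - y_pred) ** 2))


def cv_protocol(
    X: np.ndarray,
    y: np.ndarray,
    model_factory,
    n_rep: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    model_name: str = "",
    treatment: str = "none",
) -> PredictionReport:
    """Repeated random-split evaluation: per-replicate r and MSE on the test set.

    ``model_factory`` returns a fresh object with fit/predict per replicate.
    Any outlier treatment must already have been applied to (X, y): the
    workflow treats the full dataset first and splits afterwards.
    """
    if n_rep < 2:
        raise ConfigurationError("n_rep must be >= 2")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_train = int(round(train_frac * n))
    if n - n_train < 3:
        raise ConfigurationError("test set would have fewer than 3 observations")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_rep):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        rows.append(
            {"replicate": rep, "accuracy": accuracy(y[te], pred), "mse": mse(y[te], pred)}
        )
    return PredictionReport(
        replicates=pd.DataFrame(rows),
        n_rep=n_rep,
        train_frac=train_frac,
        model=model_name,
        treatment=treatment,
    )


def pct_change(
    report: "PredictionReport | float | tuple",
    baseline: "PredictionReport | float | tuple",
) -> tuple[float, float]:
    """Percentage gain in accuracy and percentage reduction in MSE vs a baseline.

    gain% = 100 (acc - acc_base) / acc_base;
    reduction% = 100 (mse_base - mse) / mse_base.
    Accepts either reports or bare (accuracy, mse) pairs.
    """

    def unpack(r):
        if isinstance(r, PredictionReport):
            return r.mean_accuracy, r.mean_mse
        acc, m = r
        return float(acc), float(m)

    acc, m = unpack(report)
    acc_base, m_base = unpack(baseline)
    if acc_base == 0 or m_base == 0:
        raise InputError("baseline accuracy/MSE must be nonzero")
    gain = 100.0 * (acc - acc_base) / acc_base
    reduction = 100.0 * (m_base - m) / m_base
    return gain, reduction


def score_detector(
    flagged_set: np.ndarray, truth_set: np.ndarray, n: int
) -> tuple[ConfusionCounts, dict]:
    """Precision, recall and F1 of a flagged set against the injected truth.

    F1 is sqrt(precision * recall); 0/0 cases resolve to 0.  The
    harmonic-mean variant is reported alongside under ``f1_harmonic``.
    """
    flagged = set(np.asarray(flagged_set, dtype=int).tolist())
    truth = set(np.asarray(truth_set, dtype=int).tolist())
    universe = set(range(n))
    if not flagged <= universe or not truth <= universe:
        raise InputError("flagged/truth indices outside 0..n-1")
    tp = len(flagged & truth)
    fp = len(flagged - truth)
    fn = len(truth - flagged)
    tn = n - tp - fp - fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = float(np.sqrt(precision * recall))
    f1_harm = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    return counts, {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "f1_harmonic": f1_harm,
    }


def topsis(
    matrix: pd.DataFrame,
    weights: np.ndarray | None = None,
    impacts: list[str] | None = None,
) -> pd.DataFrame:
    """Rank alternatives by closeness to the ideal solution.

    Each criterion column is divided by its Euclidean norm, multiplied by its
    weight; the positive/negative ideal solutions take the per-column
    best/worst according to ``impacts`` ('+' benefit, '-' cost).  Closeness
    C = d^- / (d^+ + d^-) is returned with ranks (1 = best).
    """
    if len(matrix) < 2:
        raise InputError("TOPSIS needs at least 2 alternatives")
    values = matrix.to_numpy(dtype=float)
    n_alt, n_crit = values.shape
    if n_crit < 1:
        raise InputError("TOPSIS needs at least 1 criterion")
    if weights is None:
        weights = np.ones(n_crit)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0) or len(weights) != n_crit:
        raise ConfigurationError("weights must be positive, one per criterion")
    if impacts is None:
        impacts = ["+"] * n_crit
    if len(impacts) != n_crit or any(s not in "+-" for s in impacts):
        raise ConfigurationError("impacts must be '+' or '-', one per criterion")
    norms = np.linalg.norm(values, axis=0)
    if np.any(norms == 0):
        raise InputError("a criterion column is identically zero")
    V = values / norms * (weights / weights.sum())
    best = np.where([s == "+" for s in impacts], V.max(axis=0), V.min(axis=0))
    worst = np.where([s == "+" for s in impacts], V.min(axis=0), V.max(axis=0))
    d_plus = np.linalg.norm(V - best, axis=1)
    d_minus = np.linalg.norm(V - worst, axis=1)
    with np.errstate(invalid="ignore"):
        closeness = np.where(d_plus + d_minus > 0, d_minus / (d_plus + d_minus), 0.0)
    order = np.argsort(-closeness, kind="stable")
    ranks = np.empty(n_alt, dtype=int)
    ranks[order] = np.arange(1, n_alt + 1)
    return pd.DataFrame(
        {"closeness": closeness, "rank": ranks}, index=matrix.index
    )
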