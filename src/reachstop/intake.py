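"""Intake prediction and feature selection.

Predicts ad-libitum chocolate intake (kcal) from the standardized
per-participant predictor set with ordinary least squares, elastic net and
Lasso.  The elastic-net mixing parameter and penalty strength are chosen by
grid search over K-fold cross-validated mean absolute error (MAE); the Lasso
is the same search restricted to a pure L1 penalty, which is the only
configuration that zeroes out coefficients and thereby performs feature
selection.  Weights are reported on the standardized predictor scale; MAE
stays in kcal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import PREDICTORS


@dataclass
class FitReport:
    model: str                          # ols | elastic_net | lasso
    weights: dict[str, float]           # standardized scale
    intercept: float
    selected: list[str]                 # nonzero-weight predictors
    mae_in: float                       # kcal, full training data
    mae_out: float                      # kcal, mean held-out MAE over folds
    l1_ratio: float | None = None
    alpha: float | None = None
    cv_seed: int | None = None
    flags: list[str] = field(default_factory=list)


def standardize_features(table: pd.DataFrame,
                         predictors=PREDICTORS) -> tuple[pd.DataFrame, dict]:
    """Centre/scale each predictor to mean 0, SD 1 (complete cases).

    Zero-variance predictors are dropped with a warning.  Returns the
    standardized table and the scaler record {name: (mean, sd)} so held-out
    data can be transformed with training statistics.
    """
    cols = [c for c in predictors if c in table.columns]
    data = table[cols].dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 complete cases")
    scaler: dict[str, tuple[float, float]] = {}
    out = {}
    for c in cols:
        m = float(data[c].mean())
        s = float(data[c].std(ddof=0))
        if s == 0:
            warnings.warn(f"dropping zero-variance predictor {c!r}")
            continue
        scaler[c] = (m, s)
        out[c] = (data[c] - m) / s
    return pd.DataFrame(out, index=data.index), scaler


def apply_scaler(table: pd.DataFrame, scaler: dict) -> pd.DataFrame:
    """Standardize with a previously fitted scaler record."""
    return pd.DataFrame({c: (table[c] - m) / s
                         for c, (m, s) in scaler.items()},
                        index=table.index)


def penalty_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_alphas: int = 50, eps: float = 1e-4) -> np.ndarray:
    """Log-spaced penalty strengths from the null-model penalty downward.

    The largest value is the smallest alpha whose L1 part zeroes every
    coefficient; the path descends by a factor ``eps``.
    """
    n = X.shape[0]
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    return np.geomspace(alpha_max, alpha_max * eps, n_alphas)


def _mae(model, X, y) -> float:
    return float(np.mean(np.abs(model.predict(X) - y)))


def fit_models(table: pd.DataFrame, outcome: str = "intake_kcal",
               predictors=PREDICTORS,
               l1_ratios=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
               n_alphas: int = 50, cv: int = 5, seed: int = 0,
               max_iter: int = 50_000) -> dict[str, FitReport]:
    """Fit OLS, elastic net and Lasso on the complete cases of ``table``.

    Standardization happens inside the CV pipeline (training-fold statistics
    only); reported weights come from a final refit on the full data.
    Returns reports keyed by model name.
    """
    cols = [c for c in predictors if c in table.columns]
    data = table[[*cols, outcome]].dropna()
    if len(data) <= cv:
        raise ValueError("complete-case n must exceed the number of folds")
    X = data[cols].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    Xz = StandardScaler().fit_transform(X)
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)

    reports: dict[str, FitReport] = {}

    ols = Pipeline([("scale", StandardScaler()), ("reg", LinearRegression())])
    ols.fit(X, y)
    mae_out = -cross_val_score(ols, X, y, cv=folds,
                               scoring="neg_mean_absolute_error").mean()
    w = dict(zip(cols, ols["reg"].coef_))
    reports["ols"] = FitReport(
        model="ols", weights=w, intercept=float(ols["reg"].intercept_),
        selected=[c for c, v in w.items() if v != 0],
        mae_in=_mae(ols, X, y), mae_out=float(mae_out), cv_seed=seed)

    grids = {
        "elastic_net": [{"reg__l1_ratio": [r],
                         "reg__alpha": penalty_grid(Xz, y, r, n_alphas)}
                        for r in l1_ratios],
        "lasso": [{"reg__l1_ratio": [1.0],
                   "reg__alpha": penalty_grid(Xz, y, 1.0, n_alphas)}],
    }
    for name, grid in grids.items():
        pipe = Pipeline([("scale", StandardScaler()),
                         ("reg", ElasticNet(max_iter=max_iter))])
        search = GridSearchCV(pipe, grid, cv=folds,
                              scoring="neg_mean_absolute_error", refit=True)
        flags: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            search.fit(X, y)
            if any(issubclass(c.category, ConvergenceWarning)
                   for c in caught):
                flags.append("convergence")
        best = search.best_estimator_
        w = dict(zip(cols, best["reg"].coef_))
        reports[name] = FitReport(
            model=name, weights=w, intercept=float(best["reg"].intercept_),
            selected=[c for c, v in w.items() if v != 0],
            mae_in=_mae(best, X, y), mae_out=float(-search.best_score_),
            l1_ratio=float(search.best_params_["reg__l1_ratio"]),
            alpha=float(search.best_params_["reg__alpha"]),
            cv_seed=seed, flags=flags)
    return reports


def support_recall(selected, true_support) -> float:
    """Fraction of truly nonzero predictors recovered by a selected set."""
    truth = set(true_support)
    if not truth:
        raise ValueError("true support is empty")
    return len(truth & set(selected)) / len(truth)


def weights_table(reports: dict[str, FitReport]) -> pd.DataFrame:
    """Standardized-weights table, one row per predictor, one column per model."""
    cols = {name: pd.Series(rep.weights) for name, rep in reports.items()}
    out = pd.DataFrame(cols)
    out.index.name = "predictor"
    return out.reset_index()
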