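"""Biomarker screening and the cross-validated ML regression benchmark.

The scientific question: do biomarkers measured at surgery (Ki67, CD31,
proliferating endothelial counts, circulating tumor cells, myeloid-derived
suppressor cells) predict the mechanistic parameters — in particular the
dissemination coefficient mu that drives long-term metastatic burden?

The benchmark regresses ln(mu) on the biomarker panel with several
regression families under repeated k-fold cross-validation (10-fold, five
repeats) and compares each model's CV RMSE and R^2 against an
intercept-only baseline that predicts the training-fold median for every
animal.  Centering/scaling and hyperparameter tuning are nested inside each
training fold; there is no leakage of held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, RepeatedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .growth import doubling_time

__all__ = [
    "correlation_screen",
    "doubling_time_covariate",
    "ml_benchmark",
    "MLBenchmark",
    "default_algorithms",
]


def correlation_screen(table: pd.DataFrame, columns=None, min_pairs: int = 3):
    """Pairwise Pearson correlations with two-sided p-values.

    Uses pairwise-complete observations; cells with fewer than ``min_pairs``
    complete pairs or a constant column are reported as NaN.  Returns
    ``(r, p, n)`` DataFrames.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        col = table[a].dropna()
        n.loc[a, a] = len(col)
        r.loc[a, a], p.loc[a, a] = (1.0, 0.0) if col.nunique() > 1 \
            else (np.nan, np.nan)
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = table[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < min_pairs or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p, n


def doubling_time_covariate(ebe: pd.DataFrame, Vi: float = 1.0e6,
                            V0: float = 1.0) -> pd.Series:
    """Per-animal log Gompertz doubling time at the inoculum size.

    The growth parameters alpha and beta are nearly collinear across
    animals, so their joint effect on growth speed is summarized by the
    doubling time at Vi = 1 mm^3 (10^6 cells); the log is the natural scale
    for regression.  ``ebe`` needs ``alpha`` and ``beta`` columns.
    """
    dt = [doubling_time(a, b, Vi, V0)
          for a, b in zip(ebe["alpha"], ebe["beta"])]
    return pd.Series(np.log(dt), index=ebe.index, name="log_DT")


class MedianBaseline(RegressorMixin, BaseEstimator):
    """Intercept-only model: predicts the training-set median of y for
    every animal."""

    def fit(self, X, y):
        self.median_ = float(np.median(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.median_)


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def default_algorithms(seed: int = 0, n_trees: int = 500) -> dict:
    """Benchmark suite: intercept-only baseline, linear and PLS regression,
    radial SVM, random forest, a randomized-split (extra-trees) forest, and
    a single-hidden-layer neural network.  Hyperparameter grids are modest,
    sized for cohorts of tens of animals; tree models skip centering and
    scaling (scale-invariant splits)."""
    return {
        "intercept": MedianBaseline(),
        "linear": _scaled(LinearRegression()),
        "pls": GridSearchCV(_scaled(PLSRegression()),
                            {"model__n_components": [1, 2, 3, 4, 5]},
                            cv=3, scoring="neg_root_mean_squared_error"),
        "svm_rbf": GridSearchCV(_scaled(SVR(kernel="rbf", gamma="scale")),
                                {"model__C": [0.25, 1.0, 4.0]},
                                cv=3, scoring="neg_root_mean_squared_error"),
        "rf": GridSearchCV(
            RandomForestRegressor(n_estimators=n_trees, random_state=seed),
            {"max_features": [2, 3, 5]},
            cv=3, scoring="neg_root_mean_squared_error"),
        "xtrees": GridSearchCV(
            ExtraTreesRegressor(n_estimators=n_trees, random_state=seed),
            {"max_features": [2, 3, 5]},
            cv=3, scoring="neg_root_mean_squared_error"),
        "ann": GridSearchCV(
            _scaled(MLPRegressor(solver="lbfgs", max_iter=5000,
                                 random_state=seed)),
            {"model__hidden_layer_sizes": [(1,), (3,), (5,)],
             "model__alpha": [0.1, 0.01]},
            cv=3, scoring="neg_root_mean_squared_error"),
    }


@dataclass
class MLBenchmark:
    """Cross-validation benchmark output.

    ``metrics``: per-algorithm mean CV RMSE / R^2 with 95% CIs over the
    resamples and the relative prediction error on y (mean +- sd of
    |yhat - y| / |y| in %).  ``resamples``: per-(algorithm, resample)
    metrics.  ``predictions``: held-out predictions (one per animal per
    repeat) for observed-vs-predicted plots.
    """

    metrics: pd.DataFrame
    resamples: pd.DataFrame
    predictions: pd.DataFrame

    def compare_to_baseline(self, baseline: str = "intercept") -> pd.DataFrame:
        """Paired comparison of CV RMSE against the baseline over the shared
        resamples: mean difference with a 95% normal CI.  An algorithm is
        significantly better only if ci_hi < 0."""
        wide = self.resamples.pivot_table(index=["repeat", "fold"],
                                          columns="algorithm", values="rmse")
        base = wide[baseline]
        rows = []
        for alg in wide.columns:
            if alg == baseline:
                continue
            d = (wide[alg] - base).dropna()
            se = d.std(ddof=1) / np.sqrt(len(d))
            rows.append({"algorithm": alg, "mean_diff": d.mean(),
                         "ci_lo": d.mean() - 1.96 * se,
                         "ci_hi": d.mean() + 1.96 * se,
                         "significantly_better": d.mean() + 1.96 * se < 0})
        return pd.DataFrame(rows).set_index("algorithm")


def ml_benchmark(X: pd.DataFrame, y: pd.Series, algorithms: dict | None = None,
                 n_splits: int = 10, n_repeats: int = 5, seed: int = 0,
                 impute: bool = False) -> MLBenchmark:
    """Repeated k-fold CV benchmark of y (e.g. ln mu-hat) on biomarkers.

    Rows with missing values are dropped (complete-case) unless ``impute``
    requests median imputation.  All preprocessing lives inside the fitted
    pipelines, so each training fold is self-contained.  Deterministic for a
    fixed seed (fold assignment and tree/ANN randomness).
    """
    df = X.copy()
    df["_y"] = np.asarray(y, float)
    if impute:
        df = df.fillna(df.median(numeric_only=True))
    else:
        df = df.dropna()
    if len(df) < 20:
        raise ValueError("need at least 20 complete animals for the benchmark")
    Xc = df.drop(columns="_y").to_numpy(float)
    yc = df["_y"].to_numpy(float)
    if algorithms is None:
        algorithms = default_algorithms(seed)

    rkf = RepeatedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    folds = list(rkf.split(Xc))
    res_rows, pred_rows = [], []
    for name, est in algorithms.items():
        for fi, (tr, te) in enumerate(folds):
            rep, fold = divmod(fi, n_splits)
            model = clone(est)
            model.fit(Xc[tr], yc[tr])
            yhat = model.predict(Xc[te]).ravel()
            rmse = float(np.sqrt(np.mean((yhat - yc[te]) ** 2)))
            sst = float(np.sum((yc[te] - yc[te].mean()) ** 2))
            if sst > 0:
                r2 = 1.0 - np.sum((yhat - yc[te]) ** 2) / sst
            else:
                warnings.warn(f"constant y in test fold {fold} (repeat {rep}); "
                              "R^2 undefined for this resample, dropped")
                r2 = np.nan
            res_rows.append({"algorithm": name, "repeat": rep, "fold": fold,
                             "rmse": rmse, "r2": r2})
            for i, j in enumerate(te):
                pred_rows.append({"algorithm": name, "repeat": rep,
                                  "index": df.index[j], "observed": yc[j],
                                  "predicted": yhat[i]})
    resamples = pd.DataFrame(res_rows)
    predictions = pd.DataFrame(pred_rows)

    def ci(v):
        v = v.dropna()
        se = v.std(ddof=1) / np.sqrt(len(v))
        return v.mean(), v.mean() - 1.96 * se, v.mean() + 1.96 * se

    rows = []
    for name, grp in resamples.groupby("algorithm", sort=False):
        rmse_m, rmse_lo, rmse_hi = ci(grp["rmse"])
        r2_m, r2_lo, r2_hi = ci(grp["r2"])
        pr = predictions[predictions["algorithm"] == name]
        with np.errstate(divide="ignore"):
            rel = 100.0 * np.abs(pr["predicted"] - pr["observed"]) \
                / np.abs(pr["observed"])
        rows.append({"algorithm": name, "cv_rmse": rmse_m,
                     "cv_rmse_lo": rmse_lo, "cv_rmse_hi": rmse_hi,
                     "cv_r2": r2_m, "cv_r2_lo": r2_lo, "cv_r2_hi": r2_hi,
                     "pred_err_pct_mean": float(rel.mean()),
                     "pred_err_pct_sd": float(rel.std(ddof=1))})
    metrics = pd.DataFrame(rows).set_index("algorithm")
    return MLBenchmark(metrics=metrics, resamples=resamples, predictions=predictions)
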