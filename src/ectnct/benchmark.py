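"""35-pipeline machine-learning benchmark under nested leave-one-out CV.

The comparison pits multivariate models on vectorized connectome features
(FA / MD / streamline-count upper triangles) against the two single-feature
whole-brain controllability predictors and a demographic baseline. The grid
is 5 preprocessing variants x 7 estimators = 35 pipelines:

    preprocessing: identity | PCA (95% variance) | PCA (20 components) |
                   univariate selection top 5% | top 10%
    estimators:    OLS | ridge | linear SVR (C=1, C=10) |
                   RBF SVR (C=1, C=10) | random forest (100 trees)

Every pipeline (including scaling, PCA, and feature selection) is fit inside
each training fold only; performance is percent variance explained by the
Spearman rank correlation between true and out-of-fold predicted response,
with negative correlations clamped to 0% (anti-prediction explains nothing
usable). Univariate selection scores features by their squared Pearson
correlation with the training-fold target (sklearn's f_regression, monotone
in |r|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import SelectPercentile, f_regression
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "PipelineSpec",
    "BenchmarkResult",
    "build_grid",
    "nested_loocv",
    "spearman_variance_explained",
    "covariate_baseline",
    "run_benchmark",
    "connectome_feature_matrix",
]

_PREPROCESSORS = ("none", "pca95", "pca20", "select5", "select10")
_ESTIMATORS = (
    "ols",
    "ridge",
    "svm_linear_c1",
    "svm_linear_c10",
    "svm_rbf_c1",
    "svm_rbf_c10",
    "random_forest",
)


@dataclass(frozen=True)
class PipelineSpec:
    """One preprocessing x estimator combination of the benchmark grid.

    ``param_grid`` is empty for all 35 default specs (hyperparameters are
    fixed by construction); when non-empty, ``nested_loocv`` selects values
    by an inner leave-one-out loop on the training fold.
    """

    name: str
    preprocessing: str
    estimator: str
    param_grid: dict = field(default_factory=dict)


def build_grid() -> list[PipelineSpec]:
    """The full 35-spec grid (5 preprocessing variants x 7 estimators)."""
    return [
        PipelineSpec(name=f"{prep}+{est}", preprocessing=prep, estimator=est)
        for prep in _PREPROCESSORS
        for est in _ESTIMATORS
    ]


def _build_pipeline(spec: PipelineSpec, n_train: int, n_features: int, seed: int) -> Pipeline:
    steps = [("scale", StandardScaler())]
    if spec.preprocessing == "none":
        pass
    elif spec.preprocessing == "pca95":
        steps.append(("prep", PCA(n_components=0.95, svd_solver="full")))
    elif spec.preprocessing == "pca20":
        k = min(20, n_train - 1, n_features)
        steps.append(("prep", PCA(n_components=k, svd_solver="full")))
    elif spec.preprocessing == "select5":
        steps.append(("prep", SelectPercentile(f_regression, percentile=5)))
    elif spec.preprocessing == "select10":
        steps.append(("prep", SelectPercentile(f_regression, percentile=10)))
    else:
        raise ValueError(f"unknown preprocessing {spec.preprocessing!r}")

    est_map = {
        "ols": lambda: LinearRegression(),
        "ridge": lambda: Ridge(alpha=1.0),
        "svm_linear_c1": lambda: SVR(kernel="linear", C=1.0),
        "svm_linear_c10": lambda: SVR(kernel="linear", C=10.0),
        "svm_rbf_c1": lambda: SVR(kernel="rbf", C=1.0),
        "svm_rbf_c10": lambda: SVR(kernel="rbf", C=10.0),
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=100, random_state=seed
        ),
    }
    if spec.estimator not in est_map:
        raise ValueError(f"unknown estimator {spec.estimator!r}")
    steps.append(("est", est_map[spec.estimator]()))
    return Pipeline(steps)


def nested_loocv(
    X: np.ndarray, y: np.ndarray, spec: PipelineSpec, seed: int = 0
) -> np.ndarray:
    """Out-of-fold predictions under nested leave-one-out cross-validation.

    For each held-out row the entire pipeline — scaling, PCA / feature
    selection, and the estimator — is refit on the remaining N-1 rows only;
    specs with tunable settings run an inner leave-one-out grid search on
    those N-1 rows. The held-out row's target never influences its own
    prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 samples")
    if p == 0:
        raise ValueError("no features")
    if np.ptp(y) == 0:
        raise ValueError("constant target")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pipe = _build_pipeline(spec, n_train=n - 1, n_features=p, seed=seed)
        model = (
            GridSearchCV(pipe, spec.param_grid, cv=LeaveOneOut(),
                         scoring="neg_mean_squared_error")
            if spec.param_grid
            else pipe
        )
        model.fit(X[mask], y[mask])
        preds[i] = float(model.predict(X[i : i + 1])[0])
    return preds


def spearman_variance_explained(true: np.ndarray, predicted: np.ndarray) -> float:
    """Percent variance explained: ``100 * rho^2`` if Spearman rho > 0 else 0."""
    true = np.asarray(true, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if true.shape != predicted.shape or true.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(true) == 0:
        raise ValueError("constant true vector")
    rho = sps.spearmanr(true, predicted).statistic
    if not np.isfinite(rho) or rho <= 0:
        return 0.0
    return float(100.0 * rho * rho)


def _loocv_linear(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain leave-one-out OLS predictions (no scaling, no selection)."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = LinearRegression().fit(X[mask], y[mask])
        preds[i] = float(model.predict(X[i : i + 1])[0])
    return preds


def covariate_baseline(table: pd.DataFrame, seed: int = 0) -> float:
    """Demographic baseline: LOO OLS on age, sex, and baseline severity.

    Returns percent variance in response explained (Spearman convention).
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    cols = ["age", "sex", "hdrs_pre", "response"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    data = table[cols].dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete rows")
    X = data[["age", "sex", "hdrs_pre"]].to_numpy(dtype=float)
    y = data["response"].to_numpy(dtype=float)
    return spearman_variance_explained(y, _loocv_linear(X, y))


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-pipeline performance table plus the headline comparisons."""

    results: pd.DataFrame  # columns: modality, pipeline, variance_explained_pct
    best_per_modality: dict[str, float]
    single_feature: dict[str, float]  # ac_mean / mc_mean LOO linear models


def run_benchmark(
    modalities: dict[str, np.ndarray],
    controllability_features: pd.DataFrame,
    target: np.ndarray,
    seed: int = 0,
    specs: list[PipelineSpec] | None = None,
) -> BenchmarkResult:
    """Run the full grid per feature modality plus the single-feature models.

    ``controllability_features`` must carry ``ac_mean`` and ``mc_mean``
    columns aligned with ``target``; each is evaluated as a plain LOO linear
    regression with no optimization or model selection.
    """
    target = np.asarray(target, dtype=float).ravel()
    n = target.size
    for name, X in modalities.items():
        if np.asarray(X).shape[0] != n:
            raise ValueError(f"modality {name!r} row count differs from target")
    if len(controllability_features) != n:
        raise ValueError("controllability feature rows differ from target")
    specs = build_grid() if specs is None else specs

    rows = []
    for mod_name, X in modalities.items():
        X = np.asarray(X, dtype=float)
        for spec in specs:
            preds = nested_loocv(X, target, spec, seed=seed)
            rows.append(
                {
                    "modality": mod_name,
                    "pipeline": spec.name,
                    "variance_explained_pct": spearman_variance_explained(
                        target, preds
                    ),
                }
            )
    single = {}
    for feat in ("ac_mean", "mc_mean"):
        x = controllability_features[feat].to_numpy(dtype=float).reshape(-1, 1)
        preds = _loocv_linear(x, target)
        ve = spearman_variance_explained(target, preds)
        single[feat] = ve
        rows.append(
            {
                "modality": "controllability",
                "pipeline": f"{feat}_linear",
                "variance_explained_pct": ve,
            }
        )
    results = pd.DataFrame(rows)
    grid_rows = results[results["modality"] != "controllability"]
    best = (
        grid_rows.groupby("modality")["variance_explained_pct"].max().to_dict()
        if len(grid_rows)
        else {}
    )
    return BenchmarkResult(results=results, best_per_modality=best, single_feature=single)


def connectome_feature_matrix(weight_matrices: list[np.ndarray]) -> np.ndarray:
    """Stack vectorized strict upper triangles of per-subject matrices."""
    if not weight_matrices:
        raise ValueError("no matrices")
    n = weight_matrices[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return np.vstack([np.asarray(w, dtype=float)[iu] for w in weight_matrices])
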