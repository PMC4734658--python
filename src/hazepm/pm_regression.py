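"""ε-SVR regression of PM2.5 on haze features, with grid search, 2-fold CV,
PCA-SVR and sequential backward feature selection (SBFS).

The regressor is ε-insensitive support vector regression with the RBF
kernel K(x, x') = exp(-gamma |x - x'|^2); the dual problem is solved by
scikit-learn's libsvm backend.  Features and targets are z-scored on the
training fold only (the ε tube lives on the standardized-target scale) and
predictions are mapped back to index units.  Hyper-parameters C and gamma
come from an exhaustive grid search scored by 2-fold cross-validated RMSE
with a recorded fold seed, mirroring the half/half train-test exchange used
to evaluate the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from hazepm.metrics import EvalReport, evaluate, rmse

_DEFAULT_GRID_C = tuple(2.0**k for k in range(-5, 16, 2))
_DEFAULT_GRID_GAMMA = tuple(2.0**k for k in range(-15, 6, 2))


@dataclass
class SVRConfig:
    """Hyper-parameters and search grids for the ε-SVR."""

    C: float = 2.0**8
    gamma: float = 2.0**2
    epsilon: float = 0.1            # on the standardized-target scale
    grid_C: tuple[float, ...] = _DEFAULT_GRID_C
    grid_gamma: tuple[float, ...] = _DEFAULT_GRID_GAMMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")
        if not self.grid_C or not self.grid_gamma:
            raise ValueError("search grids must be non-empty")


@dataclass
class SVRModel:
    """Trained ε-SVR plus the train-fold standardization parameters."""

    svr: SVR
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    standardize_x: bool = True
    version: int = 1


@dataclass
class SelectionResult:
    """SBFS output: removal order, nested subsets with CV errors, optimum."""

    removal_order: list[str]
    subsets: list[tuple[tuple[str, ...], float]]   # (feature names, CV RMSE), |D_1| ... |D_p|
    best_subset: tuple[str, ...]
    best_error: float


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def standardize(
    train_X, apply_X=None, *, impute: bool = False
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Column z-scores from the training matrix, applied to both matrices.

    Constant columns get unit divisor (zeros out, no NaN).  Missing values
    raise unless ``impute`` is set, in which case they are replaced by the
    training column mean before scoring.
    """
    train_X = _as_matrix(train_X).copy()
    if train_X.shape[0] < 2:
        raise ValueError("need >= 2 training rows to standardize")
    if np.isnan(train_X).any():
        if not impute:
            raise ValueError("missing values present; pass impute=True to mean-impute")
        col_mean = np.nanmean(train_X, axis=0)
        train_X = np.where(np.isnan(train_X), col_mean, train_X)
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out_apply = None
    if apply_X is not None:
        apply_X = _as_matrix(apply_X).copy()
        if np.isnan(apply_X).any():
            if not impute:
                raise ValueError("missing values present; pass impute=True to mean-impute")
            apply_X = np.where(np.isnan(apply_X), mean, apply_X)
        out_apply = (apply_X - mean) / sd
    return (train_X - mean) / sd, out_apply, mean, sd


def train_svr(X, y, cfg: SVRConfig | None = None, *, standardize_x: bool = True) -> SVRModel:
    """Fit the ε-SVR with RBF kernel on (X, y).

    Features are z-scored with training statistics unless ``standardize_x``
    is False (e.g. when the caller already works in a projected space whose
    scale must be preserved); targets are always z-scored so that ε is
    scale-free, and predictions are returned in original units.
    """
    cfg = cfg or SVRConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    if standardize_x:
        Xz, _, x_mean, x_sd = standardize(X)
    else:
        Xz = X
        x_mean = np.zeros(X.shape[1])
        x_sd = np.ones(X.shape[1])
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0:
        y_sd = 1.0
    yz = (y - y_mean) / y_sd
    svr = SVR(kernel="rbf", C=cfg.C, gamma=cfg.gamma, epsilon=cfg.epsilon)
    svr.fit(Xz, yz)
    return SVRModel(svr, x_mean, x_sd, y_mean, y_sd, standardize_x=standardize_x)


def predict(model: SVRModel, X) -> np.ndarray:
    """Predict PM values for raw feature rows."""
    X = _as_matrix(X)
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({model.x_mean.size})"
        )
    Xz = (X - model.x_mean) / model.x_sd
    return model.svr.predict(Xz) * model.y_sd + model.y_mean


def _half_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return perm[: n // 2], perm[n // 2 :]


def cv_predict_2fold(
    X, y, cfg: SVRConfig | None = None, *, standardize_x: bool = True
) -> np.ndarray:
    """Out-of-fold predictions from a random half/half split.

    Half the samples train a model that predicts the other half, and vice
    versa; every sample is predicted exactly once.  The split is a uniform
    random permutation driven by ``cfg.seed``.
    """
    cfg = cfg or SVRConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("2-fold CV needs n >= 4")
    first, second = _half_split(n, cfg.seed)
    yhat = np.empty(n)
    for train_idx, test_idx in ((first, second), (second, first)):
        model = train_svr(X[train_idx], y[train_idx], cfg, standardize_x=standardize_x)
        yhat[test_idx] = predict(model, X[test_idx])
    return yhat


def grid_search(X, y, cfg: SVRConfig | None = None) -> tuple[float, float]:
    """Exhaustive (C, gamma) search scored by 2-fold CV RMSE.

    All grid points share the fold split from ``cfg.seed``; ties go to the
    smaller C, then the smaller gamma.
    """
    cfg = cfg or SVRConfig()
    best = (math.inf, math.inf, math.inf)  # (error, C, gamma)
    for c in sorted(cfg.grid_C):
        for g in sorted(cfg.grid_gamma):
            trial = SVRConfig(
                C=c, gamma=g, epsilon=cfg.epsilon,
                grid_C=cfg.grid_C, grid_gamma=cfg.grid_gamma, seed=cfg.seed,
            )
            err = rmse(y, cv_predict_2fold(X, y, trial))
            if err < best[0]:
                best = (err, c, g)
    return best[1], best[2]


def pca_svr(X, y, k: int, cfg: SVRConfig | None = None) -> EvalReport:
    """2-fold CV of SVR on the top-k principal components.

    Standardization and the PCA basis are fitted on each training fold only
    and applied to its test fold; the SVR runs in component space without
    re-scaling the components, so full-rank PCA is a pure rotation of the
    standardized features.
    """
    cfg = cfg or SVRConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")
    if y.size < 4:
        raise ValueError("2-fold CV needs n >= 4")
    first, second = _half_split(y.size, cfg.seed)
    yhat = np.empty(y.size)
    for train_idx, test_idx in ((first, second), (second, first)):
        Xz_tr, Xz_te, _, _ = standardize(X[train_idx], X[test_idx])
        pca = PCA(n_components=k, svd_solver="full")
        Z_tr = pca.fit_transform(Xz_tr)
        Z_te = pca.transform(Xz_te)
        model = train_svr(Z_tr, y[train_idx], cfg, standardize_x=False)
        yhat[test_idx] = predict(model, Z_te)
    return evaluate(y, yhat, k=k, seed=cfg.seed)


def sbfs(X, y, feature_names: Sequence[str], cfg: SVRConfig | None = None) -> SelectionResult:
    """Sequential backward feature selection under the CV-RMSE criterion.

    Starting from the full set D_p, each remaining feature's removal is
    scored by 2-fold CV RMSE (one fixed fold seed throughout, so errors are
    comparable); the feature whose removal minimizes the error is dropped,
    yielding nested subsets D_{p-1} ... D_1.  The optimum is the recorded
    subset (including D_p itself) with the smallest error, ties going to
    the smaller subset.
    """
    cfg = cfg or SVRConfig()
    X = _as_matrix(X)
    names = list(feature_names)
    p = X.shape[1]
    if len(names) != p:
        raise ValueError("feature_names length must match X columns")
    if p < 2:
        raise ValueError("SBFS needs >= 2 features")

    current = list(range(p))
    full_err = rmse(y, cv_predict_2fold(X, y, cfg))
    subsets: list[tuple[tuple[str, ...], float]] = [
        (tuple(names[i] for i in current), full_err)
    ]
    removal_order: list[str] = []
    while len(current) > 1:
        errs = []
        for j in current:
            keep = [i for i in current if i != j]
            errs.append((rmse(y, cv_predict_2fold(X[:, keep], y, cfg)), j))
        best_err, drop = min(errs, key=lambda t: (t[0], t[1]))
        current = [i for i in current if i != drop]
        removal_order.append(names[drop])
        subsets.append((tuple(names[i] for i in current), best_err))
    removal_order.append(names[current[0]])

    # subsets currently ordered D_p ... D_1; store as D_1 ... D_p.
    subsets = subsets[::-1]
    best_names, best_error = min(subsets, key=lambda t: (t[1], len(t[0])))
    return SelectionResult(
        removal_order=removal_order,
        subsets=subsets,
        best_subset=best_names,
        best_error=best_error,
    )


def save_model(model: SVRModel, path: str | Path) -> None:
    """Serialize a trained model to a single joblib file (versioned)."""
    import joblib

    joblib.dump(
        {
            "format": "hazepm-svr",
            "version": model.version,
            "svr": model.svr,
            "x_mean": model.x_mean,
            "x_sd": model.x_sd,
            "y_mean": model.y_mean,
            "y_sd": model.y_sd,
            "standardize_x": model.standardize_x,
        },
        path,
    )


def load_model(path: str | Path) -> SVRModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format") != "hazepm-svr":
        raise ValueError(f"{path} is not a hazepm SVR model file")
    return SVRModel(
        svr=blob["svr"],
        x_mean=blob["x_mean"],
        x_sd=blob["x_sd"],
        y_mean=blob["y_mean"],
        y_sd=blob["y_sd"],
        standardize_x=blob.get("standardize_x", True),
        version=blob.get("version", 1),
    )
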