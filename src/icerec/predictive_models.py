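"""Per-arm outcome/cost regression with leave-one-out evaluation.

The prediction problem is factorized per treatment arm and per target:
p(outcome, cost | baseline, arm) = p(outcome | baseline, arm) * p(cost | baseline, arm),
so every model here is trained on the patients of a single arm only.

Learners: an intercept-only mean reference (the bar any useful model must
clear), OLS, ridge, lasso, a CART regression tree, and epsilon-insensitive
SVR.  Ridge/lasso/SVR standardize features on the training fold only and
leave the intercept unpenalized.  Evaluation is leave-one-out CV with MAE and
RMSE, hyperparameters tuned by an inner k-fold grid search inside each
training fold (nested by default; a non-nested mode tunes once on the full
sample).  Model-vs-reference comparisons use the two-sided Wilcoxon
signed-rank test on paired absolute errors.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import Lasso, LassoCV, LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ALGORITHMS",
    "ModelFit",
    "CVResult",
    "MeanReference",
    "fit_mean_reference",
    "fit_ols",
    "fit_ridge",
    "fit_lasso",
    "fit_tree",
    "fit_svr",
    "fit_model",
    "default_grid",
    "loocv",
    "mae",
    "rmse",
    "compare_to_reference",
    "select_features_lasso",
    "SelectionResult",
]

ALGORITHMS = ("mean_ref", "ols", "ridge", "lasso", "tree", "svr")
VALID_KERNELS = ("linear", "rbf", "poly", "sigmoid")


class MeanReference(BaseEstimator, RegressorMixin):
    """Intercept-only predictor: the training-mean reference measure."""

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("cannot fit the mean reference on an empty target vector")
        self.mean_ = float(y.mean())
        self.n_features_in_ = 0 if X is None else np.shape(X)[1]
        return self

    def predict(self, X):
        n = 1 if X is None else np.shape(X)[0]
        return np.full(n, self.mean_)


@dataclasses.dataclass
class ModelFit:
    """A fitted predictor for one (arm, target) pair."""

    algorithm: str
    hyperparams: dict
    estimator: object  # fitted sklearn estimator or pipeline
    feature_names: list[str] | None = None
    arm: str | None = None
    target: str | None = None

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                missing = [c for c in self.feature_names if c not in X.columns]
                if missing:
                    raise KeyError(f"input lacks design columns: {missing}")
                X = X[self.feature_names]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.feature_names is not None and X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} columns, got {X.shape[1]}")
        return X

    def predict(self, X) -> np.ndarray:
        if self.algorithm == "mean_ref":
            n = len(X) if X is not None else 1
            return np.full(n, self.estimator.mean_)
        return np.asarray(self.estimator.predict(self._matrix(X)), dtype=float)

    @property
    def standardization(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(center, scale) of the training fold, when standardization applied."""
        if isinstance(self.estimator, Pipeline) and "scale" in self.estimator.named_steps:
            sc = self.estimator.named_steps["scale"]
            return sc.mean_, sc.scale_
        return None

    @property
    def coefficients(self) -> np.ndarray | None:
        est = self.estimator
        if isinstance(est, Pipeline):
            est = est.named_steps["model"]
        return getattr(est, "coef_", None)

    @property
    def intercept(self) -> float | None:
        est = self.estimator
        if isinstance(est, Pipeline):
            est = est.named_steps["model"]
        ic = getattr(est, "intercept_", None)
        return None if ic is None else float(np.ravel(ic)[0]) if np.ndim(ic) else float(ic)

    def to_dict(self) -> dict:
        d = {
            "algorithm": self.algorithm,
            "hyperparams": self.hyperparams,
            "arm": self.arm,
            "target": self.target,
            "feature_names": self.feature_names,
        }
        if self.coefficients is not None:
            d["coefficients"] = np.asarray(self.coefficients).tolist()
            d["intercept"] = self.intercept
        std = self.standardization
        if std is not None:
            d["standardization"] = {"center": std[0].tolist(), "scale": std[1].tolist()}
        return d


def _names_and_matrix(X) -> tuple[list[str] | None, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        return list(X.columns), X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return None, X


def fit_mean_reference(y, arm: str | None = None, target: str | None = None) -> ModelFit:
    est = MeanReference().fit(None, y)
    return ModelFit("mean_ref", {}, est, None, arm, target)


def fit_ols(X, y, arm: str | None = None, target: str | None = None) -> ModelFit:
    """Least squares via a numerically stable (SVD) solver.

    Requires strictly fewer columns than rows: with p >= n an unregularized
    fit is an interpolation, not an estimate.  Rank-deficient designs fall
    back to the minimum-norm solution with a warning.
    """
    names, Xm = _names_and_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if p >= n:
        raise ValueError(f"OLS requires fewer features than observations (p={p}, n={n}); regularize or select features")
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < min(n - 1, p):
        warnings.warn("rank-deficient design: returning the minimum-norm least-squares solution")
    est = LinearRegression().fit(Xm, y)
    return ModelFit("ols", {}, est, names, arm, target)


def _standardized_pipeline(model) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def fit_ridge(X, y, lam: float, arm: str | None = None, target: str | None = None) -> ModelFit:
    """L2-penalized least squares: ||y - Xb||^2 + lam * ||b||^2 on standardized
    features with an unpenalized intercept; lam = 0 reduces to OLS."""
    if lam < 0:
        raise ValueError(f"ridge penalty must be >= 0, got {lam}")
    names, Xm = _names_and_matrix(X)
    est = _standardized_pipeline(Ridge(alpha=lam, solver="svd")).fit(Xm, np.asarray(y, dtype=float))
    return ModelFit("ridge", {"lam": lam}, est, names, arm, target)


def fit_lasso(
    X,
    y,
    lam: float,
    arm: str | None = None,
    target: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> ModelFit:
    """L1-penalized least squares (coordinate descent):
    (1/2n) ||y - Xb||^2 + lam * ||b||_1 on standardized features, intercept
    unpenalized.  lam = 0 is solved as plain least squares."""
    if lam < 0:
        raise ValueError(f"lasso penalty must be >= 0, got {lam}")
    names, Xm = _names_and_matrix(X)
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        est = _standardized_pipeline(LinearRegression()).fit(Xm, y)
        return ModelFit("lasso", {"lam": 0.0}, est, names, arm, target)
    model = Lasso(alpha=lam, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = _standardized_pipeline(model).fit(Xm, y)
    fitted = est.named_steps["model"]
    if fitted.n_iter_ >= max_iter:
        raise RuntimeError(f"lasso coordinate descent did not reach tolerance {tol} within {max_iter} iterations")
    return ModelFit("lasso", {"lam": lam}, est, names, arm, target)


def fit_tree(
    X,
    y,
    max_depth: int = 3,
    min_samples_leaf: int = 5,
    arm: str | None = None,
    target: str | None = None,
) -> ModelFit:
    """CART regression tree grown by variance-reduction splits; leaves predict
    their training mean."""
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    if min_samples_leaf < 1:
        raise ValueError(f"min_samples_leaf must be >= 1, got {min_samples_leaf}")
    names, Xm = _names_and_matrix(X)
    est = DecisionTreeRegressor(max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=0)
    est.fit(Xm, np.asarray(y, dtype=float))
    return ModelFit("tree", {"max_depth": max_depth, "min_samples_leaf": min_samples_leaf}, est, names, arm, target)


def fit_svr(
    X,
    y,
    C: float = 1.0,
    epsilon: float = 0.1,
    kernel: str = "rbf",
    arm: str | None = None,
    target: str | None = None,
    max_iter: int = 20_000,
) -> ModelFit:
    """Epsilon-insensitive support vector regression on standardized features.

    The solver iteration count is capped: libsvm's SMO can stall on
    near-degenerate linear problems at large C, and the capped solution is
    deterministic and accurate to well below the epsilon tube in practice.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    if kernel not in VALID_KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {VALID_KERNELS}")
    names, Xm = _names_and_matrix(X)
    model = SVR(C=C, epsilon=epsilon, kernel=kernel, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = _standardized_pipeline(model).fit(Xm, np.asarray(y, dtype=float))
    return ModelFit("svr", {"C": C, "epsilon": epsilon, "kernel": kernel}, est, names, arm, target)


def fit_model(algorithm: str, X, y, params: Mapping | None = None, **meta) -> ModelFit:
    """Dispatch to the per-algorithm fit function, resolving data-scaled
    hyperparameters (``epsilon_frac`` -> epsilon = frac * SD(y))."""
    params = dict(params or {})
    if "epsilon_frac" in params:
        sd = float(np.std(np.asarray(y, dtype=float)))
        params["epsilon"] = params.pop("epsilon_frac") * (sd if sd > 0 else 1.0)
    fitters = {
        "mean_ref": lambda: fit_mean_reference(y, **meta),
        "ols": lambda: fit_ols(X, y, **meta),
        "ridge": lambda: fit_ridge(X, y, **params, **meta),
        "lasso": lambda: fit_lasso(X, y, **params, **meta),
        "tree": lambda: fit_tree(X, y, **params, **meta),
        "svr": lambda: fit_svr(X, y, **params, **meta),
    }
    if algorithm not in fitters:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return fitters[algorithm]()


def default_grid(algorithm: str) -> list[dict]:
    """Hyperparameter candidates searched by the inner CV."""
    if algorithm == "ridge":
        return [{"lam": v} for v in (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)]
    if algorithm == "lasso":
        return [{"lam": v} for v in np.geomspace(1e-4, 1.0, 8)]
    if algorithm == "tree":
        return [
            {"max_depth": d, "min_samples_leaf": m}
            for d in (2, 3, 4, 5)
            for m in (5, 10, 20)
        ]
    if algorithm == "svr":
        return [
            {"C": c, "epsilon_frac": e, "kernel": k}
            for c in (0.1, 1.0, 10.0, 100.0)
            for e in (0.01, 0.1)
            for k in ("linear", "rbf")
        ]
    return [{}]


def mae(y_true, y_pred) -> float:
    return float(np.mean(np.abs(np.asarray(y_true, float) - np.asarray(y_pred, float))))


def rmse(y_true, y_pred) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true, float) - np.asarray(y_pred, float)) ** 2)))


@dataclasses.dataclass
class CVResult:
    """Leave-one-out predictions and error summaries for one learner."""

    algorithm: str
    y_true: np.ndarray
    predictions: np.ndarray
    mae: float
    rmse: float
    chosen_params: list[dict]
    arm: str | None = None
    target: str | None = None

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.y_true - self.predictions)

    def compare_to(self, reference: "CVResult") -> float:
        return compare_to_reference(self.abs_errors, reference.abs_errors)

    def summary(self) -> dict:
        return {"algorithm": self.algorithm, "arm": self.arm, "target": self.target, "mae": self.mae, "rmse": self.rmse}


def _tune(algorithm: str, X: np.ndarray, y: np.ndarray, grid: Sequence[Mapping], inner_cv: int, seed: int) -> dict:
    """Grid search by k-fold mean squared error; ties keep the earliest grid
    entry (grids are ordered simplest-first)."""
    if len(grid) == 1:
        return dict(grid[0])
    kf = KFold(n_splits=min(inner_cv, len(y)), shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    scores = np.zeros(len(grid))
    for g, params in enumerate(grid):
        sse = 0.0
        for tr, te in folds:
            if np.ptp(y[tr]) == 0.0:
                pred = np.full(len(te), y[tr].mean())
            else:
                fit = fit_model(algorithm, X[tr], y[tr], params)
                pred = fit.predict(X[te])
            sse += float(np.sum((y[te] - pred) ** 2))
        scores[g] = sse
    return dict(grid[int(np.argmin(scores))])


def loocv(
    algorithm: str,
    X,
    y,
    grid: Sequence[Mapping] | None = None,
    inner_cv: int = 5,
    nested: bool = True,
    seed: int = 0,
    arm: str | None = None,
    target: str | None = None,
) -> CVResult:
    """Leave-one-out cross-validation: each patient is predicted by a model
    trained on all others.

    Tunable learners pick hyperparameters by an inner ``inner_cv``-fold grid
    search *inside each training fold* (nested; avoids selection leakage).
    With ``nested=False`` hyperparameters are tuned once on the full sample
    and reused in every fold.  Degenerate (constant-target) training folds
    fall back to a mean prediction with a warning.
    """
    names, Xm = _names_and_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 observations, got {n}")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if grid is None:
        grid = default_grid(algorithm)
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be nonempty")

    if algorithm == "mean_ref":
        preds = (y.sum() - y) / (n - 1)
        return CVResult("mean_ref", y, preds, mae(y, preds), rmse(y, preds), [{}] * n, arm, target)

    tunable = len(grid) > 1
    fixed_params = None
    if tunable and not nested:
        fixed_params = _tune(algorithm, Xm, y, grid, inner_cv, seed)
    elif not tunable:
        fixed_params = dict(grid[0])

    preds = np.empty(n)
    chosen: list[dict] = []
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        y_tr = y[tr]
        if np.ptp(y_tr) == 0.0:
            warnings.warn(f"constant target in training fold {i}; predicting the mean")
            preds[i] = y_tr.mean()
            chosen.append({})
            continue
        params = fixed_params if fixed_params is not None else _tune(algorithm, Xm[tr], y_tr, grid, inner_cv, seed)
        fit = fit_model(algorithm, Xm[tr], y_tr, params)
        preds[i] = fit.predict(Xm[i : i + 1])[0]
        chosen.append(dict(params))
    return CVResult(algorithm, y, preds, mae(y, preds), rmse(y, preds), chosen, arm, target)


def compare_to_reference(abs_errors_model, abs_errors_reference) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired absolute errors."""
    a = np.asarray(abs_errors_model, dtype=float)
    b = np.asarray(abs_errors_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("error vectors must be paired (equal length)")
    if np.allclose(a, b):
        warnings.warn("all paired error differences are zero; p-value defined as 1")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


@dataclasses.dataclass
class SelectionResult:
    """Lasso path selection for one (arm, target) pair."""

    selected: list[str]
    lam: float
    coefficients: pd.Series
    arm: str | None = None
    target: str | None = None


def select_features_lasso(
    X,
    y,
    arm: str | None = None,
    target: str | None = None,
    cv_folds: int = 5,
    n_lambdas: int = 100,
    seed: int = 0,
) -> SelectionResult:
    """Pick the penalty minimizing mean cross-validated error along a log-spaced
    lambda path from lambda_max downward; features with nonzero coefficients at
    the optimum are selected.  Selection is per (arm, target): call once for
    each pair.  An empty selection falls back to intercept-only (the
    downstream model then equals the mean reference) with a warning."""
    names, Xm = _names_and_matrix(X)
    if names is None:
        names = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    Xs = StandardScaler().fit_transform(Xm)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = LassoCV(alphas=n_lambdas, cv=kf, max_iter=50_000, tol=1e-6).fit(Xs, y)
    coefs = pd.Series(cv.coef_, index=names)
    selected = [c for c in names if coefs[c] != 0.0]
    if not selected:
        warnings.warn(f"lasso selected no features for arm={arm} target={target}; falling back to intercept only")
    return SelectionResult(selected, float(cv.alpha_), coefs, arm, target)
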