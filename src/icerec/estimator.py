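"""scikit-learn-style estimator bundling the whole recommendation method.

``CostEffectivenessRecommender`` fits one predictor per (arm, target) pair —
optionally on lasso-selected features — and turns both-arm predictions into a
treatment recommendation via the net-monetary-benefit rule.  It follows the
sklearn protocol (get_params/set_params, clone-compatible constructor,
fitted attributes with trailing underscores), so it composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._rand import derive_seed
from .health_economics import DEFAULT_HORIZON_YEARS
from .predictive_models import (
    _tune,
    default_grid,
    fit_mean_reference,
    fit_model,
    select_features_lasso,
)
from .recommendation import ARMS, DEFAULT_WTP, TARGETS, build_recommendations, predict_both_arms

__all__ = ["CostEffectivenessRecommender"]


class CostEffectivenessRecommender(BaseEstimator):
    """Per-arm outcome/cost regression plus an NMB treatment-decision rule.

    Parameters
    ----------
    algorithm:
        Learner for all four (arm, target) models: one of mean_ref, ols,
        ridge, lasso, tree, svr.  Tunable learners are tuned by ``inner_cv``-
        fold grid search on each arm's training data.
    select_features:
        Run per-(arm, target) lasso path selection first and fit the learner
        on the selected columns only.  An empty selection falls back to the
        intercept-only mean reference for that pair.
    wtp:
        Willingness-to-pay threshold in EUR per QALY for the decision rule.
    horizon:
        Analysis horizon in years (bounds the attainable QALY predictions).
    """

    def __init__(
        self,
        algorithm: str = "ridge",
        select_features: bool = True,
        wtp: float = DEFAULT_WTP,
        horizon: float = DEFAULT_HORIZON_YEARS,
        inner_cv: int = 5,
        random_state: int = 0,
    ) -> None:
        self.algorithm = algorithm
        self.select_features = select_features
        self.wtp = wtp
        self.horizon = horizon
        self.inner_cv = inner_cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "CostEffectivenessRecommender":
        """Fit the four (arm, target) models.

        ``X`` is the fully numeric design matrix (one row per patient);
        ``y`` is a DataFrame with columns ``arm`` ('TAU'/'BT'), ``qaly`` and
        ``cost`` aligned with ``X``.
        """
        X = pd.DataFrame(X)
        for col in ("arm", "qaly", "cost"):
            if col not in y.columns:
                raise ValueError(f"y must have columns arm/qaly/cost; missing {col!r}")
        if not set(y["arm"].unique()) <= set(ARMS):
            raise ValueError(f"arm labels must be in {ARMS}, got {sorted(y['arm'].unique())}")
        target_col = {"outcome": "qaly", "cost": "cost"}
        self.models_ = {}
        self.selections_ = {}
        for arm in ARMS:
            mask = (y["arm"] == arm).to_numpy()
            if mask.sum() < 3:
                raise ValueError(f"arm {arm} has fewer than 3 patients; cannot fit per-arm models")
            Xa = X.loc[mask]
            for target in TARGETS:
                ya = y.loc[mask, target_col[target]].to_numpy(dtype=float)
                cols = list(X.columns)
                if self.select_features:
                    sel = select_features_lasso(
                        Xa, ya, arm=arm, target=target,
                        seed=derive_seed(self.random_state, f"select:{arm}:{target}"),
                    )
                    self.selections_[(arm, target)] = sel
                    cols = sel.selected
                if not cols:
                    self.models_[(arm, target)] = fit_mean_reference(ya, arm=arm, target=target)
                    continue
                Xsub = Xa[cols]
                grid = default_grid(self.algorithm)
                params = grid[0]
                if len(grid) > 1:
                    params = _tune(
                        self.algorithm,
                        Xsub.to_numpy(dtype=float),
                        ya,
                        grid,
                        self.inner_cv,
                        derive_seed(self.random_state, f"tune:{arm}:{target}"),
                    )
                self.models_[(arm, target)] = fit_model(self.algorithm, Xsub, ya, params, arm=arm, target=target)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_outcomes(self, X) -> pd.DataFrame:
        """Predicted (q_tau, q_bt, c_tau, c_bt) for every patient."""
        self._check_fitted()
        return predict_both_arms(self.models_, pd.DataFrame(X), horizon=self.horizon)

    def decision_function(self, X) -> np.ndarray:
        """Net monetary benefit of BT over TAU, wtp * dQ - dC (EUR)."""
        p = self.predict_outcomes(X)
        return (self.wtp * (p["q_bt"] - p["q_tau"]) - (p["c_bt"] - p["c_tau"])).to_numpy()

    def predict(self, X) -> np.ndarray:
        """Recommended arm per patient ('BT' iff NMB > 0, else 'TAU')."""
        return np.where(self.decision_function(X) > 0, "BT", "TAU")

    def recommendations(self, X, received) -> pd.DataFrame:
        """Full per-patient recommendation records (increments, ICER,
        quadrant, recommendation, concordance with the received arm)."""
        return build_recommendations(self.predict_outcomes(X), received, wtp=self.wtp)
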