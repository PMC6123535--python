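"""Individualized ICER-based treatment recommendation and policy evaluation.

For each patient the fitted per-arm models yield predicted 6-month QALYs and
societal costs under both arms.  The incremental pair (dQ, dC) = (BT - TAU)
places the patient on the cost-effectiveness plane: SE (cheaper, more
effective) means BT dominates, NW means TAU dominates, and NE/SW need a
willingness-to-pay (WTP) judgement.  The decision rule is net monetary
benefit, NMB = WTP * dQ - dC: recommend BT iff NMB > 0.  Within the NE
quadrant this is exactly the classical "recommend iff ICER < WTP" rule; in SW
it recommends BT iff the savings per QALY forgone exceed WTP; in SE/NW it
coincides with dominance; ties (NMB = 0) go to TAU as the status-quo arm.

The counterfactual evaluation re-scores the population under the recommended
allocation: concordant patients keep their observed outcomes and costs,
discordant patients get the model's prediction for the recommended arm.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .health_economics import DEFAULT_HORIZON_YEARS, UTILITY_BOUNDS

__all__ = [
    "BT_DOMINATES",
    "TAU_DOMINATES",
    "UNDEFINED_ZERO_DELTA_Q",
    "DEFAULT_WTP",
    "predict_both_arms",
    "icer",
    "classify_quadrant",
    "recommend",
    "build_recommendations",
    "contingency",
    "PolicyEvaluation",
    "counterfactual_policy_value",
    "ce_plane_export",
    "plot_ce_plane",
]

BT_DOMINATES = "bt_dominates"
TAU_DOMINATES = "tau_dominates"
UNDEFINED_ZERO_DELTA_Q = "undefined_zero_delta_q"

#: conservative willingness-to-pay threshold, EUR per QALY
DEFAULT_WTP = 25_000.0

ARMS = ("TAU", "BT")
TARGETS = ("outcome", "cost")


def predict_both_arms(
    models: Mapping[tuple[str, str], object],
    X,
    horizon: float = DEFAULT_HORIZON_YEARS,
) -> pd.DataFrame:
    """Predict (q_tau, q_bt, c_tau, c_bt) for every row of ``X``.

    ``models`` maps (arm, target) -> fitted ModelFit, one per combination;
    each was trained on its own arm's patients only, so every patient gets a
    counterfactual prediction for the arm they did not receive.  QALY
    predictions are clipped to the attainable range implied by the utility
    bounds and horizon; costs are floored at zero.
    """
    for arm in ARMS:
        for target in TARGETS:
            if (arm, target) not in models:
                raise KeyError(f"missing model for (arm={arm}, target={target})")
    q_lo, q_hi = UTILITY_BOUNDS[0] * horizon, UTILITY_BOUNDS[1] * horizon
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(np.shape(X)[0])
    out = pd.DataFrame(index=index)
    out["q_tau"] = np.clip(models[("TAU", "outcome")].predict(X), q_lo, q_hi)
    out["q_bt"] = np.clip(models[("BT", "outcome")].predict(X), q_lo, q_hi)
    out["c_tau"] = np.maximum(models[("TAU", "cost")].predict(X), 0.0)
    out["c_bt"] = np.maximum(models[("BT", "cost")].predict(X), 0.0)
    return out


def icer(delta_c: float, delta_q: float):
    """Incremental cost-effectiveness ratio dC/dQ (EUR per QALY), or a
    dominance flag where a ratio carries no decision weight: SE interior ->
    BT dominates, NW interior -> TAU dominates, dQ = 0 -> undefined."""
    if delta_q == 0.0:
        return UNDEFINED_ZERO_DELTA_Q
    if delta_q > 0 and delta_c < 0:
        return BT_DOMINATES
    if delta_q < 0 and delta_c > 0:
        return TAU_DOMINATES
    return float(delta_c / delta_q)


def classify_quadrant(delta_q: float, delta_c: float) -> str:
    """Cost-effectiveness-plane quadrant of (dQ, dC); 'axis' when either
    increment is exactly zero."""
    if delta_q == 0.0 or delta_c == 0.0:
        return "axis"
    if delta_q > 0:
        return "NE" if delta_c > 0 else "SE"
    return "NW" if delta_c > 0 else "SW"


def recommend(delta_q: float, delta_c: float, wtp: float = DEFAULT_WTP) -> str:
    """Recommend BT iff its net monetary benefit wtp*dQ - dC is positive.

    Equivalent to the ICER-threshold rule (BT iff ICER < wtp) in the NE
    quadrant, to "savings per QALY lost exceed wtp" in SW, and to dominance in
    SE/NW.  NMB = 0 recommends TAU (status quo).
    """
    if wtp <= 0:
        raise ValueError(f"willingness-to-pay must be > 0, got {wtp}")
    nmb = wtp * delta_q - delta_c
    return "BT" if nmb > 0 else "TAU"


def build_recommendations(
    predictions: pd.DataFrame,
    received: Sequence[str],
    wtp: float = DEFAULT_WTP,
) -> pd.DataFrame:
    """Per-patient recommendation records from both-arm predictions.

    ``predictions`` must have columns q_tau/q_bt/c_tau/c_bt (as produced by
    :func:`predict_both_arms`); ``received`` is the arm each patient actually
    got.  Returns one row per patient with increments, ICER/dominance status,
    plane quadrant, recommendation and concordance flag.
    """
    received = pd.Series(np.asarray(received, dtype=object), index=predictions.index)
    rec = predictions.copy()
    rec["delta_q"] = rec["q_bt"] - rec["q_tau"]
    rec["delta_c"] = rec["c_bt"] - rec["c_tau"]
    rec["icer"] = [icer(dc, dq) for dq, dc in zip(rec["delta_q"], rec["delta_c"])]
    rec["quadrant"] = [classify_quadrant(dq, dc) for dq, dc in zip(rec["delta_q"], rec["delta_c"])]
    rec["recommended"] = [recommend(dq, dc, wtp) for dq, dc in zip(rec["delta_q"], rec["delta_c"])]
    rec["received"] = received
    rec["concordant"] = rec["recommended"] == rec["received"]
    return rec


def contingency(received: Sequence[str], recommended: Sequence[str]) -> dict:
    """Received x recommended 2x2 table with cell percentages of N and the
    concordance percentage (patients whose received arm was the recommended
    one)."""
    received = np.asarray(received, dtype=object)
    recommended = np.asarray(recommended, dtype=object)
    if received.shape != recommended.shape:
        raise ValueError(f"length mismatch: {received.shape} received vs {recommended.shape} recommended")
    n = received.size
    if n == 0:
        raise ValueError("empty input")
    counts = pd.DataFrame(0, index=list(ARMS), columns=list(ARMS))
    counts.index.name = "received"
    counts.columns.name = "recommended"
    for rec_arm in ARMS:
        for rcm_arm in ARMS:
            counts.loc[rec_arm, rcm_arm] = int(np.sum((received == rec_arm) & (recommended == rcm_arm)))
    percentages = counts / n * 100.0
    concordant = int(counts.loc["TAU", "TAU"] + counts.loc["BT", "BT"])
    return {
        "counts": counts,
        "percentages": percentages,
        "n": n,
        "concordant": concordant,
        "concordance_pct": concordant / n * 100.0,
    }


@dataclasses.dataclass
class PolicyEvaluation:
    """Population totals under the observed vs the recommended allocation."""

    observed_total_qaly: float
    observed_total_cost: float
    recommended_total_qaly: float
    recommended_total_cost: float
    n: int
    n_concordant: int
    pct_change_qaly: float | None
    pct_change_cost: float | None

    @property
    def observed_mean_qaly(self) -> float:
        return self.observed_total_qaly / self.n

    @property
    def observed_mean_cost(self) -> float:
        return self.observed_total_cost / self.n

    @property
    def recommended_mean_qaly(self) -> float:
        return self.recommended_total_qaly / self.n

    @property
    def recommended_mean_cost(self) -> float:
        return self.recommended_total_cost / self.n

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def counterfactual_policy_value(
    observed_q: Sequence[float],
    observed_c: Sequence[float],
    predicted_q: Sequence[float],
    predicted_c: Sequence[float],
    concordant: Sequence[bool],
) -> PolicyEvaluation:
    """Evaluate the recommended allocation against the observed one.

    ``predicted_q``/``predicted_c`` are the model predictions *under the
    recommended arm*.  Concordant patients contribute their observed values;
    discordant patients contribute the predictions.  Percent changes are
    (recommended - observed) / observed * 100 on population totals
    (equivalently means); a zero observed total leaves the percent change
    undefined (None).
    """
    oq = np.asarray(observed_q, dtype=float)
    oc = np.asarray(observed_c, dtype=float)
    pq = np.asarray(predicted_q, dtype=float)
    pc = np.asarray(predicted_c, dtype=float)
    flags = np.asarray(concordant, dtype=bool)
    n = oq.size
    if not (oc.size == pq.size == pc.size == flags.size == n):
        raise ValueError("all per-patient inputs must be aligned and of equal length")
    rec_q = np.where(flags, oq, pq)
    rec_c = np.where(flags, oc, pc)
    tot_oq, tot_oc = float(oq.sum()), float(oc.sum())
    tot_rq, tot_rc = float(rec_q.sum()), float(rec_c.sum())
    return PolicyEvaluation(
        observed_total_qaly=tot_oq,
        observed_total_cost=tot_oc,
        recommended_total_qaly=tot_rq,
        recommended_total_cost=tot_rc,
        n=n,
        n_concordant=int(flags.sum()),
        pct_change_qaly=None if tot_oq == 0 else (tot_rq - tot_oq) / tot_oq * 100.0,
        pct_change_cost=None if tot_oc == 0 else (tot_rc - tot_oc) / tot_oc * 100.0,
    )


def ce_plane_export(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready cost-effectiveness-plane table: per-patient (delta_q,
    delta_c, concordant).  Concordant and discordant patients are rendered
    distinctly downstream."""
    if len(records) == 0:
        return pd.DataFrame(columns=["delta_q", "delta_c", "concordant"])
    return records[["delta_q", "delta_c", "concordant"]].copy()


def plot_ce_plane(records: pd.DataFrame, wtp: float = DEFAULT_WTP, ax=None):
    """Scatter the cost-effectiveness plane (requires matplotlib): concordant
    patients as green crosses, discordant as red circles, with the WTP line."""
    import matplotlib.pyplot as plt

    table = ce_plane_export(records)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    con = table[table["concordant"]]
    dis = table[~table["concordant"]]
    ax.scatter(con["delta_q"], con["delta_c"], marker="x", color="green", label="concordant")
    ax.scatter(dis["delta_q"], dis["delta_c"], marker="o", facecolors="none", edgecolors="red", label="discordant")
    if len(table):
        q = np.linspace(table["delta_q"].min(), table["delta_q"].max(), 50)
        ax.plot(q, wtp * q, linestyle="--", color="gray", label=f"WTP {wtp:,.0f} EUR/QALY")
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("difference in QALYs (BT - TAU)")
    ax.set_ylabel("difference in costs, EUR (BT - TAU)")
    ax.legend()
    return ax
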