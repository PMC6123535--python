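"""Health-economic primitives: EQ-5D-5L utilities, QALYs, and societal costs.

Utilities are preference weights for health states, anchored at 1 (perfect
health) and 0 (worst perceivable health); country value sets ("tariffs") may
assign negative weights to states considered worse than death.  QALYs over a
fixed horizon are the time integral of the utility trajectory, with linear
interpolation between measurement points.  Societal costs add healthcare
utilization (quantity x unit cost), productivity losses (hours x hourly
rate), and — for the blended-treatment arm — a fixed platform cost for the
internet-delivered component.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValueSet",
    "UtilityTrajectory",
    "UnitCostTable",
    "utility_from_profile",
    "qaly",
    "societal_cost",
    "synthetic_additive_value_set",
]

EQ5D_DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")
N_LEVELS = 5

#: horizon of the 6-month analysis, in years
DEFAULT_HORIZON_YEARS = 0.5

#: utility weights admitted by value sets (worse-than-death states allowed)
UTILITY_BOUNDS = (-0.5, 1.0)


@dataclasses.dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L value set: utility = 1 - sum of per-dimension decrements.

    ``decrements[d][k]`` is the utility loss for answering level ``k`` (1-5) on
    dimension ``d``; level 1 ("no problems") always has decrement 0, so the
    profile (1,1,1,1,1) maps to 1.0 exactly.
    """

    decrements: Mapping[str, Sequence[float]]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        missing = [d for d in EQ5D_DIMENSIONS if d not in self.decrements]
        if missing:
            raise ValueError(f"value set {self.name!r} missing dimensions: {missing}")
        for d in EQ5D_DIMENSIONS:
            dec = np.asarray(self.decrements[d], dtype=float)
            if dec.shape != (N_LEVELS,):
                raise ValueError(f"dimension {d!r}: expected {N_LEVELS} decrements, got {dec.shape}")
            if dec[0] != 0.0:
                raise ValueError(f"dimension {d!r}: level-1 decrement must be 0 (perfect-health anchor)")

    def utility(self, profile: Sequence[int]) -> float:
        return utility_from_profile(profile, self)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ValueSet":
        """Load decrements from CSV with columns dimension, level, decrement."""
        df = pd.read_csv(path)
        required = {"dimension", "level", "decrement"}
        if not required.issubset(df.columns):
            raise ValueError(f"value-set CSV needs columns {sorted(required)}, got {list(df.columns)}")
        dec: dict[str, list[float]] = {}
        for d, grp in df.groupby("dimension"):
            levels = grp.set_index("level")["decrement"]
            dec[str(d)] = [float(levels.get(k, np.nan)) for k in range(1, N_LEVELS + 1)]
            if np.isnan(dec[str(d)]).any():
                raise ValueError(f"value-set CSV: dimension {d!r} does not cover levels 1-{N_LEVELS}")
        return cls(decrements=dec, name=name or str(path))

    def to_csv(self, path) -> None:
        rows = [
            {"dimension": d, "level": k + 1, "decrement": self.decrements[d][k]}
            for d in EQ5D_DIMENSIONS
            for k in range(N_LEVELS)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def synthetic_additive_value_set() -> ValueSet:
    """A synthetic additive value set for testing and simulation.

    Not a published national tariff: decrements increase with level severity
    within each dimension and sum to 1.5 at the worst state (5,5,5,5,5), giving
    a utility floor of -0.5 — the qualitative shape of EQ-5D-5L tariffs that
    admit worse-than-death states.  Real analyses must load a published value
    set via :meth:`ValueSet.from_csv`.
    """
    base = [0.0, 0.05, 0.12, 0.22, 0.30]
    dec = {d: list(base) for d in EQ5D_DIMENSIONS}
    return ValueSet(decrements=dec, name="synthetic-additive")


def utility_from_profile(profile: Sequence[int], vs: ValueSet) -> float:
    """Utility weight of a complete EQ-5D-5L response profile under ``vs``.

    ``profile`` is the 5 dimension levels in the standard order
    (mobility, self-care, usual activities, pain/discomfort, anxiety/depression).
    """
    prof = list(profile)
    if len(prof) != len(EQ5D_DIMENSIONS):
        raise ValueError(f"profile must have {len(EQ5D_DIMENSIONS)} answered dimensions, got {len(prof)}")
    total = 1.0
    for d, lvl in zip(EQ5D_DIMENSIONS, prof):
        if lvl is None or (isinstance(lvl, float) and np.isnan(lvl)):
            raise ValueError(f"dimension {d!r} is unanswered; impute upstream before valuation")
        lvl = int(lvl)
        if not 1 <= lvl <= N_LEVELS:
            raise ValueError(f"dimension {d!r}: level {lvl} outside 1-{N_LEVELS}")
        total -= float(vs.decrements[d][lvl - 1])
    return float(total)


@dataclasses.dataclass(frozen=True)
class UtilityTrajectory:
    """Time-stamped utility weights over the analysis horizon.

    ``times`` are years since baseline, strictly increasing and starting at 0;
    the last time must not exceed ``horizon``.  If the last measurement falls
    short of the horizon the final utility is carried forward (constant
    extrapolation) for integration.
    """

    times: Sequence[float]
    utilities: Sequence[float]
    horizon: float = DEFAULT_HORIZON_YEARS

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.utilities, dtype=float)
        if t.size == 0:
            raise ValueError("empty trajectory")
        if t.size != u.size:
            raise ValueError("times and utilities must have equal length")
        if t[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[-1] > self.horizon + 1e-12:
            raise ValueError(f"last time {t[-1]} exceeds horizon {self.horizon}")


def qaly(trajectory: UtilityTrajectory) -> float:
    """QALYs accrued over the horizon: trapezoidal integral of the linearly
    interpolated utility trajectory.

    For a 0.5-year horizon with utilities <= 1 the result is at most 0.5.
    """
    t = np.asarray(trajectory.times, dtype=float)
    u = np.asarray(trajectory.utilities, dtype=float)
    if t[-1] < trajectory.horizon:  # carry last utility forward to the horizon
        t = np.append(t, trajectory.horizon)
        u = np.append(u, u[-1])
    return float(np.trapezoid(u, t))


@dataclasses.dataclass(frozen=True)
class UnitCostTable:
    """Unit costs (EUR) for valuing resource use from the societal perspective."""

    unit_costs: Mapping[str, float]
    productivity_hourly_rate: float
    bt_platform_cost: float

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.unit_costs.items() if v < 0}
        if bad:
            raise ValueError(f"negative unit costs: {bad}")
        if self.productivity_hourly_rate < 0:
            raise ValueError("productivity_hourly_rate must be >= 0")
        if self.bt_platform_cost < 0:
            raise ValueError("bt_platform_cost must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                unit_costs={str(k): float(v) for k, v in raw["unit_costs"].items()},
                productivity_hourly_rate=float(raw["productivity_hourly_rate"]),
                bt_platform_cost=float(raw["bt_platform_cost"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed unit-cost YAML {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "unit_costs": dict(self.unit_costs),
                    "productivity_hourly_rate": self.productivity_hourly_rate,
                    "bt_platform_cost": self.bt_platform_cost,
                },
                fh,
            )


def societal_cost(
    resource_use: Mapping[str, float],
    hours_lost: float,
    arm: str,
    costs: UnitCostTable,
) -> float:
    """Total societal cost in EUR: healthcare utilization plus productivity
    losses, plus the platform cost when the patient is in the BT arm."""
    if arm not in ("TAU", "BT"):
        raise ValueError(f"arm must be 'TAU' or 'BT', got {arm!r}")
    if hours_lost < 0:
        raise ValueError("hours_lost must be >= 0")
    total = 0.0
    for category, qty in resource_use.items():
        if category not in costs.unit_costs:
            raise KeyError(f"unknown resource category: {category!r}")
        if qty < 0:
            raise ValueError(f"negative quantity for {category!r}")
        total += qty * costs.unit_costs[category]
    total += hours_lost * costs.productivity_hourly_rate
    if arm == "BT":
        total += costs.bt_platform_cost
    return float(total)
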