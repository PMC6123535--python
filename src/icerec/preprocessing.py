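"""Feature-table preparation: merge, prune, impute, encode.

The fixed order is merge -> drop degenerate -> impute -> encode.  Two single
imputation methods are provided: median/mode fills, and draws from each
column's observed distribution (normal for numeric, empirical frequencies for
categorical).  Imputation statistics are computed on the full table before any
cross-validation split; this mirrors the common single-imputation workflow and
leaks a small amount of information across folds — callers wanting strict
fold-wise imputation can re-run the imputer inside each training fold.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "DesignMatrix",
    "FeatureEncoder",
    "merge_sources",
    "drop_degenerate_features",
    "impute_median_mode",
    "impute_distribution_sample",
    "encode_features",
    "improvement_summary",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclasses.dataclass
class FeatureMatrix:
    """Mixed-type feature table; NaN marks a missing cell."""

    values: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        missing_kinds = [c for c in self.values.columns if c not in self.kinds]
        if missing_kinds:
            raise ValueError(f"no kind declared for columns: {missing_kinds}")
        bad = {c: k for c, k in self.kinds.items() if k not in (NUMERIC, CATEGORICAL)}
        if bad:
            raise ValueError(f"unknown column kinds: {bad}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        """Infer kinds from dtypes: object/category/bool -> categorical."""
        kinds = {
            c: CATEGORICAL if df[c].dtype.kind in "ObU" or isinstance(df[c].dtype, pd.CategoricalDtype) else NUMERIC
            for c in df.columns
        }
        return cls(values=df.copy(), kinds=kinds)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == kind]


@dataclasses.dataclass
class DesignMatrix:
    """Fully numeric model matrix with a provenance map back to source features.

    ``provenance`` maps each design column to ``(source feature, level)`` —
    level is None for pass-through numeric columns.
    """

    values: pd.DataFrame
    provenance: dict[str, tuple[str, object | None]]

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("design matrix must not contain missing cells")
        missing = [c for c in self.values.columns if c not in self.provenance]
        if missing:
            raise ValueError(f"provenance missing for design columns: {missing}")


def merge_sources(
    sources: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Merge keyed feature tables into one row per patient.

    Every source must be indexed by patient id with unique ids.  Column names
    shared between sources are disambiguated by a ``source.`` prefix.  When an
    ``outcome`` table (columns ``qaly`` and ``cost``) is supplied, the merged
    table is restricted to patients present there with *both* dependent
    variables observed.
    """
    if not sources:
        raise ValueError("no sources to merge")
    for name, tab in sources.items():
        if tab.index.duplicated().any():
            dup = tab.index[tab.index.duplicated()].tolist()
            raise ValueError(f"source {name!r} has duplicate patient ids: {dup}")

    seen: dict[str, list[str]] = {}
    for name, tab in sources.items():
        for col in tab.columns:
            seen.setdefault(col, []).append(name)
    renamed = []
    for name, tab in sources.items():
        cols = {c: f"{name}.{c}" if len(seen[c]) > 1 else c for c in tab.columns}
        renamed.append(tab.rename(columns=cols))

    merged = pd.concat(renamed, axis=1, join="outer")
    if outcome is not None:
        for dv in ("qaly", "cost"):
            if dv not in outcome.columns:
                raise ValueError(f"outcome table lacks column {dv!r}")
        keep = outcome.dropna(subset=["qaly", "cost"]).index
        merged = merged.reindex(keep)
    return FeatureMatrix.from_dataframe(merged)


def drop_degenerate_features(
    m: FeatureMatrix,
    arm_split: pd.Series | Sequence[str] | None = None,
) -> tuple[FeatureMatrix, list[dict]]:
    """Remove features that are entirely missing or carry a single observed
    value — overall, or within any arm subgroup when ``arm_split`` is given
    (a level present in only one arm cannot be estimated arm-wise).

    Returns the pruned matrix and a removal report (name + reason per column).
    """
    report: list[dict] = []
    groups: list[tuple[str, pd.DataFrame]]
    if arm_split is not None:
        arms = pd.Series(np.asarray(arm_split), index=m.values.index)
        groups = [(str(a), m.values.loc[arms == a]) for a in arms.unique()]
    else:
        groups = []

    keep = []
    for col in m.values.columns:
        observed = m.values[col].dropna()
        if observed.empty:
            report.append({"feature": col, "reason": "all values missing"})
            continue
        if observed.nunique() < 2:
            report.append({"feature": col, "reason": "single observed level"})
            continue
        degenerate_arm = None
        for arm_name, sub in groups:
            if sub[col].dropna().nunique() < 2:
                degenerate_arm = arm_name
                break
        if degenerate_arm is not None:
            report.append({"feature": col, "reason": f"degenerate within arm {degenerate_arm}"})
            continue
        keep.append(col)
    if not keep:
        report.append({"feature": None, "reason": "no features survived pruning"})
    pruned = FeatureMatrix(values=m.values[keep].copy(), kinds={c: m.kinds[c] for c in keep})
    return pruned, report


def impute_median_mode(m: FeatureMatrix) -> FeatureMatrix:
    """Fill numeric columns with the observed median and categorical columns
    with the modal observed level (ties: lexicographically smallest)."""
    out = m.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed values; drop it upstream")
        if not out[col].isna().any():
            continue
        if m.kinds[col] == NUMERIC:
            fill = float(observed.median())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()]
            fill = sorted(top.index)[0]
        out[col] = out[col].fillna(fill)
    return FeatureMatrix(values=out, kinds=dict(m.kinds))


def impute_distribution_sample(m: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Fill numeric cells with Normal(mean, SD) draws and categorical cells
    with draws from the observed level frequencies; reproducible under seed."""
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    for col in out.columns:  # fixed column order keeps the stream reproducible
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed values; drop it upstream")
        mask = out[col].isna()
        k = int(mask.sum())
        if k == 0:
            continue
        if m.kinds[col] == NUMERIC:
            sd = float(observed.std(ddof=1)) if len(observed) > 1 else 0.0
            if not np.isfinite(sd) or sd == 0.0:
                if len(observed) == 1:
                    warnings.warn(f"column {col!r}: single observed value, filling with it")
                fills = np.full(k, float(observed.mean()))
            else:
                fills = rng.normal(float(observed.mean()), sd, size=k)
            out.loc[mask, col] = fills
        else:
            freq = observed.value_counts(normalize=True)
            out.loc[mask, col] = rng.choice(freq.index.to_numpy(), size=k, p=freq.to_numpy())
    return FeatureMatrix(values=out, kinds=dict(m.kinds))


class FeatureEncoder:
    """One-hot encoder with the modal training level as reference.

    Numeric columns pass through; each categorical feature with L observed
    levels contributes L-1 indicator columns.  Levels unseen at fit time map
    to an all-zero indicator block at transform time (with a warning), so a
    held-out patient never crashes prediction.
    """

    def __init__(self) -> None:
        self.levels_: dict[str, list] | None = None

    def fit(self, m: FeatureMatrix) -> "FeatureEncoder":
        if m.values.isna().to_numpy().any():
            raise ValueError("encode after imputation: matrix still has missing cells")
        self.kinds_ = dict(m.kinds)
        self.columns_ = list(m.values.columns)
        self.levels_ = {}
        self.reference_ = {}
        for col in self.columns_:
            if self.kinds_[col] == CATEGORICAL:
                counts = m.values[col].value_counts()
                top = counts[counts == counts.max()]
                ref = sorted(top.index)[0]
                others = sorted(lvl for lvl in counts.index if lvl != ref)
                self.reference_[col] = ref
                self.levels_[col] = others
        return self

    def transform(self, values: pd.DataFrame) -> DesignMatrix:
        if self.levels_ is None:
            raise RuntimeError("encoder not fitted")
        cols: dict[str, np.ndarray] = {}
        provenance: dict[str, tuple[str, object | None]] = {}
        for col in self.columns_:
            if col not in values.columns:
                raise KeyError(f"column {col!r} missing from input")
            if self.kinds_[col] == NUMERIC:
                cols[col] = values[col].to_numpy(dtype=float)
                provenance[col] = (col, None)
            else:
                known = set(self.levels_[col]) | {self.reference_[col]}
                unseen = set(values[col].unique()) - known
                if unseen:
                    warnings.warn(f"column {col!r}: unseen levels {sorted(map(str, unseen))} encoded as all-zero")
                for lvl in self.levels_[col]:
                    name = f"{col}={lvl}"
                    cols[name] = (values[col] == lvl).to_numpy(dtype=float)
                    provenance[name] = (col, lvl)
        frame = pd.DataFrame(cols, index=values.index)
        return DesignMatrix(values=frame, provenance=provenance)

    def fit_transform(self, m: FeatureMatrix) -> DesignMatrix:
        return self.fit(m).transform(m.values)


def encode_features(m: FeatureMatrix) -> DesignMatrix:
    """One-hot encode a fully imputed feature matrix (modal level as reference)."""
    return FeatureEncoder().fit_transform(m)


def improvement_summary(
    phq9_start: Mapping[str, Sequence[float]],
    phq9_end: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, float]:
    """Per-arm PHQ-9 summary and a Welch t-test on 6-month scores.

    Improvement means the 6-month score is strictly below baseline.  Returns
    (summary table indexed by arm, two-sided p-value comparing mean end scores
    between the two arms).
    """
    arms = list(phq9_start.keys())
    if set(arms) != set(phq9_end.keys()):
        raise ValueError("start and end tables must cover the same arms")
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, got {arms}")
    rows = {}
    ends = {}
    for arm in arms:
        start = np.asarray(phq9_start[arm], dtype=float)
        end = np.asarray(phq9_end[arm], dtype=float)
        if start.size == 0 or end.size != start.size:
            raise ValueError(f"arm {arm!r}: start/end scores must be paired and nonempty")
        rows[arm] = {
            "n": start.size,
            "mean_start": start.mean(),
            "mean_end": end.mean(),
            "improved": int((end < start).sum()),
            "not_improved": int((end >= start).sum()),
        }
        ends[arm] = end
    summary = pd.DataFrame(rows).T
    pvalue = float(stats.ttest_ind(ends[arms[0]], ends[arms[1]], equal_var=False).pvalue)
    return summary, pvalue
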