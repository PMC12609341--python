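"""Panel utilities: preprocessing and robustness manipulations.

Operations on the canonical long-format province(unit)-year panel:
linear interpolation of missing indicator series, quantile winsorization,
unit exclusion, one-period lagging of controls, subgroup splits
(membership lists, median splits) and the Simpson crop-diversification
index.  All operations are pure: they return new DataFrames and never
mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNIT",
    "YEAR",
    "OUTCOME",
    "TREATMENTS",
    "CONTROLS",
    "CROP_SHARES",
    "PanelDataset",
    "SubgroupRule",
    "interpolate_missing",
    "simpson_index",
    "winsorize",
    "exclude_units",
    "lag_controls",
    "split_subgroup",
]

# Canonical column names of the long-format panel.
UNIT = "unit"
YEAR = "year"
OUTCOME = "FASCR"
TREATMENTS = ("TEMP", "RAIN")
CONTROLS = ("UL", "RTSI", "EPA", "EUE", "VAFA", "RECA", "RGPBE")
MODERATOR = "SID"
CROPS = ("rice", "wheat", "maize", "beans", "potatoes", "oilseeds")
CROP_SHARES = tuple(f"N_{c}" for c in CROPS)
GROUP_COLS = ("major_producer", "mech_score")


@dataclass
class PanelDataset:
    """A validated unit-year panel.

    Thin wrapper around a :class:`pandas.DataFrame` carrying the canonical
    columns (unit, year, indicators, TEMP, RAIN, SID, controls, crop
    shares, group labels).  ``validate`` enforces the structural
    invariants: unique (unit, year) keys, contiguous years per unit,
    SID inside [0, 1], nonnegative crop shares.
    """

    frame: pd.DataFrame

    def validate(self) -> "PanelDataset":
        df = self.frame
        for col in (UNIT, YEAR):
            if col not in df.columns:
                raise ValueError(f"panel is missing required column {col!r}")
        if df.duplicated([UNIT, YEAR]).any():
            raise ValueError("panel has duplicate (unit, year) pairs")
        for unit, grp in df.groupby(UNIT):
            years = np.sort(grp[YEAR].to_numpy())
            if len(years) > 1 and not np.all(np.diff(years) == 1):
                raise ValueError(f"years are not contiguous for unit {unit!r}")
        if MODERATOR in df.columns:
            sid = df[MODERATOR].dropna()
            if ((sid < 0) | (sid > 1)).any():
                raise ValueError("SID values must lie in [0, 1]")
        share_cols = [c for c in CROP_SHARES if c in df.columns]
        if share_cols and (df[share_cols] < 0).any().any():
            raise ValueError("crop shares must be nonnegative")
        return self

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PanelDataset":
        return cls(pd.read_csv(path)).validate()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class SubgroupRule:
    """Row-filter rule: membership list of units, or unit-median split.

    ``kind="membership_list"`` with ``side`` "in"/"out" keeps units in or
    out of ``units``.  ``kind="median_split"`` ranks units by their panel
    mean of ``variable``, splits at the median of those unit means (ties
    to the lower group) and keeps the "above"/"below" side.
    """

    kind: str
    units: Sequence[str] = field(default_factory=list)
    variable: str | None = None
    side: str = "in"

    def __post_init__(self) -> None:
        if self.kind not in ("membership_list", "median_split"):
            raise ValueError(f"unknown SubgroupRule.kind {self.kind!r}")
        if self.kind == "membership_list":
            if not self.units:
                raise ValueError("membership_list rule requires a nonempty unit list")
            if self.side not in ("in", "out"):
                raise ValueError("membership_list side must be 'in' or 'out'")
        else:
            if not self.variable:
                raise ValueError("median_split rule requires a variable name")
            if self.side not in ("above", "below"):
                raise ValueError("median_split side must be 'above' or 'below'")


def _as_frame(panel: PanelDataset | pd.DataFrame) -> pd.DataFrame:
    return panel.frame if isinstance(panel, PanelDataset) else panel


def interpolate_missing(
    panel: PanelDataset | pd.DataFrame, columns: Iterable[str] | None = None
) -> pd.DataFrame:
    """Fill missing values by linear interpolation along year within unit.

    Interior gaps are filled linearly; leading/trailing gaps take the
    nearest observed value (linear interpolation is undefined beyond the
    observed range).  Observed values are never altered.

    Parameters
    ----------
    columns
        Columns to repair.  Default: every numeric column with at least
        one missing value (identifier columns excluded).
    """
    df = _as_frame(panel).copy()
    if columns is None:
        numeric = df.select_dtypes(include=[np.number]).columns
        columns = [c for c in numeric if c not in (YEAR,) and df[c].isna().any()]
    columns = list(columns)
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in panel")
    out = df.sort_values([UNIT, YEAR]).reset_index(drop=True)
    for col in columns:
        for unit, grp in out.groupby(UNIT, sort=False):
            vals = grp[col].to_numpy(dtype=float)
            mask = np.isfinite(vals)
            if not mask.any():
                raise ValueError(
                    f"cannot interpolate: all values missing for unit {unit!r}, column {col!r}"
                )
            if mask.all():
                continue
            years = grp[YEAR].to_numpy(dtype=float)
            # np.interp clamps outside the observed range -> nearest-value
            # boundary fill for leading/trailing gaps.
            filled = np.interp(years, years[mask], vals[mask])
            out.loc[grp.index, col] = np.where(mask, vals, filled)
    return out


def simpson_index(shares: Sequence[float] | np.ndarray) -> float:
    """Simpson diversification index SID = 1 - sum(N_i^2).

    ``shares`` are the six crop planting shares (or raw areas — they are
    renormalized to sum to one before squaring, so the index is
    scale-invariant).  Returns 0 for complete specialization and at most
    1 - 1/k for k evenly planted crops.
    """
    arr = np.asarray(shares, dtype=float)
    if arr.ndim != 1:
        raise ValueError("shares must be a one-dimensional vector")
    if (arr < 0).any():
        raise ValueError("crop shares must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("crop shares are all zero; SID undefined")
    p = arr / total
    return float(1.0 - np.sum(p**2))


def winsorize(
    panel: PanelDataset | pd.DataFrame,
    columns: Iterable[str],
    lower_q: float,
    upper_q: float,
) -> pd.DataFrame:
    """Clamp each column to its pooled [lower_q, upper_q] quantiles.

    Quantiles are computed on the pooled panel (all units and years) using
    order statistics — the largest observation at or below the lower
    position and the smallest at or above the upper position — so the
    operation is exactly idempotent (an interpolated quantile of already
    clipped data would drift past the clipped mass).
    """
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError(f"require 0 <= lower_q < upper_q <= 1, got ({lower_q}, {upper_q})")
    df = _as_frame(panel).copy()
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in panel")
        vals = df[col].to_numpy(dtype=float)
        lo = np.nanquantile(vals, lower_q, method="lower")
        hi = np.nanquantile(vals, upper_q, method="higher")
        df[col] = np.clip(vals, lo, hi)
    return df


def exclude_units(panel: PanelDataset | pd.DataFrame, units: Iterable[str]) -> pd.DataFrame:
    """Drop all rows of the named units (sample-adjustment robustness)."""
    df = _as_frame(panel)
    units = list(units)
    present = set(df[UNIT].unique())
    unknown = [u for u in units if u not in present]
    if unknown:
        raise KeyError(f"unknown units: {unknown}")
    out = df[~df[UNIT].isin(units)].reset_index(drop=True)
    if out.empty:
        raise ValueError("excluding these units leaves an empty panel")
    return out


def lag_controls(
    panel: PanelDataset | pd.DataFrame, columns: Iterable[str], lag: int = 1
) -> pd.DataFrame:
    """Replace ``columns`` by their ``lag``-year lags within unit.

    The first ``lag`` years of each unit, for which no lagged value
    exists, are dropped from the estimation sample.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    df = _as_frame(panel)
    columns = list(columns)
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in panel")
    out = df.sort_values([UNIT, YEAR]).reset_index(drop=True).copy()
    n_years = out.groupby(UNIT)[YEAR].transform("size")
    if (n_years <= lag).any():
        raise ValueError("lag is >= the series length for at least one unit")
    for col in columns:
        out[col] = out.groupby(UNIT, sort=False)[col].shift(lag)
    out = out.dropna(subset=columns).reset_index(drop=True)
    return out


def split_subgroup(panel: PanelDataset | pd.DataFrame, rule: SubgroupRule) -> pd.DataFrame:
    """Return the rows selected by a subgroup rule (pure row filter)."""
    df = _as_frame(panel)
    if rule.kind == "membership_list":
        present = set(df[UNIT].unique())
        unknown = [u for u in rule.units if u not in present]
        if unknown:
            raise KeyError(f"unknown units in membership list: {unknown}")
        mask = df[UNIT].isin(rule.units)
        if rule.side == "out":
            mask = ~mask
    else:
        if rule.variable not in df.columns:
            raise KeyError(f"median_split variable {rule.variable!r} not in panel")
        unit_means = df.groupby(UNIT)[rule.variable].mean()
        cut = unit_means.median()
        # ties go to the lower group
        below_units = unit_means.index[unit_means <= cut]
        mask = df[UNIT].isin(below_units)
        if rule.side == "above":
            mask = ~mask
    out = df[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError("subgroup rule selects no rows")
    return out
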