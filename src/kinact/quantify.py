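"""Exposure-series quantification: slopes, log2 activity matrix, kinetic QC.

The activity readout of a peptide-array spot is the rate at which its
fluorescence grows with camera exposure time.  Each spot's readings over the
exposure series are reduced to an ordinary least-squares slope (intensity per
ms, intercept included — background fluorescence at zero exposure is not
zero), the slope is multiplied by 100 and log2-transformed, kinetically flat
peptides are removed, and technical duplicates are averaged on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io import IntensityTable

__all__ = [
    "ExposureSeries",
    "SlopeEstimate",
    "ActivityMatrix",
    "QCReport",
    "fit_exposure_slope",
    "fit_slope_table",
    "log2_transform_slopes",
    "qc_filter_peptides",
    "average_duplicates",
]

FLAG_OK = "ok"
FLAG_FLOORED = "floored"
FLAG_MISSING = "missing"


@dataclass(frozen=True)
class ExposureSeries:
    """One spot's intensity readings over strictly increasing exposure times."""

    exposure_ms: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.exposure_ms) != len(self.intensity):
            raise ValueError("exposure_ms and intensity differ in length")
        if len(self.exposure_ms) < 2:
            raise ValueError("an exposure series needs at least 2 readings")
        if any(b <= a for a, b in zip(self.exposure_ms, self.exposure_ms[1:])):
            raise ValueError("exposure times must be strictly increasing")


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float  # intensity units per ms
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass
class ActivityMatrix:
    """log2(100 x slope) values, peptides x samples, with per-cell flags."""

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags shapes differ")
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must share index and columns")

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def subset(self, peptides) -> "ActivityMatrix":
        return ActivityMatrix(self.values.loc[list(peptides)], self.flags.loc[list(peptides)])


@dataclass
class QCReport:
    retained_peptides: set[str]
    removed_peptides: set[str]
    reason: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained_peptides & self.removed_peptides:
            raise ValueError("retained and removed peptide sets overlap")


def fit_exposure_slope(series: ExposureSeries) -> SlopeEstimate:
    """OLS line (with intercept) through intensity vs exposure time."""
    t = np.asarray(series.exposure_ms, dtype=float)
    y = np.asarray(series.intensity, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct exposure times")
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return SlopeEstimate(slope=slope, intercept=intercept, r_squared=r2)


def fit_slope_table(table: IntensityTable) -> pd.DataFrame:
    """Per-spot OLS slopes for a whole intensity table.

    Returns a DataFrame indexed by peptide with one column per
    (sample, replicate) array; all spots share the exposure grid, so the
    normal equations are vectorized across spots.
    """
    peptides = table.peptide_ids
    arrays = list(dict.fromkeys(zip(table.data["sample"], table.data["replicate"])))
    out = pd.DataFrame(
        index=pd.Index(peptides, name="peptide_id"),
        columns=pd.MultiIndex.from_tuples(arrays, names=["sample", "replicate"]),
        dtype=float,
    )
    sub = table.data.sort_values("exposure_ms")
    for (sample, replicate), group in sub.groupby(["sample", "replicate"], sort=False):
        pivot = group.pivot(index="peptide_id", columns="exposure_ms", values="intensity")
        t = pivot.columns.to_numpy(dtype=float)
        y = pivot.to_numpy(dtype=float)
        tc = t - t.mean()
        slopes = (y - y.mean(axis=1, keepdims=True)) @ tc / float(tc @ tc)
        out.loc[pivot.index, (sample, replicate)] = slopes
    return out


def log2_transform_slopes(
    slopes: pd.DataFrame, floor_epsilon: float = 1e-3
) -> ActivityMatrix:
    """value = log2(100 x max(slope, floor_epsilon)); floored cells flagged.

    The transform is undefined for slopes <= 0, so nonpositive (or tiny)
    slopes are floored at ``floor_epsilon`` and flagged rather than dropped.
    """
    if floor_epsilon <= 0:
        raise ValueError("floor_epsilon must be > 0")
    arr = slopes.to_numpy(dtype=float)
    floored = arr < floor_epsilon
    values = np.log2(100.0 * np.maximum(arr, floor_epsilon))
    missing = np.isnan(arr)
    values[missing] = np.nan
    flags = np.where(missing, FLAG_MISSING, np.where(floored, FLAG_FLOORED, FLAG_OK))
    return ActivityMatrix(
        pd.DataFrame(values, index=slopes.index, columns=slopes.columns),
        pd.DataFrame(flags, index=slopes.index, columns=slopes.columns),
    )


def qc_filter_peptides(
    slopes: pd.DataFrame,
    rule: Literal["median", "mean", "all_positive"] = "median",
    threshold: float = 0.0,
) -> QCReport:
    """Remove peptides with no intensity increase over exposure time.

    Default rule: a peptide is removed iff its *median* slope across all
    sample x replicate spots is <= ``threshold`` (the median is robust to a
    single bad array).  ``mean`` and ``all_positive`` are selectable
    alternatives.
    """
    if slopes.size == 0:
        raise ValueError("empty slope table")
    arr = slopes.to_numpy(dtype=float)
    if rule == "median":
        stat = np.nanmedian(arr, axis=1)
        removed_mask = stat <= threshold
    elif rule == "mean":
        stat = np.nanmean(arr, axis=1)
        removed_mask = stat <= threshold
    elif rule == "all_positive":
        removed_mask = np.nanmin(arr, axis=1) <= threshold
    else:
        raise ValueError(f"unknown QC rule {rule!r}")
    retained, removed, reason = set(), set(), {}
    for pep, bad in zip(slopes.index, removed_mask):
        if bad:
            removed.add(pep)
            reason[pep] = "non-increasing"
        else:
            retained.add(pep)
    return QCReport(retained_peptides=retained, removed_peptides=removed, reason=reason)


def average_duplicates(
    matrix: ActivityMatrix,
    replicate_map: Mapping | None = None,
    scale: Literal["log2", "linear"] = "log2",
) -> ActivityMatrix:
    """Average technical duplicates per case.

    ``replicate_map`` assigns each array column to a case; by default columns
    are (sample, replicate) tuples and the case is the sample.  Averaging is
    on the log2 scale (duplicates are technical replicates of one lysate); a
    linear-scale mode is available.  If one replicate is missing the
    surviving value is used and the cell flagged; a floored replicate flags
    the averaged cell as floored.
    """
    if replicate_map is None:
        if isinstance(matrix.values.columns, pd.MultiIndex):
            replicate_map = {col: col[0] for col in matrix.values.columns}
        else:
            replicate_map = {col: col for col in matrix.values.columns}
    cases = list(dict.fromkeys(replicate_map[c] for c in matrix.values.columns))
    values = pd.DataFrame(index=matrix.values.index, columns=cases, dtype=float)
    flags = pd.DataFrame(FLAG_OK, index=matrix.values.index, columns=cases)
    for case in cases:
        cols = [c for c in matrix.values.columns if replicate_map[c] == case]
        if not cols:
            raise ValueError(f"case {case!r} has zero replicate columns")
        block = matrix.values[cols]
        fblock = matrix.flags[cols]
        n_present = block.notna().sum(axis=1)
        if (n_present == 0).any():
            raise ValueError(f"case {case!r} has peptides with zero usable replicates")
        if scale == "linear":
            mean = np.log2((2.0 ** block).mean(axis=1, skipna=True))
        else:
            mean = block.mean(axis=1, skipna=True)
        values[case] = mean
        any_missing = (fblock == FLAG_MISSING).any(axis=1) | block.isna().any(axis=1)
        any_floored = (fblock == FLAG_FLOORED).any(axis=1)
        flags.loc[any_floored, case] = FLAG_FLOORED
        flags.loc[any_missing, case] = FLAG_MISSING
    return ActivityMatrix(values, flags)
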