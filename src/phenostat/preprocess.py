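"""Outlier handling within experimental cells and technical aggregation.

An *experimental cell* is the subgroup within which trait values are expected
to be biologically homogeneous — by default cultivar x treatment x trait x
time point. Outlier statistics (IQR fences or Z-scores) are computed
independently per cell; the policy then filters, winsorizes, or merely
annotates the flagged rows. Technical aggregation collapses repeated scans of
one plant within one time point to a single value (median or mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_project import Project

__all__ = [
    "OutlierPolicy",
    "iqr_fences",
    "zscore_flags",
    "apply_outlier_policy",
    "technical_aggregate",
    "MIN_CELL_IQR",
    "MIN_CELL_Z",
]

log = logging.getLogger(__name__)

#: Minimum cell sizes below which no flagging happens (fences from tiny cells
#: are noise).
MIN_CELL_IQR = 4
MIN_CELL_Z = 3

DEFAULT_CELL_FACTORS = ("cultivar", "treatment", "trait", "time_point")


@dataclass
class OutlierPolicy:
    """How outliers are detected and what happens to them.

    method
        ``"iqr"`` — flag values outside Q1 - k*IQR .. Q3 + k*IQR;
        ``"zscore"`` — flag values with |value - mean| / sd > threshold.
    mode
        ``"filter"`` drops flagged rows, ``"winsorize"`` clips them to the
        nearest fence, ``"annotate"`` keeps them and sets an ``is_outlier``
        column.
    cell_factors
        Columns defining the experimental cell within which statistics are
        computed.
    """

    method: str = "iqr"
    mode: str = "annotate"
    iqr_k: float = 1.5
    z_threshold: float = 3.0
    cell_factors: tuple = field(default_factory=lambda: DEFAULT_CELL_FACTORS)

    def __post_init__(self):
        if self.method not in ("iqr", "zscore"):
            raise ValueError(f"unknown outlier method {self.method!r}")
        if self.mode not in ("filter", "winsorize", "annotate"):
            raise ValueError(f"unknown outlier mode {self.mode!r}")
        if self.iqr_k <= 0 or self.z_threshold <= 0:
            raise ValueError("outlier thresholds must be positive")


def iqr_fences(values, k: float = 1.5):
    """Tukey fences (Q1 - k*IQR, Q3 + k*IQR) with linearly interpolated quartiles.

    Returns ``None`` (a no-op signal, not an error) for fewer than four finite
    values — such cells are too small for meaningful fences.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < MIN_CELL_IQR:
        return None
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation (default)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def zscore_flags(values, threshold: float = 3.0) -> np.ndarray:
    """Flag values whose |z| exceeds ``threshold`` (sd with n-1 denominator).

    Degenerate inputs (n < 3 or zero variance) flag nothing.
    """
    arr = np.asarray(values, dtype=float)
    flags = np.zeros(arr.shape, dtype=bool)
    finite = np.isfinite(arr)
    if finite.sum() < MIN_CELL_Z:
        return flags
    sd = np.std(arr[finite], ddof=1)
    if sd == 0:
        return flags
    mean = np.mean(arr[finite])
    flags[finite] = np.abs(arr[finite] - mean) / sd > threshold
    return flags


def _cell_flags_and_clips(values: np.ndarray, policy: OutlierPolicy):
    """Per-cell flags plus the clipped values used by winsorize mode."""
    if policy.method == "iqr":
        fences = iqr_fences(values, policy.iqr_k)
        if fences is None:
            return np.zeros(values.shape, bool), values
        low, high = fences
        flags = (values < low) | (values > high)
        return flags, np.clip(values, low, high)
    flags = zscore_flags(values, policy.z_threshold)
    if not flags.any():
        return flags, values
    mean = np.mean(values)
    sd = np.std(values, ddof=1)
    low, high = mean - policy.z_threshold * sd, mean + policy.z_threshold * sd
    return flags, np.clip(values, low, high)


def apply_outlier_policy(project: Project, policy: OutlierPolicy) -> tuple[Project, pd.DataFrame]:
    """Apply an outlier policy cell by cell.

    Requires ``time_point`` to be assigned when it is part of the cell
    structure. Returns the transformed project and a flag table aligned with
    the *input* rows, carrying ``is_outlier`` and, for winsorized rows, the
    pre-clip ``original_value`` for audit.
    """
    df = project.measurements
    missing = [f for f in policy.cell_factors if f not in df.columns]
    if missing:
        raise KeyError(f"unknown cell factor(s): {missing}")

    values = df["value"].to_numpy(dtype=float)
    flags = np.zeros(len(df), dtype=bool)
    clipped = values.copy()
    for _, idx in df.groupby(list(policy.cell_factors), observed=True, sort=False).indices.items():
        f, c = _cell_flags_and_clips(values[idx], policy)
        flags[idx] = f
        clipped[idx] = c

    flag_table = pd.DataFrame(
        {
            "is_outlier": flags,
            "original_value": np.where(flags & (policy.mode == "winsorize"), values, np.nan),
        },
        index=df.index,
    )

    out = df.copy()
    out["is_outlier"] = flags
    if policy.mode == "filter":
        out = out[~out["is_outlier"]].drop(columns="is_outlier").reset_index(drop=True)
    elif policy.mode == "winsorize":
        out["value"] = clipped
        out["original_value"] = flag_table["original_value"].to_numpy()
    n_flagged = int(flags.sum())
    if n_flagged:
        log.info("outlier policy %s/%s flagged %d of %d rows", policy.method, policy.mode, n_flagged, len(df))
    return project.with_measurements(out), flag_table


def technical_aggregate(project: Project, stat: str = "median") -> Project:
    """Collapse technical replicates to one row per (vtr, trait, time_point).

    ``stat`` is the aggregation statistic for the trait value (median or
    mean); the representative timestamp is the median scan time and all
    per-plant metadata columns are carried through unchanged.
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"aggregation statistic must be 'median' or 'mean', got {stat!r}")
    df = project.measurements
    if "time_point" not in df.columns:
        raise KeyError("time_point not assigned; run temporal clustering first")

    keys = ["vtr", "trait", "time_point"]
    carried = [
        c for c in df.columns
        if c not in keys + ["value", "timestamp", "is_outlier", "original_value"]
    ]
    agg_spec = {"value": stat, "timestamp": "median"}
    agg_spec.update({c: "first" for c in carried})
    if "is_outlier" in df.columns:
        agg_spec["is_outlier"] = "any"
    out = df.groupby(keys, as_index=False, observed=True).agg(agg_spec)
    out = out.sort_values(["vtr", "trait", "time_point"], kind="mergesort").reset_index(drop=True)
    return project.with_measurements(out)
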