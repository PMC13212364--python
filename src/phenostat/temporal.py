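"""Synchronize irregular scan timestamps into ordinal time points.

Phenotyping scans of different blocks start at staggered times and the scan
schedule itself is irregular (gaps from an hour to several days). One-dimensional
DBSCAN over the timestamps, with ``min_samples = 1`` so that no measurement is
left unlabeled as noise, groups scans separated by gaps of at most ``eps``
hours into a single ordinal time point shared across blocks and plants. With
``min_samples = 1`` in one dimension this is exactly the sorted gap-split
rule: two timestamps share a cluster iff they are connected by a chain of
adjacent gaps each <= eps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .io_project import Project

__all__ = ["TimeClusterAssignment", "cluster_timestamps", "assign_time_points", "DEFAULT_EPS_HOURS"]

#: Default DBSCAN radius in hours: wide enough to merge same-day block start
#: offsets, narrow enough to keep daily scan waves apart.
DEFAULT_EPS_HOURS = 6.0


@dataclass
class TimeClusterAssignment:
    """Chronologically renumbered cluster labels for a set of timestamps.

    ``labels`` are 1-based and ordered by ``representative_times`` (the median
    member timestamp of each cluster), so cluster 1 is the earliest.
    """

    labels: np.ndarray
    representative_times: pd.DatetimeIndex | np.ndarray
    eps_hours: float

    @property
    def n_clusters(self) -> int:
        return len(self.representative_times)


def _to_hours(timestamps) -> tuple[np.ndarray, object]:
    """Convert datetimes (or plain numbers, taken as hours) to float hours."""
    arr = np.asarray(timestamps)
    if np.issubdtype(arr.dtype, np.number):
        return arr.astype(float), None
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps))
    origin = idx.min()
    return (idx - origin).total_seconds().to_numpy() / 3600.0, origin


def cluster_timestamps(timestamps, eps_hours: float) -> TimeClusterAssignment:
    """Cluster timestamps with 1-D DBSCAN (min_samples = 1).

    Parameters
    ----------
    timestamps
        Absolute datetimes, or plain numbers interpreted as hours.
    eps_hours
        DBSCAN radius: the largest within-cluster gap, in hours.
    """
    if eps_hours is None or eps_hours <= 0:
        raise ValueError(f"eps_hours must be positive, got {eps_hours}")
    arr = np.asarray(timestamps)
    if arr.size == 0:
        raise ValueError("cannot cluster an empty set of timestamps")

    hours, origin = _to_hours(timestamps)
    raw = DBSCAN(eps=eps_hours, min_samples=1).fit_predict(hours.reshape(-1, 1))

    # Renumber chronologically by cluster median time, 1-based.
    medians = {lab: np.median(hours[raw == lab]) for lab in np.unique(raw)}
    order = sorted(medians, key=medians.get)
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in raw], dtype=int)

    rep_hours = np.array([medians[lab] for lab in order])
    if origin is not None:
        reps = pd.DatetimeIndex(origin + pd.to_timedelta(rep_hours, unit="h"))
    else:
        reps = rep_hours
    return TimeClusterAssignment(labels=labels, representative_times=reps, eps_hours=float(eps_hours))


def assign_time_points(project: Project, eps_hours: float = DEFAULT_EPS_HOURS) -> Project:
    """Add an integer ``time_point`` column shared across blocks and plants.

    All timestamps in the project are clustered jointly, so scans of one wave
    started at staggered block offsets receive the same ordinal time point.
    """
    assignment = cluster_timestamps(project.measurements["timestamp"].to_numpy(), eps_hours)
    measurements = project.measurements.copy()
    measurements["time_point"] = assignment.labels
    return project.with_measurements(measurements)
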