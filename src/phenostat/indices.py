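"""Derived per-plant traits: spectral indices and the top-decile height summary.

Band reflectances come from a multispectral scanner (R 624-634 nm,
G 530-540 nm, B 465-485 nm, NIR 720-750 nm). NDVI tracks photosynthetic
activity (healthy tissue above 0.66); PSRI tracks leaf senescence. Platform
exports that already carry these indices as trait columns pass through the
pipeline untouched — these functions exist for raw-band inputs.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import UndefinedIndexError

__all__ = [
    "ndvi",
    "psri",
    "classify_ndvi_health",
    "height_average_top_decile",
    "NDVI_HEALTHY_THRESHOLD",
]

#: NDVI values strictly above this indicate healthy photosynthetic tissue.
NDVI_HEALTHY_THRESHOLD = 0.66


def ndvi(nir, r):
    """Normalized difference vegetation index, (NIR - R) / (NIR + R).

    Bounded in [-1, 1]; the maximum 1 is attained exactly when R = 0.
    Accepts scalars or arrays of nonnegative reflectances. Raises
    :class:`UndefinedIndexError` when NIR + R = 0 anywhere.
    """
    nir_a = np.asarray(nir, dtype=float)
    r_a = np.asarray(r, dtype=float)
    if np.any(nir_a < 0) or np.any(r_a < 0):
        raise ValueError("reflectances must be nonnegative")
    denom = nir_a + r_a
    if np.any(denom == 0):
        raise UndefinedIndexError("NDVI undefined: NIR + R = 0")
    out = (nir_a - r_a) / denom
    return float(out) if out.ndim == 0 else out


def psri(r, g, nir):
    """Plant senescence reflectance index, (R - G) / NIR.

    Higher values indicate leaf senescence / stress. Raises
    :class:`UndefinedIndexError` when NIR = 0 anywhere.
    """
    r_a = np.asarray(r, dtype=float)
    g_a = np.asarray(g, dtype=float)
    nir_a = np.asarray(nir, dtype=float)
    if np.any(r_a < 0) or np.any(g_a < 0) or np.any(nir_a < 0):
        raise ValueError("reflectances must be nonnegative")
    if np.any(nir_a == 0):
        raise UndefinedIndexError("PSRI undefined: NIR = 0")
    out = (r_a - g_a) / nir_a
    return float(out) if out.ndim == 0 else out


def classify_ndvi_health(value: float) -> bool:
    """True iff NDVI indicates healthy photosynthetic tissue (strictly > 0.66)."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"NDVI must lie in [-1, 1], got {value}")
    return value > NDVI_HEALTHY_THRESHOLD


def height_average_top_decile(point_heights) -> float:
    """Average height (mm) of the top 10 % of plant points.

    The top decile holds ``ceil(0.1 * n)`` points, so small clouds (n < 10)
    reduce to the single maximum. Averaging the top decile rather than taking
    the raw maximum damps transient external influences such as airflow.
    """
    arr = np.asarray(point_heights, dtype=float)
    if arr.size == 0:
        raise ValueError("point_heights must be non-empty")
    k = math.ceil(0.1 * arr.size)
    top = np.sort(arr)[-k:]
    return float(np.mean(top))
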