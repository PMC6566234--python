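"""Reflectivity (percent signal enhancement) between registered volumes.

Two equivalent formulations are provided.  The ROI-mean comparator

    R = (mean_test - mean_control) / mean_control * 100

is the traditional manual-ROI figure; after registration has produced a
voxel-on-voxel match, the voxel-wise form

    R = sum_i (I_i - g_i) / sum_i g_i * 100

is computed over the common valid mask, where I_i is the test-sample signal
and g_i the control signal at voxel i, together with a per-voxel percent map
(I_i - g_i)/g_i * 100 that is rendered as a diverging color map.  On any
fixed common mask the two global formulas agree algebraically; the gain of
the voxel-wise route is the automated VOI extraction, registration and local
map, not a different statistic.

Measurement sets (e.g. enhancement percentages from two analysis methods)
are compared with an exact paired two-tailed Student t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .volio import Volume3D

__all__ = [
    "ReflectivityResult",
    "TTestResult",
    "reflectivity_roi",
    "relative_difference_percent",
    "reflectivity_voxelwise",
    "render_color_map",
    "invert_color_map",
    "paired_t_test",
]


@dataclass
class ReflectivityResult:
    global_percent: float
    voxel_map: np.ndarray  # percent; NaN where flagged/excluded
    n_voxels: int
    provenance: dict = field(default_factory=dict)


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_two_tailed: float


def reflectivity_roi(test_mean: float, control_mean: float) -> float:
    """Percent reflectivity from two ROI means."""
    if not control_mean > 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return (test_mean - control_mean) / control_mean * 100.0


def relative_difference_percent(reference: float, other: float) -> float:
    """(reference - other) / reference * 100 — the comparator used when two
    analysis methods' enhancement figures are set against each other."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return (reference - other) / reference * 100.0


def reflectivity_voxelwise(test: Volume3D, control: Volume3D, mask=None) -> ReflectivityResult:
    """Voxel-wise reflectivity of a registered test/control volume pair.

    Voxels invalid in either volume, non-finite, or with nonpositive control
    signal are excluded from both sums, the voxel map, and N.
    """
    if test.shape != control.shape:
        raise ValueError("test and control volumes are not on the same grid")
    if not (
        np.allclose(test.spacing, control.spacing)
        and np.allclose(test.origin, control.origin)
        and np.allclose(test.direction, control.direction)
    ):
        raise ValueError("test and control volumes are not on the same grid (geometry differs)")
    m = test.valid_mask() & control.valid_mask()
    if mask is not None:
        m &= np.asarray(getattr(mask, "mask", mask), dtype=bool)
    m &= control.values > 0
    n = int(m.sum())
    I = test.values[m]
    g = control.values[m]
    sum_g = float(g.sum())
    if not sum_g > 0:
        raise ValueError("control signal sum over the mask is not positive")
    global_percent = float((I.sum() - sum_g) / sum_g * 100.0)
    voxel_map = np.full(test.shape, np.nan)
    voxel_map[m] = (I - g) / g * 100.0
    prov = {
        "n_voxels": n,
        "test_water_mean": test.meta.get("water_mean"),
        "control_water_mean": control.meta.get("water_mean"),
    }
    return ReflectivityResult(global_percent, voxel_map, n, prov)


def render_color_map(result: ReflectivityResult, range_percent=(-100.0, 100.0), cmap: str = "RdBu_r"):
    """Render the voxel-wise percent map through a diverging color scale.

    Values are clipped to [lo, hi] and mapped through a 256-entry lookup
    table; flagged (NaN) voxels are rendered fully transparent.  Returns
    ``(rgba, legend)`` where ``rgba`` has shape (*map.shape, 4) and the
    legend records the scale and lookup table for exact inversion.
    """
    import matplotlib.pyplot as plt

    lo, hi = float(range_percent[0]), float(range_percent[1])
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    lut = plt.get_cmap(cmap)(np.linspace(0.0, 1.0, 256))
    vm = result.voxel_map
    flagged = ~np.isfinite(vm)
    frac = (np.clip(np.where(flagged, lo, vm), lo, hi) - lo) / (hi - lo)
    idx = np.round(frac * 255).astype(int)
    rgba = lut[idx]
    rgba[flagged] = (0.0, 0.0, 0.0, 0.0)
    legend = {"lo": lo, "hi": hi, "cmap": cmap, "lut": lut}
    return rgba, legend


def invert_color_map(rgba: np.ndarray, legend: dict) -> np.ndarray:
    """Recover percent values from a rendered map via the legend's lookup
    table (nearest color); transparent voxels come back as NaN."""
    lut = legend["lut"]
    lo, hi = legend["lo"], legend["hi"]
    flat = rgba.reshape(-1, 4)
    transparent = flat[:, 3] == 0.0
    d2 = ((flat[:, None, :3] - lut[None, :, :3]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    vals = lo + idx / 255.0 * (hi - lo)
    vals[transparent] = np.nan
    return vals.reshape(rgba.shape[:-1])


def paired_t_test(x, y) -> TTestResult:
    """Exact two-tailed paired Student t-test on the differences x - y.

    Conventions for degenerate inputs: all-zero differences give t = 0,
    p = 1; nonzero differences with zero variance give the limit p = 0 with
    t signed infinite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TTestResult(0.0, df, 1.0)
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(float(t), df, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))
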