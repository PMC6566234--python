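"""T1 relaxometry: voxel-wise T1 fitting from arrayed-TR spin-echo series,
relaxivity regression, and T1-based enhancement.

A saturation-recovery spin-echo series sampled at several repetition times
follows

    S(TR) = S0 * (1 - exp(-TR / T1)),

where the constant echo-time decay factor exp(-TE/T2) is absorbed into S0
(TE is fixed across the TR array, so the factor is unidentifiable and does
not bias T1).  T1 is fitted per voxel by bounded nonlinear least squares
with a log-linearized initialization.

Relaxivity r1 (mM^-1 s^-1) is the slope of the longitudinal relaxation rate
R1 = 1/T1 (s^-1) against contrast-agent concentration (mM); the intercept is
the diamagnetic rate of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sstats

from .volio import Volume3D

__all__ = ["T1Map", "RelaxivityFit", "fit_t1_map", "fit_relaxivity", "t1_enhancement"]

T1_BOUNDS_MS = (50.0, 10000.0)  # physical range for agarose/cell phantoms


@dataclass
class T1Map:
    t1_ms: np.ndarray
    s0: np.ndarray
    rmse: np.ndarray
    fit_mask: np.ndarray
    exclusion_reason: dict = field(default_factory=dict)  # voxel index -> code


@dataclass
class RelaxivityFit:
    r1_per_mM_per_s: float
    intercept_per_s: float
    r_squared: float


def _model(tr, s0, t1):
    return s0 * (1.0 - np.exp(-tr / t1))


def _init_guess(tr: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    s0_0 = max(float(s.max()) * 1.05, 1e-12)
    frac = np.clip(1.0 - s / s0_0, 1e-6, 1.0)
    # ln(1 - S/S0) = -TR/T1
    slope = float(np.polyfit(tr, np.log(frac), 1)[0])
    t1_0 = -1.0 / slope if slope < 0 else 1000.0
    return s0_0, float(np.clip(t1_0, *T1_BOUNDS_MS))


def fit_t1_map(series, tr_ms, mask=None) -> T1Map:
    """Fit S(TR) = S0 (1 - exp(-TR/T1)) per voxel over a co-registered series.

    Voxels whose signal shows no usable TR dependence (flat, or decreasing
    with TR) are excluded from the fit mask with a reason code.
    """
    tr = np.asarray(tr_ms, dtype=float)
    if len(series) != tr.size:
        raise ValueError("series length and TR list length differ")
    if len(set(np.round(tr, 9))) < 3:
        raise ValueError("need at least 3 distinct TR values")
    vols = [v.values if isinstance(v, Volume3D) else np.asarray(v, float) for v in series]
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("series volumes are not on a common grid")
    data = np.stack(vols, axis=-1)  # (*shape, nTR)

    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)

    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    rmse = np.full(shape, np.nan)
    fit_mask = np.zeros(shape, dtype=bool)
    reasons: dict = {}

    order = np.argsort(tr)
    tr_sorted = tr[order]
    for idx in np.argwhere(mask):
        s = data[tuple(idx)]
        vox = tuple(int(i) for i in idx)
        if not np.all(np.isfinite(s)):
            reasons[vox] = "non_finite_signal"
            continue
        span = float(np.ptp(s))
        if span <= 1e-9 * max(1.0, float(np.abs(s).max())):
            reasons[vox] = "no_tr_dependence"
            continue
        corr = np.corrcoef(tr_sorted, s[order])[0, 1]
        if not corr > 0:
            reasons[vox] = "signal_not_increasing_with_tr"
            continue
        s0_0, t1_0 = _init_guess(tr, s)
        try:
            res = optimize.least_squares(
                lambda p: _model(tr, p[0], p[1]) - s,
                x0=[s0_0, t1_0],
                bounds=([1e-9, T1_BOUNDS_MS[0]], [np.inf, T1_BOUNDS_MS[1]]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            reasons[vox] = "solver_failure"
            continue
        s0[vox], t1[vox] = res.x
        rmse[vox] = float(np.sqrt(np.mean(res.fun**2)))
        fit_mask[vox] = True
    return T1Map(t1, s0, rmse, fit_mask, reasons)


def fit_relaxivity(conc_mM, t1_ms) -> RelaxivityFit:
    """Ordinary least squares of R1 = 1/T1 (s^-1) on concentration (mM)."""
    conc = np.asarray(conc_mM, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    if conc.shape != t1.shape or conc.ndim != 1 or conc.size < 2:
        raise ValueError("need matched 1D arrays with at least two points")
    if np.any(t1 <= 0):
        raise ValueError("T1 values must be positive")
    if np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    r1 = 1000.0 / t1  # ms -> s^-1
    fit = sstats.linregress(conc, r1)
    return RelaxivityFit(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def t1_enhancement(t1_test: T1Map, t1_control: T1Map, mask=None, mode: str = "rates") -> dict:
    """Percent enhancement between two fitted T1 maps.

    ``mode="rates"`` (default) compares mask-mean relaxation rates:
    (R1_test - R1_control)/R1_control * 100 — contrast agents shorten T1,
    raising R1.  ``mode="t1_means"`` applies the ROI formula to the mask-mean
    T1 values instead (sign flipped so shorter test T1 is positive
    enhancement).  The mode used is recorded in the output.
    """
    m = t1_test.fit_mask & t1_control.fit_mask
    if mask is not None:
        m &= np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        raise ValueError("no overlapping fitted voxels")
    if mode == "rates":
        r_test = float(np.mean(1000.0 / t1_test.t1_ms[m]))
        r_ctrl = float(np.mean(1000.0 / t1_control.t1_ms[m]))
        value = (r_test - r_ctrl) / r_ctrl * 100.0
    elif mode == "t1_means":
        mt = float(np.mean(t1_test.t1_ms[m]))
        mc = float(np.mean(t1_control.t1_ms[m]))
        value = (mc - mt) / mt * 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"enhancement_percent": float(value), "mode": mode, "n_voxels": int(m.sum())}
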