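"""Xylenol-orange gadolinium quantification.

Free Gd(III) released from digested nanoparticle conjugates shifts the
xylenol orange UV-Vis absorption bands, and the A573/A433 absorbance ratio
grows linearly with concentration.  A calibration line

    ratio = slope * concentration + intercept

is inverted to read concentration off a measured ratio.  Two inversion
conventions are supported because published coefficient sets do not always
agree algebraically with their own calibration line:

* ``as_printed`` — concentration = A + B * ratio with verbatim coefficients;
* ``inverse_consistent`` — concentration = (ratio - intercept) / slope, the
  exact algebraic inverse of the stored line.

The bundled default calibration uses slope 0.3244, intercept -1.0944 and the
published coefficient pair A = 3.0826 (= 1/slope to 4 decimals),
B = 1.0944.  Since -intercept/slope = 3.3736 != B, the pair is not the
algebraic inverse of the line; constructing or inverting such a calibration
emits a warning rather than silently resolving the discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["GdCalibration", "gd_from_ratio", "invert_calibration", "fit_calibration"]

DEFAULT_SLOPE = 0.3244  # per concentration unit of the calibration data
DEFAULT_INTERCEPT = -1.0944
PUBLISHED_A = 3.0826
PUBLISHED_B = 1.0944


@dataclass
class GdCalibration:
    """Calibration line plus inversion coefficients and the active mode."""

    slope: float
    intercept: float
    coeff_A: float
    coeff_B: float
    mode: str = "as_printed"

    def __post_init__(self) -> None:
        if self.mode not in ("as_printed", "inverse_consistent"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        A, B = 1.0 / self.slope, -self.intercept / self.slope
        if not (np.isclose(self.coeff_A, A, rtol=1e-3, atol=5e-5)
                and np.isclose(self.coeff_B, B, rtol=1e-3, atol=5e-5)):
            warnings.warn(
                f"calibration coefficients (A={self.coeff_A}, B={self.coeff_B}) are not "
                f"the algebraic inverse of the line (1/slope={A:.4f}, "
                f"-intercept/slope={B:.4f}); as_printed and inverse_consistent "
                "modes will disagree",
                stacklevel=2,
            )

    @classmethod
    def published_default(cls, mode: str = "as_printed") -> "GdCalibration":
        """The bundled xylenol-orange calibration with its published
        coefficient pair (which is intentionally kept verbatim)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(DEFAULT_SLOPE, DEFAULT_INTERCEPT, PUBLISHED_A, PUBLISHED_B, mode)

    @classmethod
    def from_line(cls, slope: float, intercept: float, mode: str = "inverse_consistent") -> "GdCalibration":
        A, B = invert_calibration(slope, intercept)
        return cls(slope, intercept, A, B, mode)


def invert_calibration(slope: float, intercept: float) -> tuple[float, float]:
    """Inversion coefficients (A, B) of a calibration line.

    Follows the published convention A = 1/slope, B = -intercept/slope.
    """
    if slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    return 1.0 / slope, -intercept / slope


def gd_from_ratio(ratio_573_433: float, cal: GdCalibration) -> dict:
    """Concentration from a measured A573/A433 absorbance ratio.

    Returns the concentration with the mode that produced it; units follow
    the calibration data's units (carried as metadata, not enforced).
    """
    ratio = float(ratio_573_433)
    if ratio < 0:
        raise ValueError(f"absorbance ratio must be nonnegative, got {ratio}")
    if cal.mode == "as_printed":
        conc = cal.coeff_A + cal.coeff_B * ratio
    else:
        conc = (ratio - cal.intercept) / cal.slope
    return {"concentration": float(conc), "mode": cal.mode}


def fit_calibration(concentrations, ratios, mode: str = "inverse_consistent") -> GdCalibration:
    """Least-squares calibration line of ratio on concentration."""
    conc = np.asarray(concentrations, dtype=float)
    ratio = np.asarray(ratios, dtype=float)
    if conc.shape != ratio.shape or conc.ndim != 1 or conc.size < 2:
        raise ValueError("need matched 1D arrays with at least two points")
    if np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    fit = sstats.linregress(conc, ratio)
    return GdCalibration.from_line(float(fit.slope), float(fit.intercept), mode)
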