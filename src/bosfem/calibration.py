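"""HU -> calcium-equivalent density calibration from in-scan phantom rods.

Known rod density is regressed on mean rod HU (ordinary least squares), so
applying the calibration is a single affine map per voxel.  Rod means are
taken over a 1-voxel-eroded rod mask to avoid partial-volume rims; negative
calibrated densities are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic_ct import RawVolume

__all__ = ["CalibrationError", "CalibrationFit", "CalibratedVolume", "fit_calibration", "apply_calibration"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationFit:
    slope_mg_cm3_per_hu: float
    intercept_mg_cm3: float
    r_squared: float
    rod_samples: tuple[tuple[float, float, int], ...]  # (known density, mean HU, n voxels)

    def __post_init__(self) -> None:
        if len(self.rod_samples) < 2:
            raise CalibrationError("calibration requires >= 2 rods")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise CalibrationError("r_squared outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope_mg_cm3_per_hu": self.slope_mg_cm3_per_hu,
            "intercept_mg_cm3": self.intercept_mg_cm3,
            "r_squared": self.r_squared,
            "rod_samples": [list(s) for s in self.rod_samples],
        }


@dataclass
class CalibratedVolume:
    """Density volume (mg/cm^3, clamped >= 0) on the source grid."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    provenance: CalibrationFit | None = field(default=None, repr=False)


def fit_calibration(
    volume: RawVolume,
    rod_masks: list[np.ndarray],
    known_densities_mg_cm3: list[float],
    *,
    erode_rods: bool = True,
) -> CalibrationFit:
    """OLS line through (mean rod HU, known rod density) points.

    With ``erode_rods`` the rod mask is shrunk by one voxel before averaging;
    if erosion would empty a rod the original mask is used instead.
    """
    if len(rod_masks) != len(known_densities_mg_cm3):
        raise CalibrationError("one known density per rod mask required")
    if len(rod_masks) < 2:
        raise CalibrationError("calibration requires >= 2 rods")
    if len(set(float(d) for d in known_densities_mg_cm3)) < 2:
        raise CalibrationError("rod densities must not all be equal")

    samples = []
    for mask, dens in zip(rod_masks, known_densities_mg_cm3):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise CalibrationError("empty rod mask")
        if erode_rods:
            eroded = ndimage.binary_erosion(mask)
            if eroded.any():
                mask = eroded
        hu = volume.voxels[mask]
        samples.append((float(dens), float(hu.mean()), int(hu.size)))

    x = np.array([s[1] for s in samples])  # mean HU
    y = np.array([s[0] for s in samples])  # known density
    if np.ptp(x) < 1e-12:
        raise CalibrationError("degenerate calibration: rod HU values are identical")

    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError("non-positive calibration slope (HU not monotone in density)")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationFit(
        slope_mg_cm3_per_hu=float(slope),
        intercept_mg_cm3=float(intercept),
        r_squared=r2,
        rod_samples=tuple(samples),
    )


def apply_calibration(volume: RawVolume, fit: CalibrationFit) -> CalibratedVolume:
    """Per-voxel affine map HU -> density, clamped at zero; grid preserved."""
    rho = fit.slope_mg_cm3_per_hu * volume.voxels + fit.intercept_mg_cm3
    np.maximum(rho, 0.0, out=rho)
    return CalibratedVolume(
        voxels=rho,
        spacing_mm=volume.spacing_mm.copy(),
        affine=volume.affine.copy(),
        provenance=fit,
    )
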