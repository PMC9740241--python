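"""Classical femur segmentation: threshold, largest component, closing, fill.

Stands in for a learned segmentation model while keeping the same contract:
a single connected boolean femur mask on the source grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import CalibratedVolume

__all__ = ["SegmentationError", "FemurMask", "segment_femur"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass
class FemurMask:
    voxels: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if not self.voxels.any():
            raise SegmentationError("femur mask is empty")
        _, n = ndimage.label(self.voxels, structure=_CONN26)
        if n != 1:
            raise SegmentationError(f"femur mask has {n} connected components, expected 1")


def _ball(radius_mm: float, spacing_mm: np.ndarray) -> np.ndarray:
    r_vox = np.maximum(1, np.round(radius_mm / spacing_mm).astype(int))
    grids = np.indices(2 * r_vox + 1).astype(float)
    dist2 = sum(((g - r) / max(r, 1)) ** 2 for g, r in zip(grids, r_vox))
    return dist2 <= 1.0


def segment_femur(
    volume: CalibratedVolume,
    density_threshold_mg_cm3: float = 150.0,
    closing_radius_mm: float = 2.0,
    rod_masks: list[np.ndarray] | None = None,
) -> FemurMask:
    """Threshold -> drop rod voxels -> largest 26-connected component ->
    morphological closing -> hole fill.

    ``rod_masks`` (if given) are excluded up-front so a calibration phantom in
    the field of view cannot be picked as the bone component.
    """
    if density_threshold_mg_cm3 <= 0:
        raise SegmentationError("density threshold must be > 0")
    fg = volume.voxels >= density_threshold_mg_cm3
    if rod_masks:
        for rm in rod_masks:
            fg &= ~ndimage.binary_dilation(np.asarray(rm, dtype=bool))
    if not fg.any():
        raise SegmentationError("no bone found: threshold produced an empty mask")

    labels, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()

    if closing_radius_mm > 0:
        selem = _ball(closing_radius_mm, volume.spacing_mm)
        fg = ndimage.binary_closing(fg, structure=selem)
    fg = ndimage.binary_fill_holes(fg)

    # closing can merge in stray specks; keep the main body only
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()

    return FemurMask(voxels=fg, spacing_mm=volume.spacing_mm.copy(), affine=volume.affine.copy())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
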