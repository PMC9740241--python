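"""Femur alignment: head-sphere detection, knee-centre estimate, rigid
rotation onto the loading axis, and proximal cropping.

Conventions:
- Alignment puts the femoral head centre at the origin and the head->knee
  direction along -z, so stance loading is a -z displacement on the head.
- Density is resampled trilinearly; masks nearest-neighbour.
- The crop plane sits at the midpoint of the head-knee distance and is pushed
  distally until any supplied lesion extent is inside, plus a margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import CalibratedVolume
from .segmentation import FemurMask

__all__ = [
    "GeometryError",
    "AlignedFemur",
    "fit_sphere",
    "find_head_center",
    "find_knee_center",
    "align_and_crop",
]


class GeometryError(ValueError):
    pass


@dataclass
class AlignedFemur:
    """Density + mask resampled into the aligned (head-at-origin) frame."""

    density: np.ndarray
    mask: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray  # aligned-frame position of voxel (0,0,0)
    head_center: np.ndarray  # aligned frame; (0,0,0) by construction
    knee_center: np.ndarray
    head_radius_mm: float
    crop_plane_z: float
    world_to_aligned: np.ndarray  # 4x4: original world mm -> aligned mm

    def node_position(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin_mm + self.spacing_mm * np.asarray(ijk, dtype=float)


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Returns (center, radius, rms radial residual).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 10:
        raise GeometryError("too few points for a sphere fit")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.sum(pts * pts, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise GeometryError("degenerate sphere fit")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    rms = float(np.sqrt(np.mean(resid**2)))
    return center, radius, rms


def _trimmed_sphere_fit(points: np.ndarray, n_iter: int = 4):
    """Iteratively refit after discarding points far from the current sphere,
    so shaft voxels caught in the proximal slab do not bias the head fit."""
    pts = np.asarray(points, dtype=float)
    center, radius, rms = fit_sphere(pts)
    for _ in range(n_iter):
        resid = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
        keep = resid <= max(2.0 * rms, 1e-6)
        if keep.sum() < 10 or keep.all():
            break
        pts = pts[keep]
        center, radius, rms = fit_sphere(pts)
    return center, radius, rms


def _surface_world_points(mask: FemurMask) -> np.ndarray:
    m = mask.voxels
    surf = m & ~ndimage.binary_erosion(m)
    idx = np.argwhere(surf).astype(float)
    hom = np.column_stack([idx, np.ones(len(idx))])
    return (mask.affine @ hom.T).T[:, :3]


def _long_axis(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def find_head_center(
    mask: FemurMask, *, residual_tol_factor: float = 0.6
) -> tuple[np.ndarray, float]:
    """Locate the femoral head by a trimmed sphere fit on surface voxels in
    the end quartile of the mask's long axis.

    Both ends are tried; the better fit wins.  If neither fit's rms residual
    is below ``residual_tol_factor * mean voxel spacing`` there is no
    spherical head and an error is raised.
    """
    surf = _surface_world_points(mask)
    axis = _long_axis(surf)
    t = surf @ axis
    tmin, tmax = t.min(), t.max()
    span = tmax - tmin
    if span <= 0:
        raise GeometryError("degenerate mask")
    spacing = float(np.mean(mask.spacing_mm))
    tol = residual_tol_factor * spacing

    best = None
    for sel in (t >= tmax - 0.25 * span, t <= tmin + 0.25 * span):
        pts = surf[sel]
        if len(pts) < 10:
            continue
        try:
            center, radius, rms = _trimmed_sphere_fit(pts)
        except GeometryError:
            continue
        # reject fits whose sphere is implausibly large for the slab
        if radius > 0.6 * span:
            continue
        if best is None or rms < best[2]:
            best = (center, radius, rms)
    if best is None or best[2] > tol:
        raise GeometryError("no spherical head found")
    return best[0], float(best[1])


def find_knee_center(mask: FemurMask, head_center: np.ndarray, slab_mm: float = 5.0) -> np.ndarray:
    """Centroid of the distal-most slab of the mask (distal = far from head)."""
    idx = np.argwhere(mask.voxels).astype(float)
    hom = np.column_stack([idx, np.ones(len(idx))])
    pts = (mask.affine @ hom.T).T[:, :3]
    axis = _long_axis(pts)
    t = pts @ axis
    th = float(np.asarray(head_center) @ axis)
    # distal end is the one away from the head
    if abs(t.max() - th) > abs(t.min() - th):
        sel = t >= t.max() - slab_mm
    else:
        sel = t <= t.min() + slab_mm
    return pts[sel].mean(axis=0)


def _rotation_onto_minus_z(u: np.ndarray) -> np.ndarray:
    """Proper rotation R with R @ u = -z (u unit)."""
    target = np.array([0.0, 0.0, -1.0])
    c = float(u @ target)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    v = np.cross(u, target)
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_and_crop(
    volume: CalibratedVolume,
    mask: FemurMask,
    head_center: np.ndarray,
    knee_center: np.ndarray,
    *,
    head_radius_mm: float = 0.0,
    lesion_world_points: np.ndarray | None = None,
    margin_mm: float | None = None,
    crop: bool = True,
) -> AlignedFemur:
    """Rotate so head->knee lies along -z (head at origin), resample onto an
    axis-aligned grid, and crop to the proximal half (extended distally to
    cover ``lesion_world_points`` plus a margin).
    """
    head = np.asarray(head_center, dtype=float)
    knee = np.asarray(knee_center, dtype=float)
    d = knee - head
    L = np.linalg.norm(d)
    if L < 1e-9:
        raise GeometryError("head and knee centers coincide")
    R = _rotation_onto_minus_z(d / L)

    h = float(np.min(volume.spacing_mm))
    margin = h if margin_mm is None else float(margin_mm)

    idx = np.argwhere(mask.voxels).astype(float)
    hom = np.column_stack([idx, np.ones(len(idx))])
    world = (mask.affine @ hom.T).T[:, :3]
    aligned_pts = (world - head) @ R.T
    lo = aligned_pts.min(axis=0) - 2 * h
    hi = aligned_pts.max(axis=0) + 2 * h

    knee_a = R @ (knee - head)  # = (0, 0, -L)
    crop_z = knee_a[2] / 2.0
    if lesion_world_points is not None and len(lesion_world_points):
        lz = float(np.min((np.asarray(lesion_world_points, float) - head) @ R.T, axis=0)[2])
        crop_z = min(crop_z, lz - margin)
    if crop:
        lo[2] = max(lo[2], crop_z)

    shape = tuple(np.maximum(2, np.ceil((hi - lo) / h).astype(int) + 1))
    # input voxel coordinates for every output voxel
    ii = np.indices(shape, dtype=float)
    ax = lo[0] + h * ii[0]
    ay = lo[1] + h * ii[1]
    az = lo[2] + h * ii[2]
    Rt = R.T
    wx = head[0] + Rt[0, 0] * ax + Rt[0, 1] * ay + Rt[0, 2] * az
    wy = head[1] + Rt[1, 0] * ax + Rt[1, 1] * ay + Rt[1, 2] * az
    wz = head[2] + Rt[2, 0] * ax + Rt[2, 1] * ay + Rt[2, 2] * az
    Ainv = np.linalg.inv(volume.affine)
    ci = Ainv[0, 0] * wx + Ainv[0, 1] * wy + Ainv[0, 2] * wz + Ainv[0, 3]
    cj = Ainv[1, 0] * wx + Ainv[1, 1] * wy + Ainv[1, 2] * wz + Ainv[1, 3]
    ck = Ainv[2, 0] * wx + Ainv[2, 1] * wy + Ainv[2, 2] * wz + Ainv[2, 3]
    coords = np.stack([ci, cj, ck])

    density = ndimage.map_coordinates(volume.voxels, coords, order=1, mode="constant", cval=0.0)
    mask_out = (
        ndimage.map_coordinates(
            mask.voxels.astype(np.uint8), coords, order=0, mode="constant", cval=0
        )
        > 0
    )
    if not mask_out.any():
        raise GeometryError("aligned mask is empty")

    w2a = np.eye(4)
    w2a[:3, :3] = R
    w2a[:3, 3] = -R @ head
    return AlignedFemur(
        density=density,
        mask=mask_out,
        spacing_mm=h,
        origin_mm=lo,
        head_center=np.zeros(3),
        knee_center=knee_a,
        head_radius_mm=float(head_radius_mm),
        crop_plane_z=float(crop_z),
        world_to_aligned=w2a,
    )
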