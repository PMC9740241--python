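"""Synthetic CT-like volumes of an idealized femur plus calibration phantom.

The femur is modelled as a vertical capped cylinder (cortical shell around a
trabecular core) topped by an offset sphere for the head.  An optional lytic
lesion is a low-density sphere strictly inside the bone.  Calibration rods of
known calcium-equivalent density sit in the field of view, disjoint from the
bone.  Voxel HU values follow a known affine law

    HU = slope * density + intercept + N(0, noise_sd)

so that every downstream stage (calibration, segmentation, alignment, meshing,
solving) can be tested against exact ground truth without any external data.

World coordinates are millimetres.  Voxel centres sit at ``affine @ (i,j,k,1)``
with 0-based indices.  The affine is diagonal spacing plus origin unless a
rotation is requested explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CTProtocol",
    "PhantomSpec",
    "LesionSpec",
    "SyntheticFemurSpec",
    "RawVolume",
    "GroundTruthMasks",
    "generate_phantom_volume",
    "ground_truth_masks",
    "default_femur",
    "default_phantom",
    "preset_specs",
    "save_nifti",
    "save_sidecar",
]


class SyntheticSpecError(ValueError):
    """Raised when a synthetic-volume specification violates its invariants."""


@dataclass(frozen=True)
class CTProtocol:
    """Scan-protocol metadata carried along with generated volumes."""

    tube_voltage_kVp: float = 120.0
    slice_thickness_mm: float = 3.0
    pitch: float = 1.5
    fov_mm: float = 480.0
    in_plane_resolution_mm: float = 0.9375

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise SyntheticSpecError(f"CTProtocol.{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class PhantomSpec:
    """Calibration rods of known density placed in the field of view.

    Rods are finite cylinders with axis parallel to world z, centred at
    ``rod_world_centers``.
    """

    rod_densities_mg_cm3: tuple[float, ...]
    rod_radius_mm: float
    rod_world_centers: tuple[tuple[float, float, float], ...]
    rod_length_mm: float = 40.0

    def __post_init__(self) -> None:
        if len(self.rod_densities_mg_cm3) != len(self.rod_world_centers):
            raise SyntheticSpecError("one center per rod density required")
        if len(set(self.rod_densities_mg_cm3)) < 2:
            raise SyntheticSpecError("phantom needs >=2 distinct rod densities")
        if any(d < 0 for d in self.rod_densities_mg_cm3):
            raise SyntheticSpecError("rod densities must be >= 0")
        if not (self.rod_radius_mm > 0 and self.rod_length_mm > 0):
            raise SyntheticSpecError("rod radius/length must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float, float]
    radius_mm: float
    density_mg_cm3: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise SyntheticSpecError("lesion radius must be > 0")
        if self.density_mg_cm3 < 0:
            raise SyntheticSpecError("lesion density must be >= 0")


@dataclass(frozen=True)
class SyntheticFemurSpec:
    """Idealized femur: capped cylindrical shaft + spherical head.

    The shaft runs from z=0 (distal / knee end) to ``z=shaft_length_mm`` along
    the world z axis; the head sphere is centred at the shaft top plus
    ``head_center_offset``.
    """

    shaft_length_mm: float = 120.0
    shaft_outer_radius_mm: float = 14.0
    cortical_thickness_mm: float = 4.0
    head_radius_mm: float = 18.0
    head_center_offset: tuple[float, float, float] = (0.0, 0.0, 12.0)
    cortical_density_mg_cm3: float = 1200.0
    trabecular_density_mg_cm3: float = 300.0
    lesion: LesionSpec | None = None

    def __post_init__(self) -> None:
        if not (
            self.shaft_length_mm > 0
            and self.shaft_outer_radius_mm > 0
            and self.head_radius_mm > 0
            and 0 < self.cortical_thickness_mm < self.shaft_outer_radius_mm
        ):
            raise SyntheticSpecError("invalid femur geometry")
        lo = 0.0 if self.lesion is None else self.lesion.density_mg_cm3
        if not self.cortical_density_mg_cm3 > self.trabecular_density_mg_cm3 > lo:
            raise SyntheticSpecError(
                "densities must satisfy cortical > trabecular > lesion >= 0"
            )

    @property
    def head_center(self) -> np.ndarray:
        off = np.asarray(self.head_center_offset, dtype=float)
        return np.array([off[0], off[1], self.shaft_length_mm + off[2]])


@dataclass
class RawVolume:
    """HU volume with grid metadata and the generating ground truth."""

    voxels: np.ndarray  # (nx, ny, nz) HU
    spacing_mm: np.ndarray  # (3,)
    affine: np.ndarray  # (4, 4) voxel index -> world mm
    gt_slope_hu_per_mg_cm3: float
    gt_intercept_hu: float
    gt_noise_sd_hu: float
    protocol: CTProtocol = field(default_factory=CTProtocol)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise SyntheticSpecError("voxels must be 3-D")
        if not np.all(self.spacing_mm > 0):
            raise SyntheticSpecError("spacing must be positive")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SyntheticSpecError("affine must be invertible")

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (X, Y, Z) of all voxel centres."""
        return _voxel_world_coords(self.voxels.shape, self.affine)


@dataclass
class GroundTruthMasks:
    femur: np.ndarray
    lesion: np.ndarray | None
    rods: list[np.ndarray]
    cortical: np.ndarray
    trabecular: np.ndarray


def _voxel_world_coords(shape, affine):
    idx = np.indices(shape, dtype=float)
    M = affine[:3, :3]
    o = affine[:3, 3]
    X = M[0, 0] * idx[0] + M[0, 1] * idx[1] + M[0, 2] * idx[2] + o[0]
    Y = M[1, 0] * idx[0] + M[1, 1] * idx[1] + M[1, 2] * idx[2] + o[1]
    Z = M[2, 0] * idx[0] + M[2, 1] * idx[1] + M[2, 2] * idx[2] + o[2]
    return X, Y, Z


def _femur_masks(spec: SyntheticFemurSpec, X, Y, Z):
    """Analytic region membership evaluated at world points."""
    r2 = X * X + Y * Y
    R = spec.shaft_outer_radius_mm
    t = spec.cortical_thickness_mm
    L = spec.shaft_length_mm
    shaft = (r2 <= R * R) & (Z >= 0.0) & (Z <= L)
    shaft_inner = (r2 <= (R - t) ** 2) & (Z >= t) & (Z <= L)
    hc = spec.head_center
    d2 = (X - hc[0]) ** 2 + (Y - hc[1]) ** 2 + (Z - hc[2]) ** 2
    head = d2 <= spec.head_radius_mm**2
    head_inner = d2 <= (spec.head_radius_mm - t) ** 2
    femur = shaft | head
    trabecular = shaft_inner | head_inner
    cortical = femur & ~trabecular
    lesion = None
    if spec.lesion is not None:
        lc = np.asarray(spec.lesion.center, dtype=float)
        ld2 = (X - lc[0]) ** 2 + (Y - lc[1]) ** 2 + (Z - lc[2]) ** 2
        lesion = ld2 <= spec.lesion.radius_mm**2
    return femur, cortical, trabecular, lesion


def _check_lesion_inside(spec: SyntheticFemurSpec, n_samples: int = 200) -> None:
    """Analytic containment check: lesion sphere surface must lie in the bone
    (grid-independent, so an entirely out-of-field lesion is still caught)."""
    lesion = spec.lesion
    c = np.asarray(lesion.center, dtype=float)
    k = np.arange(n_samples, dtype=float)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_samples)  # Fibonacci sphere
    theta = np.pi * (1 + 5**0.5) * k
    pts = c + lesion.radius_mm * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    fem, *_ = _femur_masks(spec, pts[:, 0], pts[:, 1], pts[:, 2])
    if not fem.all():
        raise SyntheticSpecError("lesion extends outside the bone")


def _rod_masks(phantom: PhantomSpec, X, Y, Z) -> list[np.ndarray]:
    out = []
    half = phantom.rod_length_mm / 2.0
    for c in phantom.rod_world_centers:
        cx, cy, cz = c
        m = ((X - cx) ** 2 + (Y - cy) ** 2 <= phantom.rod_radius_mm**2) & (
            np.abs(Z - cz) <= half
        )
        out.append(m)
    return out


def _content_bounds(femur: SyntheticFemurSpec, phantom: PhantomSpec, margin: float):
    R = femur.shaft_outer_radius_mm
    hc = femur.head_center
    hr = femur.head_radius_mm
    lo = np.array([min(-R, hc[0] - hr), min(-R, hc[1] - hr), 0.0])
    hi = np.array([max(R, hc[0] + hr), max(R, hc[1] + hr), max(femur.shaft_length_mm, hc[2] + hr)])
    half = phantom.rod_length_mm / 2.0
    for c in phantom.rod_world_centers:
        c = np.asarray(c, dtype=float)
        lo = np.minimum(lo, c - [phantom.rod_radius_mm, phantom.rod_radius_mm, half])
        hi = np.maximum(hi, c + [phantom.rod_radius_mm, phantom.rod_radius_mm, half])
    return lo - margin, hi + margin


def _build_grid(femur, phantom, spacing, rotation, margin):
    spacing = np.asarray(spacing, dtype=float) * np.ones(3)
    M = np.diag(spacing)
    if rotation is not None:
        R = np.asarray(rotation, dtype=float)
        if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise SyntheticSpecError("rotation must be a proper 3x3 rotation matrix")
        M = R @ M
    lo, hi = _content_bounds(femur, phantom, margin)
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    u = np.linalg.solve(M, corners.T).T
    umin = np.floor(u.min(axis=0))
    umax = np.ceil(u.max(axis=0))
    shape = tuple((umax - umin + 1).astype(int))
    origin = M @ umin
    affine = np.eye(4)
    affine[:3, :3] = M
    affine[:3, 3] = origin
    return shape, spacing, affine


def generate_phantom_volume(
    femur: SyntheticFemurSpec,
    phantom: PhantomSpec,
    protocol: CTProtocol | None = None,
    *,
    slope_hu_per_mg_cm3: float = 1.0,
    intercept_hu: float = 0.0,
    noise_sd_hu: float = 0.0,
    seed: int | None = None,
    spacing_mm: float | Sequence[float] = 1.5,
    rotation: np.ndarray | None = None,
    margin_mm: float = 8.0,
) -> RawVolume:
    """Render femur + phantom into an HU volume under a known affine HU law.

    Raises if the lesion pokes out of the bone or any rod intersects it.
    A ``seed`` is mandatory whenever ``noise_sd_hu > 0`` so every volume is
    reproducible bit-for-bit.
    """
    protocol = protocol or CTProtocol()
    if noise_sd_hu > 0 and seed is None:
        raise SyntheticSpecError("seed is required when noise_sd_hu > 0")
    shape, spacing, affine = _build_grid(femur, phantom, spacing_mm, rotation, margin_mm)
    X, Y, Z = _voxel_world_coords(shape, affine)

    fem, cort, trab, lesion = _femur_masks(femur, X, Y, Z)
    rods = _rod_masks(phantom, X, Y, Z)

    if femur.lesion is not None:
        _check_lesion_inside(femur)
    if lesion is not None and np.any(lesion & ~fem):
        raise SyntheticSpecError("lesion extends outside the bone")
    for i, rm in enumerate(rods):
        if np.any(rm & fem):
            raise SyntheticSpecError(f"rod {i} overlaps the bone")

    rho = np.zeros(shape, dtype=float)
    rho[trab] = femur.trabecular_density_mg_cm3
    rho[cort] = femur.cortical_density_mg_cm3
    if lesion is not None:
        rho[lesion] = femur.lesion.density_mg_cm3
    for rm, d in zip(rods, phantom.rod_densities_mg_cm3):
        rho[rm] = d

    hu = slope_hu_per_mg_cm3 * rho + intercept_hu
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=shape)

    return RawVolume(
        voxels=hu,
        spacing_mm=spacing,
        affine=affine,
        gt_slope_hu_per_mg_cm3=slope_hu_per_mg_cm3,
        gt_intercept_hu=intercept_hu,
        gt_noise_sd_hu=noise_sd_hu,
        protocol=protocol,
    )


def ground_truth_masks(
    femur: SyntheticFemurSpec, phantom: PhantomSpec, volume: RawVolume
) -> GroundTruthMasks:
    """Exact analytic masks on the volume's grid, used as test oracles."""
    X, Y, Z = volume.world_coords()
    fem, cort, trab, lesion = _femur_masks(femur, X, Y, Z)
    rods = _rod_masks(phantom, X, Y, Z)
    return GroundTruthMasks(femur=fem, lesion=lesion, rods=rods, cortical=cort, trabecular=trab)


def default_phantom() -> PhantomSpec:
    return PhantomSpec(
        rod_densities_mg_cm3=(0.0, 100.0, 400.0, 800.0),
        rod_radius_mm=6.0,
        rod_world_centers=(
            (-45.0, -45.0, 40.0),
            (-45.0, -15.0, 40.0),
            (-45.0, 15.0, 40.0),
            (-45.0, 45.0, 40.0),
        ),
    )


def default_femur(lesion: LesionSpec | None = None) -> SyntheticFemurSpec:
    return SyntheticFemurSpec(lesion=lesion)


_PRESET_LESIONS = {
    "intact": None,
    "lytic-small": LesionSpec(center=(0.0, 0.0, 90.0), radius_mm=5.0, density_mg_cm3=50.0),
    "lytic-medium": LesionSpec(center=(0.0, 0.0, 90.0), radius_mm=7.0, density_mg_cm3=50.0),
    "lytic-large": LesionSpec(center=(0.0, 0.0, 90.0), radius_mm=9.0, density_mg_cm3=50.0),
}


def preset_specs(name: str) -> tuple[SyntheticFemurSpec, PhantomSpec]:
    """Named femur/phantom presets used by the CLI and the test-suite."""
    if name not in _PRESET_LESIONS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESET_LESIONS)}")
    return default_femur(_PRESET_LESIONS[name]), default_phantom()


def save_nifti(volume: RawVolume, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def save_sidecar(
    volume: RawVolume,
    femur: SyntheticFemurSpec,
    phantom: PhantomSpec,
    path: str | Path,
    seed: int | None = None,
) -> None:
    """JSON ground-truth sidecar so a saved volume stays fully reproducible."""
    payload = {
        "mapping": {
            "slope_hu_per_mg_cm3": volume.gt_slope_hu_per_mg_cm3,
            "intercept_hu": volume.gt_intercept_hu,
            "noise_sd_hu": volume.gt_noise_sd_hu,
        },
        "seed": seed,
        "protocol": dataclasses.asdict(volume.protocol),
        "femur": dataclasses.asdict(femur),
        "phantom": dataclasses.asdict(phantom),
        "spacing_mm": volume.spacing_mm.tolist(),
        "affine": volume.affine.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_sidecar(path: str | Path) -> tuple[SyntheticFemurSpec, PhantomSpec, dict]:
    payload = json.loads(Path(path).read_text())
    fd = dict(payload["femur"])
    if fd.get("lesion") is not None:
        ld = dict(fd["lesion"])
        ld["center"] = tuple(ld["center"])
        fd["lesion"] = LesionSpec(**ld)
    fd["head_center_offset"] = tuple(fd["head_center_offset"])
    femur = SyntheticFemurSpec(**fd)
    pd_ = dict(payload["phantom"])
    pd_["rod_densities_mg_cm3"] = tuple(pd_["rod_densities_mg_cm3"])
    pd_["rod_world_centers"] = tuple(tuple(c) for c in pd_["rod_world_centers"])
    phantom = PhantomSpec(**pd_)
    return femur, phantom, payload
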