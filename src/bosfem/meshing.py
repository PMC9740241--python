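"""Structured voxel -> tetrahedral meshing.

Every in-mask voxel is split into six tetrahedra around the same body
diagonal, which tiles the cube exactly (total mesh volume equals the
voxelized mask volume) and keeps shared faces between neighbouring voxels
consistent.  An integer coarsening factor merges voxels into larger cubes to
bound element counts.  Per-element density is the trilinear sample of the
density field at the element centroid, clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import AlignedFemur

__all__ = ["MeshError", "TetMesh", "mask_to_tets", "voxels_to_tets", "write_vtk"]


class MeshError(ValueError):
    pass


# cube corner offsets, bit order (i, j, k)
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [1, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
    ]
)

# six tets around the 0-7 body diagonal
_TETS_RAW = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)


def _signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _canonical_tets() -> np.ndarray:
    """Orient the 6-tet template so all signed volumes are positive."""
    tets = _TETS_RAW.copy()
    vols = _signed_volumes(_CORNERS.astype(float), tets)
    for i, v in enumerate(vols):
        if v < 0:
            tets[i, [2, 3]] = tets[i, [3, 2]]
    assert np.all(_signed_volumes(_CORNERS.astype(float), tets) > 0)
    return tets


_TETS = _canonical_tets()


@dataclass
class TetMesh:
    nodes: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_elem, 4) int
    element_density_mg_cm3: np.ndarray  # (n_elem,)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_density_mg_cm3 = np.asarray(self.element_density_mg_cm3, dtype=float)
        if len(self.elements) < 1:
            raise MeshError("mesh has no elements")
        if len(self.element_density_mg_cm3) != len(self.elements):
            raise MeshError("one density per element required")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise MeshError("mesh contains inverted or zero-volume elements")
        if len(np.unique(self.elements)) != len(self.nodes):
            raise MeshError("mesh has unreferenced nodes")

    def volumes(self) -> np.ndarray:
        return _signed_volumes(self.nodes, self.elements)

    @property
    def total_volume_mm3(self) -> float:
        return float(self.volumes().sum())


def _coarsen_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Majority-vote block reduction of a boolean mask."""
    if factor == 1:
        return mask
    pad = [(0, (-s) % factor) for s in mask.shape]
    m = np.pad(mask, pad).astype(float)
    s = np.array(m.shape) // factor
    m = m.reshape(s[0], factor, s[1], factor, s[2], factor).mean(axis=(1, 3, 5))
    return m >= 0.5


def _largest_face_connected(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 6-connected voxel component so the mesh is one body
    without hinge (edge/corner-only) links."""
    labels, n = ndimage.label(mask)  # default structure = 6-connectivity
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def mask_to_tets(
    mask: np.ndarray,
    spacing_mm: float,
    origin_mm: np.ndarray | None = None,
    density: np.ndarray | None = None,
    density_spacing_mm: float | None = None,
    density_origin_mm: np.ndarray | None = None,
    coarsen: int = 1,
) -> TetMesh:
    """Tetrahedralize the True voxels of ``mask``.

    ``density`` (optional) is a voxel field on its own grid; each element gets
    the trilinear sample at its centroid, clamped at zero.  Without a density
    field all elements get density 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeshError("empty mask")
    if coarsen < 1 or int(coarsen) != coarsen:
        raise MeshError("coarsen must be a positive integer")
    origin = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, dtype=float)

    m = _coarsen_mask(mask, int(coarsen))
    m = _largest_face_connected(m)
    if not m.any():
        raise MeshError("mask vanished after coarsening")
    h = spacing_mm * int(coarsen)

    vox = np.argwhere(m)  # (V, 3) coarse voxel indices
    nxyz = np.array(m.shape) + 1
    # global vertex ids on the (coarse) corner lattice
    corner_idx = vox[:, None, :] + _CORNERS[None, :, :]  # (V, 8, 3)
    gid = (
        corner_idx[..., 0] * (nxyz[1] * nxyz[2])
        + corner_idx[..., 1] * nxyz[2]
        + corner_idx[..., 2]
    )  # (V, 8)
    elements_g = gid[:, _TETS].reshape(-1, 4)  # (6V, 4) in global lattice ids
    used, inv = np.unique(elements_g, return_inverse=True)
    elements = inv.reshape(-1, 4)
    # lattice id -> (i, j, k) corner -> mm
    ci = used // (nxyz[1] * nxyz[2])
    cj = (used // nxyz[2]) % nxyz[1]
    ck = used % nxyz[2]
    nodes = origin + h * np.column_stack([ci, cj, ck]).astype(float)

    if density is not None:
        dsp = spacing_mm if density_spacing_mm is None else float(density_spacing_mm)
        dorg = origin if density_origin_mm is None else np.asarray(density_origin_mm, float)
        cent = nodes[elements].mean(axis=1)  # (E, 3) mm
        coords = ((cent - dorg) / dsp).T
        rho = ndimage.map_coordinates(
            np.asarray(density, float), coords, order=1, mode="nearest"
        )
        rho = np.maximum(rho, 0.0)
    else:
        rho = np.zeros(len(elements))

    return TetMesh(nodes=nodes, elements=elements, element_density_mg_cm3=rho)


def voxels_to_tets(aligned: AlignedFemur, target_edge_mm: float | None = None) -> TetMesh:
    """Mesh an aligned femur, coarsening voxels toward ``target_edge_mm``."""
    h = aligned.spacing_mm
    factor = 1 if target_edge_mm is None else max(1, int(round(target_edge_mm / h)))
    return mask_to_tets(
        aligned.mask,
        spacing_mm=h,
        origin_mm=aligned.origin_mm,
        density=aligned.density,
        density_spacing_mm=h,
        density_origin_mm=aligned.origin_mm,
        coarsen=factor,
    )


def interior_face_counts(mesh: TetMesh) -> tuple[int, int]:
    """(faces shared by exactly 2 elements, faces on the boundary).

    Any other multiplicity would mean a broken (non-watertight) mesh.
    """
    faces = mesh.elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    faces = np.sort(faces, axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise MeshError("face shared by more than two elements")
    return int((counts == 2).sum()), int((counts == 1).sum())


def write_vtk(mesh: TetMesh, path: str | Path, cell_fields: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured-grid export with per-element data."""
    fields = {"density_mg_cm3": mesh.element_density_mg_cm3}
    if cell_fields:
        fields.update(cell_fields)
    ne = len(mesh.elements)
    lines = [
        "# vtk DataFile Version 3.0",
        "bosfem tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} float",
    ]
    lines += [" ".join(f"{c:.6g}" for c in p) for p in mesh.nodes]
    lines.append(f"CELLS {ne} {5 * ne}")
    lines += ["4 " + " ".join(str(i) for i in e) for e in mesh.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += ["10"] * ne
    lines.append(f"CELL_DATA {ne}")
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in np.asarray(arr, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")
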