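"""Displacement-controlled nonlinear FE solve of a tetrahedral bone mesh.

Linear (constant-strain) tetrahedra, small-strain kinematics, isotropic
linear elasticity with von Mises perfect plasticity integrated by radial
return.  The head node set is pushed along the load direction in fixed
displacement increments; each increment is equilibrated by Newton iteration
with the algorithmically consistent tangent.  The femur "strength" is the
peak of the summed constraint forces at the loaded nodes, and the weakest
location is the set of elements with plastic strain at that peak step.

Voigt ordering: [xx, yy, zz, xy, yz, zx] with engineering shear strains.
Units: mm, MPa, N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialField
from .meshing import TetMesh

__all__ = [
    "SolverError",
    "LoadCase",
    "SimulationResult",
    "assemble_stiffness",
    "solve_to_failure",
    "make_stance_load_case",
]

_EQPS_TOL = 1e-8  # "deformed plastically" threshold on equivalent plastic strain


class SolverError(RuntimeError):
    pass


@dataclass
class LoadCase:
    """Displacement-controlled load case.

    ``loaded_constraint`` / ``fixed_constraint`` choose between clamping all
    three DOF of the set ("full") or only the axial (load-direction) DOF
    ("axial", i.e. rollers; only sensible for an axis-aligned direction).
    ``extra_pinned_dofs`` lets roller setups pin the remaining rigid-body
    modes explicitly.
    """

    loaded_nodes: np.ndarray
    fixed_nodes: np.ndarray
    load_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    displacement_increment_mm: float = 0.05
    max_displacement_mm: float = 2.0
    force_drop_fraction: float = 0.95
    loaded_constraint: str = "full"
    fixed_constraint: str = "full"
    extra_pinned_dofs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.loaded_nodes = np.unique(np.asarray(self.loaded_nodes, dtype=np.int64))
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        if len(self.loaded_nodes) == 0 or len(self.fixed_nodes) == 0:
            raise ValueError("loaded and fixed node sets must be nonempty")
        if np.intersect1d(self.loaded_nodes, self.fixed_nodes).size:
            raise ValueError("loaded and fixed node sets must be disjoint")
        d = np.asarray(self.load_direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("load direction must be a nonzero vector")
        self.load_direction = tuple(d / n)
        if self.displacement_increment_mm <= 0 or self.max_displacement_mm <= 0:
            raise ValueError("displacement increments must be > 0")
        for c in (self.loaded_constraint, self.fixed_constraint):
            if c not in ("full", "axial"):
                raise ValueError("constraint mode must be 'full' or 'axial'")

    @property
    def axial_component(self) -> int:
        return int(np.argmax(np.abs(np.asarray(self.load_direction))))


@dataclass
class SimulationResult:
    curve: list[tuple[float, float]]  # (applied displacement mm, total reaction N)
    f_max_n: float
    plastic_elements_at_peak: np.ndarray
    converged: list[bool]
    eqps_at_peak: np.ndarray = field(default=None, repr=False)
    reactions_fixed_at_peak: float = 0.0

    def to_dict(self) -> dict:
        return {
            "curve": [[float(d), float(f)] for d, f in self.curve],
            "f_max_n": float(self.f_max_n),
            "plastic_elements_at_peak": [int(i) for i in self.plastic_elements_at_peak],
            "converged": [bool(c) for c in self.converged],
        }


# ---------------------------------------------------------------- element ops


def _element_operators(mesh: TetMesh):
    """Per-element B matrices (6 x 12), volumes, and DOF index maps."""
    P = mesh.nodes[mesh.elements]  # (E, 4, 3)
    E = len(mesh.elements)
    M = np.concatenate([np.ones((E, 4, 1)), P], axis=2)  # (E, 4, 4)
    det = np.linalg.det(M)
    if np.any(det <= 0):
        raise SolverError("zero-volume or inverted element")
    vol = det / 6.0
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:4, :]  # (E, 3, 4): d N_a / d x_i
    B = np.zeros((E, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, 0, a], grads[:, 1, a], grads[:, 2, a]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 12)
    return B, vol, dof


_J = np.zeros((6, 6))
_J[:3, :3] = 1.0
_ID_ENG = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5]) - _J / 3.0


def _lame(materials: MaterialField):
    E = np.asarray(materials.youngs_modulus_mpa, dtype=float)
    nu = materials.poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return lam, mu


def _elastic_C(lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    C = lam[:, None, None] * _J[None] + mu[:, None, None] * np.diag(
        [2.0, 2.0, 2.0, 1.0, 1.0, 1.0]
    )[None]
    return C


def _radial_return(eps, eps_p, lam, mu, sy):
    """Vectorized elastic predictor / radial return for perfect plasticity.

    Returns (sigma, dgamma, trial deviatoric stress, trial q, plastic mask).
    """
    ee = eps - eps_p
    tr = ee[:, 0] + ee[:, 1] + ee[:, 2]
    kb = lam + 2.0 * mu / 3.0
    p = kb * tr
    s = np.empty_like(ee)
    s[:, :3] = 2.0 * mu[:, None] * (ee[:, :3] - (tr / 3.0)[:, None])
    s[:, 3:] = mu[:, None] * ee[:, 3:]  # engineering shear -> stress
    q = np.sqrt(1.5 * np.sum(s[:, :3] ** 2, axis=1) + 3.0 * np.sum(s[:, 3:] ** 2, axis=1))
    plastic = q > sy
    dgamma = np.zeros(len(ee))
    sigma = s.copy()
    if np.any(plastic):
        f = (sy[plastic] / q[plastic])[:, None]
        sigma[plastic] *= f
        dgamma[plastic] = (q[plastic] - sy[plastic]) / (3.0 * mu[plastic])
    sigma[:, :3] += p[:, None]
    return sigma, dgamma, s, q, plastic


def _plastic_strain_increment(s_trial, q, dgamma, plastic):
    d = np.zeros_like(s_trial)
    if np.any(plastic):
        scale = (dgamma[plastic] / q[plastic])[:, None]
        d[plastic, :3] = 1.5 * scale * s_trial[plastic, :3]
        d[plastic, 3:] = 3.0 * scale * s_trial[plastic, 3:]
    return d


def _tangent_C(lam, mu, sy, s_trial, q, plastic, beta=1e-6):
    """Consistent tangent; a small elastic fraction ``beta`` keeps the matrix
    positive definite when a full plastic mechanism forms (perfect plasticity
    has zero hardening)."""
    C = _elastic_C(lam, mu)
    if np.any(plastic):
        kb = lam + 2.0 * mu / 3.0
        idx = np.where(plastic)[0]
        mu_p = mu[idx]
        sy_p = sy[idx]
        q_p = q[idx]
        sv = s_trial[idx]  # stress-Voigt trial deviator
        Cp = (
            kb[idx][:, None, None] * _J[None]
            + (2.0 * mu_p * sy_p / q_p)[:, None, None] * _ID_ENG[None]
            - (3.0 * mu_p * sy_p / q_p**3)[:, None, None] * np.einsum("ei,ej->eij", sv, sv)
        )
        C[idx] = (1.0 - beta) * Cp + beta * C[idx]
    return C


def _assemble(B, vol, dof, C, ndof):
    Ke = np.einsum("eki,ekl,elj->eij", B, C, B) * vol[:, None, None]
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof))
    return K.tocsr()


class _BlockScatter:
    """Fixed-pattern scatter of flattened element entries into one CSR block."""

    def __init__(self, rows, cols, row_map, col_map, nrows, ncols):
        rr = row_map[rows]
        cc = col_map[cols]
        keep = (rr >= 0) & (cc >= 0)
        self.keep_idx = np.where(keep)[0]
        rk, ck = rr[self.keep_idx], cc[self.keep_idx]
        order = np.lexsort((ck, rk))
        rs, cs = rk[order], ck[order]
        new = np.empty(len(rs), dtype=bool)
        new[0] = True
        new[1:] = (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])
        uid_sorted = np.cumsum(new) - 1
        self.uid = np.empty(len(rs), dtype=np.int64)
        self.uid[order] = uid_sorted
        self.nuniq = int(uid_sorted[-1]) + 1
        indptr = np.searchsorted(rs[new], np.arange(nrows + 1))
        self.csr = sp.csr_matrix((np.zeros(self.nuniq), cs[new], indptr), shape=(nrows, ncols))

    def fill(self, flat_vals) -> sp.csr_matrix:
        vals = flat_vals[self.keep_idx]
        self.csr.data = np.bincount(self.uid, weights=vals, minlength=self.nuniq)
        return self.csr


class _AssemblyPlan:
    """Precomputed scatter of element matrices into the free-free and
    free-prescribed CSR blocks; the sparsity pattern is fixed for the whole
    solve, so each assembly only refills ``csr.data`` via one bincount."""

    def __init__(self, dof: np.ndarray, free: np.ndarray, prescribed: np.ndarray, ndof: int):
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        free_map = -np.ones(ndof, dtype=np.int64)
        free_map[free] = np.arange(len(free))
        pres_map = -np.ones(ndof, dtype=np.int64)
        pres_map[prescribed] = np.arange(len(prescribed))
        self._ff = _BlockScatter(rows, cols, free_map, free_map, len(free), len(free))
        self._fp = _BlockScatter(rows, cols, free_map, pres_map, len(free), len(prescribed))
        self._last_Ke = None

    def _element_matrices(self, B, vol, C):
        return (np.einsum("eki,ekl,elj->eij", B, C, B) * vol[:, None, None]).ravel()

    def free_block(self, B, vol, C) -> sp.csr_matrix:
        self._last_Ke = self._element_matrices(B, vol, C)
        return self._ff.fill(self._last_Ke)

    def coupling_block(self) -> sp.csr_matrix:
        """Free-prescribed block of the most recently assembled tangent."""
        return self._fp.fill(self._last_Ke)


def assemble_stiffness(mesh: TetMesh, materials: MaterialField) -> sp.csr_matrix:
    """Global elastic stiffness matrix (symmetric; 6 rigid-body modes in the
    unconstrained null space for a connected mesh)."""
    B, vol, dof = _element_operators(mesh)
    lam, mu = _lame(materials)
    C = _elastic_C(lam, mu)
    return _assemble(B, vol, dof, C, 3 * len(mesh.nodes))


def internal_forces(mesh: TetMesh, materials: MaterialField, u: np.ndarray) -> np.ndarray:
    """Elastic internal force vector for a given displacement field."""
    B, vol, dof = _element_operators(mesh)
    lam, mu = _lame(materials)
    eps = np.einsum("eij,ej->ei", B, u[dof])
    sigma, *_ = _radial_return(eps, np.zeros_like(eps), lam, mu, np.full(len(eps), np.inf))
    fe = np.einsum("eij,ei->ej", B, sigma) * vol[:, None]
    f = np.zeros(3 * len(mesh.nodes))
    np.add.at(f, dof.ravel(), fe.ravel())
    return f


def element_stresses(mesh: TetMesh, materials: MaterialField, u: np.ndarray) -> np.ndarray:
    """Per-element elastic Voigt stresses for a displacement field."""
    B, _, dof = _element_operators(mesh)
    lam, mu = _lame(materials)
    eps = np.einsum("eij,ej->ei", B, u[dof])
    sigma, *_ = _radial_return(eps, np.zeros_like(eps), lam, mu, np.full(len(eps), np.inf))
    return sigma


def make_stance_load_case(
    mesh: TetMesh,
    head_center: np.ndarray,
    head_radius_mm: float,
    *,
    cap_angle_deg: float = 30.0,
    displacement_increment_mm: float = 0.05,
    max_displacement_mm: float = 2.0,
    force_drop_fraction: float = 0.95,
) -> LoadCase:
    """Stance loading: the polar cap of the head is pushed along -z while the
    distal cut plane is fully fixed."""
    c = np.asarray(head_center, dtype=float)
    z = mesh.nodes[:, 2]
    cap_z = c[2] + head_radius_mm * np.cos(np.deg2rad(cap_angle_deg))
    loaded = np.where(z >= cap_z)[0]
    if len(loaded) == 0:  # coarse mesh fallback: top node layer
        loaded = np.where(z >= z.max() - 1e-6)[0]
    fixed = np.where(z <= z.min() + 1e-6)[0]
    return LoadCase(
        loaded_nodes=loaded,
        fixed_nodes=fixed,
        displacement_increment_mm=displacement_increment_mm,
        max_displacement_mm=max_displacement_mm,
        force_drop_fraction=force_drop_fraction,
    )


def solve_to_failure(
    mesh: TetMesh,
    materials: MaterialField,
    load: LoadCase,
    *,
    newton_tol: float = 1e-6,
    max_iter: int = 25,
    min_increment_factor: float = 1.0 / 16.0,
) -> SimulationResult:
    """Ramp prescribed displacement until the reaction force peaks.

    Loaded nodes are displaced uniformly along the load direction (their
    remaining DOF held), the distal set is fully fixed.  Each increment is
    equilibrated by Newton iteration; non-converged increments are halved
    down to ``min_increment_factor`` of the nominal size before giving up.
    """
    B, vol, dof = _element_operators(mesh)
    lam, mu = _lame(materials)
    sy = np.asarray(materials.yield_stress_mpa, dtype=float)
    nn = len(mesh.nodes)
    ndof = 3 * nn
    d = np.asarray(load.load_direction, dtype=float)
    ax = load.axial_component

    if load.fixed_constraint == "full":
        fixed_dofs = (3 * load.fixed_nodes[:, None] + np.arange(3)).ravel()
    else:
        fixed_dofs = 3 * load.fixed_nodes + ax
    if load.loaded_constraint == "full":
        loaded_dofs_all = (3 * load.loaded_nodes[:, None] + np.arange(3)).ravel()
    else:
        loaded_dofs_all = 3 * load.loaded_nodes + ax
    prescribed = np.unique(
        np.concatenate([fixed_dofs, loaded_dofs_all, np.asarray(load.extra_pinned_dofs, dtype=np.int64)])
    )
    free = np.setdiff1d(np.arange(ndof), prescribed)
    plan = _AssemblyPlan(dof, free, prescribed, ndof)

    u = np.zeros(ndof)
    eps_p = np.zeros((len(mesh.elements), 6))
    eqps = np.zeros(len(mesh.elements))

    curve = [(0.0, 0.0)]
    converged_flags = [True]
    f_max = 0.0
    eqps_at_peak = eqps.copy()
    react_fixed_at_peak = 0.0

    inc0 = load.displacement_increment_mm
    inc = inc0
    disp = 0.0

    def _forces_and_state(u_vec):
        eps = np.einsum("eij,ej->ei", B, u_vec[dof])
        sigma, dgamma, s_tr, q, plastic = _radial_return(eps, eps_p, lam, mu, sy)
        fe = np.einsum("eij,ei->ej", B, sigma) * vol[:, None]
        f_int = np.zeros(ndof)
        np.add.at(f_int, dof.ravel(), fe.ravel())
        return f_int, dgamma, s_tr, q, plastic

    def _set_prescribed(u_vec, target):
        if load.loaded_constraint == "full":
            for k in range(3):
                u_vec[3 * load.loaded_nodes + k] = target * d[k]
        else:
            u_vec[3 * load.loaded_nodes + ax] = target * d[ax]
        u_vec[fixed_dofs] = 0.0
        u_vec[list(load.extra_pinned_dofs)] = 0.0

    while disp < load.max_displacement_mm - 1e-12:
        target = min(disp + inc, load.max_displacement_mm)
        u_try = u.copy()
        _set_prescribed(u_try, target)

        # tangent predictor at the committed state: distributes the boundary
        # increment over the body instead of shocking the surface elements
        eps_n = np.einsum("eij,ej->ei", B, u[dof])
        _, _, s_n, q_n, pl_n = _radial_return(eps_n, eps_p, lam, mu, sy)
        Cn = _tangent_C(lam, mu, sy, s_n, q_n, pl_n)
        Kff_n = plan.free_block(B, vol, Cn).tocsc()
        Kfp_n = plan.coupling_block()
        du_p = (u_try - u)[prescribed]
        try:
            u_try[free] += spla.splu(Kff_n).solve(-Kfp_n @ du_p)
        except RuntimeError as exc:
            raise SolverError(f"linear solve failed in predictor: {exc}") from exc

        ok = False
        for _ in range(max_iter):
            f_int, dgamma, s_tr, q, plastic = _forces_and_state(u_try)
            r = -f_int[free]
            rnorm = float(np.linalg.norm(r))
            ref = max(float(np.linalg.norm(f_int[prescribed])), 1e-8)
            if rnorm <= newton_tol * ref:
                ok = True
                break
            C = _tangent_C(lam, mu, sy, s_tr, q, plastic)
            Kff = plan.free_block(B, vol, C).tocsc()
            try:
                lu = spla.splu(Kff)
            except RuntimeError as exc:  # singular factorization
                raise SolverError(f"linear solve failed: {exc}") from exc
            du = lu.solve(r)
            if not np.all(np.isfinite(du)):
                break
            u_try[free] += du

        if not ok:
            inc /= 2.0
            if inc < inc0 * min_increment_factor - 1e-15:
                raise SolverError(
                    f"solver diverged at displacement {disp:.4f} mm "
                    f"(increment floor reached)"
                )
            continue

        # commit
        u = u_try
        f_int, dgamma, s_tr, q, plastic = _forces_and_state(u)
        eps_p = eps_p + _plastic_strain_increment(s_tr, q, dgamma, plastic)
        eqps = eqps + dgamma
        disp = target
        inc = min(inc * 2.0, inc0)  # recover step size after a successful step

        node_forces = f_int.reshape(nn, 3)
        reaction = float(np.sum(node_forces[load.loaded_nodes] @ d))
        curve.append((disp, reaction))
        converged_flags.append(True)
        if reaction > f_max:
            f_max = reaction
            eqps_at_peak = eqps.copy()
            react_fixed_at_peak = float(np.sum(node_forces[load.fixed_nodes] @ d))
        if f_max > 0 and reaction < load.force_drop_fraction * f_max:
            break

    plastic_set = np.where(eqps_at_peak > _EQPS_TOL)[0]
    return SimulationResult(
        curve=curve,
        f_max_n=f_max,
        plastic_elements_at_peak=plastic_set,
        converged=converged_flags,
        eqps_at_peak=eqps_at_peak,
        reactions_fixed_at_peak=react_fixed_at_peak,
    )
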