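import numpy as np
import pytest
import scipy.sparse.linalg as spla

from bosfem.fe_solver import (
    LoadCase,
    SolverError,
    _radial_return,
    _tangent_C,
    assemble_stiffness,
    element_stresses,
    internal_forces,
    solve_to_failure,
)
from bosfem.materials import MaterialField
from bosfem.meshing import mask_to_tets

from conftest import roller_pins


def _bar_materials(n_elem, E=1000.0, sy=1e12, nu=0.0):
    return MaterialField(np.full(n_elem, E), np.full(n_elem, sy), nu)


def test_single_tet_stiffness_rank():
    mesh = mask_to_tets(np.ones((1, 1, 1), bool), 1.0)
    # take the assembled cube stiffness: symmetric with 6 rigid-body modes
    K = assemble_stiffness(mesh, _bar_materials(6, nu=0.25)).toarray()
    assert np.allclose(K, K.T, atol=1e-10)
    w = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(w) < 1e-8 * w.max()) == 6
    assert np.all(w > -1e-8 * w.max())


def test_patch_test_constant_stress():
    """Affine boundary displacement reproduces constant interior stress to
    machine precision (linear tets represent constant strain exactly)."""
    mesh = mask_to_tets(np.ones((3, 3, 3), bool), 1.0)
    mat = _bar_materials(len(mesh.elements), E=1500.0, nu=0.3)
    K = assemble_stiffness(mesh, mat).tocsc()
    A = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 3e-4]])
    xyz = mesh.nodes
    on_boundary = np.any((xyz <= xyz.min(0) + 1e-9) | (xyz >= xyz.max(0) - 1e-9), axis=1)
    u = (xyz @ A.T).ravel()
    bdofs = np.where(np.repeat(on_boundary, 3))[0]
    fdofs = np.setdiff1d(np.arange(3 * len(xyz)), bdofs)
    rhs = -K[fdofs, :][:, bdofs] @ u[bdofs]
    u_full = u.copy()
    u_full[fdofs] = spla.spsolve(K[fdofs, :][:, fdofs], rhs)
    sig = element_stresses(mesh, mat, u_full)
    np.testing.assert_allclose(sig, np.broadcast_to(sig[0], sig.shape), rtol=1e-9, atol=1e-12)
    # and matches the closed-form isotropic stress of strain sym(A)
    E, nu = 1500.0, 0.3
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    eps = 0.5 * (A + A.T)
    sig_exact = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
    np.testing.assert_allclose(sig[0][:3], np.diag(sig_exact), rtol=1e-9)
    np.testing.assert_allclose(
        sig[0][3:], [sig_exact[0, 1], sig_exact[1, 2], sig_exact[2, 0]], rtol=1e-9
    )


def test_strain_energy_uniaxial_bar(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements))
    K = assemble_stiffness(mesh, mat)
    delta = 0.01
    u = np.zeros(3 * len(mesh.nodes))
    u[2::3] = delta * mesh.nodes[:, 2] / 10.0
    energy = 0.5 * u @ (K @ u)
    assert energy == pytest.approx(0.5 * 1000.0 * 1.0 * delta**2 / 10.0, rel=1e-12)


def test_elastic_bar_reaction_closed_form(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements))
    lc = LoadCase(top, bot, displacement_increment_mm=0.01, max_displacement_mm=0.01)
    res = solve_to_failure(mesh, mat, lc)
    # E*A*delta/L = 1000 * 1 * 0.01 / 10 = 1.0 N
    assert res.curve[0] == (0.0, 0.0)
    assert res.f_max_n == pytest.approx(1.0, rel=1e-8)


def test_perfectly_plastic_bar_limit_load(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements), sy=10.0)
    pins = roller_pins(mesh, bot)
    lc = LoadCase(
        top, bot, displacement_increment_mm=0.025, max_displacement_mm=0.5,
        loaded_constraint="axial", fixed_constraint="axial", extra_pinned_dofs=pins,
    )
    res = solve_to_failure(mesh, mat, lc)
    assert res.f_max_n == pytest.approx(10.0, rel=0.01)  # sigma_y * A
    assert len(res.plastic_elements_at_peak) > 0


def test_rigid_translation_invariance(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements), sy=10.0)
    pins = roller_pins(mesh, bot)
    kw = dict(
        displacement_increment_mm=0.05, max_displacement_mm=0.3,
        loaded_constraint="axial", fixed_constraint="axial", extra_pinned_dofs=pins,
    )
    res1 = solve_to_failure(mesh, mat, LoadCase(top, bot, **kw))
    mesh2 = mask_to_tets(np.ones((1, 1, 10), bool), 1.0, origin_mm=np.array([7.0, -4.0, 11.0]))
    res2 = solve_to_failure(mesh2, mat, LoadCase(top, bot, **kw))
    np.testing.assert_allclose(
        [f for _, f in res1.curve], [f for _, f in res2.curve], rtol=1e-9
    )


def test_elastic_linearity(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements), nu=0.3)
    r1 = solve_to_failure(
        mesh, mat, LoadCase(top, bot, displacement_increment_mm=0.02, max_displacement_mm=0.02)
    )
    r2 = solve_to_failure(
        mesh, mat, LoadCase(top, bot, displacement_increment_mm=0.01, max_displacement_mm=0.01)
    )
    assert r2.f_max_n == pytest.approx(r1.f_max_n / 2.0, rel=1e-8)


def test_global_equilibrium_at_converged_steps(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements), sy=10.0, nu=0.3)
    lc = LoadCase(top, bot, displacement_increment_mm=0.05, max_displacement_mm=0.3)
    res = solve_to_failure(mesh, mat, lc)
    # loaded-cap reaction balances fixed-plane reaction at the peak step
    assert res.reactions_fixed_at_peak == pytest.approx(-res.f_max_n, rel=1e-5)


def test_sum_internal_forces_is_zero(bar_mesh):
    mesh, _, _ = bar_mesh
    mat = _bar_materials(len(mesh.elements), nu=0.3)
    rng = np.random.default_rng(5)
    u = rng.normal(0, 1e-3, 3 * len(mesh.nodes))
    f = internal_forces(mesh, mat, u)
    total = f.reshape(-1, 3).sum(axis=0)
    assert np.allclose(total, 0.0, atol=1e-10 * np.abs(f).max())


def test_consistent_tangent_matches_finite_differences():
    rng = np.random.default_rng(3)
    n = 8
    lam = rng.uniform(500, 2000, n)
    mu = rng.uniform(300, 1500, n)
    sy = rng.uniform(1.0, 5.0, n)
    eps_p = np.zeros((n, 6))
    eps = rng.normal(0, 0.01, (n, 6))
    _, _, s_tr, q, pl = _radial_return(eps, eps_p, lam, mu, sy)
    assert pl.any()
    C = _tangent_C(lam, mu, sy, s_tr, q, pl, beta=0.0)
    h = 1e-7
    for j in range(6):
        ep, em = eps.copy(), eps.copy()
        ep[:, j] += h
        em[:, j] -= h
        sp_, *_ = _radial_return(ep, eps_p, lam, mu, sy)
        sm_, *_ = _radial_return(em, eps_p, lam, mu, sy)
        np.testing.assert_allclose(C[:, :, j], (sp_ - sm_) / (2 * h), rtol=1e-4, atol=1e-4)


def test_divergence_reports_error(bar_mesh):
    mesh, top, bot = bar_mesh
    mat = _bar_materials(len(mesh.elements), sy=10.0)
    lc = LoadCase(top, bot, displacement_increment_mm=0.5, max_displacement_mm=0.5)
    with pytest.raises(SolverError, match="diverged"):
        solve_to_failure(mesh, mat, lc, max_iter=1)


def test_load_case_validation():
    with pytest.raises(ValueError):
        LoadCase(np.array([0, 1]), np.array([1, 2]))  # overlap
    with pytest.raises(ValueError):
        LoadCase(np.array([0]), np.array([], dtype=int))
    with pytest.raises(ValueError):
        LoadCase(np.array([0]), np.array([1]), load_direction=(0, 0, 0))
    with pytest.raises(ValueError):
        LoadCase(np.array([0]), np.array([1]), loaded_constraint="sideways")
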