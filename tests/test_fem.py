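"""Elasticity solver verification: patch tests, beam benchmark, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rcdlife.fem as fem
from rcdlife import (Material, MaterialSet, UnconstrainedModelError, assemble,
                     box_mesh, principal_stresses, reaction_sum,
                     recover_stress, solve, von_mises)
from rcdlife.geometry import triangle_areas


def surface_load(mesh, patch, traction):
    """Consistent nodal loads for a constant traction vector on a patch."""
    shape_int = fem._N_TRI3 if mesh.element_order == 1 else fem._N_TRI6
    f = np.zeros((mesh.num_nodes, 3))
    facets = mesh.patches[patch]
    areas = triangle_areas(mesh.points, facets)
    vals = areas[:, None, None] * shape_int[None, :, None] \
        * np.asarray(traction)[None, None, :]
    np.add.at(f, facets.ravel(), vals.reshape(-1, 3))
    return f


def rollers(mesh):
    """Symmetry rollers on the three coordinate planes through the origin."""
    pts = mesh.points
    return [(np.flatnonzero(np.abs(pts[:, 0]) < 1e-12), 0, 0.0),
            (np.flatnonzero(np.abs(pts[:, 1]) < 1e-12), 1, 0.0),
            (np.flatnonzero(np.abs(pts[:, 2]) < 1e-12), 2, 0.0)]


# ---------------------------------------------------------------------------
# element-level oracle: shape functions differentiated numerically

def _bary_coords(pts4, x):
    A = np.vstack([np.ones(4), pts4.T])
    return np.linalg.solve(A, np.concatenate([[1.0], x]))


def _shape_values(pts4, x, order):
    L = _bary_coords(pts4, x)
    if order == 1:
        return L
    from rcdlife.geometry import TET10_EDGES
    N = [L[i] * (2 * L[i] - 1) for i in range(4)]
    N += [4 * L[a] * L[b] for a, b in TET10_EDGES]
    return np.asarray(N)


def brute_force_stiffness(pts4, D, order):
    """Quadrature + central-difference gradients; independent of the
    analytic inverse-Jacobian path used by the implementation."""
    npe = 4 if order == 1 else 10
    vol = abs(np.linalg.det(pts4[1:] - pts4[0]) / 6.0)
    K = np.zeros((3 * npe, 3 * npe))
    h = 1e-5
    for g, w in zip(fem.TET_GAUSS, fem.TET_GAUSS_W):
        x = g @ pts4
        grad = np.zeros((npe, 3))
        for c in range(3):
            dx = np.zeros(3)
            dx[c] = h
            grad[:, c] = (_shape_values(pts4, x + dx, order)
                          - _shape_values(pts4, x - dx, order)) / (2 * h)
        B = np.zeros((6, 3 * npe))
        for a in range(npe):
            gx, gy, gz = grad[a]
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a], B[3, 3 * a + 1] = gy, gx
            B[4, 3 * a + 1], B[4, 3 * a + 2] = gz, gy
            B[5, 3 * a], B[5, 3 * a + 2] = gz, gx
        K += w * vol * B.T @ D @ B
    return K


@pytest.mark.parametrize("order", [1, 2])
def test_single_element_stiffness_matches_brute_force(order):
    """Analytic assembly equals independent numerical integration to 1e-9."""
    rng = np.random.default_rng(7)
    D = fem.elasticity_matrix(E=1.0, nu=0.3)
    for _ in range(5):
        pts = rng.uniform(0.0, 1.0, (4, 3))
        if np.linalg.det(pts[1:] - pts[0]) < 0.05:  # avoid slivers
            continue
        K = fem.element_stiffness(pts, D, order)
        K_ref = brute_force_stiffness(pts, D, order)
        assert np.abs(K - K_ref).max() < 1e-9
        assert np.abs(K - K.T).max() < 1e-12


@pytest.mark.parametrize("order", [1, 2])
def test_uniaxial_patch_test_exact(order):
    """Uniform traction on a unit cube reproduces constant stress exactly."""
    mesh = box_mesh((1, 1, 1), (3, 3, 3), element_order=order)
    mats = MaterialSet({"base": Material(E=1000.0)})
    system = assemble(mesh, mats, dirichlet=rollers(mesh))
    sigma = 5.0
    u = solve(system, surface_load(mesh, "zmax", (0, 0, sigma)))
    stress = recover_stress(u, mesh, mats)
    assert np.abs(stress.nodal[:, 2] - sigma).max() < 1e-9
    assert np.abs(np.delete(stress.nodal, 2, axis=1)).max() < 1e-9
    assert np.abs(stress.element[:, 2] - sigma).max() < 1e-9


def test_hydrostatic_compression_deviatoric_free():
    mesh = box_mesh((1, 1, 1), (2, 2, 2), element_order=2)
    mats = MaterialSet({"base": Material(E=1000.0)})
    system = assemble(mesh, mats, dirichlet=rollers(mesh))
    p = 2.0
    f = (surface_load(mesh, "zmax", (0, 0, -p))
         + surface_load(mesh, "xmax", (-p, 0, 0))
         + surface_load(mesh, "ymax", (0, -p, 0)))
    u = solve(system, f)
    stress = recover_stress(u, mesh, mats)
    assert np.abs(von_mises(stress.nodal)).max() < 1e-9
    assert np.abs(stress.nodal[:, :3] + p).max() < 1e-9


def test_cantilever_tip_deflection_matches_beam_theory():
    """Quadratic tets reproduce FL^3/3EI within 2% (nu = 0, slender bar)."""
    L, b, h = 20.0, 2.0, 2.0
    E, F = 1000.0, 1.0
    mesh = box_mesh((L, b, h), (20, 4, 4), element_order=2)
    mats = MaterialSet({"base": Material(E=E, nu=0.0)})
    clamp = np.flatnonzero(np.abs(mesh.points[:, 0]) < 1e-12)
    dirichlet = [(clamp, c, 0.0) for c in range(3)]
    system = assemble(mesh, mats, dirichlet=dirichlet)
    u = solve(system, surface_load(mesh, "xmax", (0, 0, -F / (b * h))))
    tip = np.flatnonzero((np.abs(mesh.points[:, 0] - L) < 1e-9))
    deflection = -u[tip, 2].mean()
    expected = F * L ** 3 / (3 * E * (b * h ** 3 / 12.0))
    assert deflection == pytest.approx(expected, rel=0.02)


def test_rigid_block_on_winkler_foundation():
    """Uniform pressure p over stiffness k settles the base by p / k."""
    mesh = box_mesh((2, 2, 1), (3, 3, 2), element_order=2)
    mats = MaterialSet({"base": Material(E=1000.0)})
    k, p = 7.0, 3.5
    pts = mesh.points
    lateral = [(np.arange(mesh.num_nodes), 0, 0.0),
               (np.arange(mesh.num_nodes), 1, 0.0)]
    system = assemble(mesh, mats, foundation={"zmin": (k, 0.0)},
                      dirichlet=lateral)
    u = solve(system, surface_load(mesh, "zmax", (0, 0, -p)))
    bottom = np.unique(mesh.patches["zmin"][:, :3])
    assert np.abs(u[bottom, 2] + p / k).max() < 1e-9


def test_zero_load_zero_displacement_and_linearity(default_mesh, materials):
    from rcdlife import FoundationSpec, LoadCase, build_load_case
    system = assemble(default_mesh, materials, FoundationSpec())
    u0 = solve(system, np.zeros((default_mesh.num_nodes, 3)))
    assert np.abs(u0).max() == 0.0
    f = build_load_case(LoadCase(("III",), "symmetric", 50.0), default_mesh)
    u1 = solve(system, f)
    u2 = solve(system, 2.0 * f)
    assert np.allclose(u2, 2.0 * u1, rtol=1e-10, atol=1e-14)
    r1, r2 = reaction_sum(u1, system), reaction_sum(u2, system)
    assert np.allclose(r2, 2.0 * r1, rtol=1e-9, atol=1e-12)


def test_unconstrained_model_raises():
    mesh = box_mesh((1, 1, 1), (2, 2, 2))
    with pytest.raises(UnconstrainedModelError, match="unconstrained"):
        assemble(mesh, MaterialSet({"base": Material(E=10.0)}))


def test_mesh_refinement_converges():
    """Probe deflection differences shrink under uniform refinement."""
    E, p = 1000.0, 1.0
    probes = []
    for n in (2, 4, 8):
        mesh = box_mesh((4.0, 1.0, 1.0), (2 * n, n, n), element_order=1)
        mats = MaterialSet({"base": Material(E=E)})
        clamp = np.flatnonzero(np.abs(mesh.points[:, 0]) < 1e-12)
        system = assemble(mesh, mats,
                          dirichlet=[(clamp, c, 0.0) for c in range(3)])
        u = solve(system, surface_load(mesh, "xmax", (0, 0, -p)))
        tip = np.flatnonzero(np.abs(mesh.points[:, 0] - 4.0) < 1e-9)
        probes.append(u[tip, 2].mean())
    d1 = abs(probes[1] - probes[0])
    d2 = abs(probes[2] - probes[1])
    assert d2 < d1  # Cauchy-converging probe sequence


class TestStressInvariants:
    def test_von_mises_closed_forms(self):
        assert von_mises(np.array([7.0, 0, 0, 0, 0, 0])) == pytest.approx(7.0)
        assert von_mises(np.array([-3.0, -3, -3, 0, 0, 0])) == pytest.approx(0.0)
        tau = 2.5
        assert von_mises(np.array([0, 0, 0, tau, 0, 0])) \
            == pytest.approx(np.sqrt(3) * tau)

    def test_principal_closed_forms(self):
        assert np.allclose(principal_stresses(np.array([1.0, 5.0, -2.0,
                                                        0, 0, 0])),
                           [5.0, 1.0, -2.0])
        tau = 4.0
        assert np.allclose(principal_stresses(np.array([0, 0, 0, tau, 0, 0])),
                           [tau, 0.0, -tau], atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_principal_matches_generic_eigensolver(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=6)
        mat = np.array([[v[0], v[3], v[5]],
                        [v[3], v[1], v[4]],
                        [v[5], v[4], v[2]]])
        expected = np.sort(np.linalg.eigvals(mat).real)[::-1]
        assert np.allclose(principal_stresses(v), expected, atol=1e-9)
        s = principal_stresses(v)
        assert s[0] >= s[1] >= s[2]


def test_single_element_stress_recovery_oracle():
    """Stress of a random displacement field on one element matches a
    hand-assembled B-matrix product."""
    rng = np.random.default_rng(11)
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    from rcdlife.geometry import LabeledMesh
    mesh = LabeledMesh(points=pts,
                       elements=np.array([[0, 1, 2, 3]]),
                       element_labels=np.array(["base"]),
                       patches={}, element_order=1)
    mats = MaterialSet({"base": Material(E=200.0, nu=0.25)})
    u = rng.normal(size=(4, 3))
    stress = recover_stress(u, mesh, mats)
    # independent: constant B from barycentric gradients of the unit tet
    grads = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    eps = np.zeros(6)
    eps[:3] = np.einsum("ai,ai->i", grads, u)
    eps[3] = grads[:, 1] @ u[:, 0] + grads[:, 0] @ u[:, 1]
    eps[4] = grads[:, 2] @ u[:, 1] + grads[:, 1] @ u[:, 2]
    eps[5] = grads[:, 2] @ u[:, 0] + grads[:, 0] @ u[:, 2]
    expected = fem.elasticity_matrix(200.0, 0.25) @ eps
    assert np.allclose(stress.element[0], expected, atol=1e-9)
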