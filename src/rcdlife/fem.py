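"""Small-strain isotropic linear elasticity on labeled tetrahedral meshes.

Supports 4-node (constant-strain) and 10-node (quadratic) tetrahedra, Robin
elastic-foundation boundary terms on named surface patches (the Winkler
mucosa model), optional Dirichlet constraints for verification problems,
direct sparse solution, and stress recovery with nodal averaging.

Unit system: mm / N / MPa.  Stress tensors use Voigt order
(xx, yy, zz, xy, yz, zx) with engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LabeledMesh, TET10_EDGES, triangle_areas, triangle_normals

__all__ = [
    "Material",
    "MaterialSet",
    "LinearSystem",
    "StressField",
    "UnconstrainedModelError",
    "assemble",
    "assemble_stiffness",
    "assemble_foundation",
    "solve",
    "recover_stress",
    "von_mises",
    "principal_stresses",
    "reaction_sum",
    "element_stiffness",
    "elasticity_matrix",
]

VOIGT_IDX = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))


class UnconstrainedModelError(RuntimeError):
    """The model has no foundation patches and no Dirichlet constraints."""


@dataclass(frozen=True)
class Material:
    """Isotropic elastic constants (MPa) plus carried density (kg/m^3)."""

    E: float
    nu: float = 0.3
    density: float = 1000.0
    sigma_ucs: float = 60.0  # ultimate compressive strength, MPa

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be > 0, got {self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")


@dataclass(frozen=True)
class MaterialSet:
    """Per-label materials; defaults are denture-base and tooth acrylics
    (E = 1000 / 2000 MPa, nu = 0.3, rho = 1000 kg/m^3)."""

    materials: Mapping[str, Material] = field(default_factory=lambda: {
        "base": Material(E=1000.0),
        "tooth": Material(E=2000.0),
    })

    def __getitem__(self, label: str) -> Material:
        try:
            return self.materials[label]
        except KeyError:
            raise KeyError(f"no material defined for element label {label!r}")


def elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt notation (engineering shears)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


# ---------------------------------------------------------------------------
# shape functions

# Keast 4-point rule, exact to degree 2, barycentric coordinates.
_A, _B = 0.5854101966249685, 0.1381966011250105
TET_GAUSS = np.array([
    [_A, _B, _B, _B],
    [_B, _A, _B, _B],
    [_B, _B, _A, _B],
    [_B, _B, _B, _A],
])
TET_GAUSS_W = np.full(4, 0.25)


def tet10_shape(bary: np.ndarray) -> np.ndarray:
    """Tet10 shape values at barycentric points (..., 4) -> (..., 10)."""
    L = np.asarray(bary)
    N = np.empty(L.shape[:-1] + (10,))
    for i in range(4):
        N[..., i] = L[..., i] * (2 * L[..., i] - 1)
    for e, (a, b) in enumerate(TET10_EDGES):
        N[..., 4 + e] = 4 * L[..., a] * L[..., b]
    return N


def tet10_shape_dL(bary: np.ndarray) -> np.ndarray:
    """d(shape)/d(barycentric) at points (..., 4) -> (..., 10, 4)."""
    L = np.asarray(bary)
    dN = np.zeros(L.shape[:-1] + (10, 4))
    for i in range(4):
        dN[..., i, i] = 4 * L[..., i] - 1
    for e, (a, b) in enumerate(TET10_EDGES):
        dN[..., 4 + e, a] = 4 * L[..., b]
        dN[..., 4 + e, b] = 4 * L[..., a]
    return dN


def _bary_gradients(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric-coordinate gradients for tets (m, 4, 3) -> (m, 4, 3), vols."""
    J = pts[:, 1:] - pts[:, :1]  # (m, 3, 3), rows are edge vectors
    det = np.linalg.det(J)
    vols = det / 6.0
    Jinv = np.linalg.inv(J)  # d(xi)/d(x), xi = (L1, L2, L3)
    gL = np.empty((len(pts), 4, 3))
    gL[:, 1:] = np.transpose(Jinv, (0, 2, 1))
    gL[:, 0] = -gL[:, 1:].sum(axis=1)
    return gL, vols


def _b_matrix(gradN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from shape gradients (m, n, 3) -> (m, 6, 3n)."""
    m, n, _ = gradN.shape
    B = np.zeros((m, 6, 3 * n))
    gx, gy, gz = gradN[..., 0], gradN[..., 1], gradN[..., 2]
    cols = 3 * np.arange(n)
    B[:, 0, cols + 0] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols + 0] = gy
    B[:, 3, cols + 1] = gx
    B[:, 4, cols + 1] = gz
    B[:, 4, cols + 2] = gy
    B[:, 5, cols + 0] = gz
    B[:, 5, cols + 2] = gx
    return B


def _element_gradients(pts: np.ndarray, order: int):
    """Shape-function gradients per element.

    Returns (gradN, vols, weights): gradN has shape (g, m, n, 3) over g
    integration points with weights summing to 1 (volume fractions).
    """
    gL, vols = _bary_gradients(pts[:, :4])
    if order == 1:
        # constant-strain tet: shape gradients equal barycentric gradients
        return gL[None], vols, np.array([1.0])
    dN = tet10_shape_dL(TET_GAUSS)  # (4, 10, 4)
    gradN = np.einsum("gna,mac->gmnc", dN, gL)
    return gradN, vols, TET_GAUSS_W


def element_stiffness(pts: np.ndarray, D: np.ndarray, order: int = 1) -> np.ndarray:
    """Stiffness matrix of a single (straight-sided) tet element."""
    pts = np.asarray(pts, dtype=float)[None, :4, :]
    gradN, vols, w = _element_gradients(pts, order)
    n = 4 if order == 1 else 10
    K = np.zeros((3 * n, 3 * n))
    for g in range(len(w)):
        B = _b_matrix(gradN[g])[0]
        K += w[g] * abs(vols[0]) * B.T @ D @ B
    return K


# ---------------------------------------------------------------------------
# assembly

def assemble_stiffness(mesh: LabeledMesh, materials: MaterialSet) -> sp.csr_array:
    """Global elastic stiffness (3n x 3n, SPD up to rigid-body modes)."""
    n_nodes = mesh.num_nodes
    order = mesh.element_order
    npe = 4 if order == 1 else 10
    pts = mesh.points[mesh.corner_elements()]
    gradN, vols, w = _element_gradients(pts, order)

    labels = np.asarray(mesh.element_labels)
    Ke = np.zeros((mesh.num_elements, 3 * npe, 3 * npe))
    for label in np.unique(labels):
        mat = materials[label]
        D = elasticity_matrix(mat.E, mat.nu)
        sel = labels == label
        for g in range(len(w)):
            B = _b_matrix(gradN[g][sel])
            Ke[sel] += (w[g] * np.abs(vols[sel]))[:, None, None] * np.einsum(
                "mji,jk,mkl->mil", B, D, B, optimize=True)

    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(
        mesh.num_elements, 3 * npe)
    rows = np.repeat(dofs, 3 * npe, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * npe)).ravel()
    K = sp.coo_array((Ke.ravel(), (rows, cols)),
                     shape=(3 * n_nodes, 3 * n_nodes)).tocsr()
    return K


# consistent surface shape-integral matrices for straight facets (unit area)
_M_TRI3 = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
_M_TRI6 = np.array([
    [6, -1, -1, 0, -4, 0],
    [-1, 6, -1, 0, 0, -4],
    [-1, -1, 6, -4, 0, 0],
    [0, 0, -4, 32, 16, 16],
    [-4, 0, 0, 16, 32, 16],
    [0, -4, 0, 16, 16, 32],
]) / 180.0
_N_TRI3 = np.full(3, 1.0 / 3.0)
_N_TRI6 = np.array([0.0, 0.0, 0.0, 1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0])


def _foundation_table(mesh: LabeledMesh, foundation) -> dict[str, tuple]:
    """Normalize a foundation argument to {patch: (k_n, k_t)}.

    Accepts a mapping patch -> (k_n, k_t) (scalars or per-facet arrays) or
    any object exposing ``stiffness_table(mesh)`` with that signature.
    """
    if foundation is None:
        return {}
    if hasattr(foundation, "stiffness_table"):
        return dict(foundation.stiffness_table(mesh))
    return dict(foundation)


def assemble_foundation(mesh: LabeledMesh, foundation) -> sp.csr_array:
    """Robin boundary stiffness: k_n normal + k_t tangential springs per patch."""
    n_dof = 3 * mesh.num_nodes
    table = _foundation_table(mesh, foundation)
    Mref = _M_TRI3 if mesh.element_order == 1 else _M_TRI6
    npf = Mref.shape[0]

    rows_all, cols_all, data_all = [], [], []
    for patch, (k_n, k_t) in table.items():
        facets = mesh.patch_facets(patch)
        if len(facets) == 0:
            continue
        areas = triangle_areas(mesh.points, facets)
        normals = triangle_normals(mesh.points, facets)
        k_n = np.broadcast_to(np.asarray(k_n, dtype=float), (len(facets),))
        k_t = np.broadcast_to(np.asarray(k_t, dtype=float), (len(facets),))
        nn = np.einsum("fi,fj->fij", normals, normals)
        C = (k_n[:, None, None] * nn
             + k_t[:, None, None] * (np.eye(3)[None] - nn))  # (f, 3, 3)
        Kf = np.einsum("ab,fij->faibj", Mref, C * areas[:, None, None])
        Kf = Kf.reshape(len(facets), 3 * npf, 3 * npf)
        dofs = (3 * facets[:, :, None] + np.arange(3)).reshape(len(facets), 3 * npf)
        rows_all.append(np.repeat(dofs, 3 * npf, axis=1).ravel())
        cols_all.append(np.tile(dofs, (1, 3 * npf)).ravel())
        data_all.append(Kf.ravel())
    if not rows_all:
        return sp.csr_array((n_dof, n_dof))
    return sp.coo_array(
        (np.concatenate(data_all), (np.concatenate(rows_all),
                                    np.concatenate(cols_all))),
        shape=(n_dof, n_dof)).tocsr()


@dataclass
class LinearSystem:
    """Assembled elastic + foundation system with optional Dirichlet data."""

    K: sp.csr_array
    K_foundation: sp.csr_array
    mesh: LabeledMesh
    fixed_dofs: np.ndarray
    fixed_values: np.ndarray


def assemble(mesh: LabeledMesh, materials: MaterialSet | None = None,
             foundation=None, dirichlet=None) -> LinearSystem:
    """Assemble the linear system.

    ``foundation`` is a FoundationSpec or a {patch: (k_n, k_t)} mapping;
    ``dirichlet`` an iterable of (node_ids, component, value) triples used by
    the verification problems.  Raises :class:`UnconstrainedModelError` when
    neither is present (pure Neumann problem would be singular).
    """
    materials = materials or MaterialSet()
    K_el = assemble_stiffness(mesh, materials)
    K_f = assemble_foundation(mesh, foundation)

    fixed_dofs: list[int] = []
    fixed_vals: list[float] = []
    for node_ids, component, value in (dirichlet or []):
        for node in np.atleast_1d(node_ids):
            fixed_dofs.append(3 * int(node) + component)
            fixed_vals.append(float(value))

    if K_f.nnz == 0 and not fixed_dofs:
        raise UnconstrainedModelError(
            "unconstrained model: no foundation stiffness and no Dirichlet "
            "constraints; rigid-body motion is unresolved")
    return LinearSystem(K=(K_el + K_f).tocsr(), K_foundation=K_f, mesh=mesh,
                        fixed_dofs=np.asarray(fixed_dofs, dtype=np.int64),
                        fixed_values=np.asarray(fixed_vals))


def solve(system: LinearSystem, loads: np.ndarray,
          rtol: float = 1e-8) -> np.ndarray:
    """Solve for nodal displacements (n, 3) given nodal loads (n, 3).

    Direct sparse LU with fixed column ordering (deterministic); the
    relative residual is verified to ``rtol``.
    """
    n_dof = system.K.shape[0]
    f = np.asarray(loads, dtype=float).reshape(n_dof)
    u = np.zeros(n_dof)

    free = np.ones(n_dof, dtype=bool)
    if len(system.fixed_dofs):
        free[system.fixed_dofs] = False
        u[system.fixed_dofs] = system.fixed_values

    K = system.K.tocsc()
    if len(system.fixed_dofs):
        f_eff = f - K @ u
        Kff = K[free][:, free].tocsc()
        rhs = f_eff[free]
    else:
        Kff = K
        rhs = f
    try:
        lu = spla.splu(sp.csc_matrix(Kff), permc_spec="COLAMD")
    except RuntimeError as exc:  # singular factorization
        raise UnconstrainedModelError(f"factorization failed: {exc}") from exc
    u[free] = lu.solve(rhs)

    residual = np.linalg.norm(K @ u - f) if not len(system.fixed_dofs) else \
        np.linalg.norm(Kff @ u[free] - rhs)
    scale = max(np.linalg.norm(rhs if len(system.fixed_dofs) else f), 1e-30)
    if np.linalg.norm(f) > 0 and residual / scale > rtol:
        raise RuntimeError(
            f"solver residual {residual / scale:.2e} exceeds tolerance {rtol:.0e}")
    return u.reshape(-1, 3)


# ---------------------------------------------------------------------------
# stress recovery

@dataclass
class StressField:
    """Per-node and per-element stress tensors in Voigt order (MPa)."""

    nodal: np.ndarray    # (n, 6)
    element: np.ndarray  # (m, 6)

    @property
    def von_mises_nodal(self) -> np.ndarray:
        return von_mises(self.nodal)

    @property
    def von_mises_element(self) -> np.ndarray:
        return von_mises(self.element)

    @property
    def principal_nodal(self) -> np.ndarray:
        return principal_stresses(self.nodal)


def recover_stress(displacements: np.ndarray, mesh: LabeledMesh,
                   materials: MaterialSet | None = None) -> StressField:
    """Recover stresses from displacements.

    Element stresses are evaluated at the element nodes (constant for tet4,
    linear within straight tet10s) and averaged to mesh nodes with
    element-volume weights; the per-element value is the nodal mean.
    """
    materials = materials or MaterialSet()
    order = mesh.element_order
    npe = 4 if order == 1 else 10
    pts = mesh.points[mesh.corner_elements()]
    gL, vols = _bary_gradients(pts)
    vols = np.abs(vols)

    if order == 1:
        gradN = gL[None]  # evaluate once (constant)
        eval_pts = 1
    else:
        corners = np.eye(4)
        mids = np.zeros((6, 4))
        for e, (a, b) in enumerate(TET10_EDGES):
            mids[e, a] = mids[e, b] = 0.5
        bary = np.vstack([corners, mids])  # (10, 4) nodal barycentric coords
        dN = tet10_shape_dL(bary)  # (10, 10, 4)
        gradN = np.einsum("pna,mac->pmnc", dN, gL)  # (10, m, 10, 3)
        eval_pts = 10

    u_elem = displacements.reshape(-1, 3)[mesh.elements]  # (m, npe, 3)
    u_flat = u_elem.reshape(mesh.num_elements, 3 * npe)

    labels = np.asarray(mesh.element_labels)
    sig_at_nodes = np.zeros((eval_pts, mesh.num_elements, 6))
    for label in np.unique(labels):
        mat = materials[label]
        D = elasticity_matrix(mat.E, mat.nu)
        sel = labels == label
        for p in range(eval_pts):
            B = _b_matrix(gradN[p][sel])  # (ms, 6, 3npe)
            eps = np.einsum("mij,mj->mi", B, u_flat[sel])
            sig_at_nodes[p, sel] = eps @ D.T

    element = sig_at_nodes.mean(axis=0)

    nodal = np.zeros((mesh.num_nodes, 6))
    weight = np.zeros(mesh.num_nodes)
    if order == 1:
        conn = mesh.elements
        for local in range(4):
            np.add.at(nodal, conn[:, local], sig_at_nodes[0] * vols[:, None])
            np.add.at(weight, conn[:, local], vols)
    else:
        for local in range(10):
            np.add.at(nodal, mesh.elements[:, local],
                      sig_at_nodes[local] * vols[:, None])
            np.add.at(weight, mesh.elements[:, local], vols)
    nodal /= np.maximum(weight, 1e-300)[:, None]
    return StressField(nodal=nodal, element=element)


def von_mises(tensor: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress of Voigt tensors (..., 6)."""
    t = np.asarray(tensor)
    sxx, syy, szz, sxy, syz, szx = (t[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy ** 2 + syz ** 2 + szx ** 2))


def principal_stresses(tensor: np.ndarray) -> np.ndarray:
    """Principal stresses sorted descending, sigma1 >= sigma2 >= sigma3."""
    t = np.asarray(tensor, dtype=float)
    mats = np.zeros(t.shape[:-1] + (3, 3))
    mats[..., 0, 0] = t[..., 0]
    mats[..., 1, 1] = t[..., 1]
    mats[..., 2, 2] = t[..., 2]
    mats[..., 0, 1] = mats[..., 1, 0] = t[..., 3]
    mats[..., 1, 2] = mats[..., 2, 1] = t[..., 4]
    mats[..., 0, 2] = mats[..., 2, 0] = t[..., 5]
    vals = np.linalg.eigvalsh(mats)  # ascending
    return vals[..., ::-1]


def reaction_sum(displacements: np.ndarray, system: LinearSystem) -> np.ndarray:
    """Total force (N) transmitted through the elastic-foundation patches.

    By global equilibrium this balances the applied external load; the
    per-component agreement is the discretization/solver error check.
    """
    r = system.K_foundation @ np.asarray(displacements).reshape(-1)
    return r.reshape(-1, 3).sum(axis=0)
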