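"""Mucosal foundation model, occlusal load cases and balance calibration.

The denture base rests on mucosa modelled as a Winkler foundation: each
intaglio segment carries a normal stiffness (MPa/mm), the border seal a
normal stiffness, and the posterior retention zones tangential
(displacement-opposing, friction-like) stiffness.  Occlusal loading applies
a vertical pressure P_k = F_k / S0_k on selected tooth blocks, where S0 is
the horizontal projection of the (possibly curved) occlusal patch, so the
integrated vertical force always equals the prescribed total F0.

Because the denture has no kinematic fixation, an unbalanced foundation lets
it pitch (anteroposterior tilt) or roll (lateral tilt) as a quasi-rigid
body.  ``calibrate_foundation`` adjusts the per-segment stiffnesses until
the uniform all-teeth load produces vanishing pitch/roll and a vertical
displacement range within the prescribed band (0.02 mm by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from . import fem
from .geometry import (BLOCK_NAMES, SIDES, LabeledMesh, triangle_areas,
                       triangle_normals)

__all__ = [
    "FoundationSpec",
    "LoadCase",
    "RigidMotionMetrics",
    "CalibrationResult",
    "projected_area",
    "block_pressure",
    "build_load_case",
    "rigid_motion_metrics",
    "calibrate_foundation",
    "solve_case",
]

INTAGLIO_PATCHES = tuple(f"intaglio_seg_{q}_{s}" for q in (1, 2, 3, 4) for s in SIDES)


@dataclass(frozen=True)
class FoundationSpec:
    """Per-patch foundation stiffness laws (MPa/mm).

    ``segment_normal`` maps intaglio segment patches to normal stiffness;
    ``compliance_slope`` is the c1 of the linear compliance law
    c(u_n) = 1/k0 + c1 * u_n (u_n = outward-normal displacement, i.e.
    penetration into the tissue is positive; tissue stiffening under
    compression corresponds to c1 < 0).  The default c1 = 0 keeps the solve
    linear.
    """

    segment_normal: Mapping[str, float] = field(
        default_factory=lambda: {p: 10.0 for p in INTAGLIO_PATCHES})
    seal_normal: float = 10.0
    retention_tangential: float = 5.0
    compliance_slope: float = 0.0

    def __post_init__(self):
        ks = list(self.segment_normal.values()) + [self.seal_normal,
                                                   self.retention_tangential]
        if any(k < 0 for k in ks):
            raise ValueError("foundation stiffnesses must be >= 0")
        if not any(k > 0 for k in ks):
            raise ValueError("at least one foundation patch must have k > 0")

    def stiffness_table(self, mesh: LabeledMesh) -> dict[str, tuple]:
        """{patch: (k_n, k_t)} restricted to patches present in the mesh."""
        table: dict[str, tuple] = {}
        for patch, k in self.segment_normal.items():
            if patch in mesh.patches and len(mesh.patches[patch]):
                table[patch] = (k, 0.0)
        if "border_seal" in mesh.patches and len(mesh.patches["border_seal"]):
            table["border_seal"] = (self.seal_normal, 0.0)
        for side in SIDES:
            name = f"retention_{side}"
            if name in mesh.patches and len(mesh.patches[name]):
                table[name] = (0.0, self.retention_tangential)
        return table

    def scaled(self, factor: float) -> "FoundationSpec":
        return replace(
            self,
            segment_normal={p: k * factor for p, k in self.segment_normal.items()},
            seal_normal=self.seal_normal * factor,
            retention_tangential=self.retention_tangential * factor)

    def with_multipliers(self, mult: Mapping[int, float]) -> "FoundationSpec":
        """Scale segment stiffness per segment index (1..4), both sides."""
        seg = {}
        for patch, k in self.segment_normal.items():
            q = int(patch.split("_")[2])
            seg[patch] = k * mult.get(q, 1.0)
        return replace(self, segment_normal=seg)


@dataclass(frozen=True)
class LoadCase:
    """Occlusal load: which blocks, which side(s), total force F0 (N).

    ``sidedness``: "symmetric" loads each selected block on both sides at
    F0/2 per side (total F0 per block set); "asymmetric-left/right" applies
    the full F0 on one side; "uniform-all" spreads F0 over all eight blocks
    in proportion to projected area (uniform pressure).
    """

    blocks: tuple[str, ...] = ("I",)
    sidedness: str = "symmetric"
    total_force: float = 100.0

    _SIDEDNESS = ("symmetric", "asymmetric-left", "asymmetric-right", "uniform-all")

    def __post_init__(self):
        if self.total_force <= 0:
            raise ValueError("total_force must be > 0")
        if self.sidedness not in self._SIDEDNESS:
            raise ValueError(f"sidedness must be one of {self._SIDEDNESS}")
        for b in self.blocks:
            if b not in BLOCK_NAMES:
                raise ValueError(f"unknown block {b!r}")

    @property
    def name(self) -> str:
        return f"{'+'.join(self.blocks)}:{self.sidedness}"


@dataclass
class RigidMotionMetrics:
    """Best-fit rigid motion of the denture base (degrees / mm)."""

    roll: float      # rotation about the anteroposterior (y) axis
    pitch: float     # rotation about the transverse (x) axis
    yaw: float       # rotation about the vertical (z) axis
    translation: np.ndarray
    vertical_range: float  # max - min vertical displacement over base nodes
    residual: float

    def as_dict(self) -> dict:
        return {"roll_deg": self.roll, "pitch_deg": self.pitch,
                "yaw_deg": self.yaw,
                "translation_mm": [float(t) for t in self.translation],
                "vertical_range_mm": self.vertical_range,
                "fit_residual_mm": self.residual}


def projected_area(mesh: LabeledMesh, patch: str) -> float:
    """Horizontal projection S0 = sum(area * |n_z|) of a patch (mm^2)."""
    facets = mesh.patch_facets(patch)
    if len(facets) == 0:
        raise ValueError(f"patch {patch!r} is empty")
    p = mesh.points[facets[:, :3]]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    # area * |n_z| = |cross_z| / 2, robust for degenerate facets
    return float(0.5 * np.abs(cross[:, 2]).sum())


def block_pressure(total_force: float, area: float) -> float:
    """Occlusal pressure P_k = F0 / S_k (MPa for N and mm^2)."""
    if area <= 0:
        raise ValueError(f"block area must be > 0, got {area}")
    return total_force / area


def _target_patches(case: LoadCase, mesh: LabeledMesh) -> dict[str, float]:
    """Map occlusal patch -> force carried by that patch (N)."""
    if case.sidedness == "uniform-all":
        patches = [f"occlusal_{b}_{s}" for b in BLOCK_NAMES for s in SIDES]
        areas = {p: projected_area(mesh, p) for p in patches}
        total = sum(areas.values())
        return {p: case.total_force * a / total for p, a in areas.items()}
    per_block = case.total_force / len(case.blocks)
    out: dict[str, float] = {}
    for b in case.blocks:
        if case.sidedness == "symmetric":
            for s in SIDES:
                out[f"occlusal_{b}_{s}"] = per_block / 2.0
        else:
            side = case.sidedness.split("-")[1]
            out[f"occlusal_{b}_{side}"] = per_block
    return out


def build_load_case(case: LoadCase, mesh: LabeledMesh) -> np.ndarray:
    """Consistent nodal load vector (n, 3) for an occlusal load case.

    A vertical (downward) traction of magnitude P * |n_z| is integrated over
    each selected occlusal patch with P = F_patch / S0_patch, so the
    integrated vertical force equals the patch force exactly regardless of
    occlusal-surface curvature.
    """
    f = np.zeros((mesh.num_nodes, 3))
    shape_int = fem._N_TRI3 if mesh.element_order == 1 else fem._N_TRI6
    for patch, force in _target_patches(case, mesh).items():
        facets = mesh.patch_facets(patch)
        if len(facets) == 0:
            raise ValueError(f"load case targets empty patch {patch!r}")
        s0 = projected_area(mesh, patch)
        pressure = block_pressure(force, s0)
        if not 0.1 <= pressure <= 20.0:
            warnings.warn(
                f"pressure {pressure:.3g} MPa on {patch} is outside the "
                "plausible 0.1-20 MPa band", stacklevel=2)
        areas = triangle_areas(mesh.points, facets)
        nz = np.abs(triangle_normals(mesh.points, facets)[:, 2])
        fz = -pressure * (areas * nz)[:, None] * shape_int[None, :]  # (f, npf)
        np.add.at(f[:, 2], facets.ravel(), fz.ravel())
    return f


def rigid_motion_metrics(displacements: np.ndarray,
                         mesh: LabeledMesh) -> RigidMotionMetrics:
    """Least-squares rigid motion u ~ t + omega x r over denture-base nodes."""
    base_nodes = np.unique(
        mesh.elements[np.asarray(mesh.element_labels) == "base"])
    if len(base_nodes) == 0:
        base_nodes = np.arange(mesh.num_nodes)
    pts = mesh.points[base_nodes]
    u = np.asarray(displacements).reshape(-1, 3)[base_nodes]
    centre = pts.mean(axis=0)
    r = pts - centre

    n = len(base_nodes)
    A = np.zeros((3 * n, 6))
    A[0::3, 0] = A[1::3, 1] = A[2::3, 2] = 1.0
    # omega x r = [wy*rz - wz*ry, wz*rx - wx*rz, wx*ry - wy*rx]
    A[0::3, 4] = r[:, 2]
    A[0::3, 5] = -r[:, 1]
    A[1::3, 3] = -r[:, 2]
    A[1::3, 5] = r[:, 0]
    A[2::3, 3] = r[:, 1]
    A[2::3, 4] = -r[:, 0]
    sol, *_ = np.linalg.lstsq(A, u.ravel(), rcond=None)
    t, omega = sol[:3], sol[3:]
    residual = float(np.linalg.norm(A @ sol - u.ravel()) / math.sqrt(n))
    uz = u[:, 2]
    return RigidMotionMetrics(
        roll=math.degrees(omega[1]), pitch=math.degrees(omega[0]),
        yaw=math.degrees(omega[2]), translation=t,
        vertical_range=float(uz.max() - uz.min()), residual=residual)


# ---------------------------------------------------------------------------
# solving with the (optionally displacement-dependent) foundation

def solve_case(mesh: LabeledMesh, materials: fem.MaterialSet,
               foundation: FoundationSpec, loads: np.ndarray,
               max_iterations: int = 5, tol: float = 1e-8):
    """Solve a load case; secant fixed-point iteration when the compliance
    law is displacement dependent (compliance_slope != 0).

    Returns (displacements, system).
    """
    system = fem.assemble(mesh, materials, foundation)
    u = fem.solve(system, loads)
    if foundation.compliance_slope == 0.0:
        return u, system

    table0 = foundation.stiffness_table(mesh)
    for _ in range(max_iterations):
        table = dict(table0)
        for patch in INTAGLIO_PATCHES:
            if patch not in table:
                continue
            k0 = np.asarray(table0[patch][0], dtype=float)
            facets = mesh.patch_facets(patch)
            normals = triangle_normals(mesh.points, facets)
            u_f = u[facets[:, :3]].mean(axis=1)  # facet-average displacement
            u_n = np.einsum("fi,fi->f", u_f, normals)  # penetration > 0
            c = 1.0 / k0 + foundation.compliance_slope * u_n
            c = np.maximum(c, 0.05 / k0)  # keep stiffness positive, bounded
            table[patch] = (1.0 / c, 0.0)
        system = fem.LinearSystem(
            K=(fem.assemble_stiffness(mesh, materials)
               + fem.assemble_foundation(mesh, table)).tocsr(),
            K_foundation=fem.assemble_foundation(mesh, table),
            mesh=mesh, fixed_dofs=np.array([], dtype=np.int64),
            fixed_values=np.array([]))
        u_new = fem.solve(system, loads)
        if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), 1e-30):
            u = u_new
            break
        u = u_new
    return u, system


@dataclass
class CalibrationResult:
    spec: FoundationSpec
    before: RigidMotionMetrics
    after: RigidMotionMetrics
    multipliers: dict[int, float]
    global_scale: float

    def report(self) -> dict:
        return {"multipliers": {str(k): v for k, v in self.multipliers.items()},
                "global_scale": self.global_scale,
                "before": self.before.as_dict(),
                "after": self.after.as_dict()}


def calibrate_foundation(mesh: LabeledMesh,
                         materials: fem.MaterialSet | None = None,
                         initial: FoundationSpec | None = None,
                         total_force: float = 100.0,
                         angle_tol_deg: float = 0.01,
                         range_target: float = 0.02,
                         max_nfev: int = 60) -> CalibrationResult:
    """Balance the foundation under the uniform all-teeth load.

    Optimizes one stiffness multiplier per intaglio segment pair (4 values,
    left/right tied by symmetry, bounded to 1e-2..1e2 in log space) to null
    the pitch and roll angles, then scales the whole foundation up (doubling)
    if the vertical displacement range still exceeds ``range_target`` mm.
    Deterministic: fixed solver, fixed starting point.
    """
    materials = materials or fem.MaterialSet()
    initial = initial or FoundationSpec()
    case = LoadCase(blocks=BLOCK_NAMES, sidedness="uniform-all",
                    total_force=total_force)
    loads = build_load_case(case, mesh)
    K_el = fem.assemble_stiffness(mesh, materials)

    def metrics_for(spec: FoundationSpec) -> RigidMotionMetrics:
        K_f = fem.assemble_foundation(mesh, spec)
        system = fem.LinearSystem(K=(K_el + K_f).tocsr(), K_foundation=K_f,
                                  mesh=mesh,
                                  fixed_dofs=np.array([], dtype=np.int64),
                                  fixed_values=np.array([]))
        u = fem.solve(system, loads)
        return rigid_motion_metrics(u, mesh)

    before = metrics_for(initial)

    def residual(log10_mult: np.ndarray) -> np.ndarray:
        mult = {q + 1: 10.0 ** log10_mult[q] for q in range(4)}
        m = metrics_for(initial.with_multipliers(mult))
        return np.array([m.pitch, m.roll])

    fit = least_squares(residual, x0=np.zeros(4), bounds=(-2.0, 2.0),
                        diff_step=0.05, xtol=1e-12, ftol=1e-14, gtol=1e-14,
                        max_nfev=max_nfev)
    mult = {q + 1: float(10.0 ** fit.x[q]) for q in range(4)}
    spec = initial.with_multipliers(mult)
    after = metrics_for(spec)

    # uniform scaling reduces settlement, range and residual angles together
    scale = 1.0
    for _ in range(8):
        if (after.vertical_range <= range_target
                and abs(after.pitch) <= angle_tol_deg
                and abs(after.roll) <= angle_tol_deg):
            break
        scale *= 2.0
        spec = initial.with_multipliers(mult).scaled(scale)
        after = metrics_for(spec)

    if abs(after.pitch) > angle_tol_deg or abs(after.roll) > angle_tol_deg \
            or after.vertical_range > range_target:
        raise RuntimeError(
            "foundation calibration infeasible within stiffness bounds: "
            f"pitch={after.pitch:.4g} deg, roll={after.roll:.4g} deg, "
            f"range={after.vertical_range:.4g} mm")
    return CalibrationResult(spec=spec, before=before, after=after,
                             multipliers=mult, global_scale=scale)
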