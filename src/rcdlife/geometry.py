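"""Parametric mandibular denture-base geometry.

A removable complete denture (RCD) base is a horseshoe-shaped acrylic plate
that rests on the edentulous alveolar ridge.  This module generates a
mirror-symmetric parametric stand-in for a scanned denture: an elliptical
arch centerline swept with a flange-plus-ridge-saddle cross-section, four
prismatic tooth blocks per side (incisors I, canines II, premolars III,
molars IV) bonded conformally to the plate, V-notch technological cutouts on
the vestibular flange, a peripheral border-seal band, two posterior
retention zones, and four mucosal compliance segments per side on the
intaglio (tissue-facing) surface.

Meshes are 4- or 10-node tetrahedra produced from a structured hex grid, so
generation is deterministic and the midsagittal mirror symmetry holds by
construction.  All lengths are millimetres (mm-N-MPa unit system).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ArchParameters",
    "ArrangementSpec",
    "LabeledMesh",
    "generate_denture",
    "patch_area",
    "triangle_areas",
    "box_mesh",
    "BLOCK_NAMES",
    "SIDES",
]

BLOCK_NAMES = ("I", "II", "III", "IV")
SIDES = ("left", "right")

# Kuhn decomposition of a hexahedron (local vertex ids 0..7, bottom face
# 0-1-2-3 counter-clockwise, top 4-5-6-7) into six tetrahedra that all share
# the 0-6 diagonal.  Face diagonals of adjacent hexes in a structured grid
# coincide, so the decomposition is conforming.
_HEX_TO_TETS = np.array(
    [
        (0, 1, 2, 6),
        (0, 2, 3, 6),
        (0, 1, 6, 5),
        (0, 5, 6, 4),
        (0, 3, 7, 6),
        (0, 7, 4, 6),
    ],
    dtype=np.int64,
)

# Faces of a positively oriented tet (v0,v1,v2,v3) with outward normals.
_TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))

# Edge ordering for tet10 midside nodes (VTK convention).
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


class MeshingError(ValueError):
    """Raised when parameters produce a degenerate or infeasible mesh."""


@dataclass(frozen=True)
class ArchParameters:
    """Dimensions of the parametric denture base (mm).

    ``block_footprints`` are the target occlusal areas per side for blocks
    I..IV in mm^2; the defaults make single-block pressures at 100 N span
    roughly 1-10 MPa.  ``mesh_size`` is the target element edge length and
    ``element_order`` selects 4-node (1) or 10-node (2) tetrahedra.
    """

    arch_width: float = 50.0
    arch_depth: float = 45.0
    arch_sweep_deg: float = 200.0
    cross_width: float = 12.0
    base_thickness: float = 3.0
    ridge_height: float = 4.0
    flange_height: float = 5.0
    tooth_height: float = 8.0
    tooth_band_width: float = 8.0
    cutout_depth: float = 4.0
    cutout_width: float = 4.0
    support_band_width: float = 6.0
    block_footprints: tuple[float, float, float, float] = (60.0, 25.0, 50.0, 100.0)
    block_gap: float = 2.0
    midline_gap: float = 3.0
    seal_band_width: float = 2.0
    retention_ellipse_axes: tuple[float, float] = (9.0, 5.0)
    mesh_size: float = 2.0
    element_order: int = 2
    jitter: float = 0.0

    def validate(self) -> None:
        positive = (
            "arch_width",
            "arch_depth",
            "arch_sweep_deg",
            "cross_width",
            "base_thickness",
            "tooth_height",
            "tooth_band_width",
            "mesh_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise MeshingError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("ridge_height", "flange_height", "cutout_depth", "cutout_width",
                     "seal_band_width", "block_gap", "midline_gap", "jitter"):
            if getattr(self, name) < 0:
                raise MeshingError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.element_order not in (1, 2):
            raise MeshingError(f"element_order must be 1 or 2, got {self.element_order}")
        if self.tooth_band_width > self.cross_width:
            raise MeshingError("tooth_band_width exceeds cross_width")
        if self.seal_band_width >= self.cross_width / 2:
            raise MeshingError("seal_band_width must be smaller than cross_width/2")
        if self.support_band_width <= 0 or self.support_band_width > self.cross_width:
            raise MeshingError("support_band_width must be in (0, cross_width]")
        if self.cutout_depth >= self.base_thickness + self.ridge_height + self.flange_height:
            raise MeshingError("cutout_depth must be smaller than the flange wall height")
        if len(self.block_footprints) != 4 or any(a <= 0 for a in self.block_footprints):
            raise MeshingError("block_footprints must be four positive areas")


@dataclass(frozen=True)
class ArrangementSpec:
    """Tooth-arrangement variant: per-block displacement and inclination.

    ``displacement`` maps a block key to an in-plane vector
    (vestibular-oral, anteroposterior) in mm; positive first component moves
    the block vestibularly (outward), positive second component anteriorly.
    ``inclination`` maps a block key to a rotation (degrees) about the
    block's mesio-distal axis.  Keys are block names ("I".."IV", applied to
    both sides symmetrically) or side-qualified names such as "II_left".
    The empty spec reproduces the normal arrangement exactly.
    """

    displacement: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    inclination: Mapping[str, float] = field(default_factory=dict)
    max_displacement: float = 5.0
    max_inclination: float = 30.0

    def validate(self) -> None:
        for key, vec in self.displacement.items():
            self._check_key(key)
            if math.hypot(*vec) > self.max_displacement:
                raise MeshingError(
                    f"displacement for block {key} exceeds limit {self.max_displacement} mm")
        for key, ang in self.inclination.items():
            self._check_key(key)
            if abs(ang) > self.max_inclination:
                raise MeshingError(
                    f"inclination for block {key} exceeds limit {self.max_inclination} deg")

    @staticmethod
    def _check_key(key: str) -> None:
        parts = key.split("_")
        if parts[0] not in BLOCK_NAMES or (len(parts) == 2 and parts[1] not in SIDES) \
                or len(parts) > 2:
            raise MeshingError(f"unknown block key {key!r}")

    def applies_to(self, block: str, side: str) -> tuple[tuple[float, float], float]:
        disp = (0.0, 0.0)
        if block in self.displacement:
            disp = tuple(self.displacement[block])
        if f"{block}_{side}" in self.displacement:
            disp = tuple(self.displacement[f"{block}_{side}"])
        incl = self.inclination.get(block, 0.0)
        incl = self.inclination.get(f"{block}_{side}", incl)
        return disp, incl

    @property
    def is_zero(self) -> bool:
        return not self.displacement and not self.inclination


@dataclass
class LabeledMesh:
    """Tetrahedral volume mesh with named boundary patches.

    ``points`` (n, 3) mm; ``elements`` (m, 4) or (m, 10) node indices;
    ``element_labels`` (m,) material names ("base"/"tooth"); ``patches``
    maps a patch name to oriented boundary facets, (f, 3) corner triples for
    tet4 or (f, 6) corner-plus-midside rows for tet10 in the order
    (a, b, c, m_ab, m_bc, m_ca), outward normals implied by winding.
    """

    points: np.ndarray
    elements: np.ndarray
    element_labels: np.ndarray
    patches: dict[str, np.ndarray]
    element_order: int
    metadata: dict = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return len(self.points)

    @property
    def num_elements(self) -> int:
        return len(self.elements)

    def corner_elements(self) -> np.ndarray:
        return self.elements[:, :4]

    def patch_facets(self, patch: str) -> np.ndarray:
        if patch not in self.patches:
            raise KeyError(
                f"unknown patch {patch!r}; available: {sorted(self.patches)}")
        return self.patches[patch]

    def boundary_corner_triangles(self) -> np.ndarray:
        """All boundary facets (corner triples), concatenated over patches."""
        tris = [f[:, :3] for f in self.patches.values() if len(f)]
        if not tris:
            return np.zeros((0, 3), dtype=np.int64)
        return np.vstack(tris)

    def element_volumes(self) -> np.ndarray:
        p = self.points[self.corner_elements()]
        return _tet_volumes(p)

    def validate(self) -> None:
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise MeshingError(f"{int(np.sum(vols <= 0))} inverted elements")
        free = _boundary_facets(self.corner_elements())[0]
        labelled = self.boundary_corner_triangles()
        if len(free) != len(labelled):
            raise MeshingError(
                f"boundary facet count {len(free)} != labelled facet count {len(labelled)}")
        keys = {tuple(sorted(t)) for t in labelled.tolist()}
        if len(keys) != len(labelled):
            raise MeshingError("a boundary facet carries more than one patch label")


# ---------------------------------------------------------------------------
# low-level helpers

def _tet_volumes(p: np.ndarray) -> np.ndarray:
    """Signed volumes of tets given corner coords (m, 4, 3)."""
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _orient_tets(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two nodes of negatively oriented tets so all volumes > 0."""
    vols = _tet_volumes(points[tets])
    flip = vols < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _boundary_facets(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outward-oriented boundary triangles and owning element indices."""
    m = len(tets)
    faces = np.empty((4 * m, 3), dtype=np.int64)
    owners = np.repeat(np.arange(m), 4)
    for fi, (a, b, c) in enumerate(_TET_FACES):
        faces[fi::4] = tets[:, (a, b, c)]
    keys = np.sort(faces, axis=1)
    order = np.lexsort(keys.T[::-1])
    keys_sorted = keys[order]
    uniq, first, counts = np.unique(
        keys_sorted, axis=0, return_index=True, return_counts=True)
    single = first[counts == 1]
    idx = order[single]
    return faces[idx], owners[idx]


def triangle_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Areas of triangles given by corner-index rows (f, >=3)."""
    p = points[np.asarray(tris)[:, :3]]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def triangle_normals(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[np.asarray(tris)[:, :3]]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def patch_area(mesh: LabeledMesh, patch: str) -> float:
    """Total area (mm^2) of a named surface patch."""
    facets = mesh.patch_facets(patch)
    if len(facets) == 0:
        return 0.0
    return float(triangle_areas(mesh.points, facets).sum())


def _to_tet10(points, tets, patch_tris):
    """Insert edge-midside nodes, returning tet10 connectivity and tri6 patches."""
    edge_mid: dict[tuple[int, int], int] = {}
    pts = [points]
    next_id = len(points)

    def mid(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        node = edge_mid.get(key)
        if node is None:
            node = next_id
            edge_mid[key] = node
            next_id += 1
        return node

    tet10 = np.empty((len(tets), 10), dtype=np.int64)
    tet10[:, :4] = tets
    for e, (a, b) in enumerate(TET10_EDGES):
        tet10[:, 4 + e] = [mid(t[a], t[b]) for t in tets]
    new_pts = np.empty((len(edge_mid), 3))
    for (a, b), node in edge_mid.items():
        new_pts[node - len(points)] = 0.5 * (points[a] + points[b])
    pts.append(new_pts)
    all_pts = np.vstack(pts)

    patches6 = {}
    for name, tris in patch_tris.items():
        out = np.empty((len(tris), 6), dtype=np.int64)
        for i, (a, b, c) in enumerate(tris):
            out[i] = (a, b, c, edge_mid[(min(a, b), max(a, b))],
                      edge_mid[(min(b, c), max(b, c))],
                      edge_mid[(min(a, c), max(a, c))])
        patches6[name] = out
    return all_pts, tet10, patches6


# ---------------------------------------------------------------------------
# denture generation

def _arc_table(rx: float, ry: float, phi_max: float, n: int = 2001):
    """Cumulative arc length of the half ellipse centerline for phi in [0, phi_max]."""
    phi = np.linspace(0.0, phi_max, n)
    dx = rx * np.cos(phi)
    dy = -ry * np.sin(phi)
    speed = np.hypot(dx, dy)
    s = np.concatenate(([0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(phi))))
    return phi, s


def _centerline(rx, ry, phi):
    phi = np.atleast_1d(phi)
    c = np.stack([rx * np.sin(phi), ry * np.cos(phi)], axis=-1)
    # outward (vestibular) horizontal normal of the elliptical centerline
    n = np.stack([ry * np.sin(phi), rx * np.cos(phi)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    t = np.stack([rx * np.cos(phi), -ry * np.sin(phi)], axis=-1)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    return c, n, t


def _block_intervals(params: ArchParameters, half_arc: float):
    """Arc-length intervals [s0, s1] of blocks I..IV on one side."""
    start = params.midline_gap
    intervals = []
    for area in params.block_footprints:
        length = area / params.tooth_band_width
        intervals.append((start, start + length))
        start += length + params.block_gap
    if intervals[-1][1] > half_arc - 1.0:
        raise MeshingError(
            "block_footprints/arch dimensions: tooth blocks do not fit on the "
            f"arch (need {intervals[-1][1]:.1f} mm, have {half_arc - 1.0:.1f} mm)")
    return intervals


def generate_denture(params: ArchParameters | None = None,
                     arrangement: ArrangementSpec | None = None,
                     seed: int = 0) -> LabeledMesh:
    """Generate the labeled denture-base mesh.

    Returns a :class:`LabeledMesh` with 8 occlusal patches (blocks I..IV x
    left/right), 8 intaglio mucosa segments (4 per side), one border-seal
    band, two posterior retention zones, the cutout notch surfaces and the
    remaining free surface.  Deterministic for fixed inputs; ``seed`` fixes
    the optional interior-node jitter.
    """
    params = params or ArchParameters()
    arrangement = arrangement or ArrangementSpec()
    params.validate()
    arrangement.validate()

    rx = params.arch_width / 2.0
    ry = params.arch_depth
    phi_max = math.radians(params.arch_sweep_deg) / 2.0
    h = params.mesh_size
    cw = params.cross_width

    phi_fine, s_fine = _arc_table(rx, ry, phi_max)
    half_arc = float(s_fine[-1])
    m = max(6, int(round(half_arc / h)))
    s_half = np.linspace(0.0, half_arc, m + 1)
    phi_half = np.interp(s_half, s_fine, phi_fine)
    # stations mirror-symmetric about the midsagittal plane (x = 0)
    phi_st = np.concatenate([-phi_half[::-1][:-1], phi_half])
    s_st = np.concatenate([-s_half[::-1][:-1], s_half])
    n_st = len(phi_st)

    nu = max(4, int(round(cw / h)))
    u_nodes = np.linspace(-cw / 2.0, cw / 2.0, nu + 1)
    u_mid = 0.5 * (u_nodes[:-1] + u_nodes[1:])
    nw = max(2, int(math.ceil((params.base_thickness + params.ridge_height) / h)))
    nt = max(1, int(round(params.tooth_height / h)))

    z_top = params.ridge_height + params.base_thickness

    def z_bot(u):
        saddle = params.ridge_height * 0.5 * (1.0 + np.cos(2.0 * np.pi * u / cw))
        flange = params.flange_height * (2.0 * u / cw) ** 2
        return saddle - flange

    c2, n2, t2 = _centerline(rx, ry, phi_st)

    # base grid nodes, id = ((i * (nu+1)) + j) * (nw+1) + k
    w_frac = np.linspace(0.0, 1.0, nw + 1)
    zb = z_bot(u_nodes)  # (nu+1,)
    xy = c2[:, None, :] + u_nodes[None, :, None] * n2[:, None, :]  # (n_st, nu+1, 2)
    z = zb[None, :, None] + w_frac[None, None, :] * (z_top - zb)[None, :, None]
    base_pts = np.empty((n_st, nu + 1, nw + 1, 3))
    base_pts[..., 0] = xy[..., 0][:, :, None]
    base_pts[..., 1] = xy[..., 1][:, :, None]
    base_pts[..., 2] = z
    base_ids = np.arange(n_st * (nu + 1) * (nw + 1)).reshape(n_st, nu + 1, nw + 1)
    points = [base_pts.reshape(-1, 3)]
    next_id = base_ids.size

    # ---- cell classification -------------------------------------------------
    s_mid = 0.5 * (s_st[:-1] + s_st[1:])  # (n_st-1,) signed arc of phi-cells
    intervals = _block_intervals(params, half_arc)
    delta = half_arc / m

    # per-side block allocation in whole cells, mirrored left/right so the
    # mesh stays midsagittally symmetric; at least one gap cell between blocks
    side_alloc: list[tuple[int, int]] = []  # (i0, i1) in side-cell indices
    cursor = max(1, int(round(params.midline_gap / delta)))
    for s0, s1 in intervals:
        ncells = max(1, int(round((s1 - s0) / delta)))
        i0, i1 = cursor, cursor + ncells
        side_alloc.append((i0, i1))
        cursor = i1 + max(1, int(round(params.block_gap / delta)))
    if side_alloc[-1][1] > m - 1:
        raise MeshingError(
            "block_footprints/arch dimensions: tooth blocks do not fit on the "
            f"meshed arch ({side_alloc[-1][1]} cells needed, {m - 1} available)")

    cell_block: list[str | None] = [None] * (n_st - 1)
    for b, (i0, i1) in zip(BLOCK_NAMES, side_alloc):
        for i in range(i0, i1):
            cell_block[m + i] = b          # right side
            cell_block[m - 1 - i] = b      # mirrored left side
    cell_side = ["right" if sm > 0 else "left" for sm in s_mid]

    band = params.tooth_band_width / 2.0
    tooth_cols = [j for j in range(nu) if -band <= u_mid[j] <= band]

    # cutout notch arc-centres: anterior midline plus the canine-premolar gaps
    # (labial/buccal frenal notches cut into the vestibular flange border)
    lateral = delta * 0.5 * (side_alloc[1][1] + side_alloc[2][0])
    notch_centres = [0.0, lateral, -lateral]
    notch_cols = [j for j in range(nu) if u_mid[j] > cw / 4.0]  # outer wall band

    def is_cutout_cell(ci: int, j: int, k: int) -> bool:
        """V-notch: arc width tapers with height so the tip concentrates stress."""
        if params.cutout_depth <= 0 or params.cutout_width <= 0:
            return False
        if j not in notch_cols:
            return False
        wall_height = z_top - z_bot(u_mid[j])
        z_centre = (k + 0.5) / nw * wall_height  # height above local border
        if z_centre >= params.cutout_depth:
            return False
        half_width = 0.5 * params.cutout_width * (1.0 - z_centre / params.cutout_depth)
        return any(abs(s_mid[ci] - sc) < half_width for sc in notch_centres)

    # ---- hexes ---------------------------------------------------------------
    hexes: list[np.ndarray] = []
    regions: list[tuple] = []  # (kind, block, side, ci, j, k)

    def add_hex(corner_ids, kind, block, side, ci, j, k):
        hexes.append(np.asarray(corner_ids, dtype=np.int64))
        regions.append((kind, block, side, ci, j, k))

    # Hexes are emitted for the right half and mirrored node-by-node onto the
    # left half, so the tetrahedral decomposition (and hence the discrete
    # stress field under symmetric loads) is exactly midsagittally symmetric.
    def ms(i: int) -> int:
        return n_st - 1 - i

    def base_hex(ci, j, k, mirrored: bool):
        i0, i1 = (ms(ci), ms(ci + 1)) if mirrored else (ci, ci + 1)
        return (base_ids[i0, j, k], base_ids[i1, j, k],
                base_ids[i1, j + 1, k], base_ids[i0, j + 1, k],
                base_ids[i0, j, k + 1], base_ids[i1, j, k + 1],
                base_ids[i1, j + 1, k + 1], base_ids[i0, j + 1, k + 1])

    for ci in range(m, n_st - 1):
        cm = n_st - 2 - ci  # mirrored cell index
        for j in range(nu):
            for k in range(nw):
                kind = "void" if is_cutout_cell(ci, j, k) else "base"
                add_hex(base_hex(ci, j, k, False), kind, None,
                        cell_side[ci], ci, j, k)
                add_hex(base_hex(ci, j, k, True), kind, None,
                        cell_side[cm], cm, j, k)

    # tooth prisms: extra node layers above the plate, sharing the top base nodes
    tooth_nodes: dict[tuple[int, int, int], int] = {}
    tooth_membership: dict[int, tuple[str, str]] = {}  # node -> (block, side)
    tooth_pts: list[np.ndarray] = []

    def tooth_node(i: int, j: int, level: int, blk: str, side: str) -> int:
        nonlocal next_id
        if level == 0:
            return int(base_ids[i, j, nw])
        key = (i, j, level)
        node = tooth_nodes.get(key)
        if node is None:
            node = next_id
            tooth_nodes[key] = node
            tooth_membership[node] = (blk, side)
            next_id += 1
            base = base_pts[i, j, nw]
            tooth_pts.append(base + np.array([0.0, 0.0,
                                              params.tooth_height * level / nt]))
        return node

    for ci in range(m, n_st - 1):
        blk = cell_block[ci]
        if blk is None:
            continue
        cm = n_st - 2 - ci
        for j in tooth_cols:
            for t in range(nt):
                for mirrored, cell, side in ((False, ci, cell_side[ci]),
                                             (True, cm, cell_side[cm])):
                    i0, i1 = (ms(ci), ms(ci + 1)) if mirrored else (ci, ci + 1)
                    tn = lambda i, jj, lvl: tooth_node(i, jj, lvl, blk, side)
                    ids = (tn(i0, j, t), tn(i1, j, t),
                           tn(i1, j + 1, t), tn(i0, j + 1, t),
                           tn(i0, j, t + 1), tn(i1, j, t + 1),
                           tn(i1, j + 1, t + 1), tn(i0, j + 1, t + 1))
                    add_hex(ids, "tooth", blk, side, cell, j, t)

    all_points = np.vstack(points + ([np.asarray(tooth_pts)] if tooth_pts else []))

    # ---- tooth arrangement (displacement / inclination) ----------------------
    if not arrangement.is_zero:
        cell_intervals = [(delta * i0, delta * i1) for i0, i1 in side_alloc]
        all_points = _apply_arrangement(
            all_points, tooth_membership, params, arrangement, rx, ry,
            phi_fine, s_fine, cell_intervals, z_top)

    # ---- hexes -> tets -------------------------------------------------------
    hex_arr = np.asarray(hexes)
    kinds = np.asarray([r[0] for r in regions])
    tets_all = hex_arr[:, _HEX_TO_TETS].reshape(-1, 4)
    tet_hex = np.repeat(np.arange(len(hex_arr)), 6)
    keep = kinds[tet_hex] != "void"
    void_tets = tets_all[~keep]
    tets = tets_all[keep]
    tet_hex = tet_hex[keep]

    # drop orphan nodes left by removed cutout cells
    used = np.unique(tets)
    remap = -np.ones(len(all_points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    all_points = all_points[used]
    tets = remap[tets]
    void_tets = remap[void_tets]  # may contain -1 for dropped nodes; keys still work

    tets = _orient_tets(all_points, tets)
    labels = np.where(kinds[tet_hex] == "tooth", "tooth", "base")

    # ---- boundary facets and patch labels ------------------------------------
    boundary, owners = _boundary_facets(tets)
    void_face_keys = set()
    for f in (void_tets if len(void_tets) else []):
        for a, b, c in _TET_FACES:
            void_face_keys.add(tuple(sorted((f[a], f[b], f[c]))))

    normals = triangle_normals(all_points, boundary)
    owner_region = [regions[tet_hex[o]] for o in owners]
    ell_a, ell_b = params.retention_ellipse_axes

    patch_names = (
        [f"occlusal_{b}_{s}" for b in BLOCK_NAMES for s in SIDES]
        + [f"intaglio_seg_{q}_{s}" for q in (1, 2, 3, 4) for s in SIDES]
        + ["border_seal", "retention_left", "retention_right", "cutouts", "free"]
    )
    patch_facets: dict[str, list] = {name: [] for name in patch_names}

    for f, (kind, blk, side, ci, j, k) in zip(range(len(boundary)), owner_region):
        tri = boundary[f]
        nz = normals[f, 2]
        key = tuple(sorted(tri.tolist()))
        name = "free"
        if kind == "tooth" and nz > 0.5:
            name = f"occlusal_{blk}_{side}"
        elif key in void_face_keys:
            name = "cutouts"
        elif kind == "base" and k == 0 and nz < -0.3:
            # retention ellipse in (arc-from-posterior-end, cross) coordinates,
            # decided per cell so left/right stay mirror images
            sm, um = abs(s_mid[ci]), u_mid[j]
            in_retention = (ell_a > 0 and ell_b > 0 and
                            ((half_arc - sm) / ell_a) ** 2
                            + (um / ell_b) ** 2 <= 1.0)
            if in_retention:
                name = f"retention_{side}"
            elif abs(u_mid[j]) > cw / 2.0 - params.seal_band_width:
                name = "border_seal"
            elif abs(u_mid[j]) <= params.support_band_width / 2.0:
                # minimal-compliance mucosa band at the ridge crest
                q = min(3, int(abs(s_mid[ci]) / half_arc * 4.0)) + 1
                name = f"intaglio_seg_{q}_{side}"
            # remaining intaglio is compliant mucosa, mechanically free
        patch_facets[name].append(tri)

    patches = {name: (np.asarray(rows, dtype=np.int64) if rows
                      else np.zeros((0, 3), dtype=np.int64))
               for name, rows in patch_facets.items()}

    # ---- optional interior jitter --------------------------------------------
    if params.jitter > 0:
        rng = np.random.default_rng(seed)
        on_boundary = np.zeros(len(all_points), dtype=bool)
        on_boundary[np.unique(boundary)] = True
        interior = ~on_boundary
        all_points[interior] += (rng.uniform(-1.0, 1.0, (int(interior.sum()), 3))
                                 * params.jitter * params.mesh_size)
        tets = _orient_tets(all_points, tets)

    if params.element_order == 2:
        all_points, elements, patches = _to_tet10(all_points, tets, patches)
    else:
        elements = tets

    mesh = LabeledMesh(
        points=all_points,
        elements=elements,
        element_labels=labels,
        patches=patches,
        element_order=params.element_order,
        metadata={
            "params": dataclasses.asdict(params),
            "arrangement": {
                "displacement": dict(arrangement.displacement),
                "inclination": dict(arrangement.inclination),
            },
            "seed": seed,
            "half_arc_length": half_arc,
            "z_top": z_top,
        },
    )
    for b in BLOCK_NAMES:
        for s in SIDES:
            if len(mesh.patches[f"occlusal_{b}_{s}"]) == 0:
                raise MeshingError(
                    f"block {b} ({s}) produced no occlusal facets; refine mesh_size "
                    "or enlarge block_footprints")
    mesh.validate()
    return mesh


def _apply_arrangement(points, tooth_membership, params, arrangement, rx, ry,
                       phi_fine, s_fine, intervals, z_top):
    """Displace/incline tooth-block nodes, blending to zero at the plate top.

    The blend weight grows linearly with height above the plate so the mesh
    stays conforming at the bonded interface while the occlusal surface
    receives the full requested displacement.
    """
    points = points.copy()
    for bi, block in enumerate(BLOCK_NAMES):
        s0, s1 = intervals[bi]
        s_c = 0.5 * (s0 + s1)
        for side, sign in (("left", -1.0), ("right", 1.0)):
            (d_vo, d_ap), incl = arrangement.applies_to(block, side)
            if d_vo == 0.0 and d_ap == 0.0 and incl == 0.0:
                continue
            phi_c = sign * float(np.interp(s_c, s_fine, phi_fine))
            c2, n2, t2 = _centerline(rx, ry, phi_c)
            outward = np.array([n2[0, 0], n2[0, 1], 0.0])
            anterior = np.array([0.0, 1.0, 0.0])
            axis = np.array([t2[0, 0], t2[0, 1], 0.0])
            axis /= np.linalg.norm(axis)
            centre = np.array([c2[0, 0], c2[0, 1], z_top])
            shift = d_vo * outward + d_ap * anterior
            rot = _rotation_matrix(axis, math.radians(incl))
            node_ids = [n for n, (b, s) in tooth_membership.items()
                        if b == block and s == side]
            for node in node_ids:
                p = points[node]
                w = min(1.0, max(0.0, (p[2] - z_top) / params.tooth_height))
                moved = rot @ (p - centre) + centre + shift
                points[node] = p + w * (moved - p)
    return points


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    ux, uy, uz = axis
    c, s = math.cos(angle), math.sin(angle)
    return np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
    ])


# ---------------------------------------------------------------------------
# simple box mesh (verification workhorse)

def box_mesh(lengths: Sequence[float] = (1.0, 1.0, 1.0),
             divisions: Sequence[int] = (4, 4, 4),
             element_order: int = 1,
             label: str = "base") -> LabeledMesh:
    """Structured tetrahedral box mesh with face patches xmin..zmax.

    Used for patch tests, beam benchmarks and foundation closed forms.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    ids = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append((ids[i, j, k], ids[i + 1, j, k], ids[i + 1, j + 1, k],
                              ids[i, j + 1, k], ids[i, j, k + 1], ids[i + 1, j, k + 1],
                              ids[i + 1, j + 1, k + 1], ids[i, j + 1, k + 1]))
    hex_arr = np.asarray(hexes, dtype=np.int64)
    tets = hex_arr[:, _HEX_TO_TETS].reshape(-1, 4)
    tets = _orient_tets(points, tets)

    boundary, _ = _boundary_facets(tets)
    centroids = points[boundary].mean(axis=1)
    tol = 1e-9 * max(lx, ly, lz)
    patches: dict[str, list] = {n: [] for n in
                                ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax")}
    for tri, cen in zip(boundary, centroids):
        if cen[0] < tol:
            patches["xmin"].append(tri)
        elif cen[0] > lx - tol:
            patches["xmax"].append(tri)
        elif cen[1] < tol:
            patches["ymin"].append(tri)
        elif cen[1] > ly - tol:
            patches["ymax"].append(tri)
        elif cen[2] < tol:
            patches["zmin"].append(tri)
        else:
            patches["zmax"].append(tri)
    patch_arr = {n: np.asarray(v, dtype=np.int64) for n, v in patches.items()}

    if element_order == 2:
        points, elements, patch_arr = _to_tet10(points, tets, patch_arr)
    else:
        elements = tets
    labels = np.full(len(elements), label)
    return LabeledMesh(points, elements, labels, patch_arr, element_order,
                       metadata={"box": {"lengths": list(lengths),
                                         "divisions": list(divisions)}})
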