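"""Occlusal loading, projected areas, rigid-motion fit and calibration."""

import numpy as np
import pytest

from rcdlife import (ArchParameters, FoundationSpec, LoadCase, box_mesh,
                     block_pressure, build_load_case, calibrate_foundation,
                     generate_denture, projected_area, rigid_motion_metrics,
                     solve_case)
from rcdlife.geometry import LabeledMesh
from rcdlife.loading import INTAGLIO_PATCHES


def _surface_mesh(points, tris, name):
    """Surface-only container for projection tests."""
    return LabeledMesh(points=np.asarray(points, dtype=float),
                       elements=np.zeros((0, 4), dtype=np.int64),
                       element_labels=np.zeros(0, dtype=object),
                       patches={name: np.asarray(tris, dtype=np.int64)},
                       element_order=1)


class TestProjectedArea:
    def test_horizontal_patch_projects_to_itself(self):
        mesh = box_mesh((2.0, 3.0, 1.0), (2, 3, 1))
        assert projected_area(mesh, "zmax") == pytest.approx(6.0, abs=1e-12)

    def test_vertical_patch_projects_to_zero(self):
        mesh = box_mesh((2.0, 3.0, 1.0), (2, 3, 1))
        assert projected_area(mesh, "xmax") == pytest.approx(0.0, abs=1e-12)

    def test_hemisphere_projects_to_disc(self):
        r, n_th, n_ph = 2.0, 60, 120
        th = np.linspace(0.0, np.pi / 2, n_th + 1)
        ph = np.linspace(0.0, 2 * np.pi, n_ph + 1)
        T, P = np.meshgrid(th, ph[:-1], indexing="ij")
        pts = np.stack([r * np.sin(T) * np.cos(P),
                        r * np.sin(T) * np.sin(P),
                        r * np.cos(T)], axis=-1).reshape(-1, 3)
        idx = np.arange(n_th + 1)[:, None] * n_ph + np.arange(n_ph)[None, :]
        tris = []
        for i in range(n_th):
            for j in range(n_ph):
                a, b = idx[i, j], idx[i, (j + 1) % n_ph]
                c, d = idx[i + 1, j], idx[i + 1, (j + 1) % n_ph]
                tris += [(a, c, d), (a, d, b)]
        mesh = _surface_mesh(pts, tris, "dome")
        assert projected_area(mesh, "dome") == pytest.approx(np.pi * r ** 2,
                                                             rel=0.01)

    def test_empty_patch_rejected(self):
        mesh = _surface_mesh(np.zeros((3, 3)), np.zeros((0, 3)), "empty")
        with pytest.raises(ValueError, match="empty"):
            projected_area(mesh, "empty")


class TestBlockPressure:
    def test_physiological_band_endpoints(self):
        assert block_pressure(100.0, 100.0) == pytest.approx(1.0)
        assert block_pressure(100.0, 10.0) == pytest.approx(10.0)

    def test_doubling_area_halves_pressure(self):
        assert block_pressure(100.0, 50.0) == 2 * block_pressure(100.0, 100.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            block_pressure(100.0, 0.0)


class TestBuildLoadCase:
    def test_canine_only_load_restricted_to_canine_patch(self, default_mesh):
        case = LoadCase(("II",), "asymmetric-right", 100.0)
        f = build_load_case(case, default_mesh)
        loaded = np.flatnonzero(np.abs(f[:, 2]) > 0)
        canine = np.unique(default_mesh.patches["occlusal_II_right"])
        assert set(loaded) <= set(canine.tolist())
        assert f[:, 2].sum() == pytest.approx(-100.0, rel=1e-9)
        assert np.abs(f[:, :2]).max() == 0.0

    def test_uniform_all_partitions_total_force(self, default_mesh):
        f = build_load_case(LoadCase(sidedness="uniform-all",
                                     total_force=100.0), default_mesh)
        assert f[:, 2].sum() == pytest.approx(-100.0, rel=1e-9)

    def test_symmetric_total_force_preserved(self, default_mesh):
        f = build_load_case(LoadCase(("IV",), "symmetric", 100.0),
                            default_mesh)
        assert f[:, 2].sum() == pytest.approx(-100.0, rel=1e-9)

    def test_curved_surface_carries_same_vertical_force(self):
        """Tilting the loaded surface does not change the vertical resultant."""
        flat = box_mesh((2.0, 2.0, 1.0), (4, 4, 2))
        slanted = box_mesh((2.0, 2.0, 1.0), (4, 4, 2))
        pts = slanted.points.copy()
        pts[:, 2] += 0.4 * pts[:, 0]  # shear the box: zmax becomes oblique
        slanted.points = pts
        for mesh in (flat, slanted):
            mesh.patches["occlusal_I_right"] = mesh.patches["zmax"]
        case = LoadCase(("I",), "asymmetric-right", 80.0)
        f_flat = build_load_case(case, flat)[:, 2].sum()
        f_slant = build_load_case(case, slanted)[:, 2].sum()
        assert f_flat == pytest.approx(-80.0, rel=1e-12)
        assert f_slant == pytest.approx(f_flat, rel=1e-12)

    def test_implausible_pressure_warns(self, default_mesh):
        with pytest.warns(UserWarning, match="plausible"):
            build_load_case(LoadCase(("II",), "asymmetric-right", 5000.0),
                            default_mesh)


class TestRigidMotionMetrics:
    def test_pure_translation(self, coarse_mesh):
        u = np.zeros((coarse_mesh.num_nodes, 3))
        u[:, 2] = -0.25
        m = rigid_motion_metrics(u, coarse_mesh)
        assert abs(m.roll) < 1e-10 and abs(m.pitch) < 1e-10 \
            and abs(m.yaw) < 1e-10
        assert m.translation[2] == pytest.approx(-0.25)
        assert m.vertical_range == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_roll(self, coarse_mesh):
        angle = np.radians(1.0)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])  # about y: roll
        centre = coarse_mesh.points.mean(axis=0)
        u = (coarse_mesh.points - centre) @ R.T + centre - coarse_mesh.points
        m = rigid_motion_metrics(u, coarse_mesh)
        assert m.roll == pytest.approx(1.0, abs=1e-3)
        assert abs(m.pitch) < 1e-3 and abs(m.yaw) < 1e-3

    def test_vertical_load_produces_no_yaw(self, canine_solution,
                                           default_mesh):
        _, _, u, _ = canine_solution
        m = rigid_motion_metrics(u, default_mesh)
        assert abs(m.yaw) < 0.01
        assert abs(m.roll) < 1e-6  # symmetric load on a symmetric mesh


class TestFoundationSpec:
    def test_nonnegative_stiffness_required(self):
        with pytest.raises(ValueError):
            FoundationSpec(seal_normal=-1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            FoundationSpec(segment_normal={p: 0.0 for p in INTAGLIO_PATCHES},
                           seal_normal=0.0, retention_tangential=0.0)

    def test_stiffening_compliance_reduces_settlement(self, default_mesh,
                                                      materials):
        """c1 < 0 (tissue stiffens under penetration) raises support
        stiffness and lowers the settlement."""
        loads = build_load_case(LoadCase(sidedness="uniform-all"),
                                default_mesh)
        u_lin, _ = solve_case(default_mesh, materials, FoundationSpec(), loads)
        stiffening = FoundationSpec(compliance_slope=-2.0)
        u_nl, _ = solve_case(default_mesh, materials, stiffening, loads)
        assert abs(u_nl[:, 2].mean()) < abs(u_lin[:, 2].mean())


class TestCalibration:
    def test_calibrated_balance(self, calibrated):
        """Uniform 100 N load: negligible pitch/roll, range within 0.02 mm."""
        after = calibrated.after
        assert abs(after.pitch) < 0.01
        assert abs(after.roll) < 0.01
        assert after.vertical_range <= 0.02

    def test_perturbed_segment_recovers(self, materials):
        """Halving one segment pair's stiffness induces pitch; recalibration
        restores balance."""
        params = ArchParameters(mesh_size=3.0, element_order=1)
        mesh = generate_denture(params)
        lopsided = FoundationSpec().with_multipliers({1: 0.5})
        loads = build_load_case(LoadCase(sidedness="uniform-all"), mesh)
        u, _ = solve_case(mesh, materials, lopsided, loads)
        assert abs(rigid_motion_metrics(u, mesh).pitch) > 0.005
        result = calibrate_foundation(mesh, materials, initial=lopsided)
        assert abs(result.after.pitch) < 0.01
        assert abs(result.after.roll) < 0.01
        assert abs(result.after.pitch) < abs(result.before.pitch)
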