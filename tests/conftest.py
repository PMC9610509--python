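"""Shared fixtures: meshes, materials and one calibrated scenario run.

Session-scoped because mesh generation and FEM solves dominate runtime; all
fixtures are deterministic (fixed parameters, fixed seeds).
"""

import pytest
from hypothesis import settings

from rcdlife import (ArchParameters, FoundationSpec, LoadCase, MaterialSet,
                     Scenario, build_load_case, calibrate_foundation,
                     generate_denture, run_scenario, solve_case)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def materials():
    return MaterialSet()


@pytest.fixture(scope="session")
def coarse_params():
    """Fast tet4 geometry for unit tests."""
    return ArchParameters(mesh_size=3.0, element_order=1)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_params):
    return generate_denture(coarse_params, seed=0)


@pytest.fixture(scope="session")
def default_params():
    """Default-resolution geometry, linear elements for test runtime."""
    return ArchParameters(mesh_size=2.0, element_order=1)


@pytest.fixture(scope="session")
def default_mesh(default_params):
    return generate_denture(default_params, seed=0)


@pytest.fixture(scope="session")
def calibrated(default_mesh, materials):
    """Foundation calibrated against the uniform 100 N all-teeth load."""
    return calibrate_foundation(default_mesh, materials, total_force=100.0)


@pytest.fixture(scope="session")
def canine_solution(default_mesh, materials):
    """Symmetric canine (Block II) load solved on the default foundation."""
    case = LoadCase(("II",), "symmetric", 100.0)
    loads = build_load_case(case, default_mesh)
    u, system = solve_case(default_mesh, materials, FoundationSpec(), loads)
    return case, loads, u, system


@pytest.fixture(scope="session")
def normal_run(default_params, calibrated):
    """Full canonical scenario on the default geometry, normal arrangement."""
    sc = Scenario(params=default_params, foundation=calibrated.spec)
    return run_scenario(sc)
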