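"""Scenario orchestration: geometry -> calibration -> solves -> life maps.

Mirrors the computational stages of a denture-design workflow: generate the
arch for a tooth-arrangement variant, balance the mucosal foundation, run
the canonical occlusal load cases (blocks I..IV, symmetric and asymmetric),
recover stresses, map fatigue life and compare variants.  Clinical stages
(impressions, try-in, printing) are represented as named no-op stages so the
computational stages keep their place in the overall design algorithm.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import fatigue as fat
from . import fem, loading
from .geometry import (ArchParameters, ArrangementSpec, BLOCK_NAMES,
                       LabeledMesh, generate_denture)
from .mesh_io import write_vtk_fields

__all__ = [
    "Scenario",
    "CaseResult",
    "ScenarioResult",
    "ComparisonReport",
    "canonical_cases",
    "run_scenario",
    "compare_arrangements",
    "render_report",
    "CONTOUR_LEVELS",
    "CLINICAL_STAGES",
]

logger = logging.getLogger(__name__)

# normalized von Mises isoline levels at a 10% step
CONTOUR_LEVELS = tuple(round(0.1 * k, 1) for k in range(1, 11))

CLINICAL_STAGES = (
    "impressions (clinical, no-op)",
    "occlusal registration (clinical, no-op)",
    "try-in (clinical, no-op)",
    "manufacturing (no-op)",
)


def canonical_cases(total_force: float = 100.0) -> list[loading.LoadCase]:
    """Blocks I..IV under symmetric and asymmetric (right) loading."""
    cases = []
    for block in BLOCK_NAMES:
        cases.append(loading.LoadCase((block,), "symmetric", total_force))
        cases.append(loading.LoadCase((block,), "asymmetric-right", total_force))
    return cases


@dataclass
class Scenario:
    """Fully serializable description of one analysis run."""

    params: ArchParameters = field(default_factory=ArchParameters)
    arrangement: ArrangementSpec = field(default_factory=ArrangementSpec)
    materials: fem.MaterialSet = field(default_factory=fem.MaterialSet)
    fatigue: fat.FatigueParams = field(default_factory=fat.FatigueParams)
    foundation: loading.FoundationSpec | str = "calibrate"
    cases: list[loading.LoadCase] = field(default_factory=canonical_cases)
    criterion: str = "swt-principal"
    cycle_model: str = "pulsating"
    meals_per_day: float = 3.0
    chews_per_meal: float = 1000.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "arrangement": {
                "displacement": {k: list(v) for k, v in
                                 self.arrangement.displacement.items()},
                "inclination": dict(self.arrangement.inclination),
            },
            "materials": {lab: dataclasses.asdict(m)
                          for lab, m in self.materials.materials.items()},
            "fatigue": dataclasses.asdict(self.fatigue),
            "foundation": (self.foundation if isinstance(self.foundation, str)
                           else dataclasses.asdict(self.foundation)),
            "cases": [dataclasses.asdict(c) for c in self.cases],
            "criterion": self.criterion,
            "cycle_model": self.cycle_model,
            "meals_per_day": self.meals_per_day,
            "chews_per_meal": self.chews_per_meal,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        foundation = d.get("foundation", "calibrate")
        if isinstance(foundation, dict):
            foundation = loading.FoundationSpec(**foundation)
        materials = d.get("materials")
        mats = (fem.MaterialSet({lab: fem.Material(**m)
                                 for lab, m in materials.items()})
                if materials else fem.MaterialSet())
        arr = d.get("arrangement", {})
        return cls(
            params=ArchParameters(**{
                **d.get("params", {}),
                "block_footprints": tuple(d.get("params", {}).get(
                    "block_footprints", (60.0, 25.0, 50.0, 100.0))),
                "retention_ellipse_axes": tuple(d.get("params", {}).get(
                    "retention_ellipse_axes", (9.0, 5.0))),
            }),
            arrangement=ArrangementSpec(
                displacement={k: tuple(v) for k, v in
                              arr.get("displacement", {}).items()},
                inclination=dict(arr.get("inclination", {}))),
            materials=mats,
            fatigue=fat.FatigueParams(**d["fatigue"]) if "fatigue" in d
            else fat.FatigueParams(),
            foundation=foundation,
            cases=[loading.LoadCase(tuple(c["blocks"]), c["sidedness"],
                                    c["total_force"])
                   for c in d.get("cases", [])] or canonical_cases(),
            criterion=d.get("criterion", "swt-principal"),
            cycle_model=d.get("cycle_model", "pulsating"),
            meals_per_day=d.get("meals_per_day", 3.0),
            chews_per_meal=d.get("chews_per_meal", 1000.0),
            seed=d.get("seed", 0),
        )

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CaseResult:
    case: loading.LoadCase
    displacements: np.ndarray
    stress: fem.StressField
    life: fat.LifeField
    summary: dict


@dataclass
class ScenarioResult:
    scenario: Scenario
    mesh: LabeledMesh
    foundation: loading.FoundationSpec
    calibration: loading.CalibrationResult | None
    cases: dict[str, CaseResult]

    @property
    def min_years(self) -> float:
        return min(c.life.min_years for c in self.cases.values())

    @property
    def min_cycles(self) -> float:
        return min(c.life.min_cycles for c in self.cases.values())

    def summary_table(self) -> dict:
        return {name: c.summary for name, c in self.cases.items()}


def _nearest_patch(mesh: LabeledMesh, node: int) -> str:
    """Patch containing (or nearest to) a node; used to localize maxima."""
    for name, facets in mesh.patches.items():
        if len(facets) and np.any(facets == node):
            return name
    p = mesh.points[node]
    best, best_d = "free", np.inf
    for name, facets in mesh.patches.items():
        if not len(facets):
            continue
        cen = mesh.points[facets[:, :3]].mean(axis=1)
        d = float(np.min(np.linalg.norm(cen - p, axis=1)))
        if d < best_d:
            best, best_d = name, d
    return best


def hazard_zone_count(mesh: LabeledMesh, life: fat.LifeField,
                      max_code: int = 1) -> int:
    """Number of disjoint hazard zones (red or intermediate node clusters).

    Nodes with hazard code >= ``max_code`` are linked through element edges
    and counted as connected components.
    """
    hot = life.hazard >= max_code
    if not hot.any():
        return 0
    idx = np.flatnonzero(hot)
    pos = -np.ones(mesh.num_nodes, dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    conn = mesh.elements
    rows, cols = [], []
    npe = conn.shape[1]
    for a in range(npe):
        for b in range(a + 1, npe):
            va, vb = conn[:, a], conn[:, b]
            mask = hot[va] & hot[vb]
            rows.append(pos[va[mask]])
            cols.append(pos[vb[mask]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    g = sp.coo_array((np.ones(len(rows)), (rows, cols)),
                     shape=(len(idx), len(idx)))
    n, _ = connected_components(g, directed=False)
    return int(n)


def run_scenario(scenario: Scenario) -> ScenarioResult:
    """Run all load cases of a scenario; deterministic for a fixed config.

    Stages: (clinical no-ops) -> geometry -> foundation calibration ->
    per-case solve -> stress recovery -> life map.  Every solve enforces the
    equilibrium check (reactions balance applied load within 0.1%).
    """
    for stage in CLINICAL_STAGES[:3]:
        logger.info("stage %s [config %s]", stage, scenario.config_hash)

    logger.info("stage geometry [config %s]", scenario.config_hash)
    mesh = generate_denture(scenario.params, scenario.arrangement,
                            seed=scenario.seed)

    calibration = None
    if isinstance(scenario.foundation, str):
        if scenario.foundation != "calibrate":
            raise ValueError(f"unknown foundation mode {scenario.foundation!r}")
        logger.info("stage foundation-calibration")
        total = scenario.cases[0].total_force if scenario.cases else 100.0
        calibration = loading.calibrate_foundation(
            mesh, scenario.materials, total_force=total)
        foundation = calibration.spec
    else:
        foundation = scenario.foundation

    results: dict[str, CaseResult] = {}
    for case in scenario.cases:
        logger.info("stage solve %s", case.name)
        try:
            loads = loading.build_load_case(case, mesh)
            u, system = loading.solve_case(mesh, scenario.materials,
                                           foundation, loads)
            reactions = fem.reaction_sum(u, system)
            applied = loads.sum(axis=0)
            imbalance = np.linalg.norm(reactions - applied)
            if imbalance > 1e-3 * max(np.linalg.norm(applied), 1e-12):
                raise RuntimeError(
                    f"equilibrium violated: |R - F| = {imbalance:.3g} N "
                    f"for |F| = {np.linalg.norm(applied):.3g} N")
            stress = fem.recover_stress(u, mesh, scenario.materials)
            life = fat.life_field(stress, scenario.fatigue,
                                  cycle_model=scenario.cycle_model,
                                  criterion=scenario.criterion,
                                  meals_per_day=scenario.meals_per_day,
                                  chews_per_meal=scenario.chews_per_meal)
        except Exception as exc:
            raise RuntimeError(
                f"scenario stage 'solve {case.name}' failed: {exc}") from exc

        base_nodes = np.unique(
            mesh.elements[np.asarray(mesh.element_labels) == "base"])
        vm = stress.von_mises_nodal
        vm_base = vm[base_nodes]
        peak_local = int(np.argmax(vm_base))
        peak_node = int(base_nodes[peak_local])
        motion = loading.rigid_motion_metrics(u, mesh)
        summary = {
            "case": case.name,
            "max_vm_nodal_MPa": float(vm.max()),
            "max_vm_element_MPa": float(stress.von_mises_element.max()),
            "max_base_vm_nodal_MPa": float(vm_base.max()),
            "max_base_stress_patch": _nearest_patch(mesh, peak_node),
            "min_cycles": life.min_cycles,
            "min_years": life.min_years,
            "red_fraction": life.hazard_fraction(2),
            "hazard_zones": hazard_zone_count(mesh, life),
            "rigid_motion": motion.as_dict(),
            "reaction_force_N": [float(v) for v in reactions],
        }
        results[case.name] = CaseResult(case, u, stress, life, summary)

    logger.info("stage %s", CLINICAL_STAGES[3])
    return ScenarioResult(scenario=scenario, mesh=mesh, foundation=foundation,
                          calibration=calibration, cases=results)


@dataclass
class ComparisonReport:
    """Arrangement-variant comparison keyed by scenario name."""

    entries: dict[str, dict]
    ranking: list[str]  # variant names, shortest minimum life first

    def to_dict(self) -> dict:
        return {"ranking": self.ranking, "entries": self.entries}


def compare_arrangements(scenarios: dict[str, Scenario]) -> ComparisonReport:
    """Run and compare arrangement variants (e.g. normal/displaced/inclined).

    All scenarios must share mesh resolution and load cases; variants are
    ranked by minimum predicted life and flagged when hazard zones multiply.
    """
    ref = next(iter(scenarios.values()))
    for name, sc in scenarios.items():
        if sc.params.mesh_size != ref.params.mesh_size \
                or sc.params.element_order != ref.params.element_order:
            raise ValueError(
                f"scenario {name!r} has a different mesh resolution; "
                "variants must share mesh_size and element_order")
        if [c.name for c in sc.cases] != [c.name for c in ref.cases]:
            raise ValueError(f"scenario {name!r} has different load cases")

    runs = {name: run_scenario(sc) for name, sc in scenarios.items()}
    base_name = "normal" if "normal" in runs else next(iter(runs))
    base_min_years = runs[base_name].min_years

    entries = {}
    for name, res in runs.items():
        zones = max(c.summary["hazard_zones"] for c in res.cases.values())
        sym, asym = {}, {}
        for cname, c in res.cases.items():
            block = c.case.blocks[0]
            if c.case.sidedness == "symmetric":
                sym[block] = c.summary["max_base_vm_nodal_MPa"]
            elif c.case.sidedness.startswith("asymmetric"):
                asym[block] = c.summary["max_base_vm_nodal_MPa"]
        ratios = {b: asym[b] / sym[b] for b in sym if b in asym and sym[b] > 0}
        entries[name] = {
            "config_hash": res.scenario.config_hash,
            "min_cycles": res.min_cycles,
            "min_years": res.min_years,
            "life_ratio_vs_reference": (res.min_years / base_min_years
                                        if base_min_years > 0 else np.nan),
            "max_hazard_zones": zones,
            "max_base_stress_MPa": {n: c.summary["max_base_vm_nodal_MPa"]
                                    for n, c in res.cases.items()},
            "asym_sym_stress_ratio": ratios,
            "multi_zone_flag": zones > entries.get(base_name, {}).get(
                "max_hazard_zones", zones),
        }
    ranking = sorted(entries, key=lambda n: entries[n]["min_years"])
    return ComparisonReport(entries=entries, ranking=ranking)


def render_report(result: ScenarioResult, outdir, formats=("vtk", "json", "csv")):
    """Write VTK fields, a JSON summary and a Table-2-style CSV.

    The normalized von Mises field comes with 10%-step contour levels in the
    JSON metadata; the CSV lists max base stress per block for symmetric and
    asymmetric loading.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if "vtk" in formats:
        for name, c in result.cases.items():
            vm = c.stress.von_mises_nodal
            vm_max = vm.max() if vm.max() > 0 else 1.0
            fields = {
                "displacement": c.displacements,
                "von_mises": vm,
                "von_mises_normalized": vm / vm_max,
                "log10_cycles": np.log10(np.maximum(c.life.cycles, 1.0)),
                "years": c.life.years,
                "hazard": c.life.hazard.astype(float),
            }
            fname = name.replace(":", "_").replace("+", "")
            written.append(write_vtk_fields(result.mesh,
                                            outdir / f"case_{fname}.vtk",
                                            fields))

    if "json" in formats:
        payload = {
            "config_hash": result.scenario.config_hash,
            "scenario": result.scenario.to_dict(),
            "contour_levels_normalized": list(CONTOUR_LEVELS),
            "assumptions": {
                "mastication_schedule": {
                    "meals_per_day": result.scenario.meals_per_day,
                    "chews_per_meal": result.scenario.chews_per_meal},
                "fatigue_constants_placeholder":
                    result.scenario.fatigue.placeholder,
                "criterion": result.scenario.criterion,
                "cycle_model": result.scenario.cycle_model,
            },
            "calibration": (result.calibration.report()
                            if result.calibration else None),
            "cases": result.summary_table(),
        }
        if not result.cases:
            logger.warning("rendering a report with no case results")
        path = outdir / "summary.json"
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)

    if "csv" in formats:
        path = outdir / "max_stress_table.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["load", *[f"Block {b}" for b in BLOCK_NAMES]])
            for mode, label in (("symmetric", "Symmetric, MPa"),
                                ("asymmetric", "Asymmetric, MPa")):
                row = [label]
                for b in BLOCK_NAMES:
                    val = ""
                    for c in result.cases.values():
                        if c.case.blocks == (b,) and \
                                c.case.sidedness.startswith(mode):
                            val = f"{c.summary['max_base_vm_nodal_MPa']:.4g}"
                    row.append(val)
                writer.writerow(row)
        written.append(path)
    return written
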