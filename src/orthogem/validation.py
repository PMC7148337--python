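"""Functional test harness: metabolite conversion and reaction optimisation tests.

A metabolite conversion test (MCT) asks whether source metabolites can be
converted into target metabolites under a named medium: supply sinks for the
sources and demand drains for the targets are added (when no boundary
reaction already provides them) and the summed target demand is maximised.
A reaction optimisation test (ROT) asks whether a named reaction can carry
non-zero optimised flux under a stated condition (organic exchanges closed
except allowed substrates; oxygen uptake open only when aerobic).

Either kind fails in exactly one of three modes: a participating component is
missing from the model, the optimisation has no optimal solution, or the
optimum is almost zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import FLUX_TOL, LinearProblem, Medium, apply_medium
from .model import MetabolicModel, Reaction

__all__ = [
    "FunctionalTest",
    "TestResult",
    "load_test_battery",
    "save_test_battery",
    "run_mct",
    "run_rot",
    "run_suite",
    "save_suite_summary",
]


@dataclass
class FunctionalTest:
    id: str
    kind: str  # MCT | ROT
    sources: list[str] = field(default_factory=list)  # metabolite ids (MCT) /
    # metabolite or exchange ids allowed open (ROT)
    targets: list[str] = field(default_factory=list)
    medium: str = ""  # MCT medium name
    objective_reaction: str = ""  # ROT objective
    condition: str = "aerobic"  # ROT: aerobic | anaerobic
    closure_policy: str = "organic_only"  # ROT exchange closure
    oxygen_exchange: str = "EX_o2_e"

    def __post_init__(self) -> None:
        if self.kind not in {"MCT", "ROT"}:
            raise ValueError(f"test {self.id}: unknown kind {self.kind!r}")
        if self.kind == "MCT" and (not self.sources or not self.targets):
            raise ValueError(f"MCT {self.id}: needs at least one source and target")
        if self.kind == "ROT" and not self.objective_reaction:
            raise ValueError(f"ROT {self.id}: needs an objective reaction")


@dataclass
class TestResult:
    test_id: str
    status: str  # pass | fail
    failure_mode: str  # missing_component | infeasible | zero_objective | none
    objective_value: float


def load_test_battery(path: str | Path) -> list[FunctionalTest]:
    records = json.loads(Path(path).read_text())["tests"]
    return [FunctionalTest(**record) for record in records]


def save_test_battery(tests: list[FunctionalTest], path: str | Path) -> None:
    records = [
        {
            "id": t.id,
            "kind": t.kind,
            "sources": t.sources,
            "targets": t.targets,
            "medium": t.medium,
            "objective_reaction": t.objective_reaction,
            "condition": t.condition,
            "closure_policy": t.closure_policy,
            "oxygen_exchange": t.oxygen_exchange,
        }
        for t in tests
    ]
    Path(path).write_text(json.dumps({"tests": records}, indent=1) + "\n")


def _boundary_reactions_for(model: MetabolicModel, met_id: str) -> list[str]:
    return [
        r.id
        for r in model.reactions.values()
        if r.is_exchange and met_id in r.stoichiometry
    ]


def _maximize(model: MetabolicModel, objective_ids: list[str]) -> tuple[str, float, LinearProblem]:
    lp = LinearProblem(model)
    c = np.zeros(len(lp.rxn_ids))
    for rxn_id in objective_ids:
        c[lp.rxn_index[rxn_id]] = 1.0
    sol = lp.solve(c, "max")
    return sol.status, sol.objective_value, lp


def run_mct(
    model: MetabolicModel,
    test: FunctionalTest,
    media: dict[str, Medium],
    tol: float = FLUX_TOL,
) -> TestResult:
    """Run one metabolite conversion test; the input model is not mutated."""
    if test.medium not in media:
        raise KeyError(f"MCT {test.id}: unknown medium {test.medium!r}")
    missing = [
        m for m in test.sources + test.targets if m not in model.metabolites
    ]
    if missing:
        return TestResult(test.id, "fail", "missing_component", 0.0)

    work = apply_medium(model, media[test.medium], policy="all")
    for src in test.sources:
        if not _boundary_reactions_for(work, src):
            work.add_reaction(Reaction(f"SK_{src}__mct", {src: -1.0}, -1000.0, 1000.0))
        else:
            for rxn_id in _boundary_reactions_for(work, src):
                work.reactions[rxn_id].lb = -1000.0
    demand_ids = []
    for tgt in test.targets:
        demand_id = f"DM_{tgt}__mct"
        if demand_id not in work.reactions:
            work.add_reaction(Reaction(demand_id, {tgt: -1.0}, 0.0, 1000.0))
        demand_ids.append(demand_id)

    status, total, lp = _maximize(work, demand_ids)
    if status != "optimal":
        return TestResult(test.id, "fail", "infeasible", 0.0)
    if total <= tol:
        return TestResult(test.id, "fail", "zero_objective", total)
    # every target must individually be producible, not just the aggregate
    for demand_id in demand_ids:
        c = np.zeros(len(lp.rxn_ids))
        c[lp.rxn_index[demand_id]] = 1.0
        single = lp.solve(c, "max")
        if not single.ok or single.objective_value <= tol:
            return TestResult(test.id, "fail", "zero_objective", total)
    return TestResult(test.id, "pass", "none", total)


def run_rot(
    model: MetabolicModel,
    test: FunctionalTest,
    tol: float = FLUX_TOL,
    organic_ids: set[str] | None = None,
) -> TestResult:
    """Run one reaction optimisation test; the input model is not mutated."""
    if test.closure_policy not in {"organic_only", "all"}:
        raise KeyError(f"ROT {test.id}: unknown closure policy {test.closure_policy!r}")
    if test.objective_reaction not in model.reactions:
        return TestResult(test.id, "fail", "missing_component", 0.0)

    allowed: set[str] = set()
    for entry in test.sources:
        if entry in model.reactions and model.reactions[entry].is_exchange:
            allowed.add(entry)
        elif entry in model.metabolites:
            allowed.update(_boundary_reactions_for(model, entry))
        else:
            return TestResult(test.id, "fail", "missing_component", 0.0)

    substrate_bounds = {rxn_id: (-1000.0, 1000.0) for rxn_id in allowed}
    medium = Medium(f"rot_{test.id}", substrate_bounds)
    work = apply_medium(model, medium, policy=test.closure_policy,
                        organic_ids=organic_ids)
    if test.oxygen_exchange in work.reactions:
        o2 = work.reactions[test.oxygen_exchange]
        if test.condition == "aerobic":
            o2.lb = -1000.0
        else:
            o2.lb = max(o2.lb, 0.0)

    status, value, _ = _maximize(work, [test.objective_reaction])
    if status != "optimal":
        return TestResult(test.id, "fail", "infeasible", 0.0)
    if value <= tol:
        return TestResult(test.id, "fail", "zero_objective", value)
    return TestResult(test.id, "pass", "none", value)


def _components_present(model: MetabolicModel, test: FunctionalTest) -> bool:
    if test.kind == "MCT":
        return all(m in model.metabolites for m in test.sources + test.targets)
    return test.objective_reaction in model.reactions


def run_suite(
    model: MetabolicModel,
    tests: list[FunctionalTest],
    media: dict[str, Medium],
    tol: float = FLUX_TOL,
) -> dict:
    """Run a battery of MCTs and ROTs and tally outcomes.

    Returns per-test results, pass/fail-by-mode counts split by test kind,
    and a secondary tally restricted to tests whose participating components
    exist in the model.
    """
    results: list[TestResult] = []
    for test in tests:
        if test.kind == "MCT":
            results.append(run_mct(model, test, media, tol))
        else:
            results.append(run_rot(model, test, tol))
    counts: dict[str, dict] = {}
    for kind in ("MCT", "ROT"):
        kind_results = [
            r for r, t in zip(results, tests) if t.kind == kind
        ]
        counts[kind] = {
            "total": len(kind_results),
            "passed": sum(r.status == "pass" for r in kind_results),
            "failed_by_mode": {
                mode: sum(r.failure_mode == mode for r in kind_results)
                for mode in ("missing_component", "infeasible", "zero_objective")
            },
        }
    present = [
        r for r, t in zip(results, tests) if _components_present(model, t)
    ]
    return {
        "results": results,
        "counts": counts,
        "components_present": {
            "total": len(present),
            "passed": sum(r.status == "pass" for r in present),
        },
    }


def save_suite_summary(summary: dict, tests: list[FunctionalTest], path: str | Path) -> None:
    by_id = {t.id: t for t in tests}
    pd.DataFrame(
        {
            "test_id": [r.test_id for r in summary["results"]],
            "kind": [by_id[r.test_id].kind for r in summary["results"]],
            "status": [r.status for r in summary["results"]],
            "failure_mode": [r.failure_mode for r in summary["results"]],
            "objective_value": [r.objective_value for r in summary["results"]],
        }
    ).to_csv(path, sep="\t", index=False)
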