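"""Linear-programming analyses on metabolic models.

Flux balance analysis (FBA) maximises an objective flux subject to the
steady-state mass balance ``S·v = 0`` and flux bounds; flux variability
analysis (FVA) reports per-reaction flux ranges; blocked reactions and
dead-end metabolites diagnose network consistency; media application and
gene-knockout bound constraining prepare models for simulation.

All solves go through scipy's HiGHS solver, single-threaded and
deterministic.  Only objective values are contractual — degenerate alternate
optima may return different flux vectors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .gpr import EMPTY, eval_gpr
from .model import DEFAULT_BOUND, FluxSolution, MetabolicModel

__all__ = [
    "Medium",
    "load_medium",
    "apply_medium",
    "open_exchanges",
    "fba",
    "fva",
    "blocked_and_deadends",
    "knockout_bounds",
    "LinearProblem",
    "FLUX_TOL",
]

FLUX_TOL = 1e-6  # "almost zero" flux threshold shared across the package

# Carbon in a chemical formula: a 'C' not followed by a lowercase letter
# (so Cl, Ca, Co do not count as carbon).
_CARBON_RE = re.compile(r"C(?![a-z])")


@dataclass
class Medium:
    """Named set of exchange-reaction bounds defining nutrient availability.

    Exchanges are drains (``met →``), so uptake is negative flux and a
    nutrient is available when its exchange lower bound is negative.
    ``always_open`` exchanges (water, protons, ...) are never closed by
    medium application.
    """

    name: str
    bounds: dict[str, tuple[float, float]]
    always_open: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn_id, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(f"medium {self.name}: {rxn_id} lb > ub")


def load_medium(path: str | Path, name: str | None = None) -> Medium:
    """Read a medium TSV with columns exchange_id, lb, ub, always_open."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    bounds = {}
    always_open: set[str] = set()
    for row in table.itertuples(index=False):
        bounds[row.exchange_id] = (float(row.lb), float(row.ub))
        if bool(int(row.always_open)):
            always_open.add(row.exchange_id)
    return Medium(name or path.stem, bounds, always_open)


def _is_organic(model: MetabolicModel, exchange_id: str, organic_ids) -> bool:
    rxn = model.reactions[exchange_id]
    (met_id,) = rxn.stoichiometry
    met = model.metabolites[met_id]
    if met.formula:
        return bool(_CARBON_RE.search(met.formula))
    return exchange_id in (organic_ids or set())


def apply_medium(
    model: MetabolicModel,
    medium: Medium,
    policy: str = "all",
    organic_ids: set[str] | None = None,
) -> MetabolicModel:
    """Return a copy with medium bounds applied and other uptakes closed.

    Exchanges listed in the medium receive its bounds; every other exchange
    has its uptake closed (``lb = 0``) — all of them under policy ``all``, or
    only those draining carbon-containing metabolites under ``organic_only``
    (classified by formula when present, else by ``organic_ids``).
    ``always_open`` exchanges keep their current bounds.  Idempotent.

    Medium entries absent from the model are skipped (a pruned sub-model
    need not carry every reference exchange); an id that resolves to a
    non-exchange reaction is an error.
    """
    if policy not in {"all", "organic_only"}:
        raise ValueError(f"unknown closure policy {policy!r}")
    exchange_ids = set(model.exchanges)
    not_exchange = {
        r for r in medium.bounds if r in model.reactions and r not in exchange_ids
    }
    if not_exchange:
        raise KeyError(
            f"medium {medium.name}: ids are not exchange reactions: "
            f"{sorted(not_exchange)}"
        )
    out = model.copy()
    for rxn_id in sorted(exchange_ids):
        if rxn_id in medium.always_open:
            continue
        rxn = out.reactions[rxn_id]
        if rxn_id in medium.bounds:
            rxn.lb, rxn.ub = medium.bounds[rxn_id]
        elif policy == "all" or _is_organic(model, rxn_id, organic_ids):
            rxn.lb = max(rxn.lb, 0.0)
    return out


def open_exchanges(model: MetabolicModel, bound: float = DEFAULT_BOUND) -> MetabolicModel:
    """Copy of the model with every exchange fully open (±``bound``)."""
    out = model.copy()
    for rxn_id in out.exchanges:
        rxn = out.reactions[rxn_id]
        rxn.lb, rxn.ub = -bound, bound
    return out


class LinearProblem:
    """Stoichiometry compiled once for repeated LP solves on one model.

    Variables are reaction fluxes in model order; the equality system is the
    mass balance S·v = 0.
    """

    def __init__(self, model: MetabolicModel):
        self.rxn_ids = list(model.reactions)
        self.met_ids = list(model.metabolites)
        self.rxn_index = {r: i for i, r in enumerate(self.rxn_ids)}
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        rows, cols, vals = [], [], []
        for j, rxn_id in enumerate(self.rxn_ids):
            for met_id, coef in model.reactions[rxn_id].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_ids), len(self.rxn_ids))
        )
        self.bounds = [
            (model.reactions[r].lb, model.reactions[r].ub) for r in self.rxn_ids
        ]

    def solve(
        self,
        c: np.ndarray,
        sense: str = "max",
        extra_A_ub: sparse.spmatrix | None = None,
        extra_b_ub: np.ndarray | None = None,
        bounds: list[tuple[float, float]] | None = None,
    ) -> FluxSolution:
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=bounds if bounds is not None else self.bounds,
            method="highs",
        )
        if res.status == 0:
            fluxes = dict(zip(self.rxn_ids, res.x))
            return FluxSolution("optimal", sign * res.fun, fluxes)
        if res.status == 3:
            return FluxSolution("unbounded", float("inf") if sense == "max" else float("-inf"))
        return FluxSolution("infeasible", 0.0)


def fba(
    model: MetabolicModel,
    sense: str = "max",
    objective_id: str | None = None,
    lp: LinearProblem | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    Infeasibility and unboundedness are reported in the solution status,
    never raised.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("model has no objective and none was given")
    lp = lp or LinearProblem(model)
    c = np.zeros(len(lp.rxn_ids))
    c[lp.rxn_index[objective_id]] = 1.0
    return lp.solve(c, sense=sense)


def fva(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    objective_fraction: float = 0.0,
    lp: LinearProblem | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction minimum and maximum feasible flux.

    With ``objective_fraction > 0`` the flux space is first restricted to
    solutions achieving at least that fraction of the FBA optimum; fraction 0
    probes pure feasibility (the mode used for blocked-reaction detection).
    """
    lp = lp or LinearProblem(model)
    targets = reactions if reactions is not None else list(lp.rxn_ids)
    extra_A = extra_b = None
    if objective_fraction > 0.0:
        opt = fba(model, lp=lp)
        if not opt.ok:
            raise ValueError(f"model is {opt.status}; cannot run constrained FVA")
        c = np.zeros(len(lp.rxn_ids))
        c[lp.rxn_index[model.objective_id]] = 1.0
        extra_A = sparse.csr_matrix(-c)
        extra_b = np.array([-objective_fraction * opt.objective_value])
    out: dict[str, tuple[float, float]] = {}
    for rxn_id in targets:
        c = np.zeros(len(lp.rxn_ids))
        c[lp.rxn_index[rxn_id]] = 1.0
        lo = lp.solve(c, "min", extra_A, extra_b)
        hi = lp.solve(c, "max", extra_A, extra_b)
        if not (lo.ok and hi.ok):
            raise ValueError(f"FVA subproblem for {rxn_id} was {lo.status}/{hi.status}")
        out[rxn_id] = (lo.objective_value, hi.objective_value)
    return out


def blocked_and_deadends(
    model: MetabolicModel, tol: float = FLUX_TOL
) -> tuple[set[str], set[str]]:
    """Blocked reactions and dead-end metabolites with all exchanges open.

    A reaction is blocked when neither direction can carry more than ``tol``
    flux in any steady state.  A metabolite is a dead end when the non-blocked
    reactions cannot both produce and consume it (reversibility-aware).
    """
    opened = open_exchanges(model)
    ranges = fva(opened)
    blocked = {
        r for r, (lo, hi) in ranges.items() if abs(lo) < tol and abs(hi) < tol
    }
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in opened.reactions.values():
        if rxn.id in blocked:
            continue
        for met_id, coef in rxn.stoichiometry.items():
            if (coef > 0 and rxn.ub > tol) or (coef < 0 and rxn.lb < -tol):
                producible.add(met_id)
            if (coef < 0 and rxn.ub > tol) or (coef > 0 and rxn.lb < -tol):
                consumable.add(met_id)
    deadends = {
        m for m in model.metabolites if not (m in producible and m in consumable)
    }
    return blocked, deadends


def knockout_bounds(model: MetabolicModel, genes: str | set[str]) -> MetabolicModel:
    """Copy of the model with reactions lost by deleting ``genes`` shut off.

    A reaction is shut (lb = ub = 0) when its GPR is satisfied with the full
    gene set but no longer satisfied once the deleted genes are absent.
    """
    deleted = {genes} if isinstance(genes, str) else set(genes)
    model_genes = model.genes
    unknown = deleted - model_genes
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    remaining = model_genes - deleted
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.gpr is EMPTY:
            continue
        if eval_gpr(rxn.gpr, model_genes) and not eval_gpr(rxn.gpr, remaining):
            rxn.lb = rxn.ub = 0.0
    return out
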