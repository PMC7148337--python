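"""Minimal / maximal model assembly with flux-consistency gap filling.

The minimal reconstruction keeps the core (gene-evidence) reactions plus the
smallest set of non-core candidates needed for every core reaction to carry
flux; the maximal reconstruction keeps the core plus all non-core candidates.
Gap filling follows the LP-sweep strategy of the FASTCORE family: find an
L1-cheap candidate support for each unsatisfied core reaction, then compact
the union so that no added reaction is removable.  Compactness (no removable
addition) is guaranteed; global minimum cardinality is checked only against
brute-force enumeration on small instances in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .analysis import FLUX_TOL, LinearProblem, blocked_and_deadends, open_exchanges
from .model import MetabolicModel
from .orthology import CorePartition

__all__ = [
    "GapfillResult",
    "consistent_subnetwork",
    "minimal_gapfill",
    "assemble_models",
    "save_gapfill_result",
]

EPSILON_DEFAULT = 1e-4  # minimum flux a core reaction must be able to carry


@dataclass
class GapfillResult:
    added: list[str]
    epsilon: float
    certified_consistent: bool
    unfillable: list[str] = field(default_factory=list)
    weights: dict[str, float] = field(default_factory=dict)


def save_gapfill_result(result: GapfillResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "reaction_id": result.added,
            "weight": [result.weights.get(r, 1.0) for r in result.added],
            "order_added": range(len(result.added)),
        }
    ).to_csv(path, sep="\t", index=False)


def consistent_subnetwork(model: MetabolicModel, tol: float = FLUX_TOL) -> MetabolicModel:
    """Restrict the model to its flux-consistent part.

    Blocked reactions are removed and the test repeated until a fixed point;
    the result has an empty blocked set.  An entirely blocked model returns
    with no reactions and a warning.
    """
    current = model.copy()
    while current.reactions:
        blocked, _ = blocked_and_deadends(current, tol)
        if not blocked:
            return current
        keep = [r for r in current.reactions if r not in blocked]
        if not keep:
            break
        current = current.subset(keep, model_id=current.id)
    warnings.warn(f"{model.id}: every reaction is blocked; returning empty model")
    return MetabolicModel(model.id, list(model.metabolites.values()), [])


def _max_abs_flux(lp: LinearProblem, rxn_id: str) -> float:
    c = np.zeros(len(lp.rxn_ids))
    c[lp.rxn_index[rxn_id]] = 1.0
    hi = lp.solve(c, "max")
    lo = lp.solve(c, "min")
    vals = [abs(s.objective_value) for s in (hi, lo) if s.ok]
    return max(vals) if vals else 0.0


def _core_satisfiable(lp: LinearProblem, core_ids, epsilon: float) -> bool:
    return all(_max_abs_flux(lp, r) >= epsilon - 1e-9 for r in core_ids)


def _support_lp(
    lp: LinearProblem,
    candidate_ids: list[str],
    weights: dict[str, float],
    target: str,
    epsilon: float,
    direction: int,
):
    """Min Σ wⱼ|vⱼ| over candidates s.t. S·v = 0, bounds, v_target ≥ ε
    (or ≤ −ε).  Returns the flux dict or None if infeasible."""
    n = len(lp.rxn_ids)
    k = len(candidate_ids)
    c = np.zeros(n + k)
    for j, rxn_id in enumerate(candidate_ids):
        c[n + j] = weights.get(rxn_id, 1.0)
    # t_j >= |v_j| :  v_j - t_j <= 0  and  -v_j - t_j <= 0
    rows, cols, vals = [], [], []
    for j, rxn_id in enumerate(candidate_ids):
        vi = lp.rxn_index[rxn_id]
        rows += [2 * j, 2 * j, 2 * j + 1, 2 * j + 1]
        cols += [vi, n + j, vi, n + j]
        vals += [1.0, -1.0, -1.0, -1.0]
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(2 * k, n + k))
    b_ub = np.zeros(2 * k)
    A_eq = sparse.hstack([lp.S, sparse.csr_matrix((lp.S.shape[0], k))]).tocsr()

    bounds = list(lp.bounds) + [(0.0, None)] * k
    ti = lp.rxn_index[target]
    lo, hi = bounds[ti]
    bounds[ti] = (max(lo, epsilon), hi) if direction > 0 else (lo, min(hi, -epsilon))
    if bounds[ti][0] > bounds[ti][1]:
        return None

    from scipy.optimize import linprog

    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    return dict(zip(lp.rxn_ids, res.x[:n]))


def minimal_gapfill(
    model: MetabolicModel,
    core_ids: set[str],
    candidate_ids: set[str],
    weights: dict[str, float] | None = None,
    epsilon: float = EPSILON_DEFAULT,
) -> GapfillResult:
    """Smallest compact set of candidates rescuing flux through every core.

    Works on the sub-model core ∪ candidates with all exchanges opened.  Per
    unsatisfied core reaction an L1-weighted support LP selects cheap
    candidates; the union is then compacted by attempting to drop each added
    reaction (lexicographic order, for determinism) while keeping every core
    reaction able to carry |flux| ≥ ε individually.  Core reactions that
    cannot reach ε even with all candidates are reported as unfillable, never
    silently dropped.  Zero-weight candidates are always admissible at no
    cost (used for reference-consistency keepers).
    """
    weights = dict(weights or {})
    outside = (core_ids | candidate_ids) - set(model.reactions)
    if outside:
        raise KeyError(f"ids outside the model: {sorted(outside)}")
    universe = open_exchanges(model.subset(sorted(core_ids | candidate_ids)))
    full_lp = LinearProblem(universe)
    cand_sorted = sorted(candidate_ids)

    added: set[str] = set()
    unfillable: list[str] = []
    order: list[str] = []

    def lp_for(reactions: set[str]) -> LinearProblem:
        return LinearProblem(universe.subset(sorted(reactions)))

    for core in sorted(core_ids):
        current = lp_for(core_ids | added)
        if _max_abs_flux(current, core) >= epsilon - 1e-9:
            continue
        if _max_abs_flux(full_lp, core) < epsilon - 1e-9:
            unfillable.append(core)
            continue
        support = _support_lp(full_lp, cand_sorted, weights, core, epsilon, +1)
        alt = _support_lp(full_lp, cand_sorted, weights, core, epsilon, -1)
        if support is None or (
            alt is not None
            and sum(weights.get(r, 1.0) * abs(alt[r]) for r in cand_sorted)
            < sum(weights.get(r, 1.0) * abs(support[r]) for r in cand_sorted) - 1e-9
        ):
            support = alt
        if support is None:
            unfillable.append(core)
            continue
        for rxn_id in cand_sorted:
            if rxn_id not in added and abs(support[rxn_id]) > 1e-7:
                added.add(rxn_id)
                order.append(rxn_id)

    # compaction: drop any added reaction whose removal keeps all cores alive
    for rxn_id in sorted(added):
        trial = added - {rxn_id}
        if _core_satisfiable(lp_for(core_ids | trial),
                             [c for c in sorted(core_ids) if c not in unfillable],
                             epsilon):
            added = trial
            order.remove(rxn_id)

    fillable = [c for c in sorted(core_ids) if c not in unfillable]
    certified = not unfillable and _core_satisfiable(
        lp_for(core_ids | added), fillable, epsilon
    )
    return GapfillResult(
        added=sorted(added),
        epsilon=epsilon,
        certified_consistent=certified,
        unfillable=unfillable,
        weights={r: weights.get(r, 1.0) for r in sorted(added)},
    )


def assemble_models(
    reference: MetabolicModel,
    partition: CorePartition,
    gapfill: GapfillResult,
) -> tuple[MetabolicModel, MetabolicModel]:
    """Assemble the minimal (core + gap-fill additions) and maximal
    (core + all non-core) reconstructions from one reference."""
    stray = set(gapfill.added) - partition.non_core
    if stray:
        raise ValueError(
            f"gap-fill additions outside the non-core partition: {sorted(stray)}"
        )
    missing = (partition.core | partition.non_core) - set(reference.reactions)
    if missing:
        raise ValueError(f"partition references unknown reactions: {sorted(missing)}")
    min_model = reference.subset(
        sorted(partition.core | set(gapfill.added)), model_id=f"{reference.id}_min"
    )
    max_model = reference.subset(
        sorted(partition.core | partition.non_core), model_id=f"{reference.id}_max"
    )
    return min_model, max_model
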