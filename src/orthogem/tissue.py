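"""Context-specific model extraction by expression-ranked pruning (modified mCADRE).

Reactions are scored by the ubiquity of their genes propagated through the
GPR (AND → min, OR → max) and by a connectivity score (mean expression score
of adjacent reactions).  Reactions scoring at or above the core threshold
form the tissue core; the rest are removed one by one, worst-evidence first,
and a removal is rolled back when it would

* make a key metabolite non-producible from glucose under the pruning
  medium (function check),
* block a core reaction (consistency check), or
* drop the biomass optimum under the growth medium below a fraction
  (default 80%) of the genome-scale model's optimum (biomass-production
  check, the guard added on top of classic mCADRE).

Reaction confidence scores are not used in the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    FLUX_TOL,
    LinearProblem,
    Medium,
    apply_medium,
    fba,
    open_exchanges,
)
from .gpr import EMPTY, And, FalseLeaf, Gpr, Leaf, Or
from .model import MetabolicModel
from .validation import FunctionalTest, run_mct

__all__ = [
    "ReactionScore",
    "PruneConfig",
    "score_reactions",
    "rank_and_partition",
    "prune_model",
    "extract_tissue_model",
]

# metabolites whose sharing does not count as adjacency (compartment-stripped)
CURRENCY_METABOLITES = {"h", "h2o", "atp", "adp", "pi", "nad", "nadh"}


@dataclass
class ReactionScore:
    reaction_id: str
    expression_score: float
    connectivity_score: float


@dataclass
class PruneConfig:
    core_threshold: float = 0.5
    biomass_fraction: float = 0.8
    key_metabolites: list[str] = field(default_factory=list)
    glucose_id: str = "glc_e"  # source metabolite for key-metabolite checks
    medium_name: str = "HAM"
    currency_metabolites: set[str] = field(
        default_factory=lambda: set(CURRENCY_METABOLITES)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.core_threshold <= 1.0:
            raise ValueError("core_threshold must be in [0, 1]")
        if not 0.0 <= self.biomass_fraction <= 1.0:
            raise ValueError("biomass_fraction must be in [0, 1]")


def _gpr_score(rule: Gpr, ubiquity: dict[str, float]) -> float:
    if rule is EMPTY or isinstance(rule, FalseLeaf):
        return 0.0
    if isinstance(rule, Leaf):
        return float(ubiquity.get(rule.gene, 0.0))
    child_scores = [_gpr_score(c, ubiquity) for c in rule.children]
    if isinstance(rule, And):
        return min(child_scores)
    if isinstance(rule, Or):
        return max(child_scores)
    raise TypeError(f"not a GPR node: {rule!r}")


def _strip_compartment(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0] if "_" in met_id else met_id


def score_reactions(
    model: MetabolicModel,
    ubiquity: pd.Series | dict[str, float],
    currency: set[str] | None = None,
) -> list[ReactionScore]:
    """Expression and connectivity scores for every reaction.

    The expression score propagates gene ubiquities through the GPR with
    AND = min and OR = max (complex limited by its scarcest subunit, isozyme
    set carried by its commonest member); reactions without gene association
    score 0.  The connectivity score of a reaction is the mean expression
    score of its adjacent reactions, adjacency meaning a shared non-currency
    metabolite; isolated reactions score 0.  Genes missing from the ubiquity
    vector count as never expressed.
    """
    if isinstance(ubiquity, pd.Series):
        ubiquity = ubiquity.to_dict()
    currency = currency if currency is not None else CURRENCY_METABOLITES
    expr = {
        rxn.id: _gpr_score(rxn.gpr, ubiquity) for rxn in model.reactions.values()
    }
    by_met: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        for met_id in rxn.stoichiometry:
            if _strip_compartment(met_id) in currency:
                continue
            by_met.setdefault(met_id, set()).add(rxn.id)
    scores = []
    for rxn_id in model.reactions:
        neighbours: set[str] = set()
        for met_id in model.reactions[rxn_id].stoichiometry:
            neighbours |= by_met.get(met_id, set())
        neighbours.discard(rxn_id)
        conn = float(np.mean([expr[n] for n in sorted(neighbours)])) if neighbours else 0.0
        scores.append(ReactionScore(rxn_id, expr[rxn_id], conn))
    return scores


def rank_and_partition(
    scores: list[ReactionScore], config: PruneConfig
) -> tuple[set[str], list[str]]:
    """Split scored reactions into the tissue core and an ordered removal list.

    Core: expression score at or above the threshold (inclusive).  Non-core
    reactions are ranked for removal worst first: ascending expression score,
    ties by ascending connectivity score, remaining ties lexicographic by id.
    """
    core = {s.reaction_id for s in scores if s.expression_score >= config.core_threshold}
    removal = sorted(
        (s for s in scores if s.reaction_id not in core),
        key=lambda s: (s.expression_score, s.connectivity_score, s.reaction_id),
    )
    return core, [s.reaction_id for s in removal]


def _cores_unblocked(
    model: MetabolicModel, core_ids: set[str], tol: float
) -> bool:
    opened = open_exchanges(model)
    lp = LinearProblem(opened)
    for core in sorted(core_ids):
        c = np.zeros(len(lp.rxn_ids))
        c[lp.rxn_index[core]] = 1.0
        hi = lp.solve(c, "max")
        if hi.ok and hi.objective_value >= tol:
            continue
        lo = lp.solve(c, "min")
        if not (lo.ok and lo.objective_value <= -tol):
            return False
    return True


def _function_intact(
    model: MetabolicModel, config: PruneConfig, media: dict[str, Medium], tol: float
) -> bool:
    for met_id in config.key_metabolites:
        test = FunctionalTest(
            id=f"key_{met_id}",
            kind="MCT",
            sources=[config.glucose_id],
            targets=[met_id],
            medium=config.medium_name,
        )
        if run_mct(model, test, media, tol).status != "pass":
            return False
    return True


def prune_model(
    model: MetabolicModel,
    core_ids: set[str],
    removal_list: list[str],
    config: PruneConfig,
    media: dict[str, Medium],
    tol: float = FLUX_TOL,
) -> tuple[MetabolicModel, list[tuple[str, str, str]]]:
    """Sequentially prune ranked non-core reactions under the three guards.

    Returns the tissue model and a trace covering every candidate exactly
    once: (reaction id, removed|retained, ok|breaks_function|
    breaks_consistency|breaks_biomass).  Requires the input model to grow
    under the configured medium.
    """
    growth_medium = media[config.medium_name]
    wild = fba(apply_medium(model, growth_medium, policy="all"))
    if not wild.ok or wild.objective_value <= tol:
        raise ValueError(
            f"{model.id}: no biomass production under {config.medium_name}; "
            "cannot prune"
        )
    floor = config.biomass_fraction * wild.objective_value

    current = model.copy()
    trace: list[tuple[str, str, str]] = []
    for rxn_id in removal_list:
        trial = current.subset(
            [r for r in current.reactions if r != rxn_id], model_id=current.id
        )
        if not _function_intact(trial, config, media, tol):
            trace.append((rxn_id, "retained", "breaks_function"))
            continue
        if not _cores_unblocked(trial, core_ids & set(trial.reactions), tol):
            trace.append((rxn_id, "retained", "breaks_consistency"))
            continue
        growth = fba(apply_medium(trial, growth_medium, policy="all"))
        if not growth.ok or growth.objective_value < floor - 1e-9:
            trace.append((rxn_id, "retained", "breaks_biomass"))
            continue
        current = trial
        trace.append((rxn_id, "removed", "ok"))
    return current, trace


def extract_tissue_model(
    model: MetabolicModel,
    ubiquity: pd.Series | dict[str, float],
    config: PruneConfig,
    media: dict[str, Medium],
) -> tuple[MetabolicModel, list[tuple[str, str, str]]]:
    """Score, rank and prune in one call."""
    scores = score_reactions(model, ubiquity, config.currency_metabolites)
    core, removal = rank_and_partition(scores, config)
    return prune_model(model, core, removal, config, media)
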