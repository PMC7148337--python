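"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is the stoichiometric universe every pipeline stage
operates on: metabolites, reactions with flux bounds and GPR rules, and a
biomass objective.  Fluxes follow the mmol·gDW⁻¹·h⁻¹ convention; exchange
reactions are written as single-metabolite drains (``met →``), so negative
flux means uptake.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

from .gpr import EMPTY, Gpr, gpr_genes, gpr_to_string

__all__ = ["Metabolite", "Reaction", "MetabolicModel", "FluxSolution"]

DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not self.compartment and "_" in self.id:
            self.compartment = self.id.rsplit("_", 1)[1]


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    gpr: Gpr = EMPTY
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def gpr_string(self) -> str:
        return gpr_to_string(self.gpr)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """Ordered collection of metabolites and reactions with one objective.

    Insertion order is preserved; lookups are by id.  The gene set is derived
    from the union of GPR leaves and never stored independently.
    """

    def __init__(
        self,
        model_id: str = "model",
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        objective_id: str | None = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id: str | None = None
        for met in metabolites or []:
            self.add_metabolite(met)
        for rxn in reactions or []:
            self.add_reaction(rxn)
        if objective_id is not None:
            self.set_objective(objective_id)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]
        if self.objective_id == rxn_id:
            self.objective_id = None

    def set_objective(self, rxn_id: str) -> None:
        if rxn_id not in self.reactions:
            raise ValueError(f"objective {rxn_id!r} is not a reaction in the model")
        self.objective_id = rxn_id

    # -- views ------------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def subset(self, reaction_ids, model_id: str | None = None) -> "MetabolicModel":
        """Deep-copied model restricted to ``reaction_ids`` (order preserved)
        and to the metabolites they touch."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise KeyError(f"unknown reaction ids: {sorted(missing)}")
        rxns = [_copy.deepcopy(r) for r in self.reactions.values() if r.id in keep]
        met_ids = {m for r in rxns for m in r.stoichiometry}
        mets = [
            _copy.deepcopy(m) for m in self.metabolites.values() if m.id in met_ids
        ]
        sub = MetabolicModel(model_id or self.id, mets, rxns)
        if self.objective_id in keep:
            sub.set_objective(self.objective_id)
        return sub

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- checks -----------------------------------------------------------
    def validate(self) -> None:
        """Raise on broken structural invariants."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
            if rxn.lb > rxn.ub:
                raise ValueError(f"reaction {rxn.id}: lb > ub")
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValueError(f"objective {self.objective_id} unresolved")

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )
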