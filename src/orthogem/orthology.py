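"""Reference-to-target GPR translation, reaction classification and curation.

A reference model (e.g. a human reconstruction) is mapped to a target
organism through a gene orthology table.  Each reaction is classified as
NGA (non-gene-associated), GAHM (gene-associated with orthologues in both
organisms — its GPR remains satisfiable after translation) or GAH
(gene-associated in the reference only — translation falsifies the GPR).
GAH reactions require an explicit curation decision: keep with a corrected
GPR, remove from both models, or demote to non-gene-associated status.
The outcome is a partition into core reactions (kept on gene evidence, plus
curated additions and designated artificial reactions such as biomass and
ATP maintenance) and non-core candidates.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gpr import (
    EMPTY,
    And,
    FalseLeaf,
    Gpr,
    Leaf,
    Or,
    eval_gpr,
    make_and,
    make_or,
    parse_gpr,
)
from .model import Metabolite, MetabolicModel, Reaction

__all__ = [
    "OrthologyMap",
    "CurationDecision",
    "CorePartition",
    "load_orthology_map",
    "load_curation_decisions",
    "load_reaction_additions",
    "translate_gpr",
    "classify_reaction",
    "apply_curation",
    "add_curated_reactions",
    "prune_false_markers",
]

PROVENANCE_TAGS = {"homologene", "gene_record", "kegg_ko", "ensembl", "manual"}


@dataclass
class OrthologyMap:
    """Source gene → set of (target gene, provenance) pairs.

    Absence of a key means the source gene has no orthologue.  A gene mapped
    one-to-many normally translates to an OR over all targets; an entry in
    ``resolved`` overrides that with a single curated target.
    """

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    resolved: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for source, pairs in self.entries.items():
            if not pairs:
                raise ValueError(f"empty target set stored for {source!r}")
            for target, provenance in pairs:
                if provenance not in PROVENANCE_TAGS:
                    raise ValueError(
                        f"{source}→{target}: unknown provenance {provenance!r}"
                    )

    def targets(self, source: str) -> list[str]:
        if source in self.resolved:
            return [self.resolved[source]]
        return sorted({t for t, _ in self.entries.get(source, set())})

    @property
    def mapped_sources(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass
class CurationDecision:
    reaction_id: str
    action: str  # keep_with_gpr | remove | demote_to_non_gene
    corrected_gpr: str = ""
    category: str = ""  # GAH1 | GAH2 | GAH3 | specific_addition
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.action not in {"keep_with_gpr", "remove", "demote_to_non_gene"}:
            raise ValueError(f"{self.reaction_id}: unknown action {self.action!r}")
        if self.action == "keep_with_gpr":
            parse_gpr(self.corrected_gpr)  # must parse


@dataclass
class CorePartition:
    core: set[str]
    non_core: set[str]
    classification: dict[str, str]  # reaction id -> NGA | GAHM | GAH

    def __post_init__(self) -> None:
        overlap = self.core & self.non_core
        if overlap:
            raise ValueError(f"core/non-core overlap: {sorted(overlap)}")


def load_orthology_map(path: str | Path) -> OrthologyMap:
    """Read the orthology TSV (source_gene, target_gene, provenance[, resolved])."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries: dict[str, set[tuple[str, str]]] = {}
    resolved: dict[str, str] = {}
    for row in table.itertuples(index=False):
        entries.setdefault(row.source_gene, set()).add(
            (row.target_gene, row.provenance)
        )
        if getattr(row, "resolved", "") in {"1", "true", "True"}:
            resolved[row.source_gene] = row.target_gene
    return OrthologyMap(entries, resolved)


def load_curation_decisions(path: str | Path) -> list[CurationDecision]:
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        CurationDecision(
            reaction_id=row.reaction_id,
            action=row.action,
            corrected_gpr=row.corrected_gpr,
            category=row.category,
            rationale=row.rationale,
        )
        for row in table.itertuples(index=False)
    ]


def load_reaction_additions(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["additions"]


# ---------------------------------------------------------------------------
# Translation and classification
# ---------------------------------------------------------------------------


def translate_gpr(rule: Gpr, orthology: OrthologyMap) -> tuple[Gpr, set[str]]:
    """Translate a GPR into the target gene namespace.

    A leaf with k ≥ 1 orthologues becomes an OR over the k target genes
    (a plain leaf when k = 1); a leaf without orthologues is reported in the
    unmapped set and replaced by a FALSE-marker leaf that is kept in the tree
    so that downstream classification and curation can see exactly which
    genes failed.
    """
    unmapped: set[str] = set()

    def walk(node: Gpr) -> Gpr:
        if node is EMPTY:
            return EMPTY
        if isinstance(node, FalseLeaf):
            return node
        if isinstance(node, Leaf):
            targets = orthology.targets(node.gene)
            if not targets:
                unmapped.add(node.gene)
                return FalseLeaf(node.gene)
            if len(targets) == 1:
                return Leaf(targets[0])
            return make_or([Leaf(t) for t in targets])
        children = [walk(c) for c in node.children]
        return make_and(children) if isinstance(node, And) else make_or(children)

    return walk(rule), unmapped


def classify_reaction(rxn: Reaction, orthology: OrthologyMap) -> str:
    """NGA / GAHM / GAH classification of one reaction.

    Orthologue existence is read as a truth value per source gene; a reaction
    whose GPR stays satisfiable is gene-associated in both organisms (GAHM),
    one whose GPR is falsified is gene-associated in the reference only (GAH).
    """
    if rxn.gpr is EMPTY:
        return "NGA"
    present = {g for g in rxn.genes if orthology.targets(g)}
    return "GAHM" if eval_gpr(rxn.gpr, present) else "GAH"


class FalsifiedGprError(ValueError):
    pass


_FALSIFIED = object()


def prune_false_markers(rule: Gpr):
    """Remove FALSE-marker leaves: under OR the marker is dropped, a marker
    that would falsify an AND (or the whole rule) is unrecoverable and
    returns the ``_FALSIFIED`` sentinel."""
    if isinstance(rule, FalseLeaf):
        return _FALSIFIED
    if isinstance(rule, And):
        children = [prune_false_markers(c) for c in rule.children]
        if any(c is _FALSIFIED for c in children):
            return _FALSIFIED
        return make_and(children)
    if isinstance(rule, Or):
        children = [
            c for c in (prune_false_markers(x) for x in rule.children)
            if c is not _FALSIFIED
        ]
        if not children:
            return _FALSIFIED
        return make_or(children) if len(children) > 1 else children[0]
    return rule


def apply_curation(
    model: MetabolicModel,
    orthology: OrthologyMap,
    decisions: list[CurationDecision],
    artificial_ids: tuple[str, ...] = (),
    addition_ids: tuple[str, ...] = (),
) -> tuple[MetabolicModel, CorePartition]:
    """Translate the model and partition reactions into core and non-core.

    Core = satisfiable gene-associated reactions (GAHM) ∪ reactions kept by a
    corrected-GPR decision ∪ curated specific additions ∪ designated
    artificial reactions (biomass, ATP maintenance).  Non-core = NGA ∪
    reactions demoted to non-gene status.  ``remove`` decisions delete the
    reaction entirely.  Every GAH reaction must be covered by a decision;
    this mirrors the manual triage obligation.  Idempotent.
    """
    by_reaction = {d.reaction_id: d for d in decisions}
    unknown = [
        d.reaction_id
        for d in decisions
        if d.reaction_id not in model.reactions and d.category != "specific_addition"
    ]
    if unknown:
        raise KeyError(f"curation decisions for unknown reactions: {sorted(unknown)}")

    classification: dict[str, str] = {
        rxn.id: classify_reaction(rxn, orthology) for rxn in model.reactions.values()
    }
    uncovered = [
        r
        for r, cls in classification.items()
        if cls == "GAH" and r not in by_reaction and r not in artificial_ids
    ]
    if uncovered:
        raise ValueError(
            "GAH reactions without a curation decision: " + ", ".join(sorted(uncovered))
        )

    out = MetabolicModel(model.id)
    for met in model.metabolites.values():
        out.add_metabolite(_copy.deepcopy(met))
    core: set[str] = set()
    non_core: set[str] = set()
    for rxn in model.reactions.values():
        decision = by_reaction.get(rxn.id)
        new_rxn = _copy.deepcopy(rxn)
        if decision is not None and decision.action == "remove":
            continue
        if decision is not None and decision.action == "demote_to_non_gene":
            new_rxn.gpr = EMPTY
            non_core.add(rxn.id)
        elif decision is not None and decision.action == "keep_with_gpr":
            corrected = parse_gpr(decision.corrected_gpr)
            translated, _ = translate_gpr(corrected, orthology)
            pruned = prune_false_markers(translated)
            if pruned is _FALSIFIED:
                raise FalsifiedGprError(
                    f"{rxn.id}: corrected GPR still unsatisfiable after translation"
                )
            new_rxn.gpr = pruned
            core.add(rxn.id)
        elif rxn.id in artificial_ids or rxn.id in addition_ids:
            translated, _ = translate_gpr(rxn.gpr, orthology)
            pruned = prune_false_markers(translated)
            new_rxn.gpr = EMPTY if pruned is _FALSIFIED else pruned
            core.add(rxn.id)
        elif classification[rxn.id] == "GAHM":
            translated, _ = translate_gpr(rxn.gpr, orthology)
            pruned = prune_false_markers(translated)
            if pruned is _FALSIFIED:
                raise FalsifiedGprError(
                    f"{rxn.id}: classified GAHM but translation falsified the GPR"
                )
            new_rxn.gpr = pruned
            core.add(rxn.id)
        else:  # NGA, or GAH already handled above
            new_rxn.gpr = EMPTY
            non_core.add(rxn.id)
        out.add_reaction(new_rxn)
    if model.objective_id is not None and model.objective_id in out.reactions:
        out.set_objective(model.objective_id)
    return out, CorePartition(core, non_core, classification)


def add_curated_reactions(
    model: MetabolicModel, additions: list[dict]
) -> tuple[MetabolicModel, list[str]]:
    """Add curated organism-specific reactions (with their new metabolites).

    Each record carries id, stoichiometry, bounds, a GPR string in the target
    namespace and the records of any metabolites new to the model.  New
    metabolites left structurally dead-ended by the additions get an
    auto-generated reversible sink reaction so the additions cannot introduce
    new dead ends.  Returns the extended model and the list of added reaction
    ids (sinks included).
    """
    out = model.copy()
    added: list[str] = []
    new_mets: list[str] = []
    for record in additions:
        if record["id"] in out.reactions:
            raise ValueError(f"addition duplicates existing reaction id {record['id']!r}")
        for met in record.get("metabolites", []):
            if met["id"] not in out.metabolites:
                out.add_metabolite(
                    Metabolite(
                        id=met["id"],
                        name=met.get("name", ""),
                        compartment=met.get("compartment", ""),
                        formula=met.get("formula"),
                        charge=met.get("charge"),
                    )
                )
                new_mets.append(met["id"])
        unknown = set(record["stoichiometry"]) - set(out.metabolites)
        if unknown:
            raise KeyError(
                f"addition {record['id']}: unknown metabolites {sorted(unknown)} "
                "not included in the record"
            )
        out.add_reaction(
            Reaction(
                id=record["id"],
                name=record.get("name", ""),
                stoichiometry={k: float(v) for k, v in record["stoichiometry"].items()},
                lb=float(record.get("lower_bound", -1000.0)),
                ub=float(record.get("upper_bound", 1000.0)),
                gpr=parse_gpr(record.get("gene_reaction_rule", "")),
                subsystem=record.get("subsystem", ""),
            )
        )
        added.append(record["id"])

    # structural producibility/consumability over the whole extended model
    for met_id in new_mets:
        produced = consumed = False
        for rxn in out.reactions.values():
            coef = rxn.stoichiometry.get(met_id)
            if coef is None:
                continue
            if (coef > 0 and rxn.ub > 0) or (coef < 0 and rxn.lb < 0):
                produced = True
            if (coef < 0 and rxn.ub > 0) or (coef > 0 and rxn.lb < 0):
                consumed = True
        if not (produced and consumed):
            sink_id = f"SK_{met_id}"
            if sink_id not in out.reactions:
                out.add_reaction(
                    Reaction(sink_id, {met_id: -1.0}, lb=-1000.0, ub=1000.0)
                )
                added.append(sink_id)
    return out, added
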