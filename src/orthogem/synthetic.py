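"""Synthetic study inputs: toy reference models, orthology maps, expression
calls, functional-test batteries and brute-force ground truth.

The generator emulates the shape of a reference human reconstruction and its
companion data so the whole pipeline is testable offline: a flux-consistent
toy model with compartments, transporters, AND/OR GPR rules, a biomass
reaction over several precursors and an ATP maintenance reaction; an
orthology map with tunable unmapped and one-to-many fractions; binarized
expression calls with planted tissue-active genes and planted decorrelated
outlier arrays; and lethal/viable gene labels derived by exhaustive
knockouts.

Every generator is a pure function of its configuration (the seed included).
Ground truths are computed by independent machinery — a local recursive GPR
evaluator and a locally formulated dense LP — never by the pipeline modules
they are used to test.

Topology of the toy network (always present; sizes vary with the config):
glucose uptake feeds a capacity-limited glycolysis producing pyruvate and a
little ATP; pyruvate is either fermented to exported lactate or respired
(oxygen-dependent, high ATP yield, mitochondrial when three compartments are
configured); ``n_pathways`` nutrient pathways convert imported amino-acid
like nutrients into biomass precursors, and even-numbered pathways also have
a redundant de-novo route from pyruvate and ammonium — genes on unique
routes are lethal, genes on redundant routes viable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import Medium
from .gpr import EMPTY, And, FalseLeaf, Gpr, Leaf, Or, parse_gpr
from .model import Metabolite, MetabolicModel, Reaction
from .orthology import CurationDecision, OrthologyMap
from .validation import FunctionalTest

__all__ = [
    "GeneratorConfig",
    "make_reference_model",
    "make_media",
    "make_orthology_map",
    "make_curation_decisions",
    "make_expression_calls",
    "make_truth_and_tests",
    "plant_orphan_branch",
    "make_workspace",
    "load_species_additions",
    "oracle_fba",
    "oracle_flux_range",
    "oracle_blocked",
    "oracle_lethal_genes",
    "oracle_eval_rule",
    "medium_bounds",
]

DATA_DIR = Path(__file__).parent / "data"

GLYCOLYSIS_CAP = 50.0  # enzyme-capacity cap separating fermentative/respiratory yields
LETHAL_RATIO = 0.30


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic inputs.

    Defaults give models of roughly 45–60 reactions and 30–50 genes — large
    enough for non-trivial gap filling and pruning, small enough for the
    exhaustive oracles.  Call probabilities: an active gene is called
    Present with probability 0.9 per sample, an inactive one with 0.1.
    """

    seed: int
    n_pathways: int = 4
    pathway_length: int = 3
    n_isozyme_genes: int = 8  # genes in OR (isozyme) pairs → that many /2 reactions
    n_complex_genes: int = 8  # genes in AND (complex) pairs
    n_compartments: int = 3
    noncore_fraction: float = 0.2
    unmapped_fraction: float = 0.08
    one2many_fraction: float = 0.15
    n_samples: int = 20
    outlier_count: int = 2
    tissue_active_fraction: float = 0.7
    p_call_active: float = 0.9
    p_call_inactive: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "noncore_fraction",
            "unmapped_fraction",
            "one2many_fraction",
            "tissue_active_fraction",
            "p_call_active",
            "p_call_inactive",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pathways < 1 or self.pathway_length < 1:
            raise ValueError("need at least one pathway of length >= 1")
        if self.n_compartments not in (2, 3):
            raise ValueError("n_compartments must be 2 or 3")


# ---------------------------------------------------------------------------
# Independent oracles (deliberately separate from the pipeline modules)
# ---------------------------------------------------------------------------


def oracle_eval_rule(rule: Gpr, present: set[str]) -> bool:
    """Reference truth-table evaluator, independent of gpr.eval_gpr."""
    if rule is EMPTY:
        return True
    if isinstance(rule, FalseLeaf):
        return False
    if isinstance(rule, Leaf):
        return rule.gene in present
    values = [oracle_eval_rule(c, present) for c in rule.children]
    return all(values) if isinstance(rule, And) else any(values)


def _dense_system(model: MetabolicModel, bound_overrides=None):
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    met_index = {m: i for i, m in enumerate(met_ids)}
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met_id, coef in rxn.stoichiometry.items():
            S[met_index[met_id], j] = coef
        lb, ub = rxn.lb, rxn.ub
        if bound_overrides and rid in bound_overrides:
            lb, ub = bound_overrides[rid]
        bounds.append((lb, ub))
    return rxn_ids, S, bounds


def _oracle_solve(S, bounds, c, sense):
    # equality via paired inequalities: an intentionally different encoding
    from scipy.optimize import linprog

    A_ub = np.vstack([S, -S])
    b_ub = np.zeros(2 * S.shape[0])
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * np.asarray(c), A_ub=A_ub, b_ub=b_ub, bounds=bounds,
                  method="highs")
    if res.status != 0:
        return None
    return sign * res.fun, res.x


def oracle_fba(model: MetabolicModel, objective_id: str | None = None,
               bound_overrides=None) -> float | None:
    rxn_ids, S, bounds = _dense_system(model, bound_overrides)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id or model.objective_id)] = 1.0
    out = _oracle_solve(S, bounds, c, "max")
    return None if out is None else out[0]


def oracle_flux_range(model: MetabolicModel, rxn_id: str,
                      bound_overrides=None) -> tuple[float, float]:
    rxn_ids, S, bounds = _dense_system(model, bound_overrides)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(rxn_id)] = 1.0
    lo = _oracle_solve(S, bounds, c, "min")
    hi = _oracle_solve(S, bounds, c, "max")
    if lo is None or hi is None:
        raise ValueError(f"oracle FVA infeasible for {rxn_id}")
    return lo[0], hi[0]


def oracle_blocked(model: MetabolicModel, tol: float = 1e-6) -> set[str]:
    """Blocked reactions with every exchange forced fully open."""
    overrides = {r: (-1000.0, 1000.0) for r in model.exchanges}
    out = set()
    for rxn_id in sorted(model.reactions):
        lo, hi = oracle_flux_range(model, rxn_id, overrides)
        if abs(lo) < tol and abs(hi) < tol:
            out.add(rxn_id)
    return out


def medium_bounds(model: MetabolicModel, medium: Medium) -> dict[str, tuple[float, float]]:
    """Exchange bound overrides implementing a medium (closure policy: all)."""
    overrides = {}
    for rxn_id in model.exchanges:
        rxn = model.reactions[rxn_id]
        if rxn_id in medium.always_open:
            continue
        if rxn_id in medium.bounds:
            overrides[rxn_id] = medium.bounds[rxn_id]
        else:
            overrides[rxn_id] = (max(rxn.lb, 0.0), rxn.ub)
    return overrides


def oracle_lethal_genes(
    model: MetabolicModel, medium: Medium, ratio: float = LETHAL_RATIO
) -> set[str]:
    """Exhaustive single-gene knockout FBA (independent LP formulation)."""
    overrides = medium_bounds(model, medium)
    wild = oracle_fba(model, bound_overrides=overrides)
    if wild is None or wild <= 1e-6:
        raise ValueError("wild type does not grow under the given medium")
    genes = sorted(model.genes)
    lethal: set[str] = set()
    for gene in genes:
        remaining = set(genes) - {gene}
        ko = dict(overrides)
        for rxn in model.reactions.values():
            if rxn.gpr is EMPTY:
                continue
            if oracle_eval_rule(rxn.gpr, set(genes)) and not oracle_eval_rule(
                rxn.gpr, remaining
            ):
                ko[rxn.id] = (0.0, 0.0)
        value = oracle_fba(model, bound_overrides=ko)
        if value is None or value < ratio * wild:
            lethal.add(gene)
    return lethal


# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------

_FORMULAS = {
    "glc": "C6H12O6", "pyr": "C3H3O3", "lac": "C3H5O3", "o2": "O2",
    "co2": "CO2", "h2o": "H2O", "h": "H", "pi": "HO4P", "nh4": "H4N",
    "atp": "C10H12N5O13P3", "adp": "C10H12N5O10P2", "nad": "C21H26N7O14P2",
    "nadh": "C21H27N7O14P2",
}


def _formula_for(base: str) -> str:
    if base in _FORMULAS:
        return _FORMULAS[base]
    return "C4H7NO2"  # generic organic nutrient / intermediate


def make_reference_model(config: GeneratorConfig) -> MetabolicModel:
    """Deterministic flux-consistent toy reference model.

    Raises if the generated model fails its own growth or consistency
    self-check (verified with the independent LP oracle).
    """
    rng = np.random.default_rng([config.seed, 0])
    mets: dict[str, Metabolite] = {}
    rxns: list[tuple[Reaction, bool]] = []  # (reaction, gene_eligible)

    def met(met_id: str) -> str:
        if met_id not in mets:
            base, comp = met_id.rsplit("_", 1)
            mets[met_id] = Metabolite(met_id, name=base, compartment=comp,
                                      formula=_formula_for(base))
        return met_id

    def rxn(rid, stoich, lb, ub, eligible, subsystem=""):
        stoich = {met(k): v for k, v in stoich.items()}
        rxns.append((Reaction(rid, stoich, lb, ub, subsystem=subsystem), eligible))

    mito = config.n_compartments >= 3
    nutrients = ["glc", "o2", "pi", "nh4"] + [
        f"aa{i}" for i in range(1, config.n_pathways + 1)
    ]
    for base in nutrients + ["co2", "lac", "pyr", "h2o", "h"]:
        rxn(f"EX_{base}_e", {f"{base}_e": -1.0}, -1000.0, 1000.0, False, "exchange")

    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, True, "transport")
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, True, "transport")
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, True, "transport")
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, 0, 1000, True, "transport")
    rxn("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, True, "transport")
    rxn("LACt", {"lac_c": -1, "lac_e": 1}, 0, 1000, True, "transport")
    rxn("PYRt", {"pyr_c": -1, "pyr_e": 1}, 0, 1000, True, "transport")
    rxn("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, False, "transport")
    rxn("Ht", {"h_e": -1, "h_c": 1}, -1000, 1000, False, "transport")

    rxn(
        "GLY",
        {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
         "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
        0, GLYCOLYSIS_CAP, True, "glycolysis",
    )
    rxn(
        "LDH",
        {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1},
        0, 1000, True, "fermentation",
    )
    # oxygen-dependent NADH re-oxidation decoupled from pyruvate, so redox
    # balance does not lock pyruvate to its downstream consumers
    rxn(
        "NADHox",
        {"nadh_c": -1, "o2_c": -0.5, "h_c": -1, "nad_c": 1, "h2o_c": 1},
        0, 1000, True, "oxidase",
    )
    if mito:
        rxn("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, 1000, True, "transport")
        rxn("O2tm", {"o2_c": -1, "o2_m": 1}, 0, 1000, True, "transport")
        rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, 0, 1000, True, "transport")
        rxn("PItm", {"pi_c": -1, "pi_m": 1}, 0, 1000, True, "transport")
        rxn("ATPtm", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1},
            0, 1000, True, "transport")
        rxn(
            "RESP",
            {"pyr_m": -1, "o2_m": -3, "nadh_c": -1, "adp_m": -10, "pi_m": -10,
             "co2_m": 3, "nad_c": 1, "atp_m": 10},
            0, 1000, True, "respiration",
        )
    else:
        rxn(
            "RESP",
            {"pyr_c": -1, "o2_c": -3, "nadh_c": -1, "adp_c": -10, "pi_c": -10,
             "co2_c": 3, "nad_c": 1, "atp_c": 10},
            0, 1000, True, "respiration",
        )

    precursors = []
    for i in range(1, config.n_pathways + 1):
        rxn(f"AA{i}t", {f"aa{i}_e": -1, f"aa{i}_c": 1}, 0, 1000, True, "transport")
        prev = f"aa{i}_c"
        for k in range(1, config.pathway_length):
            nxt = f"p{i}x{k}_c"
            stoich = {prev: -1, nxt: 1}
            if k == 1:  # first step pays ATP
                stoich.update({"atp_c": -1, "adp_c": 1, "pi_c": 1})
            rxn(f"PW{i}_{k}", stoich, 0, 1000, True, f"pathway{i}")
            prev = nxt
        rxn(f"PW{i}_{config.pathway_length}", {prev: -1, f"prec{i}_c": 1},
            0, 1000, True, f"pathway{i}")
        precursors.append(f"prec{i}_c")
        if i % 2 == 0:  # redundant de-novo route (reductive amination)
            rxn(f"ALT{i}_1",
                {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1,
                 f"q{i}_c": 1, "nad_c": 1, "h2o_c": 1},
                0, 1000, True, f"alt{i}")
            rxn(f"ALT{i}_2",
                {f"q{i}_c": -1, "atp_c": -1, f"prec{i}_c": 1, "adp_c": 1, "pi_c": 1},
                0, 1000, True, f"alt{i}")

    biomass_stoich = {p: -1.0 for p in precursors}
    # ATP hydrolysis drives polymerisation; phosphate and ammonium are also
    # net-incorporated so their importers can carry steady-state flux
    biomass_stoich.update(
        {"atp_c": -10, "h2o_c": -5, "nh4_c": -1,
         "adp_c": 10, "pi_c": 8, "h_c": 5}
    )
    rxn("BIOMASS", biomass_stoich, 0, 1000, False, "biomass")
    rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        0, 1000, False, "maintenance")

    # GPR assignment: complexes, isozyme pairs, single genes
    eligible = [r.id for r, ok in rxns if ok]
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    n_complex = min(config.n_complex_genes // 2, len(order))
    n_isozyme = min(config.n_isozyme_genes // 2, max(len(order) - n_complex, 0))
    counter = 1000
    gprs: dict[str, Gpr] = {}

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return str(counter)

    for rid in order[:n_complex]:
        gprs[rid] = And((Leaf(fresh()), Leaf(fresh())))
    for rid in order[n_complex : n_complex + n_isozyme]:
        gprs[rid] = Or((Leaf(fresh()), Leaf(fresh())))
    for rid in order[n_complex + n_isozyme :]:
        gprs[rid] = Leaf(fresh())

    n_strip = int(np.floor(config.noncore_fraction * len(eligible)))
    stripped = set(
        rng.choice(sorted(eligible), size=n_strip, replace=False)
    ) if n_strip else set()

    model = MetabolicModel(f"synthref_seed{config.seed}")
    for m in mets.values():
        model.add_metabolite(m)
    for reaction, ok in rxns:
        if ok and reaction.id not in stripped:
            reaction.gpr = gprs[reaction.id]
        model.add_reaction(reaction)
    model.set_objective("BIOMASS")

    media = make_media(config)
    growth = oracle_fba(model, bound_overrides=medium_bounds(model, media["HAM"]))
    if growth is None or growth <= 1e-6:
        raise ValueError(
            f"generated model (seed {config.seed}) does not grow under HAM; "
            "regenerate with another seed"
        )
    blocked = oracle_blocked(model)
    if blocked:
        raise ValueError(
            f"generated model (seed {config.seed}) has blocked reactions: "
            f"{sorted(blocked)}"
        )
    return model


def plant_orphan_branch(
    model: MetabolicModel, n_reactions: int = 2, tag: str = "orphan"
) -> tuple[MetabolicModel, list[str], list[str]]:
    """Copy of the model with a planted inconsistent branch.

    The branch produces a chain of new metabolites ending in a dead end, so
    every branch reaction is blocked.  Returns (model, planted reaction ids,
    planted metabolite ids) as ground truth for consistency tests.
    """
    out = model.copy()
    planted_rxns, planted_mets = [], []
    prev = None
    for k in range(n_reactions):
        met_id = f"{tag}{k}_c"
        out.add_metabolite(Metabolite(met_id, compartment="c", formula="C2H4O2"))
        planted_mets.append(met_id)
        stoich = {met_id: 1.0} if prev is None else {prev: -1.0, met_id: 1.0}
        if prev is None:
            # produced from a real metabolite so the branch is attached
            stoich["pyr_c" if "pyr_c" in out.metabolites else sorted(out.metabolites)[0]] = -1.0
        rid = f"{tag.upper()}{k}"
        out.add_reaction(Reaction(rid, stoich, 0.0, 1000.0))
        planted_rxns.append(rid)
        prev = met_id
    return out, planted_rxns, planted_mets


def make_media(config: GeneratorConfig) -> dict[str, Medium]:
    """Synthetic growth media over the generated exchange namespace.

    HAM opens every nutrient exchange at ±1000; RPMI1640 is the leaner
    medium: glucose, oxygen, phosphate, ammonium and the odd-numbered
    nutrient set only.  Water and proton exchanges are always open.
    """
    always = {"EX_h2o_e", "EX_h_e"}
    wide = (-1000.0, 1000.0)
    ham = {f"EX_{b}_e": wide for b in ["glc", "o2", "pi", "nh4"]}
    ham.update({f"EX_aa{i}_e": wide for i in range(1, config.n_pathways + 1)})
    rpmi = {f"EX_{b}_e": wide for b in ["glc", "o2", "pi", "nh4"]}
    rpmi.update(
        {f"EX_aa{i}_e": wide for i in range(1, config.n_pathways + 1) if i % 2 == 1}
    )
    return {
        "HAM": Medium("HAM", ham, set(always)),
        "RPMI1640": Medium("RPMI1640", rpmi, set(always)),
    }


# ---------------------------------------------------------------------------
# Orthology map and curation
# ---------------------------------------------------------------------------

_PROVENANCE = ["homologene", "gene_record", "kegg_ko", "ensembl"]


def make_orthology_map(
    model: MetabolicModel, config: GeneratorConfig
) -> tuple[OrthologyMap, dict[str, str]]:
    """Orthology map plus the analytically expected class per reaction.

    Each source gene is unmapped with probability ``unmapped_fraction``,
    mapped one-to-two with probability ``one2many_fraction``, else
    one-to-one.  The expected NGA/GAHM/GAH classification is derived with
    the local truth-table evaluator, not the pipeline's.
    """
    rng = np.random.default_rng([config.seed, 1])
    entries: dict[str, set[tuple[str, str]]] = {}
    for gene in sorted(model.genes):
        u = rng.random()
        provenance = _PROVENANCE[rng.integers(len(_PROVENANCE))]
        if u < config.unmapped_fraction:
            continue
        if u < config.unmapped_fraction + config.one2many_fraction:
            entries[gene] = {(f"2{gene}", provenance), (f"3{gene}", "ensembl")}
        else:
            entries[gene] = {(f"2{gene}", provenance)}
    orthology = OrthologyMap(entries)
    mapped = set(entries)
    expected: dict[str, str] = {}
    for rxn in model.reactions.values():
        if rxn.gpr is EMPTY:
            expected[rxn.id] = "NGA"
        elif oracle_eval_rule(rxn.gpr, mapped & rxn.genes):
            expected[rxn.id] = "GAHM"
        else:
            expected[rxn.id] = "GAH"
    return orthology, expected


def make_curation_decisions(
    model: MetabolicModel,
    orthology: OrthologyMap,
    expected_classes: dict[str, str],
) -> tuple[list[CurationDecision], OrthologyMap]:
    """Curation table covering every GAH reaction.

    Cycles through the three triage outcomes: corrected-GPR keeps (a fresh
    functional source gene with a mapped orthologue, mirroring
    pseudogene-to-paralog corrections), removals (only when the oracle
    confirms the network stays consistent and growing), and demotions to
    non-gene status.  Returns the decisions and the orthology map extended
    with the correction genes.
    """
    gah = sorted(r for r, cls in expected_classes.items() if cls == "GAH")
    entries = {k: set(v) for k, v in orthology.entries.items()}
    decisions: list[CurationDecision] = []
    for idx, rxn_id in enumerate(gah):
        mode = idx % 3
        if mode == 0:
            fix_gene = f"9{1000 + idx}"
            entries[fix_gene] = {(f"2{fix_gene}", "manual")}
            decisions.append(
                CurationDecision(rxn_id, "keep_with_gpr", corrected_gpr=fix_gene,
                                 category="GAH1",
                                 rationale="reassigned to a functional paralog"))
            continue
        if mode == 1:
            trial = model.subset([r for r in model.reactions if r != rxn_id])
            safe = not oracle_blocked(trial)
            if safe and model.objective_id in trial.reactions:
                growth = oracle_fba(
                    trial,
                    bound_overrides={r: (-1000.0, 1000.0) for r in trial.exchanges},
                )
                safe = growth is not None and growth > 1e-6
            if safe:
                decisions.append(
                    CurationDecision(rxn_id, "remove", category="GAH2",
                                     rationale="no target-organism activity; removal keeps consistency"))
                continue
        decisions.append(
            CurationDecision(rxn_id, "demote_to_non_gene", category="GAH3",
                             rationale="reference-only gene evidence; needed for consistency"))
    return decisions, OrthologyMap(entries, dict(orthology.resolved))


# ---------------------------------------------------------------------------
# Expression calls
# ---------------------------------------------------------------------------


def make_expression_calls(
    genes: list[str], config: GeneratorConfig
) -> dict:
    """Expression intensities, P/M/A calls, probe map and planted truth.

    Regular samples measure one underlying transcriptome up to a per-sample
    affine gain/offset (so their pairwise Pearson correlation is exactly 1);
    planted outlier samples draw an independent activity pattern and
    decorrelate from the rest.  Calls are Present with probability
    ``p_call_active`` for tissue-active genes and ``p_call_inactive``
    otherwise; Marginal replaces a tenth of the non-Present calls.  Genes
    get 1–3 probes; two unmapped control probes are included.
    """
    if config.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng([config.seed, 2])
    genes = sorted(genes)
    n_active = int(round(config.tissue_active_fraction * len(genes)))
    active = set(rng.choice(genes, size=n_active, replace=False)) if n_active else set()

    probes: list[str] = []
    probe_map: dict[str, str] = {}
    for gene in genes:
        for k in range(int(rng.integers(1, 4))):
            probe = f"{gene}_pr{k}"
            probes.append(probe)
            probe_map[probe] = gene
    controls = ["AFFX_ctrl0", "AFFX_ctrl1"]
    probes.extend(controls)

    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    outliers = sorted(
        rng.choice(samples, size=config.outlier_count, replace=False)
    ) if config.outlier_count else []

    def base_profile(active_set: set[str]) -> np.ndarray:
        vals = []
        for probe in probes:
            gene = probe_map.get(probe)
            if gene is None:
                vals.append(7.0 + rng.uniform(-0.2, 0.2))
            else:
                centre = 10.0 if gene in active_set else 5.0
                vals.append(centre + rng.uniform(-0.5, 0.5))
        return np.array(vals)

    shared = base_profile(active)
    values = {}
    sample_active: dict[str, set[str]] = {}
    for sample in samples:
        gain = rng.uniform(0.8, 1.2)
        offset = rng.uniform(-0.5, 0.5)
        if sample in outliers:
            own = set(rng.choice(genes, size=n_active, replace=False))
            values[sample] = gain * base_profile(own) + offset
            sample_active[sample] = own
        else:
            values[sample] = gain * shared + offset
            sample_active[sample] = active
    values_df = pd.DataFrame(values, index=pd.Index(probes, name="probe"))

    calls = {}
    for sample in samples:
        col = []
        for probe in probes:
            gene = probe_map.get(probe)
            if gene is None:
                col.append("A")
                continue
            p = (
                config.p_call_active
                if gene in sample_active[sample]
                else config.p_call_inactive
            )
            if rng.random() < p:
                col.append("P")
            else:
                col.append("M" if rng.random() < 0.1 else "A")
        calls[sample] = col
    calls_df = pd.DataFrame(calls, index=pd.Index(probes, name="probe"))

    return {
        "values": values_df,
        "calls": calls_df,
        "probe_map": probe_map,
        "truth": {"outliers": outliers, "active_genes": sorted(active)},
    }


# ---------------------------------------------------------------------------
# Ground-truth labels and functional-test battery
# ---------------------------------------------------------------------------


def make_truth_and_tests(
    model: MetabolicModel, media: dict[str, Medium]
) -> tuple[dict[str, str], list[FunctionalTest]]:
    """Lethal/viable labels by exhaustive knockout FBA, plus an MCT/ROT battery.

    Labels: growth ratio below 30% of the wild-type optimum under the rich
    (HAM) medium → lethal.  Battery: one conversion test per non-currency
    biomass precursor (glucose as source, under the lean medium) and ATP
    maintenance optimisation tests aerobic and anaerobic; satisfiable on the
    generating model by construction.
    """
    lethal = oracle_lethal_genes(model, media["HAM"])
    labels = {
        g: ("lethal" if g in lethal else "viable") for g in sorted(model.genes)
    }

    currency = {"atp", "adp", "pi", "h2o", "h", "nad", "nadh"}
    biomass = model.reactions[model.objective_id]
    targets = [
        m for m, coef in sorted(biomass.stoichiometry.items())
        if coef < 0 and m.rsplit("_", 1)[0] not in currency
    ]
    tests = [
        FunctionalTest(
            id=f"mct_glc_to_{m}",
            kind="MCT",
            sources=["glc_e"],
            targets=[m],
            medium="RPMI1640",
        )
        for m in targets
    ]
    for condition in ("aerobic", "anaerobic"):
        tests.append(
            FunctionalTest(
                id=f"rot_atpm_{condition}",
                kind="ROT",
                sources=["glc_e"],
                objective_reaction="ATPM",
                condition=condition,
                oxygen_exchange="EX_o2_e",
            )
        )
    return labels, tests


def load_species_additions() -> list[dict]:
    """Shipped synthetic stand-in for curated species-specific reactions."""
    path = DATA_DIR / "species_specific_additions.synthetic.json"
    return json.loads(path.read_text())["additions"]


# ---------------------------------------------------------------------------
# Workspace emitter
# ---------------------------------------------------------------------------


def make_workspace(config: GeneratorConfig, outdir: str | Path) -> dict:
    """Generate every pipeline input into a directory; returns the objects.

    Files: reference model (JSON + SBML), orthology and curation tables,
    species-specific additions, media TSVs, expression values/calls/probe
    map, knockout labels, functional-test battery and the planted truth.
    """
    from .io import save_model  # local import to keep generator importable early
    from .orthology import add_curated_reactions, apply_curation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = make_reference_model(config)
    media = make_media(config)
    orthology, expected = make_orthology_map(model, config)
    decisions, orthology = make_curation_decisions(model, orthology, expected)
    # knockout labels and expression emulate experiments on the target
    # organism, so they live in the translated gene namespace
    translated, _ = apply_curation(
        model, orthology, decisions, artificial_ids=("BIOMASS", "ATPM")
    )
    translated, _ = add_curated_reactions(translated, load_species_additions())
    expression = make_expression_calls(sorted(translated.genes), config)
    labels, tests = make_truth_and_tests(translated, media)

    save_model(model, outdir / "reference_model.json")
    save_model(model, outdir / "reference_model.xml")
    rows = [
        {"source_gene": s, "target_gene": t, "provenance": p, "resolved": ""}
        for s in sorted(orthology.entries)
        for (t, p) in sorted(orthology.entries[s])
    ]
    pd.DataFrame(rows).to_csv(outdir / "orthology.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction_id": d.reaction_id,
                "action": d.action,
                "corrected_gpr": d.corrected_gpr,
                "category": d.category,
                "rationale": d.rationale,
            }
            for d in decisions
        ]
    ).to_csv(outdir / "curation.tsv", sep="\t", index=False)
    (outdir / "species_specific_additions.synthetic.json").write_text(
        json.dumps({"additions": load_species_additions()}, indent=1) + "\n"
    )
    for name, medium in media.items():
        pd.DataFrame(
            [
                {
                    "exchange_id": rid,
                    "lb": lb,
                    "ub": ub,
                    "always_open": int(rid in medium.always_open),
                }
                for rid, (lb, ub) in sorted(medium.bounds.items())
            ]
            + [
                {"exchange_id": rid, "lb": -1000.0, "ub": 1000.0, "always_open": 1}
                for rid in sorted(medium.always_open)
            ]
        ).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    expression["values"].to_csv(outdir / "expression_values.tsv", sep="\t")
    expression["calls"].to_csv(outdir / "expression_calls.tsv", sep="\t")
    pd.DataFrame(
        sorted(expression["probe_map"].items()), columns=["probe", "gene"]
    ).to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(labels.items()), columns=["gene_id", "label"]
    ).to_csv(outdir / "knockout_labels.tsv", sep="\t", index=False)
    from .validation import save_test_battery

    save_test_battery(tests, outdir / "test_battery.json")
    (outdir / "planted_truth.json").write_text(
        json.dumps(
            {
                "expected_classes": expected,
                "expression": expression["truth"],
                "lethal_genes": sorted(g for g, l in labels.items() if l == "lethal"),
            },
            indent=1,
        )
        + "\n"
    )
    return {
        "model": model,
        "media": media,
        "orthology": orthology,
        "decisions": decisions,
        "expected_classes": expected,
        "expression": expression,
        "labels": labels,
        "tests": tests,
    }
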