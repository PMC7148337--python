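"""Expression-ranked pruning (modified mCADRE)."""

import numpy as np
import pytest

from orthogem.analysis import apply_medium, fba
from orthogem.gpr import parse_gpr
from orthogem.tissue import (
    PruneConfig,
    ReactionScore,
    extract_tissue_model,
    prune_model,
    rank_and_partition,
    score_reactions,
)


def test_expression_score_and_min_or_max(chain):
    chain.reactions["R0"].gpr = parse_gpr("g1 and g2")
    chain.reactions["R1"].gpr = parse_gpr("g1 or g2")
    scores = {s.reaction_id: s for s in
              score_reactions(chain, {"g1": 0.9, "g2": 0.4})}
    assert scores["R0"].expression_score == pytest.approx(0.4)  # complex: min
    assert scores["R1"].expression_score == pytest.approx(0.9)  # isozymes: max
    assert scores["EX_m0"].expression_score == 0.0  # no gene association


def test_isolated_reaction_zero_connectivity():
    from orthogem.model import Metabolite, MetabolicModel, Reaction

    model = MetabolicModel(
        "iso",
        [Metabolite("a_c", compartment="c"), Metabolite("b_c", compartment="c")],
        [
            Reaction("LONE", {"a_c": 1.0}, 0.0, 1.0),
            Reaction("OTHER", {"b_c": 1.0}, 0.0, 1.0),
        ],
    )
    scores = {s.reaction_id: s for s in score_reactions(model, {})}
    assert scores["LONE"].connectivity_score == 0.0


def test_currency_metabolites_do_not_create_adjacency(chain):
    """Two reactions sharing only ATP are not neighbours."""
    from orthogem.model import Metabolite, Reaction

    chain.add_metabolite(Metabolite("atp_c", compartment="c"))
    chain.add_metabolite(Metabolite("w_c", compartment="c"))
    chain.add_metabolite(Metabolite("v_c", compartment="c"))
    chain.add_reaction(Reaction("U1", {"atp_c": -1.0, "w_c": 1.0}, 0, 1,
                                gpr=parse_gpr("gw")))
    chain.add_reaction(Reaction("U2", {"atp_c": -1.0, "v_c": 1.0}, 0, 1,
                                gpr=parse_gpr("gv")))
    scores = {s.reaction_id: s for s in
              score_reactions(chain, {"gw": 1.0, "gv": 1.0})}
    assert scores["U1"].connectivity_score == 0.0
    assert scores["U2"].connectivity_score == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_scores_match_bruteforce_adjacency(seed, reference_model):
    """Both scores equal direct recomputation from adjacency lists."""
    from orthogem.gpr import EMPTY, And, Leaf, Or
    from orthogem.tissue import CURRENCY_METABOLITES

    rng = np.random.default_rng(seed)
    ubiquity = {g: float(rng.random()) for g in reference_model.genes}

    def brute_score(rule):
        if rule is EMPTY:
            return 0.0
        if isinstance(rule, Leaf):
            return ubiquity.get(rule.gene, 0.0)
        vals = [brute_score(c) for c in rule.children]
        return min(vals) if isinstance(rule, And) else max(vals)

    scores = {s.reaction_id: s for s in score_reactions(reference_model, ubiquity)}
    strip = lambda m: m.rsplit("_", 1)[0]
    for rxn in reference_model.reactions.values():
        assert scores[rxn.id].expression_score == pytest.approx(brute_score(rxn.gpr))
        neighbours = {
            other.id
            for other in reference_model.reactions.values()
            if other.id != rxn.id
            and any(
                m in other.stoichiometry and strip(m) not in CURRENCY_METABOLITES
                for m in rxn.stoichiometry
            )
        }
        expected = (
            float(np.mean([brute_score(reference_model.reactions[n].gpr)
                           for n in sorted(neighbours)]))
            if neighbours
            else 0.0
        )
        assert scores[rxn.id].connectivity_score == pytest.approx(expected)


def test_threshold_is_inclusive():
    scores = [ReactionScore("R", 0.9, 0.0), ReactionScore("Q", 0.8999, 0.0)]
    core, removal = rank_and_partition(scores, PruneConfig(core_threshold=0.9))
    assert core == {"R"}
    assert removal == ["Q"]


def test_removal_ties_broken_by_connectivity_then_id():
    scores = [
        ReactionScore("high_conn", 0.1, 0.5),
        ReactionScore("low_conn", 0.1, 0.2),
        ReactionScore("zz", 0.1, 0.2),
        ReactionScore("aa", 0.1, 0.2),
    ]
    _, removal = rank_and_partition(scores, PruneConfig(core_threshold=0.5))
    assert removal == ["aa", "low_conn", "zz", "high_conn"]


def test_rank_matches_stable_sort_oracle():
    rng = np.random.default_rng(4)
    scores = [
        ReactionScore(f"R{i}", float(rng.choice([0.0, 0.1, 0.5, 0.9])),
                      float(rng.choice([0.0, 0.3])))
        for i in range(30)
    ]
    config = PruneConfig(core_threshold=0.5)
    _, removal = rank_and_partition(scores, config)
    expected = sorted(
        [s for s in scores if s.expression_score < 0.5],
        key=lambda s: (s.expression_score, s.connectivity_score, s.reaction_id),
    )
    assert removal == [s.reaction_id for s in expected]


def test_prune_empty_removal_list_is_identity(reference_model, media):
    config = PruneConfig(medium_name="HAM")
    pruned, trace = prune_model(reference_model, set(reference_model.reactions),
                                [], config, media)
    assert set(pruned.reactions) == set(reference_model.reactions)
    assert trace == []


def test_sole_biomass_route_retained_by_biomass_guard(reference_model, media):
    """Removing the only glucose transporter would zero biomass; the guard
    keeps it even at expression score 0."""
    config = PruneConfig(medium_name="HAM", key_metabolites=[])
    pruned, trace = prune_model(reference_model, set(), ["GLCt"], config, media)
    assert "GLCt" in pruned.reactions
    assert trace == [("GLCt", "retained", "breaks_biomass")]


def test_function_guard_uses_key_metabolites(reference_model, media):
    config = PruneConfig(medium_name="HAM", key_metabolites=["pyr_c"],
                         glucose_id="glc_e")
    core = set(reference_model.reactions) - {"GLY"}
    pruned, trace = prune_model(reference_model, core, ["GLY"], config, media)
    assert trace[0] == ("GLY", "retained", "breaks_function")


def test_trace_covers_every_candidate_once(study):
    from orthogem.expression import binarize_and_collapse, gene_ubiquity, \
        remove_outlier_samples

    ex = study["expression"]
    kept, _ = remove_outlier_samples(ex["values"])
    calls = binarize_and_collapse(ex["calls"][kept], ex["probe_map"])
    ubiquity = gene_ubiquity(calls, sorted(study["max_model"].genes))
    config = PruneConfig(core_threshold=0.5, key_metabolites=["pyr_c"],
                         glucose_id="glc_e")
    tissue, trace = extract_tissue_model(study["max_model"], ubiquity, config,
                                         study["media"])
    seen = [t[0] for t in trace]
    assert len(seen) == len(set(seen))
    removed = {t[0] for t in trace if t[1] == "removed"}
    assert set(tissue.reactions) == set(study["max_model"].reactions) - removed


def test_extraction_deterministic(study):
    from orthogem.expression import binarize_and_collapse, gene_ubiquity, \
        remove_outlier_samples

    ex = study["expression"]
    kept, _ = remove_outlier_samples(ex["values"])
    calls = binarize_and_collapse(ex["calls"][kept], ex["probe_map"])
    ubiquity = gene_ubiquity(calls, sorted(study["max_model"].genes))
    config = PruneConfig(core_threshold=0.7, key_metabolites=["pyr_c"],
                         glucose_id="glc_e")
    t1, trace1 = extract_tissue_model(study["max_model"], ubiquity, config,
                                      study["media"])
    t2, trace2 = extract_tissue_model(study["max_model"], ubiquity, config,
                                      study["media"])
    assert trace1 == trace2
    assert list(t1.reactions) == list(t2.reactions)


def test_tissue_model_keeps_biomass_guarantee(study):
    """Post hoc: tissue biomass under the growth medium stays at or above
    80% of the genome-scale optimum, and the tissue model is a subset."""
    from orthogem.expression import binarize_and_collapse, gene_ubiquity, \
        remove_outlier_samples

    ex = study["expression"]
    kept, _ = remove_outlier_samples(ex["values"])
    calls = binarize_and_collapse(ex["calls"][kept], ex["probe_map"])
    ubiquity = gene_ubiquity(calls, sorted(study["max_model"].genes))
    config = PruneConfig(core_threshold=0.9, key_metabolites=["pyr_c"],
                         glucose_id="glc_e")
    tissue, _ = extract_tissue_model(study["max_model"], ubiquity, config,
                                     study["media"])
    assert set(tissue.reactions) <= set(study["max_model"].reactions)
    gsm = fba(apply_medium(study["max_model"], study["media"]["HAM"]))
    tis = fba(apply_medium(tissue, study["media"]["HAM"]))
    assert tis.objective_value >= 0.8 * gsm.objective_value - 1e-6


def test_planted_inactive_branch_removed(reference_model, media):
    """A redundant branch whose genes never express is fully pruned while the
    expressed nutrient pathways survive."""
    model = reference_model
    alt_rxns = [r for r in model.reactions if r.startswith("ALT")]
    assert alt_rxns
    ubiquity = {}
    for rxn in model.reactions.values():
        active = 0.0 if rxn.id.startswith("ALT") else 1.0
        for gene in rxn.genes:
            ubiquity[gene] = min(ubiquity.get(gene, 1.0), active)
    config = PruneConfig(core_threshold=0.5, key_metabolites=["pyr_c"],
                         glucose_id="glc_e")
    tissue, trace = extract_tissue_model(model, ubiquity, config, media)
    for rxn_id in alt_rxns:
        if model.reactions[rxn_id].genes:  # scored 0 → candidate
            assert rxn_id not in tissue.reactions, rxn_id
    for i in (1, 3):  # odd pathways have no alternative and stay intact
        for rxn_id in model.reactions:
            if rxn_id.startswith(f"PW{i}_") and model.reactions[rxn_id].genes:
                assert rxn_id in tissue.reactions
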