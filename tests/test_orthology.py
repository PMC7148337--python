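"""GPR translation, reaction classification, curation and additions."""

import itertools

import numpy as np
import pytest

from orthogem.analysis import fva
from orthogem.gpr import EMPTY, FalseLeaf, Leaf, make_and, make_or, parse_gpr
from orthogem.model import Metabolite, MetabolicModel, Reaction
from orthogem.orthology import (
    CurationDecision,
    OrthologyMap,
    add_curated_reactions,
    apply_curation,
    classify_reaction,
    translate_gpr,
)
from orthogem.synthetic import load_species_additions, oracle_eval_rule


def omap(**entries):
    return OrthologyMap(
        {s: {(t, "homologene") for t in targets} for s, targets in entries.items()}
    )


def test_translate_one_to_one_and_one_to_many():
    rule = make_and([Leaf("h1"), Leaf("h2")])
    translated, unmapped = translate_gpr(rule, omap(h1=["m1"], h2=["m2a", "m2b"]))
    assert translated == make_and([Leaf("m1"), make_or([Leaf("m2a"), Leaf("m2b")])])
    assert unmapped == set()


def test_translate_unmapped_leaves_false_marker():
    rule = make_or([Leaf("h1"), Leaf("h2")])
    translated, unmapped = translate_gpr(rule, omap(h2=["m2"]))
    assert translated == make_or([FalseLeaf("h1"), Leaf("m2")])
    assert unmapped == {"h1"}


def test_resolved_flag_overrides_or_join():
    mapping = OrthologyMap(
        {"h1": {("m1a", "homologene"), ("m1b", "ensembl")}}, resolved={"h1": "m1a"}
    )
    translated, _ = translate_gpr(Leaf("h1"), mapping)
    assert translated == Leaf("m1a")


@pytest.mark.parametrize("seed", range(8))
def test_translation_preserves_truth_paired_oracle(seed):
    """Evaluating the translated tree with all targets present equals
    evaluating the source tree with the mapped sources present — over random
    trees and random maps."""
    rng = np.random.default_rng(seed)
    sources = [f"h{i}" for i in range(5)]

    def random_tree(depth=0):
        if depth >= 2 or rng.random() < 0.4:
            return Leaf(sources[rng.integers(len(sources))])
        op = make_and if rng.random() < 0.5 else make_or
        return op([random_tree(depth + 1) for _ in range(2 + (rng.random() < 0.3))])

    for _ in range(25):
        tree = random_tree()
        mapped = {s for s in sources if rng.random() < 0.6}
        mapping = omap(**{s: [f"m_{s}"] for s in mapped})
        translated, unmapped = translate_gpr(tree, mapping)
        all_targets = {f"m_{s}" for s in mapped}
        assert oracle_eval_rule(translated, all_targets) == oracle_eval_rule(
            tree, mapped
        )
        assert unmapped.isdisjoint(mapped)


def rxn_with(gpr_text):
    return Reaction("R", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1.0, gpr=parse_gpr(gpr_text))


def test_classify_reaction_cases():
    assert classify_reaction(rxn_with(""), omap()) == "NGA"
    assert classify_reaction(rxn_with("h1 and h2"), omap(h1=["m1"])) == "GAH"
    assert classify_reaction(rxn_with("h1 and h2"), omap(h1=["m1"], h2=["m2"])) == "GAHM"
    assert classify_reaction(rxn_with("h1 or h2"), omap(h1=["m1"])) == "GAHM"


def test_pseudogene_correction_flips_gah_to_gahm():
    """A reaction tied to an orthologue-less pseudogene is GAH; after the
    curation-style reassignment to a functional mapped gene it is GAHM."""
    pseudo = rxn_with("26062")
    mapping = omap(**{"26061": ["56794"]})
    assert classify_reaction(pseudo, mapping) == "GAH"
    corrected = rxn_with("26061")
    assert classify_reaction(corrected, mapping) == "GAHM"


def curation_model():
    mets = [Metabolite(f"{b}_c", compartment="c") for b in "abcd"]
    rxns = [
        Reaction("EX_a", {"a_c": -1.0}, -10.0, 1000.0),
        Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("h1")),
        Reaction("R2", {"b_c": -1.0, "c_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("h2")),
        Reaction("RGAH", {"b_c": -1.0, "d_c": 1.0}, 0.0, 1000.0, gpr=parse_gpr("hx")),
        Reaction("DM_d", {"d_c": -1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"c_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel("cur", mets, rxns, objective_id="BIOMASS")


MAPPING = omap(h1=["m1"], h2=["m2"])


def test_apply_curation_partitions_and_translates():
    model = curation_model()
    translated, part = apply_curation(
        model, MAPPING,
        [CurationDecision("RGAH", "demote_to_non_gene", category="GAH3")],
        artificial_ids=("BIOMASS",),
    )
    assert part.core == {"R1", "R2", "BIOMASS"}
    assert part.non_core == {"EX_a", "RGAH", "DM_d"}
    assert part.core | part.non_core == set(translated.reactions)
    assert translated.reactions["R1"].gpr == Leaf("m1")
    assert translated.reactions["RGAH"].gpr is EMPTY
    # demoted reaction keeps its original bounds
    assert (translated.reactions["RGAH"].lb, translated.reactions["RGAH"].ub) == (0.0, 1000.0)
    assert part.classification["RGAH"] == "GAH"


def test_apply_curation_remove_deletes_entirely():
    translated, part = apply_curation(
        curation_model(), MAPPING,
        [CurationDecision("RGAH", "remove", category="GAH2")],
        artificial_ids=("BIOMASS",),
    )
    assert "RGAH" not in translated.reactions
    assert "RGAH" not in part.core | part.non_core


def test_apply_curation_keep_with_corrected_gpr():
    mapping = omap(h1=["m1"], h2=["m2"], hfix=["mfix"])
    translated, part = apply_curation(
        curation_model(), mapping,
        [CurationDecision("RGAH", "keep_with_gpr", corrected_gpr="hfix",
                          category="GAH1")],
        artificial_ids=("BIOMASS",),
    )
    assert "RGAH" in part.core
    assert translated.reactions["RGAH"].gpr == Leaf("mfix")


def test_apply_curation_uncovered_gah_errors():
    with pytest.raises(ValueError, match="RGAH"):
        apply_curation(curation_model(), MAPPING, [], artificial_ids=("BIOMASS",))


def test_apply_curation_idempotent():
    """Re-applying with an identity map on the target namespace reproduces
    the same partition."""
    model = curation_model()
    decisions = [CurationDecision("RGAH", "demote_to_non_gene", category="GAH3")]
    first, part1 = apply_curation(model, MAPPING, decisions,
                                  artificial_ids=("BIOMASS",))
    identity = omap(**{g: [g] for g in first.genes})
    second, part2 = apply_curation(first, identity, [], artificial_ids=("BIOMASS",))
    assert part2.core == part1.core
    assert part2.non_core == part1.non_core
    for rid in first.reactions:
        assert second.reactions[rid].gpr == first.reactions[rid].gpr


def test_classification_is_exhaustive_partition(study):
    classes = study["expected_classes"]
    counts = {c: sum(1 for v in classes.values() if v == c) for c in
              ("NGA", "GAHM", "GAH")}
    assert sum(counts.values()) == len(study["reference"].reactions)


def test_identity_map_is_pure_renaming(reference_model):
    """A complete 1:1 map changes no classification and no FVA range."""
    identity = omap(**{g: [f"m_{g}"] for g in reference_model.genes})
    for rxn in reference_model.reactions.values():
        expected = "NGA" if rxn.gpr is EMPTY else "GAHM"
        assert classify_reaction(rxn, identity) == expected
    translated, part = apply_curation(
        reference_model, identity, [], artificial_ids=("BIOMASS", "ATPM")
    )
    assert set(translated.reactions) == set(reference_model.reactions)
    before = fva(reference_model, reactions=["BIOMASS", "GLY", "ATPM"])
    after = fva(translated, reactions=["BIOMASS", "GLY", "ATPM"])
    for rxn_id, (lo, hi) in before.items():
        assert after[rxn_id] == pytest.approx((lo, hi), abs=1e-7)


def test_add_curated_reactions_fixture(reference_model):
    extended, added = add_curated_reactions(reference_model, load_species_additions())
    new_rxns = set(added)
    assert sum(1 for r in new_rxns if not r.startswith("SK_")) == 4
    assert any(r.startswith("SK_") for r in new_rxns)
    # no new structural dead ends: every new metabolite producible+consumable
    for met_id in ("cmpglna_c", "hc01115_c", "ficytb5_c", "focytb5_c"):
        produced = consumed = False
        for rxn in extended.reactions.values():
            coef = rxn.stoichiometry.get(met_id)
            if coef is None:
                continue
            if (coef > 0 and rxn.ub > 0) or (coef < 0 and rxn.lb < 0):
                produced = True
            if (coef < 0 and rxn.ub > 0) or (coef > 0 and rxn.lb < 0):
                consumed = True
        assert produced and consumed, met_id


def test_add_curated_reactions_empty_is_identity(reference_model):
    extended, added = add_curated_reactions(reference_model, [])
    assert added == []
    assert set(extended.reactions) == set(reference_model.reactions)


def test_add_curated_reactions_duplicate_id_errors(reference_model):
    record = {"id": "GLY", "stoichiometry": {"glc_c": -1.0}, "metabolites": []}
    with pytest.raises(ValueError, match="duplicates"):
        add_curated_reactions(reference_model, [record])


def test_add_curated_reactions_unknown_metabolite_errors(reference_model):
    record = {"id": "RX", "stoichiometry": {"ghost_c": -1.0}, "metabolites": []}
    with pytest.raises(KeyError, match="ghost_c"):
        add_curated_reactions(reference_model, [record])
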