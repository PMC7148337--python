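"""Shared fixtures: a seeded synthetic study run end-to-end once per session."""

from __future__ import annotations

import pytest

from orthogem.assembly import assemble_models, minimal_gapfill
from orthogem.model import Metabolite, MetabolicModel, Reaction
from orthogem.orthology import add_curated_reactions, apply_curation
from orthogem.synthetic import (
    GeneratorConfig,
    load_species_additions,
    make_curation_decisions,
    make_expression_calls,
    make_media,
    make_orthology_map,
    make_reference_model,
    make_truth_and_tests,
)

PIPELINE_SEED = 11


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def reference_model(config):
    return make_reference_model(config)


@pytest.fixture(scope="session")
def media(config):
    return make_media(config)


@pytest.fixture(scope="session")
def study(config, reference_model, media):
    """Complete synthetic study: translation, curation, assembly, truths."""
    orthology, expected = make_orthology_map(reference_model, config)
    decisions, orthology = make_curation_decisions(
        reference_model, orthology, expected
    )
    translated, partition = apply_curation(
        reference_model, orthology, decisions, artificial_ids=("BIOMASS", "ATPM")
    )
    translated, added_ids = add_curated_reactions(
        translated, load_species_additions()
    )
    partition.core |= set(added_ids)
    gapfill = minimal_gapfill(translated, partition.core, partition.non_core)
    min_model, max_model = assemble_models(translated, partition, gapfill)
    labels, tests = make_truth_and_tests(translated, media)
    expression = make_expression_calls(sorted(max_model.genes), config)
    return {
        "config": config,
        "reference": reference_model,
        "media": media,
        "orthology": orthology,
        "decisions": decisions,
        "expected_classes": expected,
        "translated": translated,
        "partition": partition,
        "gapfill": gapfill,
        "min_model": min_model,
        "max_model": max_model,
        "labels": labels,
        "tests": tests,
        "expression": expression,
    }


def chain_model(n: int = 3, uptake: float = 10.0) -> MetabolicModel:
    """EX_m0 → m0 → m1 → … → m(n-1) → sink; unit stoichiometry throughout."""
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(n)]
    rxns = [Reaction("EX_m0", {"m0_c": -1.0}, -uptake, 0.0)]
    for i in range(n - 1):
        rxns.append(
            Reaction(f"R{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0.0, 1000.0)
        )
    rxns.append(Reaction("SINK", {f"m{n-1}_c": -1.0}, 0.0, 1000.0))
    return MetabolicModel("chain", mets, rxns, objective_id="SINK")


@pytest.fixture
def chain():
    return chain_model()
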