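"""FBA, FVA, blocked/dead-end detection, media and knockout bounds."""

import numpy as np
import pytest

from orthogem.analysis import (
    Medium,
    apply_medium,
    blocked_and_deadends,
    fba,
    fva,
    knockout_bounds,
)
from orthogem.gpr import parse_gpr
from orthogem.model import Metabolite, MetabolicModel, Reaction
from orthogem.synthetic import (
    GeneratorConfig,
    make_media,
    make_reference_model,
    oracle_eval_rule,
    oracle_fba,
    plant_orphan_branch,
)

from conftest import chain_model


def test_fba_linear_chain_hand_computable(chain):
    """EX(−10,0) → unit chain → sink gives optimum 10."""
    sol = fba(chain)
    assert sol.ok
    assert sol.objective_value == pytest.approx(10.0)


def test_fba_all_exchanges_closed(chain):
    chain.reactions["EX_m0"].lb = 0.0
    sol = fba(chain)
    assert sol.ok
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_steady_state_residual(reference_model):
    """S·v of any optimal solution vanishes within 1e-6 per metabolite."""
    sol = fba(reference_model)
    assert sol.ok
    residual = {m: 0.0 for m in reference_model.metabolites}
    for rxn in reference_model.reactions.values():
        v = sol.fluxes[rxn.id]
        for met_id, coef in rxn.stoichiometry.items():
            residual[met_id] += coef * v
    assert max(abs(r) for r in residual.values()) < 1e-6


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_fba_matches_independent_formulation(seed):
    """Objective equals an LP built reaction-by-reaction in a second encoding."""
    model = make_reference_model(GeneratorConfig(seed=seed))
    ours = fba(model)
    oracle = oracle_fba(model)
    assert ours.ok and oracle is not None
    assert ours.objective_value == pytest.approx(oracle, rel=1e-6, abs=1e-6)


def test_fba_invariant_under_reordering(reference_model):
    reordered = MetabolicModel(
        "perm",
        list(reversed(list(reference_model.metabolites.values()))),
        list(reversed(list(reference_model.reactions.values()))),
        objective_id=reference_model.objective_id,
    )
    assert fba(reordered).objective_value == pytest.approx(
        fba(reference_model).objective_value, abs=1e-7
    )


def test_fva_chain_fraction_zero(chain):
    ranges = fva(chain, objective_fraction=0.0)
    for rxn_id in ("R0", "R1", "SINK"):
        assert ranges[rxn_id] == pytest.approx((0.0, 10.0), abs=1e-7)


def test_fva_fixed_bounds(chain):
    chain.reactions["R0"].lb = chain.reactions["R0"].ub = 5.0
    lo, hi = fva(chain, reactions=["R0"])["R0"]
    assert (lo, hi) == pytest.approx((5.0, 5.0))


def test_fva_equals_per_reaction_fba_pairs():
    """Definitional oracle: FVA range = 2 individual optimisations per reaction."""
    model = chain_model(4)
    # add a branch to make it non-trivial (12 reactions total stays small)
    model.add_metabolite(Metabolite("y_c", compartment="c"))
    model.add_reaction(Reaction("B0", {"m1_c": -1.0, "y_c": 1.0}, 0.0, 4.0))
    model.add_reaction(Reaction("B1", {"y_c": -1.0, "m3_c": 1.0}, 0.0, 1000.0))
    ranges = fva(model)
    for rxn_id in model.reactions:
        lo = fba(model, sense="min", objective_id=rxn_id).objective_value
        hi = fba(model, sense="max", objective_id=rxn_id).objective_value
        assert ranges[rxn_id] == pytest.approx((lo, hi), abs=1e-7)


def test_fva_bounds_enclose_sampled_feasible_points(reference_model):
    """Any feasible flux vector lies inside the FVA envelope."""
    ranges = fva(reference_model)
    from orthogem.analysis import LinearProblem

    rng = np.random.default_rng(0)
    lp = LinearProblem(reference_model)
    for _ in range(50):
        sol = lp.solve(rng.normal(size=len(lp.rxn_ids)), "max")
        if not sol.ok:
            continue
        for rxn_id, flux in sol.fluxes.items():
            lo, hi = ranges[rxn_id]
            assert lo - 1e-6 <= flux <= hi + 1e-6


def test_blocked_and_deadends_trivial_cases(chain):
    blocked, deadends = blocked_and_deadends(chain)
    assert blocked == set()
    assert deadends == set()
    # orphan producer: metabolite with no consumer
    chain.add_metabolite(Metabolite("orphan_c", compartment="c"))
    chain.add_reaction(Reaction("OR0", {"m1_c": -1.0, "orphan_c": 1.0}, 0.0, 10.0))
    blocked, deadends = blocked_and_deadends(chain)
    assert blocked == {"OR0"}
    assert deadends == {"orphan_c"}


def test_blocked_planted_branch_recovered(reference_model):
    planted, rxn_ids, met_ids = plant_orphan_branch(reference_model, 3)
    blocked, deadends = blocked_and_deadends(planted)
    assert blocked == set(rxn_ids)
    assert set(met_ids) <= deadends


def test_blocked_monotone_under_tightening(reference_model):
    """Tightening any reaction's bounds never unblocks anything."""
    base_blocked, _ = blocked_and_deadends(reference_model)
    tightened = reference_model.copy()
    tightened.reactions["LDH"].ub = 0.0
    more_blocked, _ = blocked_and_deadends(tightened)
    assert base_blocked <= more_blocked


def test_apply_medium_closes_other_uptakes(reference_model, media):
    constrained = apply_medium(reference_model, media["RPMI1640"], policy="all")
    for rxn_id in constrained.exchanges:
        rxn = constrained.reactions[rxn_id]
        if rxn_id in media["RPMI1640"].bounds:
            assert (rxn.lb, rxn.ub) == media["RPMI1640"].bounds[rxn_id]
        elif rxn_id in media["RPMI1640"].always_open:
            assert rxn.lb < 0
        else:
            assert rxn.lb == 0.0


def test_apply_medium_idempotent(reference_model, media):
    once = apply_medium(reference_model, media["HAM"])
    twice = apply_medium(once, media["HAM"])
    for rxn_id in once.reactions:
        assert (once.reactions[rxn_id].lb, once.reactions[rxn_id].ub) == (
            twice.reactions[rxn_id].lb,
            twice.reactions[rxn_id].ub,
        )


def test_apply_medium_organic_only_policy(reference_model):
    """Carbon-free exchanges stay open under the organic_only closure."""
    medium = Medium("glconly", {"EX_glc_e": (-10.0, 1000.0)})
    constrained = apply_medium(reference_model, medium, policy="organic_only")
    assert constrained.reactions["EX_o2_e"].lb < 0  # inorganic, untouched
    assert constrained.reactions["EX_aa1_e"].lb == 0.0  # organic, closed
    assert constrained.reactions["EX_lac_e"].lb == 0.0


def test_apply_medium_rejects_non_exchange_id(reference_model):
    with pytest.raises(KeyError, match="not exchange"):
        apply_medium(reference_model, Medium("bad", {"GLY": (0.0, 1.0)}))


def test_medium_grows_fixture(reference_model, media):
    sol = fba(apply_medium(reference_model, media["HAM"]))
    assert sol.ok and sol.objective_value > 1.0


@pytest.mark.parametrize(
    "rule, deleted, shut",
    [("g1 or g2", "g1", False), ("g1 and g2", "g1", True)],
)
def test_knockout_isozyme_vs_complex(rule, deleted, shut, chain):
    chain.reactions["R0"].gpr = parse_gpr(rule)
    mutant = knockout_bounds(chain, deleted)
    assert (mutant.reactions["R0"].lb == mutant.reactions["R0"].ub == 0.0) is shut


def test_knockout_unknown_gene_errors(chain):
    chain.reactions["R0"].gpr = parse_gpr("g1")
    with pytest.raises(KeyError):
        knockout_bounds(chain, "ghost")


def test_knockout_gene_outside_gprs_is_neutral(reference_model):
    """Deleting a gene appearing in no GPR leaves the optimum bit-identical."""
    model = reference_model.copy()
    model.reactions["ATPM"].gpr = parse_gpr("idle_gene or " +
                                            sorted(model.genes)[0])
    before = fba(model).objective_value
    after = fba(knockout_bounds(model, "idle_gene")).objective_value
    assert before == after


@pytest.mark.parametrize("seed", list(range(5)))
def test_knockout_constrained_set_matches_truth_tables(reference_model, seed):
    """The shut reaction set equals per-reaction brute-force GPR evaluation."""
    rng = np.random.default_rng(seed)
    genes = sorted(reference_model.genes)
    deleted = set(rng.choice(genes, size=rng.integers(1, 4), replace=False))
    mutant = knockout_bounds(reference_model, deleted)
    for rxn in reference_model.reactions.values():
        expected_shut = oracle_eval_rule(rxn.gpr, set(genes)) and not oracle_eval_rule(
            rxn.gpr, set(genes) - deleted
        )
        is_shut = (
            mutant.reactions[rxn.id].lb == mutant.reactions[rxn.id].ub == 0.0
            and not rxn.lb == rxn.ub == 0.0
        )
        assert is_shut == expected_shut, rxn.id
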