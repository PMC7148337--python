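"""Single-gene deletion simulation and essentiality evaluation.

A gene is deleted by shutting every reaction whose GPR it falsifies; the
mutant's growth is then predicted either by FBA (re-optimise biomass) or by
linear MOMA (find the mutant flux distribution minimising the L1 distance
Σ|v_wild − v_mutant| to the wild-type optimum, without re-optimising growth).
A gene is called essential when mutant biomass falls below 30% of the
wild-type optimum.  Predictions against experimental lethal/viable labels
are summarised as a confusion matrix with sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .analysis import FLUX_TOL, LinearProblem, Medium, apply_medium, fba, knockout_bounds
from .model import FluxSolution, MetabolicModel

__all__ = [
    "ESSENTIALITY_THRESHOLD",
    "KnockoutResult",
    "ConfusionMatrix",
    "WildTypeReference",
    "compute_wild_type",
    "lmoma_flux",
    "single_gene_deletion",
    "classify_and_evaluate",
    "load_labels",
    "save_results",
    "save_confusion",
]

ESSENTIALITY_THRESHOLD = 0.30  # growth ratio below which a gene is essential


@dataclass
class KnockoutResult:
    gene: str
    method: str  # FBA | lMOMA
    wild_type_objective: float
    knockout_objective: float

    @property
    def growth_ratio(self) -> float:
        if self.wild_type_objective == 0.0:
            return 0.0
        return max(self.knockout_objective, 0.0) / self.wild_type_objective

    @property
    def essential(self) -> bool:
        return self.growth_ratio < ESSENTIALITY_THRESHOLD


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else float("nan")

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else float("nan")

    @property
    def sensitivity_pct(self) -> int:
        return int(np.floor(self.sensitivity * 100 + 0.5))

    @property
    def specificity_pct(self) -> int:
        return int(np.floor(self.specificity * 100 + 0.5))


@dataclass
class WildTypeReference:
    """Wild-type optimum used as the lMOMA anchor.

    ``fluxes`` is the deterministic solver's optimal vertex (recorded for
    reproducibility — the optimal face may be degenerate) and
    ``objective_value`` its biomass flux.
    """

    objective_id: str
    objective_value: float
    fluxes: dict[str, float]


def compute_wild_type(model: MetabolicModel) -> WildTypeReference:
    sol = fba(model)
    if not sol.ok:
        raise ValueError(f"{model.id}: wild type is {sol.status}")
    return WildTypeReference(model.objective_id, sol.objective_value, sol.fluxes)


def lmoma_flux(reference: WildTypeReference, perturbed: MetabolicModel) -> FluxSolution:
    """Linear MOMA: min Σ|v_w − v_d| subject to the perturbed model's
    steady state and bounds.

    The absolute values are linearised with positive/negative split
    variables.  The returned solution carries the L1 distance as its
    objective value and the mutant fluxes ``v_d``; the mutant's biomass is
    read off the flux vector at the objective reaction.  An infeasible
    perturbed model reports status infeasible with objective 0 by
    convention.
    """
    lp = LinearProblem(perturbed)
    missing = [r for r in lp.rxn_ids if r not in reference.fluxes]
    if missing:
        raise KeyError(f"wild-type reference lacks fluxes for: {missing[:5]}")
    n = len(lp.rxn_ids)
    v_w = np.array([reference.fluxes[r] for r in lp.rxn_ids])
    # variables: [v_d, p, q] with v_d + p − q = v_w, p,q ≥ 0; min Σ(p+q)
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    eye = sparse.identity(n, format="csr")
    A_eq = sparse.vstack(
        [
            sparse.hstack([lp.S, sparse.csr_matrix((lp.S.shape[0], 2 * n))]),
            sparse.hstack([eye, eye, -eye]),
        ]
    ).tocsr()
    b_eq = np.concatenate([np.zeros(lp.S.shape[0]), v_w])
    bounds = list(lp.bounds) + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return FluxSolution("infeasible", 0.0)
    fluxes = dict(zip(lp.rxn_ids, res.x[:n]))
    return FluxSolution("optimal", res.fun, fluxes)


def single_gene_deletion(
    model: MetabolicModel,
    genes: list[str] | None = None,
    method: str = "FBA",
    medium: Medium | None = None,
    policy: str = "all",
) -> tuple[list[KnockoutResult], list[str]]:
    """Simulate single-gene deletions by FBA or linear MOMA.

    The medium (when given) is applied once; the wild-type optimum is
    computed and cached.  Genes absent from the model are skipped and
    reported separately, so that a model covering only part of a screened
    gene list is evaluated on the genes it contains.
    """
    if method not in {"FBA", "lMOMA"}:
        raise ValueError(f"unknown method {method!r}")
    work = apply_medium(model, medium, policy=policy) if medium is not None else model
    reference = compute_wild_type(work)
    model_genes = work.genes
    requested = list(genes) if genes is not None else sorted(model_genes)
    skipped = [g for g in requested if g not in model_genes]
    results: list[KnockoutResult] = []
    for gene in requested:
        if gene in skipped:
            continue
        mutant = knockout_bounds(work, gene)
        if method == "FBA":
            sol = fba(mutant)
            ko_objective = sol.objective_value if sol.ok else 0.0
        else:
            sol = lmoma_flux(reference, mutant)
            ko_objective = (
                sol.fluxes.get(work.objective_id, 0.0) if sol.ok else 0.0
            )
        results.append(
            KnockoutResult(gene, method, reference.objective_value, ko_objective)
        )
    return results, skipped


def classify_and_evaluate(
    results: list[KnockoutResult], labels: dict[str, str]
) -> ConfusionMatrix:
    """Confusion matrix of essentiality predictions against lethal/viable labels.

    TP: lethal gene predicted essential; TN: viable gene predicted
    non-essential; FP: viable predicted essential; FN: lethal predicted
    non-essential.  Every evaluated gene must carry a label.
    """
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    for result in results:
        label = labels.get(result.gene)
        if label not in {"lethal", "viable"}:
            raise KeyError(f"gene {result.gene!r} has no lethal/viable label")
        if label == "lethal":
            counts["TP" if result.essential else "FN"] += 1
        else:
            counts["FP" if result.essential else "TN"] += 1
    return ConfusionMatrix(**counts)


def load_labels(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    labels = dict(zip(table["gene_id"], table["label"]))
    bad = {g: l for g, l in labels.items() if l not in {"lethal", "viable"}}
    if bad:
        raise ValueError(f"labels must be lethal/viable; offending entries: {bad}")
    return labels


def save_results(results: list[KnockoutResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene for r in results],
            "method": [r.method for r in results],
            "wild_type_objective": [r.wild_type_objective for r in results],
            "knockout_objective": [r.knockout_objective for r in results],
            "growth_ratio": [r.growth_ratio for r in results],
            "essential": [int(r.essential) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def save_confusion(matrix: ConfusionMatrix, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "TP": matrix.TP,
                "FP": matrix.FP,
                "FN": matrix.FN,
                "TN": matrix.TN,
                "sensitivity_pct": matrix.sensitivity_pct,
                "specificity_pct": matrix.specificity_pct,
            },
            indent=1,
        )
        + "\n"
    )
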