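#!/usr/bin/env python
"""Translate the reference model into the target gene namespace and partition
reactions into core and non-core sets.

Reads the workspace from step 01, classifies every reaction (NGA / GAHM /
GAH), applies the curation decisions, adds the curated species-specific
reactions, and writes the partition table to results/partition.tsv.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from orthogem.io import load_model, save_model
from orthogem.orthology import (
    add_curated_reactions,
    apply_curation,
    load_curation_decisions,
    load_orthology_map,
    load_reaction_additions,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=Path("results/workspace"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    model = load_model(args.workspace / "reference_model.json")
    orthology = load_orthology_map(args.workspace / "orthology.tsv")
    decisions = load_curation_decisions(args.workspace / "curation.tsv")
    additions = load_reaction_additions(
        args.workspace / "species_specific_additions.synthetic.json"
    )

    translated, partition = apply_curation(
        model, orthology, decisions, artificial_ids=("BIOMASS", "ATPM")
    )
    translated, added = add_curated_reactions(translated, additions)
    partition.core |= set(added)

    counts = Counter(partition.classification.values())
    print(f"classification: {counts['GAHM']} GAHM, {counts['GAH']} GAH, "
          f"{counts['NGA']} NGA of {len(model.reactions)} reference reactions")
    print(f"curation: {len(decisions)} decisions; "
          f"{len(added)} curated additions (sinks included)")
    print(f"partition: {len(partition.core)} core, "
          f"{len(partition.non_core)} non-core")

    args.outdir.mkdir(parents=True, exist_ok=True)
    save_model(translated, args.outdir / "translated_model.json")
    pd.DataFrame(
        [
            {"reaction_id": r,
             "set": "core" if r in partition.core else "non_core",
             "class": partition.classification.get(r, "addition")}
            for r in sorted(translated.reactions)
        ]
    ).to_csv(args.outdir / "partition.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir / 'translated_model.json'} and partition.tsv")


if __name__ == "__main__":
    main()
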