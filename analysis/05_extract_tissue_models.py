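#!/usr/bin/env python
"""Extract tissue-specific models from the maximal reconstruction.

Quality-controls the expression arrays (iterative correlation z-score),
binarizes the P/M/A calls, collapses probes to genes, computes gene
ubiquity, and prunes the genome-scale model at expression thresholds 0.5,
0.7 and 0.9.  Writes tissue models, prune traces and a size table.
"""

import argparse
from pathlib import Path

import pandas as pd

from orthogem.analysis import load_medium
from orthogem.expression import (
    binarize_and_collapse,
    gene_ubiquity,
    remove_outlier_samples,
)
from orthogem.io import load_model, save_model
from orthogem.tissue import PruneConfig, extract_tissue_model


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=Path("results/workspace"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    values = pd.read_csv(args.workspace / "expression_values.tsv", sep="\t",
                         index_col=0)
    calls = pd.read_csv(args.workspace / "expression_calls.tsv", sep="\t",
                        index_col=0)
    probe_map = dict(
        pd.read_csv(args.workspace / "probe_map.tsv", sep="\t", dtype=str).values
    )
    media = {
        name: load_medium(args.workspace / f"{name}.tsv")
        for name in ("HAM", "RPMI1640")
    }
    gsm = load_model(args.outdir / "model_max.xml")

    kept, trail = remove_outlier_samples(values)
    removed = sorted(set(values.columns) - set(kept))
    print(f"array QC: kept {len(kept)}/{values.shape[1]} samples "
          f"(removed {removed}) in {len(trail)} round(s)")
    call_matrix = binarize_and_collapse(calls[kept], probe_map)
    ubiquity = gene_ubiquity(call_matrix, sorted(gsm.genes))

    rows = []
    for threshold in (0.5, 0.7, 0.9):
        config = PruneConfig(core_threshold=threshold,
                             key_metabolites=["pyr_c"], glucose_id="glc_e")
        tissue, trace = extract_tissue_model(gsm, ubiquity, config, media)
        removed_n = sum(1 for t in trace if t[1] == "removed")
        print(f"threshold {threshold}: {len(tissue.reactions)} reactions "
              f"({removed_n} pruned), {len(tissue.genes)} genes")
        tag = str(threshold).replace(".", "")
        save_model(tissue, args.outdir / f"tissue_thr{tag}.xml")
        pd.DataFrame(trace, columns=["reaction_id", "outcome", "reason"]).to_csv(
            args.outdir / f"tissue_thr{tag}_trace.tsv", sep="\t", index=False
        )
        rows.append({"threshold": threshold,
                     "reactions": len(tissue.reactions),
                     "metabolites": len(tissue.metabolites),
                     "genes": len(tissue.genes)})
    pd.DataFrame(rows).to_csv(args.outdir / "tissue_summary.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
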