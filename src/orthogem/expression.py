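"""Microarray call processing: sample QC, binarization, probe collapse, ubiquity.

Sample quality control removes outlier arrays by an iterative correlation
z-score: each round computes all pairwise Pearson correlations, scores each
sample by the z-score of its mean correlation to the others, drops samples
with |z| at or above the threshold, and repeats until no sample is removed.

Detection calls (Present / Marginal / Absent) binarize as P→1, M→0, A→0;
genes measured by several probe sets collapse by the per-sample maximum.
The ubiquity of a gene is the fraction of retained samples calling it
expressed — the quantity reaction expression scores are built from.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "remove_outlier_samples",
    "binarize_and_collapse",
    "gene_ubiquity",
]

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = 2.0


def remove_outlier_samples(
    values: pd.DataFrame,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    log2_transform: bool = False,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove outlier samples by correlation z-score.

    ``values`` is a probes × samples matrix of expression intensities.  With
    ``log2_transform`` the correlation is computed on log2(x+1), for
    raw-scale inputs.  Returns the kept sample ids and an audit trail: one
    record per round with the per-sample mean correlation, its z-score and
    the samples removed (constant, zero-variance samples are removed with an
    explicit reason since their correlation is undefined).
    """
    if values.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if values.shape[1] < 3:
        raise ValueError("sample QC needs at least 3 samples")
    data = np.log2(values + 1.0) if log2_transform else values.copy()

    kept = list(data.columns)
    trail: list[dict] = []
    round_no = 0
    while True:
        round_no += 1
        sub = data[kept]
        constant = [s for s in kept if sub[s].std(ddof=1) == 0.0]
        if constant:
            kept = [s for s in kept if s not in constant]
            trail.append(
                {
                    "round": round_no,
                    "removed": [
                        {"sample": s, "reason": "zero_variance"} for s in constant
                    ],
                }
            )
            if len(kept) < 3:
                break
            continue
        corr = sub.corr(method="pearson")
        np.fill_diagonal(corr.values, np.nan)
        mean_corr = corr.mean(axis=1, skipna=True)
        sd = mean_corr.std(ddof=1)
        # sd at float-epsilon scale means the samples are equi-correlated;
        # a z-score would be a ratio of rounding errors
        if np.isnan(sd) or sd < 1e-12:
            break
        z = (mean_corr - mean_corr.mean()) / sd
        outliers = [s for s in kept if abs(z[s]) >= z_threshold]
        trail.append(
            {
                "round": round_no,
                "mean_correlation": mean_corr.to_dict(),
                "z": z.to_dict(),
                "removed": [
                    {"sample": s, "z": float(z[s]), "reason": "outlier"}
                    for s in outliers
                ],
            }
        )
        if not outliers:
            break
        kept = [s for s in kept if s not in outliers]
        if len(kept) < 3:
            break
    return kept, trail


_CALL_MAP = {"P": 1, "M": 0, "A": 0}


def binarize_and_collapse(
    calls: pd.DataFrame, probe_map: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Binarize P/M/A probe calls and collapse probes to genes by maximum.

    ``calls`` is probes × samples with symbols P, M, A.  Probes missing from
    ``probe_map`` are dropped (count logged).  Returns a genes × samples 0/1
    matrix with sorted gene index.
    """
    if isinstance(probe_map, pd.Series):
        probe_map = probe_map.to_dict()
    # gene/probe ids are opaque strings; numeral ids read from TSV coerce
    probe_map = {str(k): str(v) for k, v in probe_map.items()}
    bad = ~calls.isin(list(_CALL_MAP))
    if bad.any().any():
        probe = bad.any(axis=1).idxmax()
        sample = bad.loc[probe].idxmax()
        raise ValueError(
            f"unknown call symbol {calls.loc[probe, sample]!r} "
            f"at probe {probe!r}, sample {sample!r}"
        )
    mapped = [p for p in calls.index if p in probe_map]
    dropped = len(calls.index) - len(mapped)
    if dropped:
        logger.info("binarize_and_collapse: dropped %d unmapped probes", dropped)
    binary = calls.loc[mapped].apply(lambda col: col.map(_CALL_MAP)).astype(int)
    genes = pd.Index([probe_map[p] for p in mapped], name="gene")
    collapsed = binary.groupby(genes).max()
    return collapsed.sort_index()


def gene_ubiquity(
    calls: pd.DataFrame, genes: list[str] | None = None
) -> pd.Series:
    """Per-gene expression frequency: row means of the 0/1 call matrix.

    When a model gene list is given, genes absent from the platform are
    reported with frequency 0 and a warning naming them.
    """
    if calls.shape[1] < 1:
        raise ValueError("ubiquity needs at least one sample")
    freq = calls.mean(axis=1)
    if genes is not None:
        missing = sorted(set(genes) - set(calls.index))
        if missing:
            warnings.warn(
                f"{len(missing)} gene(s) absent from the call matrix, "
                f"assigned frequency 0: {missing}"
            )
        freq = freq.reindex(sorted(set(genes) | set(calls.index)), fill_value=0.0)
    return freq
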