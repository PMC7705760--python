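"""Per-cell effect coefficients: how strongly each cell reflects its
subpopulation's fold-changes.

For each subpopulation the detected DS genes (FDR < 0.05 and |logFC| > 1 by
default) define a direction in expression space; each cell's coefficient is
the dot product of its normalized log-expression with the subpopulation's
logFC vector over those genes, scaled to a maximum absolute value of 1
within the subpopulation.  Well-separated coefficient distributions between
condition groups indicate that the majority of cells carry the
population-level response; overlapping distributions indicate that only a
minority react.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import compute_logcounts
from .core_io import DStateError
from .ds_testing import DSResult


@dataclass
class EffectCoefficients:
    """Scaled per-cell coefficients plus the DS gene sets used."""

    cells: pd.DataFrame  # index cell id; coefficient, cluster_id, sample_id, group_id
    ds_genes: dict[str, pd.DataFrame]  # cluster -> (gene, logfc)


def compute_effect_coefficients(
    dataset,
    ds_results: DSResult,
    fdr_cutoff: float = 0.05,
    logfc_cutoff: float = 1.0,
    scale: str = "subpopulation",
    logexpr: np.ndarray | None = None,
) -> EffectCoefficients:
    """Dot products of cell log-expression with subpopulation-level logFCs.

    ``dataset`` provides counts and annotations; ``ds_results`` must carry
    locally adjusted p-values and logFC estimates.  The DS gene set of
    subpopulation k is {genes with p_adj_loc < fdr_cutoff and |logFC| >
    logfc_cutoff}; subpopulations without DS genes get all-NA coefficients
    (flagged, not an error).  ``scale`` is "subpopulation" (per-panel
    scaling, the default) or "global".
    """
    if scale not in ("subpopulation", "global"):
        raise DStateError(f"unknown scaling {scale!r}")
    Y = dataset.counts.values
    ann = dataset.annotations
    if logexpr is None:
        logexpr = compute_logcounts(Y, Y.sum(axis=0))
    gene_index = {g: i for i, g in enumerate(dataset.counts.gene_ids)}

    tab = ds_results.table
    tab = tab[
        tab["tested"]
        & (tab["p_adj_loc"] < fdr_cutoff)
        & (tab["logfc"].abs() > logfc_cutoff)
    ]
    coef = np.full(len(ann), np.nan)
    ds_genes: dict[str, pd.DataFrame] = {}
    clusters = [str(k) for k in pd.unique(ann["cluster_id"])]
    for k in clusters:
        sel = tab[tab["cluster_id"] == k]
        sel = sel[sel["gene"].isin(gene_index)]
        ds_genes[k] = sel[["gene", "logfc"]].reset_index(drop=True)
        mask = (ann["cluster_id"] == k).values
        if sel.empty:
            continue  # flagged NA for this subpopulation
        rows = [gene_index[g] for g in sel["gene"]]
        lfc = sel["logfc"].values
        coef[mask] = lfc @ logexpr[np.ix_(rows, np.where(mask)[0])]

    if scale == "global":
        m = np.nanmax(np.abs(coef)) if np.isfinite(coef).any() else 0.0
        if m > 0:
            coef = coef / m
    else:
        for k in clusters:
            mask = (ann["cluster_id"] == k).values
            vals = coef[mask]
            if np.isfinite(vals).any():
                m = np.nanmax(np.abs(vals))
                if m > 0:
                    coef[mask] = vals / m
    cells = pd.DataFrame(
        {
            "coefficient": coef,
            "cluster_id": ann["cluster_id"].values,
            "sample_id": ann["sample_id"].values,
            "group_id": ann.get("group_id", pd.Series(index=ann.index, dtype=object)).values,
        },
        index=ann.index,
    )
    return EffectCoefficients(cells, ds_genes)
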