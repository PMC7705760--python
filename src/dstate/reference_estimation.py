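"""Filtering of a labeled reference and per-subpopulation NB parameter estimation.

For every subpopulation we estimate, per gene, sample-specific log relative
abundances ``beta_g^s`` and a dispersion ``phi_g`` under the model

    y_gc ~ NB(mu_gc, phi_g),   mu_gc = exp(beta_g^{s(c)}) * lambda_c,

with var = mu + phi * mu^2.  ``beta`` is estimated by the ratio-of-totals
(the Poisson MLE with log library-size offsets), which is consistent for the
NB mean and closed-form; ``phi`` by a genewise profile maximum likelihood
with the plug-in means held fixed, followed by a local-regression trend over
expression and empirical-Bayes shrinkage of the genewise values toward that
trend.  The library sizes of each (sample, subpopulation) pool of cells are
recorded so that simulation can resample them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import estimate_dispersion_grid, lowess_trend
from .core_io import CountMatrix, DStateError, ReferenceData

logger = logging.getLogger("dstate")

#: prior weight of the dispersion trend, in genewise-degree-of-freedom units
DEFAULT_PRIOR_DF = 10.0


@dataclass
class SubpopParams:
    """NB parameters of one subpopulation."""

    beta: pd.DataFrame  # genes x samples, natural-log scale; NaN = missing
    phi: pd.Series  # per-gene dispersion, NaN = missing
    cell_pools: dict[str, np.ndarray]  # sample -> member-cell library sizes


@dataclass
class NBParams:
    """Per-subpopulation NB parameters; the simulator's fuel."""

    subpops: dict[str, SubpopParams]
    gene_ids: list[str]
    sample_ids: list[str]
    parameterization: str = "var = mu + phi * mu^2"

    def eligible_genes(self, subpop: str) -> np.ndarray:
        """Genes with finite beta in every sample and finite phi (simulation pool)."""
        sp = self.subpops[subpop]
        ok = sp.beta.notna().all(axis=1) & sp.phi.notna()
        return ok.values

    def to_json(self, path) -> None:
        payload = {
            "parameterization": self.parameterization,
            "gene_ids": self.gene_ids,
            "sample_ids": self.sample_ids,
            "subpops": {
                k: {
                    "beta": {
                        s: [None if not np.isfinite(v) else float(v) for v in sp.beta[s]]
                        for s in sp.beta.columns
                    },
                    "phi": [None if not np.isfinite(v) else float(v) for v in sp.phi],
                    "cell_pools": {s: np.asarray(p).tolist() for s, p in sp.cell_pools.items()},
                }
                for k, sp in self.subpops.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NBParams":
        payload = json.loads(Path(path).read_text())
        genes = payload["gene_ids"]
        subpops = {}
        for k, d in payload["subpops"].items():
            beta = pd.DataFrame(
                {s: pd.array(v, dtype=float) for s, v in d["beta"].items()}, index=genes
            ).astype(float)
            phi = pd.Series(pd.array(d["phi"], dtype=float), index=genes).astype(float)
            pools = {s: np.asarray(p, dtype=float) for s, p in d["cell_pools"].items()}
            subpops[k] = SubpopParams(beta, phi, pools)
        return cls(subpops, genes, payload["sample_ids"], payload["parameterization"])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_reference(
    data: ReferenceData,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 100,
    min_cells_per_instance: int = 100,
) -> ReferenceData:
    """Stagewise filtering of a reference dataset.

    1. drop cells detecting fewer than ``min_genes_per_cell`` genes;
    2. drop genes detected in fewer than ``min_cells_per_gene`` remaining cells;
    3. drop (sample, subpopulation) instances with fewer than
       ``min_cells_per_instance`` cells, removing their cells.

    Library sizes are recomputed on the filtered matrix.
    """
    Y = data.counts.values
    ann = data.annotations
    tally = {}

    detected_per_cell = (Y > 0).sum(axis=0)
    keep_cells = detected_per_cell >= min_genes_per_cell
    tally["cells_low_detection"] = int((~keep_cells).sum())

    Y1 = Y[:, keep_cells]
    cells1 = [c for c, k in zip(data.counts.cell_ids, keep_cells) if k]
    detected_per_gene = (Y1 > 0).sum(axis=1)
    keep_genes = detected_per_gene >= min_cells_per_gene
    tally["genes_low_detection"] = int((~keep_genes).sum())

    Y2 = Y1[keep_genes, :]
    genes2 = [g for g, k in zip(data.counts.gene_ids, keep_genes) if k]
    ann2 = ann.loc[cells1]
    inst_sizes = ann2.groupby(["sample_id", "cluster_id"], observed=True).size()
    small = set(inst_sizes[inst_sizes < min_cells_per_instance].index)
    in_small = [
        (s, k) in small for s, k in zip(ann2["sample_id"], ann2["cluster_id"])
    ]
    keep2 = ~np.asarray(in_small, dtype=bool)
    tally["cells_in_small_instances"] = int((~keep2).sum())

    Y3 = Y2[:, keep2]
    cells3 = [c for c, k in zip(cells1, keep2) if k]
    if Y3.shape[0] == 0 or Y3.shape[1] == 0:
        raise DStateError(f"filtering removed everything; tally: {tally}")
    logger.info("filter_reference tally: %s", tally)
    cm = CountMatrix(Y3, genes2, cells3)
    return ReferenceData(cm, ann.loc[cells3])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def estimate_sample_means(
    counts_slice: np.ndarray,
    lib_sizes: np.ndarray,
    sample_labels: np.ndarray,
) -> pd.DataFrame:
    """Ratio-of-totals estimate of beta_g^s = ln(sum_c y_gc / sum_c lambda_c).

    ``counts_slice`` is genes x cells for one subpopulation.  Genes with zero
    total count in a sample get NaN (flagged missing) rather than -inf.
    Returns a genes x samples DataFrame on the natural-log scale.
    """
    counts_slice = np.asarray(counts_slice)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    sample_labels = np.asarray(sample_labels)
    samples = pd.unique(sample_labels)
    out = {}
    for s in samples:
        mask = sample_labels == s
        if not mask.any():
            raise DStateError(f"empty cell pool for sample {s!r}")
        tot_y = counts_slice[:, mask].sum(axis=1).astype(float)
        tot_lam = lib_sizes[mask].sum()
        if tot_lam <= 0:
            raise DStateError(f"sample {s!r} has zero total library size")
        with np.errstate(divide="ignore"):
            beta = np.log(tot_y / tot_lam)
        beta[tot_y == 0] = np.nan
        out[str(s)] = beta
    return pd.DataFrame(out)


def estimate_dispersions(
    counts_slice: np.ndarray,
    lib_sizes: np.ndarray,
    sample_labels: np.ndarray,
    prior_df: float = DEFAULT_PRIOR_DF,
    return_genewise: bool = False,
):
    """Genewise profile-ML NB dispersions with trend + EB shrinkage.

    Means are the plug-in ratio-of-totals fits (sample effects as offsets);
    the genewise ML estimates are then smoothed by a local regression of
    log-dispersion on log-mean and shrunk toward that trend with a prior
    weight of ``prior_df`` genewise degrees of freedom.  Estimates are
    clamped to [0, 100]; all-zero genes come back NaN.
    """
    counts_slice = np.asarray(counts_slice, dtype=float)
    G, C = counts_slice.shape
    if C < 2:
        raise DStateError("need at least 2 cells to estimate dispersions")
    beta = estimate_sample_means(counts_slice, lib_sizes, sample_labels)
    sample_labels = np.asarray(sample_labels)
    col_idx = pd.Categorical(sample_labels.astype(str), categories=beta.columns).codes
    beta_mat = beta.values  # genes x samples
    mu = np.exp(np.where(np.isnan(beta_mat), -np.inf, beta_mat))[:, col_idx] * np.asarray(
        lib_sizes, dtype=float
    )[None, :]
    expressed = counts_slice.sum(axis=1) > 0
    phi = np.full(G, np.nan)
    if expressed.any():
        phi_gene = estimate_dispersion_grid(counts_slice[expressed], np.maximum(mu[expressed], 1e-10))
        mean_expr = counts_slice[expressed].mean(axis=1)
        log_phi = np.log(np.maximum(phi_gene, 1e-8))
        trend = lowess_trend(np.log(mean_expr + 1e-8), log_phi)
        df_gene = max(C - len(beta.columns), 1)
        w = df_gene / (df_gene + prior_df)
        shrunk = np.exp(w * log_phi + (1 - w) * trend)
        shrunk = np.where(phi_gene <= 1e-8, phi_gene, shrunk)
        phi[expressed] = np.clip(shrunk, 0.0, 100.0)
        if return_genewise:
            gw = np.full(G, np.nan)
            gw[expressed] = phi_gene
            return phi, gw
    if return_genewise:
        return phi, np.full(G, np.nan)
    return phi


def estimate_nb_params(data: ReferenceData, prior_df: float = DEFAULT_PRIOR_DF) -> NBParams:
    """Estimate NB parameters for every subpopulation of a filtered reference."""
    Y = data.counts.values
    ann = data.annotations
    lam = np.asarray(data.library_sizes, dtype=float)
    subpops = {}
    clusters = pd.unique(ann["cluster_id"])
    samples_all = [str(s) for s in pd.unique(ann["sample_id"])]
    for k in clusters:
        mask = (ann["cluster_id"] == k).values
        slice_counts = Y[:, mask]
        slice_lam = lam[mask]
        slice_samples = ann.loc[mask, "sample_id"].values
        beta = estimate_sample_means(slice_counts, slice_lam, slice_samples)
        beta.index = data.counts.gene_ids
        phi = estimate_dispersions(slice_counts, slice_lam, slice_samples, prior_df=prior_df)
        phi = pd.Series(phi, index=data.counts.gene_ids)
        pools = {
            str(s): slice_lam[slice_samples == s]
            for s in pd.unique(slice_samples)
        }
        for s, p in pools.items():
            if p.size == 0:
                raise DStateError(f"empty cell pool for instance ({s}, {k})")
        subpops[str(k)] = SubpopParams(beta, phi, pools)
    return NBParams(subpops, list(data.counts.gene_ids), samples_all)
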