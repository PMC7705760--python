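"""Ground-truth NB reference datasets for testing estimation and simulation.

:func:`make_toy_reference` draws a fully known reference — per-gene log
relative abundances with mild per-sample effects, per-gene dispersions, and
log-normal library sizes on a droplet-data scale — samples counts from the
same NB model the estimators assume, and returns both the dataset and the
generating :class:`~dstate.reference_estimation.NBParams`, so parameter
recovery and the full simulate/test/evaluate pipeline can be exercised
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix, DStateError, ReferenceData, substream
from .reference_estimation import NBParams, SubpopParams


@dataclass
class ToyReferenceSpec:
    """Settings of the synthetic ground-truth reference.

    ``beta_range`` bounds the gene-level log relative abundance (natural
    log of the expected share of a cell's library); per-sample effects
    N(0, ``beta_sample_sd``) emulate replicate-level variability.  Library
    sizes are log-normal (defaults ~ 8000 counts/cell, droplet scale).
    """

    n_genes: int = 1000
    n_cells_per_instance: int = 200
    n_samples: int = 8
    n_subpops: int = 2
    beta_range: tuple[float, float] = (-12.0, -5.0)
    beta_sample_sd: float = 0.2
    phi_values: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0)
    libsize_lognormal: tuple[float, float] = (9.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells_per_instance, self.n_samples, self.n_subpops) < 1:
            raise DStateError("all counts must be >= 1")
        if any(p < 0 for p in self.phi_values) or not self.phi_values:
            raise DStateError("phi_values must be non-negative and non-empty")
        lo, hi = self.beta_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise DStateError("beta_range must be a finite interval")
        if self.beta_sample_sd < 0:
            raise DStateError("beta_sample_sd must be >= 0")


def make_toy_reference(spec: ToyReferenceSpec) -> tuple[ReferenceData, NBParams]:
    """Generate a ground-truth NB reference and its generating parameters.

    True beta_g^s = Uniform(beta_range) gene effect + N(0, beta_sample_sd)
    sample effect; phi_g drawn from ``phi_values``; lambda_c log-normal.
    Counts are y_gc ~ NB(exp(beta_g^s) * lambda_c, phi_g), independently per
    subpopulation.  The returned ``NBParams`` holds the exact generating
    values (including the realized library-size pools).
    """
    rng = substream(spec.seed, "toy_reference")
    G, n, S, K = (
        spec.n_genes,
        spec.n_cells_per_instance,
        spec.n_samples,
        spec.n_subpops,
    )
    gene_ids = [f"g{g+1:05d}" for g in range(G)]
    sample_ids = [f"s{s+1}" for s in range(S)]
    cluster_ids = [f"k{k+1}" for k in range(K)]

    blocks, cell_ids, ann_rows = [], [], []
    subpops: dict[str, SubpopParams] = {}
    meanlog, sdlog = spec.libsize_lognormal
    for k_name in cluster_ids:
        beta_gene = rng.uniform(*spec.beta_range, size=G)
        beta = beta_gene[:, None] + rng.normal(0.0, spec.beta_sample_sd, size=(G, S))
        # normalize so each sample's relative abundances sum to 1: expected
        # column totals then match the drawn library sizes
        beta -= np.log(np.exp(beta).sum(axis=0))[None, :]
        phi = rng.choice(np.asarray(spec.phi_values, float), size=G)
        pools: dict[str, np.ndarray] = {}
        for s_idx, s_name in enumerate(sample_ids):
            lam = np.round(rng.lognormal(meanlog, sdlog, size=n)).astype(float)
            lam = np.maximum(lam, 1.0)
            pools[s_name] = lam
            mu = np.exp(beta[:, s_idx])[:, None] * lam[None, :]
            r = 1.0 / np.maximum(phi, 1e-8)[:, None]
            y = np.where(
                phi[:, None] < 1e-8,
                rng.poisson(mu),
                rng.negative_binomial(r, r / (r + mu)),
            ).astype(np.int64)
            blocks.append(y)
            for i in range(n):
                cell_ids.append(f"{s_name}.{k_name}.c{i+1}")
                ann_rows.append((s_name, k_name))
        subpops[k_name] = SubpopParams(
            beta=pd.DataFrame(beta, index=gene_ids, columns=sample_ids),
            phi=pd.Series(phi, index=gene_ids),
            cell_pools=pools,
        )

    counts = CountMatrix(np.concatenate(blocks, axis=1), gene_ids, cell_ids)
    ann = pd.DataFrame(ann_rows, index=cell_ids, columns=["sample_id", "cluster_id"])
    true_params = NBParams(subpops, gene_ids, sample_ids)
    return ReferenceData(counts, ann), true_params
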