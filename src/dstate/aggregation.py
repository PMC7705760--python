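"""Pseudobulk assembly: per-subpopulation gene x sample aggregates.

Three flavors are supported, matching the combinations that make
methodological sense for the downstream engines:

* ``counts`` + ``sum`` - raw counts summed per instance (input to the NB
  quasi-likelihood and voom engines);
* ``logcounts`` + ``mean`` - library-size-normalized log2 expression
  averaged per instance (input to the trend engine);
* ``scalecpm`` + ``sum`` - per-cell CPM summed per instance, rescaled by the
  instance library size Lambda_sk * 1e-6 back to the counting scale.

The instance library size Lambda_sk = sum_g sum_c y_gc and the per-instance
cell counts are recorded alongside each matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DesignSpec, DStateError

logger = logging.getLogger("dstate")

VALID_COMBINATIONS = {
    ("counts", "sum"): "sum_counts",
    ("logcounts", "mean"): "mean_logcounts",
    ("scalecpm", "sum"): "sum_scalecpm",
}


@dataclass
class Pseudobulk:
    """Per-subpopulation gene x sample matrices plus instance bookkeeping."""

    matrices: dict[str, pd.DataFrame]  # cluster -> genes x samples
    assay_type: str
    n_cells: pd.DataFrame  # clusters x samples
    instance_libsize: pd.DataFrame  # clusters x samples, Lambda_sk
    design: DesignSpec

    def clusters(self) -> list[str]:
        return list(self.matrices)


def compute_logcounts(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """log2(y_gc * (mean library size / lambda_c) + 1) per cell.

    Library-size normalization to a counts-like scale with pseudo-count 1;
    invariant to rescaling all library sizes by a common factor.
    """
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise DStateError("zero library size; filter cells first")
    mean_lib = lib_sizes.mean()
    return np.log2(np.asarray(counts, float) * (mean_lib / lib_sizes)[None, :] + 1.0)


def compute_scaled_cpm(
    counts: np.ndarray, lib_sizes: np.ndarray, instance_mask: np.ndarray
) -> np.ndarray:
    """Scaled-CPM pseudobulk column for one (sample, subpopulation) instance.

    Per-cell CPM_gc = y_gc / lambda_c * 1e6 summed over the instance's cells,
    then multiplied by Lambda_sk * 1e-6 where Lambda_sk is the instance's
    total count.
    """
    instance_mask = np.asarray(instance_mask, dtype=bool)
    if not instance_mask.any():
        raise DStateError("empty instance")
    lib = np.asarray(lib_sizes, dtype=float)[instance_mask]
    if np.any(lib <= 0):
        raise DStateError("zero library size in instance")
    sub = np.asarray(counts, float)[:, instance_mask]
    cpm_sum = (sub / lib[None, :] * 1e6).sum(axis=1)
    lam_sk = sub.sum()
    return cpm_sum * lam_sk * 1e-6


def aggregate(dataset, assay: str = "counts", statistic: str = "sum") -> Pseudobulk:
    """Aggregate cell-level data to pseudobulk, one matrix per subpopulation.

    ``dataset`` is any object with ``counts`` (CountMatrix) and
    ``annotations`` (sample_id / cluster_id / group_id).  Samples with zero
    cells in a subpopulation are dropped for that subpopulation (logged).
    """
    if (assay, statistic) not in VALID_COMBINATIONS:
        raise DStateError(
            f"unsupported assay/statistic pair ({assay}, {statistic}); "
            f"valid: {sorted(VALID_COMBINATIONS)}"
        )
    assay_type = VALID_COMBINATIONS[(assay, statistic)]
    Y = dataset.counts.values
    genes = dataset.counts.gene_ids
    ann = dataset.annotations
    lam = Y.sum(axis=0).astype(float)
    design = DesignSpec.from_annotations(ann)
    clusters = [str(k) for k in pd.unique(ann["cluster_id"])]
    samples = design.sample_ids

    if assay == "logcounts":
        values = compute_logcounts(Y, lam)
    else:
        values = Y.astype(float)

    matrices: dict[str, pd.DataFrame] = {}
    n_cells = pd.DataFrame(0, index=clusters, columns=samples, dtype=int)
    lam_sk = pd.DataFrame(0.0, index=clusters, columns=samples)
    for k in clusters:
        cols = {}
        for s in samples:
            mask = ((ann["cluster_id"] == k) & (ann["sample_id"] == s)).values
            m = int(mask.sum())
            n_cells.loc[k, s] = m
            if m == 0:
                logger.info("sample %s has no cells in subpopulation %s; dropped", s, k)
                continue
            lam_sk.loc[k, s] = Y[:, mask].sum()
            if assay == "scalecpm":
                cols[s] = compute_scaled_cpm(Y, lam, mask)
            elif statistic == "sum":
                cols[s] = values[:, mask].sum(axis=1)
            else:
                cols[s] = values[:, mask].mean(axis=1)
        if not cols:
            raise DStateError(f"subpopulation {k} has no non-empty sample")
        mat = pd.DataFrame(cols, index=genes)
        if assay == "counts":
            mat = mat.astype(np.int64)
        matrices[k] = mat
    return Pseudobulk(matrices, assay_type, n_cells, lam_sk, design)
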