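"""Data model and I/O for multi-sample multi-subpopulation count data.

The central objects are a genes x cells integer :class:`CountMatrix`, per-cell
annotations (sample, subpopulation/cluster, optional group), and
:class:`ReferenceData`, which bundles the two together with per-cell library
sizes ``lambda_c`` (column totals).  On disk we use the 10x-style Matrix Market
triplet convention: genes in rows, 1-based indices, accompanied by
``genes.tsv`` / ``cells.tsv`` and, for simulated data, a ``truth.tsv`` ground
-truth table.

Every randomized stage of the package draws its generator from
:func:`substream`, which derives an independent stream from a master seed and
a stage name, so stages can be rerun in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("dstate")

DD_CATEGORIES = ("EE", "EP", "DE", "DP", "DM", "DB")
#: categories that constitute true differential states
DS_CATEGORIES = ("DE", "DP", "DM", "DB")

ANNOTATION_COLUMNS = ("sample_id", "cluster_id", "group_id")


class DStateError(ValueError):
    """Raised for invalid inputs or configurations."""


def substream(master_seed: int, stage: str) -> np.random.Generator:
    """Derive an independent RNG stream from ``(master_seed, stage name)``.

    The stage name is hashed with CRC-32 and used as a spawn key, so each
    stage's stream is reproducible on its own without replaying earlier
    stages.
    """
    key = zlib.crc32(stage.encode("utf8"))
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer counts."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise DStateError("count matrix must be 2-dimensional")
        g, c = self.values.shape
        if g != len(self.gene_ids) or c != len(self.cell_ids):
            raise DStateError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != g:
            raise DStateError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise DStateError("duplicate cell ids")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.all(self.values == np.round(self.values)):
                raise DStateError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise DStateError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Column totals lambda_c."""
        return self.values.sum(axis=0)


def validate_annotations(ann: pd.DataFrame, cell_ids: Sequence[str]) -> pd.DataFrame:
    """Check one annotation row per cell, required columns, group/sample nesting."""
    if "sample_id" not in ann.columns or "cluster_id" not in ann.columns:
        raise DStateError("annotations need 'sample_id' and 'cluster_id' columns")
    missing = set(cell_ids) - set(ann.index)
    if missing:
        raise DStateError(f"{len(missing)} cells missing from annotations")
    extra = set(ann.index) - set(cell_ids)
    if extra:
        raise DStateError(f"annotation barcodes absent from matrix: {sorted(extra)[:5]}")
    ann = ann.loc[list(cell_ids)].copy()
    if ann[["sample_id", "cluster_id"]].isna().any().any():
        raise DStateError("every cell needs a sample_id and a cluster_id")
    if "group_id" in ann.columns and ann["group_id"].notna().any():
        per_sample = ann.groupby("sample_id", observed=True)["group_id"].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise DStateError(f"group_id not constant within sample(s): {bad}")
    return ann


@dataclass
class ReferenceData:
    """Counts + cell annotations + library sizes; the anchor of a simulation."""

    counts: CountMatrix
    annotations: pd.DataFrame
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.annotations = validate_annotations(self.annotations, self.counts.cell_ids)
        computed = self.counts.library_sizes()
        if self.library_sizes is None:
            self.library_sizes = computed
        else:
            self.library_sizes = np.asarray(self.library_sizes)
            if not np.array_equal(self.library_sizes, computed):
                raise DStateError("stored library sizes differ from column sums")
        n_zero = int((self.library_sizes == 0).sum())
        if n_zero:
            warnings.warn(
                f"{n_zero} cell(s) with zero library size retained; "
                "filtering is a later stage",
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.counts.n_genes

    @property
    def n_cells(self) -> int:
        return self.counts.n_cells


@dataclass
class DesignSpec:
    """Sample-to-group assignment and the contrast to test."""

    sample_ids: list[str]
    group_of_sample: dict[str, str]
    contrast: tuple[str, str]  # (reference group, comparison group)

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        missing = [s for s in self.sample_ids if s not in self.group_of_sample]
        if missing:
            raise DStateError(f"samples without a group: {missing}")
        groups = {self.group_of_sample[s] for s in self.sample_ids}
        ref, cmp_ = self.contrast
        if ref not in groups or cmp_ not in groups:
            raise DStateError(f"contrast groups {self.contrast} not both present")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of_sample[s] == group]

    @classmethod
    def from_annotations(cls, ann: pd.DataFrame, contrast: tuple[str, str] | None = None) -> "DesignSpec":
        if "group_id" not in ann.columns or ann["group_id"].isna().all():
            raise DStateError("annotations carry no group_id")
        pairs = ann[["sample_id", "group_id"]].drop_duplicates()
        mapping = dict(zip(pairs["sample_id"].astype(str), pairs["group_id"].astype(str)))
        samples = sorted(mapping)
        if contrast is None:
            groups = sorted(set(mapping.values()))
            if len(groups) != 2:
                raise DStateError(f"expected 2 groups, found {groups}")
            contrast = (groups[0], groups[1])
        return cls(samples, mapping, contrast)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _read_tsv_ids(path: Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_dataset(
    matrix_path,
    genes_path,
    cells_path,
    annotations_path=None,
    truth_path=None,
):
    """Read a dataset in 10x-style MTX + TSV form.

    ``matrix_path`` is a Matrix Market coordinate file with genes in rows;
    ``genes_path`` / ``cells_path`` list the row and column ids; the
    annotations TSV is keyed by cell barcode and carries ``sample_id``,
    ``cluster_id`` and optionally ``group_id``.  Returns a
    :class:`ReferenceData`, or a :class:`~dstate.simulator.SimulatedDataset`
    when ``truth_path`` is given.
    """
    mat = scipy.io.mmread(str(matrix_path))
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if np.issubdtype(dense.dtype, np.floating) and not np.all(dense == np.round(dense)):
        raise DStateError("matrix contains non-integer entries")
    dense = dense.astype(np.int64)
    if dense.size and dense.min() < 0:
        raise DStateError("matrix contains negative entries")
    gene_ids = _read_tsv_ids(Path(genes_path))
    with open(cells_path) as fh:
        has_header = fh.readline().split("\t")[0].strip() == "barcode"
    if has_header:
        cell_ids = _read_tsv_ids(Path(cells_path))[1:]
    else:
        cell_ids = _read_tsv_ids(Path(cells_path))
    if dense.shape != (len(gene_ids), len(cell_ids)):
        raise DStateError(
            f"MTX shape {dense.shape} does not match {len(gene_ids)} genes x "
            f"{len(cell_ids)} cells from the id files"
        )
    cm = CountMatrix(dense, gene_ids, cell_ids)
    ann_path = annotations_path if annotations_path is not None else cells_path
    ann = pd.read_csv(ann_path, sep="\t", dtype=str)
    if "barcode" not in ann.columns:
        raise DStateError("annotations need a 'barcode' column")
    ann = ann.set_index("barcode")
    data = ReferenceData(cm, ann)
    if truth_path is not None:
        from .simulator import SimulatedDataset  # local import to avoid cycle

        truth = pd.read_csv(truth_path, sep="\t")
        return SimulatedDataset(
            counts=cm, annotations=data.annotations, truth=truth, config=None
        )
    return data


def write_dataset(data, out_dir) -> dict[str, Path]:
    """Write a dataset as MTX + genes.tsv + cells.tsv (+ truth.tsv).

    Round-trips through :func:`read_dataset`.
    """
    counts: CountMatrix = data.counts
    if counts.n_genes == 0 or counts.n_cells == 0:
        raise DStateError("refusing to write an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    coo = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    paths["genes"].write_text("\n".join(counts.gene_ids) + "\n")
    ann = data.annotations.copy()
    ann.index.name = "barcode"
    ann.reset_index().to_csv(paths["cells"], sep="\t", index=False)
    truth = getattr(data, "truth", None)
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _check_unknown(d: Mapping, allowed: set[str], what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise DStateError(f"unknown key(s) in {what} config: {sorted(unknown)}")


@dataclass
class TestConfig:
    """Settings for the differential-testing engines."""

    method: str = "pb-nbql"
    min_cells_per_instance: int = 10  # AD tests: >=10 expressing cells
    n_permutations: int = 1000
    ebayes_trend: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise DStateError("n_permutations must be >= 100")
        if self.min_cells_per_instance < 0:
            raise DStateError("min_cells_per_instance must be >= 0")


@dataclass
class EvalConfig:
    """Settings for performance evaluation and scoring."""

    fdr_cutoffs: tuple[float, ...] = (0.01, 0.05, 0.10)
    mean_filter: float = 0.1
    encoding: str = "methods"  # or "figure": good=2 / intermediate=1
    unimodal_weight: float = 0.75
    bimodal_weight: float = 0.25
    trimodal_weight: float = 0.05
    other_criterion_weight: float = 0.5

    def __post_init__(self) -> None:
        for c in self.fdr_cutoffs:
            if not 0 < c < 1:
                raise DStateError(f"FDR cutoff {c} outside (0, 1)")
        if self.encoding not in ("methods", "figure"):
            raise DStateError(f"unknown encoding {self.encoding!r}")


def load_config(path):
    """Load and validate a YAML config.

    The file must carry ``kind: simulation | test | evaluation``; remaining
    keys mirror the corresponding dataclass fields.  Unknown keys are
    rejected, defaults filled in, and the resolved config is echoed to the
    log.
    """
    from .simulator import SimConfig  # deferred: simulator imports core_io

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict) or "kind" not in raw:
        raise DStateError("config must be a mapping with a 'kind' key")
    kind = raw.pop("kind")
    classes = {"simulation": SimConfig, "test": TestConfig, "evaluation": EvalConfig}
    if kind not in classes:
        raise DStateError(f"unknown config kind {kind!r}")
    cls = classes[kind]
    allowed = {f.name for f in dataclasses.fields(cls)}
    _check_unknown(raw, allowed, kind)
    for key in ("category_probs", "n_samples_per_group", "subpop_logfc_factors", "fdr_cutoffs"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = cls(**raw)
    logger.info("resolved %s config: %s", kind, cfg)
    return cfg


def write_manifest(out_dir, seed: int, config) -> Path:
    """Write a run manifest (resolved config + package version + seed)."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "dstate",
        "version": __version__,
        "seed": int(seed),
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
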