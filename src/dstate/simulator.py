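"""Reference-anchored simulation of multi-sample, multi-subpopulation counts.

Counts are drawn as y_gc ~ NB(mu_gc, phi_g) with mu_gc =
exp(beta_g^{s(c)}) * lambda_c, where beta, phi and the library-size pools
come from an estimated (or ground-truth) :class:`~dstate.reference_estimation.NBParams`.
On top of this baseline, each gene in each subpopulation is assigned to one
of six differential-distribution categories:

* EE  - equally expressed in both groups;
* EP  - equal bimodal proportions: the same fraction of cells in each group
  expresses at mu * FC;
* DE  - classical mean shift: all cells of the affected group at mu * FC;
* DP  - differential proportions: fraction a of group A and b of group B at
  mu * FC (defaults a = 0.3, b = 0.7);
* DM  - differential modality: half of the affected group's cells at mu * FC;
* DB  - both: the affected group entirely at mu * FC/2, the other group split
  into equal halves at mu and mu * FC.

Fold-change magnitudes (log2) are Gamma(shape 4, rate 4 / mu_logFC) draws
with random sign; the affected group is fixed to group "B", the direction of
change being carried entirely by the sign.  Ground truth (category, signed
logFC, base mean) is recorded per gene and subpopulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DD_CATEGORIES,
    CountMatrix,
    DesignSpec,
    DStateError,
    substream,
    validate_annotations,
)
from .reference_estimation import NBParams

logger = logging.getLogger("dstate")

GROUPS = ("A", "B")
AFFECTED_GROUP = "B"


@dataclass
class SimConfig:
    """Simulation settings; defaults mirror the main benchmark scenario."""

    n_subpops: int = 3
    n_samples_per_group: tuple[int, int] = (3, 3)
    paired: bool = False
    n_genes: int = 4000
    p_type: float = 0.1
    category_probs: tuple[float, ...] = (0.9, 0.0, 0.1, 0.0, 0.0, 0.0)
    mu_logfc: float = 2.0
    subpop_logfc_factors: tuple[float, ...] | None = None
    cells_per_instance: int = 200
    dp_prop_a: float = 0.3
    dp_prop_b: float = 0.7
    ep_fraction: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.size != 6:
            raise DStateError("category_probs needs 6 entries (EE,EP,DE,DP,DM,DB)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise DStateError("category_probs: probabilities outside [0,1]")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise DStateError(
                f"category_probs sums to {probs.sum():.6g}, must sum to 1"
            )
        for name in ("p_type", "dp_prop_a", "dp_prop_b", "ep_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DStateError(f"{name} = {v} outside [0,1]")
        if abs(self.dp_prop_a + self.dp_prop_b - 1.0) > 1e-8:
            raise DStateError("dp_prop_a + dp_prop_b must equal 1")
        if self.dp_prop_a == self.dp_prop_b:
            raise DStateError("dp_prop_a must differ from dp_prop_b")
        if min(self.n_subpops, self.n_genes, self.cells_per_instance, *self.n_samples_per_group) < 1:
            raise DStateError("K, S, G and cells_per_instance must all be >= 1")
        if self.mu_logfc <= 0:
            raise DStateError("mu_logfc must be positive")
        if self.subpop_logfc_factors is not None:
            if len(self.subpop_logfc_factors) != self.n_subpops:
                raise DStateError("need one logFC factor per subpopulation")
            if any(f < 0 for f in self.subpop_logfc_factors):
                raise DStateError("subpop_logfc_factors must be non-negative")


@dataclass
class SimulatedDataset:
    """Synthetic counts, cell metadata and the ground-truth table."""

    counts: CountMatrix
    annotations: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig | None = None
    #: simulated sample -> anchoring reference sample (provenance bookkeeping)
    ref_samples: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.annotations = validate_annotations(self.annotations, self.counts.cell_ids)

    def design(self) -> DesignSpec:
        return DesignSpec.from_annotations(self.annotations, contrast=GROUPS)


# ---------------------------------------------------------------------------
# elementary sampling steps
# ---------------------------------------------------------------------------


def assign_categories(
    G: int, K: int, category_probs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. categorical draws of the DD category per (gene, subpopulation)."""
    probs = np.asarray(category_probs, dtype=float)
    if probs.size != 6 or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-8:
        raise DStateError("invalid category probability vector")
    codes = rng.choice(6, size=(G, K), p=probs)
    return np.asarray(DD_CATEGORIES)[codes]

def sample_gene_mapping(
    G: int,
    K: int,
    p_type: float,
    eligible_ref_genes: Sequence[int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Map simulated genes to reference genes, with type genes per subpopulation.

    ``(1 - p_type) * G`` slots share one reference-gene draw across all
    subpopulations; the remaining ``p_type * G`` type slots are sampled
    separately per subpopulation with pairwise-disjoint reference sets.
    Returns ``(mapping, is_type)`` where ``mapping`` is a G x K integer array
    of reference-gene indices and ``is_type`` a boolean G-vector.
    """
    eligible = np.asarray(eligible_ref_genes)
    n_type = int(np.floor(p_type * G + 0.5))
    n_shared = G - n_type
    needed = n_shared + K * n_type
    if eligible.size < needed:
        raise DStateError(
            f"need {needed} distinct eligible reference genes "
            f"((1-p)G + K*pG), only {eligible.size} available"
        )
    draw = rng.choice(eligible, size=needed, replace=False)
    mapping = np.empty((G, K), dtype=draw.dtype)
    mapping[:n_shared, :] = draw[:n_shared, None]
    for k in range(K):
        mapping[n_shared:, k] = draw[n_shared + k * n_type : n_shared + (k + 1) * n_type]
    is_type = np.zeros(G, dtype=bool)
    is_type[n_shared:] = True
    return mapping, is_type


def sample_logfcs(
    categories: np.ndarray,
    mu_logfc: float,
    subpop_logfc_factors: Sequence[float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Signed log2 fold-changes per (gene, subpopulation).

    For non-EE/EP entries |logFC| ~ Gamma(shape 4, rate 4 / (r_k * mu_logFC))
    and the sign is +/- with probability 1/2 each; EE/EP entries are 0.
    """
    if mu_logfc <= 0:
        raise DStateError("mu_logfc must be positive")
    G, K = categories.shape
    factors = np.ones(K) if subpop_logfc_factors is None else np.asarray(subpop_logfc_factors, float)
    if np.any(factors < 0):
        raise DStateError("subpop logFC factors must be non-negative")
    scale = factors * mu_logfc / 4.0  # Gamma scale = 1/rate
    mag = rng.gamma(shape=4.0, scale=np.broadcast_to(scale, (G, K)))
    sign = rng.choice([-1.0, 1.0], size=(G, K))
    logfc = sign * mag
    logfc[np.isin(categories, ("EE", "EP"))] = 0.0
    return logfc


def _n_component(frac: float, n: int) -> int:
    """Cells in a mixture component: nearest integer, >= 1 when the component
    is nonempty (frac > 0), never more than n."""
    if frac <= 0 or n == 0:
        return 0
    return min(n, max(1, int(np.floor(frac * n + 0.5))))


def state_multipliers(
    category: str,
    fc: float,
    n_cells: int,
    group: str,
    dp_prop_a: float = 0.3,
    dp_prop_b: float = 0.7,
    ep_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell mean multipliers for one gene in the cells of one group.

    ``fc`` is the linear fold change 2**logFC; the affected group is "B".
    Component memberships are drawn uniformly at random.
    """
    if n_cells == 0:
        raise DStateError("empty group")
    rng = rng or np.random.default_rng()
    mult = np.ones(n_cells)
    if category == "EE":
        return mult
    if category == "EP":
        m = _n_component(ep_fraction, n_cells)
        idx = rng.choice(n_cells, size=m, replace=False)
        mult[idx] = fc
    elif category == "DE":
        if group == AFFECTED_GROUP:
            mult[:] = fc
    elif category == "DP":
        frac = dp_prop_b if group == AFFECTED_GROUP else dp_prop_a
        m = _n_component(frac, n_cells)
        idx = rng.choice(n_cells, size=m, replace=False)
        mult[idx] = fc
    elif category == "DM":
        if group == AFFECTED_GROUP:
            m = _n_component(0.5, n_cells)
            idx = rng.choice(n_cells, size=m, replace=False)
            mult[idx] = fc
    elif category == "DB":
        if group == AFFECTED_GROUP:
            mult[:] = fc / 2.0
        else:
            m = _n_component(0.5, n_cells)
            idx = rng.choice(n_cells, size=m, replace=False)
            mult[idx] = fc
    else:
        raise DStateError(f"unknown category {category!r}")
    return mult


def build_instance_means(
    category: str,
    logfc: float,
    mu: float,
    n_cells_a: int,
    n_cells_b: int,
    dp_prop_a: float = 0.3,
    dp_prop_b: float = 0.7,
    ep_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell NB means for one gene across the two groups of an instance."""
    rng = rng or np.random.default_rng()
    fc = 2.0 ** float(logfc)
    means = []
    for group, n in zip(GROUPS, (n_cells_a, n_cells_b)):
        means.append(
            mu
            * state_multipliers(
                category, fc, n, group, dp_prop_a, dp_prop_b, ep_fraction, rng
            )
        )
    return means[0], means[1]


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


def _draw_nb(mu: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Elementwise NB draws, Poisson where phi ~ 0.  phi is per-row."""
    phi = np.asarray(phi, dtype=float)[:, None]
    out = np.empty(mu.shape, dtype=np.int64)
    pois = np.broadcast_to(phi < 1e-8, mu.shape)
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        phi_full = np.broadcast_to(phi, mu.shape)[nb]
        r = 1.0 / phi_full
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def _category_multiplier_matrix(
    categories_k: np.ndarray,
    fc_k: np.ndarray,
    n_cells: int,
    group: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multipliers for all genes of one instance at once (G x n_cells)."""
    G = categories_k.size
    mult = np.ones((G, n_cells))

    def frac_rows(rows: np.ndarray, frac: float, value: np.ndarray) -> None:
        if rows.size == 0:
            return
        m = _n_component(frac, n_cells)
        if m == 0:
            return
        u = rng.random((rows.size, n_cells))
        picked = np.argpartition(u, m - 1, axis=1)[:, :m]
        mult[rows[:, None], picked] = value[:, None]

    cat = categories_k
    affected = group == AFFECTED_GROUP
    de = np.where(cat == "DE")[0]
    if affected and de.size:
        mult[de, :] = fc_k[de, None]
    frac_rows(np.where(cat == "EP")[0], cfg.ep_fraction, fc_k[np.where(cat == "EP")[0]])
    dp = np.where(cat == "DP")[0]
    frac_rows(dp, cfg.dp_prop_b if affected else cfg.dp_prop_a, fc_k[dp])
    dm = np.where(cat == "DM")[0]
    if affected:
        frac_rows(dm, 0.5, fc_k[dm])
    db = np.where(cat == "DB")[0]
    if db.size:
        if affected:
            mult[db, :] = fc_k[db, None] / 2.0
        else:
            frac_rows(db, 0.5, fc_k[db])
    return mult


def simulate_dataset(params: NBParams, config: SimConfig) -> SimulatedDataset:
    """Simulate a two-group multi-sample multi-subpopulation dataset.

    Reference subpopulations and samples are drawn from ``params`` (the same
    reference-sample set for both groups when ``paired``); each
    (sample, subpopulation) instance resamples ``cells_per_instance`` library
    sizes from the matching reference pool with replacement, composes per-cell
    means ``exp(beta) * lambda_c`` times the category multiplier, and draws NB
    counts.  Ground truth is recorded per (gene, subpopulation).
    """
    rng = substream(config.seed, "simulate")
    K = config.n_subpops
    S1, S2 = config.n_samples_per_group
    ref_subpops = list(params.subpops)
    if K > len(ref_subpops):
        raise DStateError(
            f"K={K} exceeds the {len(ref_subpops)} reference subpopulations"
        )
    chosen_subpops = list(rng.choice(ref_subpops, size=K, replace=False))

    # reference samples present in every chosen subpopulation
    pool = [
        s
        for s in params.sample_ids
        if all(s in params.subpops[k].cell_pools for k in chosen_subpops)
    ]
    if not pool:
        raise DStateError("no reference sample covers all chosen subpopulations")

    def draw_samples(n: int) -> list[str]:
        if n <= len(pool):
            return list(rng.choice(pool, size=n, replace=False))
        logger.info("drawing %d reference samples from %d with replacement", n, len(pool))
        return list(rng.choice(pool, size=n, replace=True))

    if config.paired:
        if S1 != S2:
            raise DStateError("paired design requires equal group sizes")
        shared = draw_samples(S1)
        ref_of_sim = {f"A{i+1}": shared[i] for i in range(S1)}
        ref_of_sim.update({f"B{i+1}": shared[i] for i in range(S2)})
    else:
        drawn = draw_samples(S1 + S2)
        ref_of_sim = {f"A{i+1}": drawn[i] for i in range(S1)}
        ref_of_sim.update({f"B{i+1}": drawn[S1 + i] for i in range(S2)})
    group_of_sim = {s: ("A" if s.startswith("A") else "B") for s in ref_of_sim}

    G = config.n_genes
    eligible = np.ones(len(params.gene_ids), dtype=bool)
    for k in chosen_subpops:
        eligible &= params.eligible_genes(k)
    mapping, is_type = sample_gene_mapping(
        G, K, config.p_type, np.where(eligible)[0], rng
    )
    categories = assign_categories(G, K, config.category_probs, rng)
    logfcs = sample_logfcs(categories, config.mu_logfc, config.subpop_logfc_factors, rng)
    fcs = 2.0 ** logfcs

    gene_ids = [f"gene{g+1:05d}" for g in range(G)]
    sim_clusters = [f"cluster{k+1}" for k in range(K)]
    n = config.cells_per_instance

    blocks, cell_ids, ann_rows = [], [], []
    mu_sums = np.zeros((G, K))
    cells_per_subpop = np.zeros(K, dtype=int)
    for k, (sim_k, ref_k) in enumerate(zip(sim_clusters, chosen_subpops)):
        sp = params.subpops[ref_k]
        ref_gene_idx = mapping[:, k]
        phi = sp.phi.values[ref_gene_idx]
        for sim_s, ref_s in ref_of_sim.items():
            group = group_of_sim[sim_s]
            lam_pool = sp.cell_pools[ref_s]
            lam = rng.choice(lam_pool, size=n, replace=True)
            beta = sp.beta[ref_s].values[ref_gene_idx]
            base_mu = np.exp(beta)[:, None] * lam[None, :]
            mult = _category_multiplier_matrix(
                categories[:, k], fcs[:, k], n, group, config, rng
            )
            mu = base_mu * mult
            blocks.append(_draw_nb(mu, phi, rng))
            mu_sums[:, k] += mu.sum(axis=1)
            cells_per_subpop[k] += n
            for i in range(n):
                cell_ids.append(f"{sim_s}.{sim_k}.c{i+1}")
                ann_rows.append((sim_s, sim_k, group))

    counts = CountMatrix(np.concatenate(blocks, axis=1), gene_ids, cell_ids)
    ann = pd.DataFrame(
        ann_rows, index=cell_ids, columns=["sample_id", "cluster_id", "group_id"]
    )
    truth = pd.DataFrame(
        {
            "gene": np.repeat(gene_ids, K),
            "cluster_id": np.tile(sim_clusters, G),
            "category": categories.ravel(),
            "logfc": logfcs.ravel(),
            "affected_group": AFFECTED_GROUP,
            "base_mean": (mu_sums / cells_per_subpop[None, :]).ravel(),
            "is_type_gene": np.repeat(is_type, K),
            "ref_gene": [params.gene_ids[i] for i in mapping.ravel()],
        }
    )
    return SimulatedDataset(counts, ann, truth, config, ref_samples=dict(ref_of_sim))


def subset_genes(
    dataset: SimulatedDataset, n_genes: int, rng: np.random.Generator
) -> SimulatedDataset:
    """Uniform random gene subset (keeps the empirical library-size spread)."""
    G = dataset.counts.n_genes
    if n_genes > G:
        raise DStateError(f"cannot subset {n_genes} genes from {G}")
    keep = np.sort(rng.choice(G, size=n_genes, replace=False))
    genes = [dataset.counts.gene_ids[i] for i in keep]
    cm = CountMatrix(dataset.counts.values[keep], genes, dataset.counts.cell_ids)
    truth = dataset.truth[dataset.truth["gene"].isin(genes)].reset_index(drop=True)
    return SimulatedDataset(cm, dataset.annotations, truth, dataset.config, dataset.ref_samples)
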