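"""Differential-state tests per subpopulation.

Pseudobulk engines (sample-level):

* :func:`fit_nb_ql` - NB generalized linear model on summed counts with a
  trended dispersion, quasi-likelihood dispersions from residual deviances
  squeezed by empirical Bayes, and a quasi-F test (edgeR-inspired engine).
* :func:`fit_trend_lm` - moderated t on mean log-counts with an
  intensity-dependent prior-variance trend (limma-trend-style engine).
* :func:`fit_voom_lm` - weighted least squares on pseudobulk log-CPM with
  precision weights from a mean-variance lowess trend, then the same
  moderation (voom-style engine).

Cell-level engine:

* :func:`test_ad` - k-sample Anderson-Darling permutation test on cell-level
  log-counts, grouping cells either by sample (sid) or by condition (gid).

All engines emit one row per (gene, subpopulation) with a log2 fold-change
(where defined), the test statistic, and a raw p-value; untested rows are
kept and flagged rather than dropped.  Multiple-testing adjustment lives in
:mod:`dstate.evaluation`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._stats import (
    estimate_dispersion_grid,
    fit_nb_glm,
    lowess_trend,
    nb_deviance,
    squeeze_var,
    tmm_norm_factors,
)
from .aggregation import Pseudobulk, compute_logcounts
from .core_io import DesignSpec, DStateError, TestConfig, substream

logger = logging.getLogger("dstate")

RESULT_COLUMNS = [
    "gene",
    "cluster_id",
    "logfc",
    "stat",
    "p_val",
    "p_adj_loc",
    "p_adj_glb",
    "mean_expr",
    "tested",
]


@dataclass
class DSResult:
    """Per-(gene, subpopulation) differential-state test results."""

    method: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RESULT_COLUMNS) - set(self.table.columns)
        if missing:
            raise DStateError(f"result table missing columns {sorted(missing)}")
        p = self.table["p_val"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise DStateError("p-values outside [0, 1]")

    def tests_per_subpop(self) -> pd.Series:
        t = self.table[self.table["tested"]]
        return t.groupby("cluster_id", observed=True).size()


def _untested_rows(genes, cluster: str, mean_expr=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": list(genes),
            "cluster_id": cluster,
            "logfc": np.nan,
            "stat": np.nan,
            "p_val": np.nan,
            "p_adj_loc": np.nan,
            "p_adj_glb": np.nan,
            "mean_expr": np.nan if mean_expr is None else mean_expr,
            "tested": False,
        }
    )
    return df


def _group_matrix(design: DesignSpec, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [1, group] and the comparison-group indicator."""
    ref, cmp_ = design.contrast
    grp = np.array([design.group_of_sample[s] for s in samples])
    ind = (grp == cmp_).astype(float)
    X = np.column_stack([np.ones(len(samples)), ind])
    return X, ind


def _check_two_per_group(ind: np.ndarray) -> bool:
    return (ind == 1).sum() >= 2 and (ind == 0).sum() >= 2


# ---------------------------------------------------------------------------
# NB quasi-likelihood engine on summed counts
# ---------------------------------------------------------------------------


def fit_nb_ql(
    pb: Pseudobulk,
    design: DesignSpec | None = None,
    ql_prior_df: float | None = None,
    normalization: str = "tmm",
) -> DSResult:
    """NB quasi-likelihood F-test on sum-of-counts pseudobulk.

    Per subpopulation: log effective-library-size offsets from the
    pseudobulk column sums (TMM-corrected by default, so that a minority of
    strongly differential genes cannot bias the remainder), a trended NB
    dispersion across genes, per-gene NB GLM fits of the two-group model,
    quasi-likelihood dispersions from residual deviances squeezed toward an
    intensity trend by empirical Bayes, and a quasi-F statistic with
    moderated denominator degrees of freedom.  ``ql_prior_df`` overrides the
    moment-matched prior df of the squeeze (0 reverts to the unmoderated
    quasi-F); ``normalization`` is "tmm" or "libsize".
    """
    if pb.assay_type != "sum_counts":
        raise DStateError("fit_nb_ql requires sum-of-counts pseudobulk")
    if normalization not in ("tmm", "libsize"):
        raise DStateError(f"unknown normalization {normalization!r}")
    design = design or pb.design
    rows = []
    for k, mat in pb.matrices.items():
        samples = [s for s in mat.columns]
        y = mat.values.astype(float)
        if not np.allclose(y, np.round(y)):
            raise DStateError("non-integer pseudobulk counts")
        X, ind = _group_matrix(design, samples)
        if not _check_two_per_group(ind):
            warnings.warn(f"subpopulation {k}: fewer than 2 samples per group; skipped")
            rows.append(_untested_rows(mat.index, k))
            continue
        lib = y.sum(axis=0)
        if normalization == "tmm":
            lib = lib * tmm_norm_factors(y)
        offsets = np.log(lib)
        expressed = y.sum(axis=1) > 0
        genes_e = mat.index[expressed]
        ye = y[expressed]
        G, S = ye.shape
        avg_logcpm = np.log2(((ye + 0.5) / (lib + 1.0)[None, :] * 1e6).mean(axis=1))

        # trended NB dispersion: Cox-Reid-adjusted genewise profile ML at
        # group-mean fits, then lowess over average abundance
        mu0 = _group_mean_fit(ye, lib, ind)
        phi_gene = estimate_dispersion_grid(ye, mu0, cr_labels=ind)
        log_phi = np.log(np.maximum(phi_gene, 1e-6))
        phi_trend = np.exp(lowess_trend(avg_logcpm, log_phi))
        phi_trend = np.clip(phi_trend, 0.0, 100.0)

        beta, mu_full = fit_nb_glm(ye, X, offsets, phi_trend)
        _, mu_null = fit_nb_glm(ye, X[:, :1], offsets, phi_trend)
        dev_full = nb_deviance(ye, mu_full, phi_trend)
        dev_null = nb_deviance(ye, mu_null, phi_trend)
        df_res = S - X.shape[1]
        s2 = np.maximum(dev_full, 0.0) / df_res
        s2_post, d0, _ = squeeze_var(
            np.maximum(s2, 1e-10), df_res, covariate=avg_logcpm, prior_df=ql_prior_df
        )
        # deviance differences below numerical resolution are genuine zeros;
        # floor the QL dispersion so they cannot blow up into spurious F values
        lr = np.maximum(dev_null - dev_full, 0.0)
        lr[lr < 1e-8] = 0.0
        F = lr / np.maximum(s2_post, 1e-8)
        df_total = min(d0 + df_res, 1e7) if np.isfinite(d0) else 1e7
        p = scipy.stats.f.sf(F, 1, df_total)
        logfc = beta[:, 1] / np.log(2.0)

        df = pd.DataFrame(
            {
                "gene": genes_e,
                "cluster_id": k,
                "logfc": logfc,
                "stat": F,
                "p_val": p,
                "p_adj_loc": np.nan,
                "p_adj_glb": np.nan,
                "mean_expr": avg_logcpm,
                "tested": True,
            }
        )
        rows.append(df)
        if (~expressed).any():
            rows.append(_untested_rows(mat.index[~expressed], k))
    table = pd.concat(rows, ignore_index=True)
    return DSResult("pb-nbql", table)


def _group_mean_fit(y: np.ndarray, lib: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """Closed-form two-group ratio-of-totals means with library offsets."""
    mu = np.empty_like(y, dtype=float)
    for v in (0.0, 1.0):
        m = ind == v
        tot = y[:, m].sum(axis=1)
        rate = (tot + 0.125) / lib[m].sum()
        mu[:, m] = rate[:, None] * lib[m][None, :]
    return np.maximum(mu, 1e-10)


# ---------------------------------------------------------------------------
# moderated-t engines
# ---------------------------------------------------------------------------


def _ols_two_group(y: np.ndarray, X: np.ndarray, w: np.ndarray | None = None):
    """Per-gene (weighted) least squares for a shared S x 2 design.

    Returns (beta G x 2, residual variance, unscaled var of beta1, fitted).
    """
    G, S = y.shape
    if w is None:
        w = np.ones_like(y)
    XtWX = np.einsum("gs,sp,sq->gpq", w, X, X)
    XtWy = np.einsum("gs,sp,gs->gp", w, X, y)
    XtWX += 1e-12 * np.eye(X.shape[1])[None, :, :]
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta @ X.T
    df = S - X.shape[1]
    rss = (w * (y - fitted) ** 2).sum(axis=1)
    s2 = rss / df
    cov = np.linalg.inv(XtWX)
    v11 = cov[:, 1, 1]
    return beta, s2, v11, fitted


def _moderated_t_table(
    genes,
    cluster,
    beta1,
    s2,
    v11,
    df_res: int,
    avg_expr,
    moderate: bool,
    trend: bool,
    prior_df: float | None,
):
    if moderate:
        s2_post, d0, _ = squeeze_var(
            np.maximum(s2, 1e-12),
            df_res,
            covariate=avg_expr if trend else None,
            prior_df=prior_df,
        )
        df_t = min(d0 + df_res, 1e7) if np.isfinite(d0) else 1e7
    else:
        s2_post, df_t = s2, df_res
    denom = np.sqrt(np.maximum(s2_post * v11, 1e-300))
    t = beta1 / denom
    t = np.where(np.abs(beta1) < 1e-12, 0.0, t)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df_t)
    return pd.DataFrame(
        {
            "gene": genes,
            "cluster_id": cluster,
            "logfc": beta1,
            "stat": t,
            "p_val": np.clip(p, 0.0, 1.0),
            "p_adj_loc": np.nan,
            "p_adj_glb": np.nan,
            "mean_expr": avg_expr,
            "tested": True,
        }
    )


def fit_trend_lm(
    pb: Pseudobulk,
    design: DesignSpec | None = None,
    moderate: bool = True,
    trend: bool = True,
    prior_df: float | None = None,
) -> DSResult:
    """Moderated t on mean-of-log-counts pseudobulk (limma-trend-style).

    Ordinary least squares of mean log2-counts on the group factor; residual
    variances moderated by empirical Bayes with an intensity-dependent prior
    trend.  With ``moderate=False`` this reduces to the classical pooled
    two-sample t-test.
    """
    if pb.assay_type != "mean_logcounts":
        raise DStateError("fit_trend_lm requires mean-logcounts pseudobulk")
    design = design or pb.design
    rows = []
    for k, mat in pb.matrices.items():
        samples = list(mat.columns)
        X, ind = _group_matrix(design, samples)
        if not _check_two_per_group(ind):
            warnings.warn(f"subpopulation {k}: fewer than 2 samples per group; skipped")
            rows.append(_untested_rows(mat.index, k))
            continue
        y = mat.values.astype(float)
        if y.shape[1] - 2 < 1:
            raise DStateError("zero residual degrees of freedom")
        beta, s2, v11, _ = _ols_two_group(y, X)
        rows.append(
            _moderated_t_table(
                mat.index, k, beta[:, 1], s2, v11, y.shape[1] - 2,
                y.mean(axis=1), moderate, trend, prior_df,
            )
        )
    return DSResult("pb-trend", pd.concat(rows, ignore_index=True))


def voom_weights(logcpm: np.ndarray, lib: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-observation precision weights from the mean-variance lowess trend.

    Fits each gene by OLS, smooths sqrt(residual SD) against average
    log2-count, and evaluates the trend at every fitted log-count; weights
    are the inverse fourth power (inverse predicted variance).
    """
    _, s2, _, fitted = _ols_two_group(logcpm, X)
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(np.maximum(s2, 1e-12)))
    trend_at = lowess_trend(sx, sy)
    order = np.argsort(sx)
    fitted_counts = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_counts, sx[order], trend_at[order])
    return 1.0 / np.maximum(pred, 1e-6) ** 4


def fit_voom_lm(
    pb: Pseudobulk,
    design: DesignSpec | None = None,
    prior_df: float | None = None,
    normalization: str = "tmm",
) -> DSResult:
    """Precision-weighted moderated t on pseudobulk log-CPM (voom-style).

    A lowess trend of sqrt(residual SD) versus average log-count yields
    per-observation precision weights; genes are then fit by weighted least
    squares and moderated as in :func:`fit_trend_lm` (without the prior
    trend, as the weights already absorb the mean-variance relation).
    """
    if pb.assay_type != "sum_counts":
        raise DStateError("fit_voom_lm requires sum-of-counts pseudobulk")
    design = design or pb.design
    rows = []
    for k, mat in pb.matrices.items():
        samples = list(mat.columns)
        X, ind = _group_matrix(design, samples)
        if not _check_two_per_group(ind):
            warnings.warn(f"subpopulation {k}: fewer than 2 samples per group; skipped")
            rows.append(_untested_rows(mat.index, k))
            continue
        y = mat.values.astype(float)
        expressed = y.sum(axis=1) > 0
        if (~expressed).any():
            rows.append(_untested_rows(mat.index[~expressed], k))
        ye = y[expressed]
        lib = y.sum(axis=0)
        if normalization == "tmm":
            lib = lib * tmm_norm_factors(y)
        logcpm = np.log2((ye + 0.5) / (lib + 1.0)[None, :] * 1e6)
        w = voom_weights(logcpm, lib, X)
        beta_w, s2_w, v11_w, _ = _ols_two_group(logcpm, X, w=w)
        rows.append(
            _moderated_t_table(
                mat.index[expressed], k, beta_w[:, 1], s2_w, v11_w,
                ye.shape[1] - 2, logcpm.mean(axis=1),
                moderate=True, trend=False, prior_df=prior_df,
            )
        )
    return DSResult("pb-voom", pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# k-sample Anderson-Darling permutation test on cell-level data
# ---------------------------------------------------------------------------


def _ad_stat_from_counts(f: np.ndarray, l: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Ties-adjusted (midrank) k-sample AD criterion from value-class counts.

    ``f`` has shape (..., k, L): counts of each sample in each distinct
    value class; ``l`` the pooled class counts (L,), ``n`` the sample sizes
    (k,).  Fully tied data yield 0.
    """
    N = float(l.sum())
    L = l.size
    if L < 2:
        return np.zeros(f.shape[:-2])
    B = np.cumsum(l) - l / 2.0
    M = np.cumsum(f, axis=-1) - f / 2.0
    denom = B * (N - B) - N * l / 4.0
    weight = np.where(denom > 0, (l / N) / np.maximum(denom, 1e-300), 0.0)
    inner = ((N * M - n[:, None] * B[None, :]) ** 2 * weight[None, :]).sum(axis=-1)
    return (N - 1) / N * (inner / n).sum(axis=-1)


def ad_ksample_statistic(values: np.ndarray, group_labels: np.ndarray) -> float:
    """Rank-based k-sample Anderson-Darling criterion (midrank tie handling)."""
    values = np.asarray(values, dtype=float)
    labels, counts = np.unique(np.asarray(group_labels), return_counts=True)
    if labels.size < 2:
        raise DStateError("need at least 2 groups")
    if counts.min() == 0:
        raise DStateError("empty group")
    codes = np.searchsorted(labels, np.asarray(group_labels))
    _, vi = np.unique(values, return_inverse=True)
    L = vi.max() + 1
    l = np.bincount(vi, minlength=L).astype(float)
    f = np.bincount(codes * L + vi, minlength=labels.size * L).astype(float)
    f = f.reshape(labels.size, L)
    return float(_ad_stat_from_counts(f, l, counts.astype(float)))


def _ad_permutation_p(
    values: np.ndarray,
    codes: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 250,
) -> tuple[float, float]:
    """Observed statistic and permutation p-value ((b+1)/(B+1))."""
    _, vi = np.unique(np.asarray(values, float), return_inverse=True)
    L = int(vi.max() + 1)
    n = np.bincount(codes, minlength=k).astype(float)
    l = np.bincount(vi, minlength=L).astype(float)
    f_obs = np.bincount(codes * L + vi, minlength=k * L).astype(float).reshape(k, L)
    obs = float(_ad_stat_from_counts(f_obs, l, n))
    if L < 2:
        return 0.0, 1.0
    n_ge = 0
    done = 0
    ncells = codes.size
    while done < n_perm:
        b = min(chunk, n_perm - done)
        P = rng.permuted(np.broadcast_to(codes, (b, ncells)), axis=1)
        flat = (np.arange(b)[:, None] * (k * L) + P * L + vi[None, :]).ravel()
        f = np.bincount(flat, minlength=b * k * L).astype(float).reshape(b, k, L)
        stats = _ad_stat_from_counts(f, l, n)
        n_ge += int((stats >= obs - 1e-12).sum())
        done += b
    return obs, (n_ge + 1) / (n_perm + 1)


def test_ad(dataset, grouping: str = "group", cfg: TestConfig | None = None) -> DSResult:
    """Cell-level k-sample AD permutation test per (gene, subpopulation).

    ``grouping="sample"`` (sid) tests whether any sample's distribution
    departs from the rest; ``grouping="group"`` (gid) pools cells by
    condition.  Tests run on cell-level log-counts; genes expressed in fewer
    than ``cfg.min_cells_per_instance`` cells of a subpopulation (default 10)
    are flagged untested.  No fold-change is reported.
    """
    if grouping not in ("sample", "group"):
        raise DStateError("grouping must be 'sample' or 'group'")
    cfg = cfg or TestConfig()
    rng = substream(cfg.seed, f"ad-{grouping}")
    Y = dataset.counts.values
    ann = dataset.annotations
    lam = Y.sum(axis=0).astype(float)
    logexpr = compute_logcounts(Y, lam)
    label_col = "sample_id" if grouping == "sample" else "group_id"
    rows = []
    for k in pd.unique(ann["cluster_id"]):
        mask = (ann["cluster_id"] == k).values
        labels_raw = ann.loc[mask, label_col].values
        uniq = np.unique(labels_raw)
        codes = np.searchsorted(uniq, labels_raw)
        if uniq.size < 2 or np.bincount(codes).min() == 0:
            warnings.warn(f"subpopulation {k}: fewer than 2 non-empty groups; skipped")
            rows.append(_untested_rows(dataset.counts.gene_ids, str(k)))
            continue
        sub = logexpr[:, mask]
        n_expr = (Y[:, mask] > 0).sum(axis=1)
        testable = n_expr >= cfg.min_cells_per_instance
        for g in range(Y.shape[0]):
            gene = dataset.counts.gene_ids[g]
            if not testable[g]:
                rows.append(
                    {
                        "gene": gene, "cluster_id": str(k), "logfc": np.nan,
                        "stat": np.nan, "p_val": np.nan, "p_adj_loc": np.nan,
                        "p_adj_glb": np.nan, "mean_expr": sub[g].mean(),
                        "tested": False,
                    }
                )
                continue
            stat, p = _ad_permutation_p(sub[g], codes, uniq.size, cfg.n_permutations, rng)
            rows.append(
                {
                    "gene": gene, "cluster_id": str(k), "logfc": np.nan,
                    "stat": stat, "p_val": p, "p_adj_loc": np.nan,
                    "p_adj_glb": np.nan, "mean_expr": sub[g].mean(),
                    "tested": True,
                }
            )
    frames = [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in rows]
    table = pd.concat(frames, ignore_index=True)
    return DSResult(f"ad-{'sid' if grouping == 'sample' else 'gid'}", table)


# ---------------------------------------------------------------------------
# convenience dispatch
# ---------------------------------------------------------------------------

PB_METHODS = {"pb-nbql", "pb-trend", "pb-voom"}
AD_METHODS = {"ad-sid", "ad-gid"}
#: reserved ids of out-of-scope mixed-model engines, kept for interoperability
RESERVED_METHODS = {"mm-dream", "mm-dream2", "mm-vst", "mm-nbinom"}


def run_method(dataset, method: str, cfg: TestConfig | None = None) -> DSResult:
    """Aggregate (as the method requires) and test a simulated/real dataset."""
    from .aggregation import aggregate

    if method == "pb-nbql":
        return fit_nb_ql(aggregate(dataset, "counts", "sum"))
    if method == "pb-trend":
        return fit_trend_lm(aggregate(dataset, "logcounts", "mean"))
    if method == "pb-voom":
        return fit_voom_lm(aggregate(dataset, "counts", "sum"))
    if method == "ad-sid":
        return test_ad(dataset, "sample", cfg)
    if method == "ad-gid":
        return test_ad(dataset, "group", cfg)
    if method in RESERVED_METHODS:
        raise DStateError(f"method id {method!r} is reserved but not implemented")
    raise DStateError(f"unknown method {method!r}")
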