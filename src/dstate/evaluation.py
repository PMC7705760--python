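"""Evaluation harness: adjustment, stratified TPR/FDR, calibration, scoring.

p-values are Benjamini-Hochberg adjusted either *locally* (within each
subpopulation's G tests) or *globally* (across all G x K tests).  Detection
performance is stratified by differential-distribution category against the
common EE + EP negative set, at FDR cutoffs of 1%, 5% and 10%, after
excluding genes whose simulated expression mean falls below 0.1.  Null
calibration is summarized by the one-sample Kolmogorov-Smirnov distance of
raw p-values from Uniform(0,1), and fold-change recovery by the per-category
Pearson correlation and regression slope of estimated on simulated logFC.
A weighted score card condenses all criteria per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import DS_CATEGORIES, DStateError, substream
from .ds_testing import DSResult

FDR_CUTOFFS = (0.01, 0.05, 0.10)
NEGATIVE_CATEGORIES = ("EE", "EP")

#: rating encodings: default from the printed criteria, alternative from the
#: summary-figure caption
ENCODINGS = {
    "methods": {"good": 3.0, "intermediate": 2.0, "poor": 0.0, "NA": 0.0},
    "figure": {"good": 2.0, "intermediate": 1.0, "poor": 0.0, "NA": 0.0},
}


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------


def _bh(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise DStateError("p-values outside [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def adjust_pvalues(results: DSResult, scope: str = "both") -> DSResult:
    """Fill BH-adjusted p-value columns.

    ``local`` adjusts within each subpopulation (n = G tests), ``global``
    across all subpopulations at once (n = G x K); ``both`` fills both
    columns.  Returns a new DSResult; the input is not mutated.
    """
    if scope not in ("local", "global", "both"):
        raise DStateError(f"unknown adjustment scope {scope!r}")
    table = results.table.copy()
    p = table["p_val"].values.astype(float)
    if scope in ("global", "both"):
        table["p_adj_glb"] = _bh(p)
    if scope in ("local", "both"):
        adj = np.full(p.shape, np.nan)
        for k in table["cluster_id"].unique():
            m = (table["cluster_id"] == k).values
            adj[m] = _bh(p[m])
        table["p_adj_loc"] = adj
    return DSResult(results.method, table)


# ---------------------------------------------------------------------------
# stratified TPR / FDR
# ---------------------------------------------------------------------------


def _join_truth(table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    merged = table.merge(
        truth[["gene", "cluster_id", "category", "logfc", "base_mean"]],
        on=["gene", "cluster_id"],
        how="left",
        suffixes=("", "_true"),
    )
    if merged["category"].isna().any():
        missing = merged[merged["category"].isna()][["gene", "cluster_id"]].head()
        raise DStateError(f"tests without matching truth rows, e.g.\n{missing}")
    return merged


def compute_performance(
    results: DSResult,
    truth: pd.DataFrame,
    cutoffs=FDR_CUTOFFS,
    mean_filter: float = 0.1,
) -> pd.DataFrame:
    """Stratified TPR/FDR table at each cutoff and adjustment scope.

    Rows with simulated base mean below ``mean_filter`` are excluded.  Each
    DS category is scored against the same EE + EP negative set; category
    ``"DS"`` pools all true differential categories.  FDR is defined as 0
    when nothing is called.
    """
    merged = _join_truth(results.table[results.table["tested"]], truth)
    merged = merged[merged["base_mean"] >= mean_filter]
    rows = []
    strata = list(DS_CATEGORIES) + ["DS"]
    for scope, col in (("local", "p_adj_loc"), ("global", "p_adj_glb")):
        if merged[col].isna().all():
            continue
        for category in strata:
            pos_cats = list(DS_CATEGORIES) if category == "DS" else [category]
            sub = merged[merged["category"].isin(pos_cats + list(NEGATIVE_CATEGORIES))]
            is_pos = sub["category"].isin(pos_cats).values
            n_true = int(is_pos.sum())
            if n_true == 0 and category != "DS":
                continue
            for cutoff in cutoffs:
                called = (sub[col] < cutoff).values
                tp = int((called & is_pos).sum())
                fp = int((called & ~is_pos).sum())
                rows.append(
                    {
                        "method": results.method,
                        "category": category,
                        "cutoff": cutoff,
                        "scope": scope,
                        "TPR": tp / n_true if n_true else 0.0,
                        "FDR": fp / (tp + fp) if (tp + fp) else 0.0,
                        "n_called": tp + fp,
                        "n_true": n_true,
                    }
                )
    return pd.DataFrame(rows)


def ks_uniformity(pvals) -> float:
    """Two-sided one-sample KS distance of p-values from Uniform(0,1)."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise DStateError("empty p-value vector")
    return float(scipy.stats.kstest(p, "uniform").statistic)


def logfc_concordance(results: DSResult, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-category Pearson r and slope of estimated-on-simulated logFC.

    Methods that report no fold-changes get NA rows rather than an error.
    """
    merged = _join_truth(results.table[results.table["tested"]], truth)
    rows = []
    for category in DS_CATEGORIES:
        sub = merged[merged["category"] == category]
        est, sim = sub["logfc"].values, sub["logfc_true"].values
        ok = np.isfinite(est) & np.isfinite(sim)
        if ok.sum() < 3:
            rows.append(
                {"method": results.method, "category": category, "n": int(ok.sum()),
                 "pearson_r": np.nan, "slope": np.nan}
            )
            continue
        r = scipy.stats.pearsonr(sim[ok], est[ok]).statistic
        slope = np.polyfit(sim[ok], est[ok], 1)[0]
        rows.append(
            {"method": results.method, "category": category, "n": int(ok.sum()),
             "pearson_r": float(r), "slope": float(slope)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-n intersections
# ---------------------------------------------------------------------------


def intersect_top_hits(
    results_by_method: dict[str, DSResult],
    truth: pd.DataFrame,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Upset-style intersection counts of top-n (gene, subpopulation) hits.

    Per method, the top-n set by raw p-value with n = min(n1, n2): n1 =
    number of combinations simulated differential, n2 = number called at
    ``fdr_cutoff`` on locally adjusted p-values.  Every observed membership
    pattern is counted and annotated by true-category composition.
    """
    if len(results_by_method) < 2:
        raise DStateError("need at least 2 methods to intersect")
    n1 = int(truth["category"].isin(DS_CATEGORIES).sum())
    top_sets: dict[str, set] = {}
    for name, res in results_by_method.items():
        tab = res.table[res.table["tested"]]
        n2 = int((tab["p_adj_loc"] < fdr_cutoff).sum())
        n = min(n1, n2)
        top = tab.nsmallest(n, "p_val") if n > 0 else tab.iloc[:0]
        top_sets[name] = set(zip(top["gene"], top["cluster_id"]))
    cat_of = dict(zip(zip(truth["gene"], truth["cluster_id"]), truth["category"]))
    universe = set().union(*top_sets.values())
    patterns: dict[frozenset, dict] = {}
    for hit in universe:
        members = frozenset(m for m, s in top_sets.items() if hit in s)
        entry = patterns.setdefault(members, {"count": 0, "categories": {}})
        entry["count"] += 1
        c = cat_of.get(hit, "NA")
        entry["categories"][c] = entry["categories"].get(c, 0) + 1
    rows = [
        {
            "methods": tuple(sorted(m)),
            "degree": len(m),
            "count": d["count"],
            "categories": d["categories"],
        }
        for m, d in patterns.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("count", ascending=False, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["methods", "degree", "count", "categories"])
    )


# ---------------------------------------------------------------------------
# score card
# ---------------------------------------------------------------------------


def dd_category_weights(
    unimodal: float = 0.75, bimodal: float = 0.25, trimodal: float = 0.05
) -> dict[str, float]:
    """TPR/FDR criterion weights from modality frequencies.

    The unimodal share goes to DE, the bimodal share is split equally
    between DP and DM, and the trimodal share goes to DB.
    """
    return {"DE": unimodal, "DP": bimodal / 2, "DM": bimodal / 2, "DB": trimodal}


def _rate_tpr(x: float) -> str:
    if not np.isfinite(x):
        return "NA"
    return "good" if x > 2 / 3 else ("intermediate" if x > 1 / 3 else "poor")


def _rate_fdr(x: float) -> str:
    if not np.isfinite(x):
        return "NA"
    return "good" if x < 0.05 else ("intermediate" if x < 0.1 else "poor")


def _rate_ks(x: float) -> str:
    if not np.isfinite(x):
        return "NA"
    return "good" if x < 0.1 else ("intermediate" if x < 0.25 else "poor")


def _rate_slope(x: float) -> str:
    if not np.isfinite(x):
        return "NA"
    return "good" if x > 2 / 3 else ("intermediate" if x > 1 / 3 else "poor")


@dataclass
class ScoreCard:
    """Ratings, weights and weighted scores per method."""

    ratings: pd.DataFrame  # methods x criteria, values in {good,intermediate,poor,NA}
    weights: dict[str, float]
    encoding: str
    scores: pd.Series = field(init=False)
    ranks: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        enc = ENCODINGS[self.encoding]
        unknown = set(self.ratings.columns) - set(self.weights)
        if unknown:
            raise DStateError(f"unknown criterion key(s): {sorted(unknown)}")
        w = np.array([self.weights[c] for c in self.ratings.columns])
        vals = self.ratings.apply(lambda col: col.map(enc)).values
        self.scores = pd.Series(
            (vals * w).sum(axis=1) / w.sum(), index=self.ratings.index
        ).sort_values(ascending=False)
        self.ranks = pd.Series(
            np.arange(1, len(self.scores) + 1), index=self.scores.index
        )


def score_methods(
    perf: pd.DataFrame,
    ks_by_method: dict[str, float],
    logfc_table: pd.DataFrame | None = None,
    manual_flags: dict[str, dict[str, str]] | None = None,
    encoding: str = "methods",
    category_weights: dict[str, float] | None = None,
    other_weight: float = 0.5,
    cutoff: float = 0.05,
) -> ScoreCard:
    """Condense all evaluation criteria into a weighted score card.

    ``perf`` is a (possibly replicate-averaged) performance table with a
    ``method`` column; TPR/FDR ratings use the 5% cutoff on local
    adjustment.  ``ks_by_method`` maps method to its mean null KS distance.
    logFC estimation is rated from the median concordance slope; complex
    design and speed are qualitative flags supplied by the caller, never
    measured here.
    """
    cat_w = category_weights or dd_category_weights()
    manual_flags = manual_flags or {}
    methods = sorted(perf["method"].unique())
    criteria: dict[str, dict[str, str]] = {}
    for m in methods:
        sub = perf[
            (perf["method"] == m)
            & (perf["cutoff"] == cutoff)
            & (perf["scope"] == "local")
        ]
        row: dict[str, str] = {}
        for cat in cat_w:
            c = sub[sub["category"] == cat]
            row[f"TPR_{cat}"] = _rate_tpr(c["TPR"].mean() if len(c) else np.nan)
            row[f"FDR_{cat}"] = _rate_fdr(c["FDR"].mean() if len(c) else np.nan)
        row["null_simulation"] = _rate_ks(ks_by_method.get(m, np.nan))
        if logfc_table is not None and (logfc_table["method"] == m).any():
            slopes = logfc_table.loc[logfc_table["method"] == m, "slope"]
            row["logfc_estimation"] = _rate_slope(float(slopes.median()))
        else:
            row["logfc_estimation"] = "NA"
        flags = manual_flags.get(m, {})
        row["complex_design"] = flags.get("complex_design", "NA")
        row["speed"] = flags.get("speed", "NA")
        criteria[m] = row
    ratings = pd.DataFrame(criteria).T
    weights = {}
    for cat, w in cat_w.items():
        weights[f"TPR_{cat}"] = w
        weights[f"FDR_{cat}"] = w
    for c in ("null_simulation", "logfc_estimation", "complex_design", "speed"):
        weights[c] = other_weight
    return ScoreCard(ratings, weights, encoding)


# ---------------------------------------------------------------------------
# benchmark runner (replicate grid)
# ---------------------------------------------------------------------------


def run_benchmark(
    params,
    sim_config,
    methods: list[str],
    n_replicates: int = 5,
    master_seed: int = 1,
    mean_filter: float = 0.1,
):
    """simulate -> aggregate -> test -> evaluate over a replicate grid.

    Returns (performance table with a ``replicate`` column, per-method mean
    null KS over replicates is up to the caller since replicates here carry
    signal).  Each replicate derives its own simulation seed from
    ``master_seed``.
    """
    import dataclasses

    from .ds_testing import run_method
    from .simulator import simulate_dataset

    perfs = []
    for rep in range(n_replicates):
        rep_seed = int(substream(master_seed, f"benchmark-rep{rep}").integers(2**31))
        cfg = dataclasses.replace(sim_config, seed=rep_seed)
        data = simulate_dataset(params, cfg)
        for method in methods:
            res = adjust_pvalues(run_method(data, method))
            perf = compute_performance(res, data.truth, mean_filter=mean_filter)
            perf.insert(0, "replicate", rep)
            perfs.append(perf)
    return pd.concat(perfs, ignore_index=True)
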