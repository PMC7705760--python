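import numpy as np
import pandas as pd
import pytest

import dstate as ds
from dstate.ds_testing import DSResult, RESULT_COLUMNS


def make_result(p_vals, clusters=None, genes=None, logfc=None, method="m"):
    n = len(p_vals)
    tab = pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"g{i}" for i in range(n)],
            "cluster_id": clusters if clusters is not None else ["k1"] * n,
            "logfc": logfc if logfc is not None else np.zeros(n),
            "stat": np.zeros(n),
            "p_val": p_vals,
            "p_adj_loc": np.nan,
            "p_adj_glb": np.nan,
            "mean_expr": np.ones(n),
            "tested": [np.isfinite(p) for p in p_vals],
        }
    )
    return DSResult(method, tab)


def brute_force_bh(p):
    """Reference BH step-up."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def test_bh_worked_examples():
    res = make_result([0.01, 0.02, 0.03, 0.04])
    adj = ds.adjust_pvalues(res, "local").table["p_adj_loc"]
    np.testing.assert_allclose(adj, 0.04)  # all raise to 0.04
    single = ds.adjust_pvalues(make_result([0.05]), "local").table["p_adj_loc"]
    assert single.iloc[0] == pytest.approx(0.05)


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        p = rng.random(n) ** rng.uniform(0.5, 3)
        res = ds.adjust_pvalues(make_result(p), "local")
        np.testing.assert_allclose(
            res.table["p_adj_loc"].values, brute_force_bh(p), rtol=1e-12
        )


def test_adjust_scopes_and_validation():
    res = make_result([0.01, 0.5, 0.02, 0.9], clusters=["k1", "k1", "k2", "k2"])
    out = ds.adjust_pvalues(res, "both").table
    # local: within-cluster n = 2; global n = 4
    np.testing.assert_allclose(out["p_adj_loc"], [0.02, 0.5, 0.04, 0.9])
    np.testing.assert_allclose(out["p_adj_glb"], brute_force_bh([0.01, 0.5, 0.02, 0.9]))
    assert (out["p_adj_loc"] >= out["p_val"] - 1e-15).all()
    bad = make_result([0.5])
    bad.table.loc[0, "p_val"] = 1.5
    with pytest.raises(ds.DStateError):
        ds.adjust_pvalues(bad, "local")
    # untested rows keep NaN
    res_nan = ds.adjust_pvalues(make_result([0.1, np.nan]), "local").table
    assert np.isnan(res_nan["p_adj_loc"].iloc[1])


# ---------------------------------------------------------------------------
# performance table
# ---------------------------------------------------------------------------


def _truth(categories, genes=None, clusters=None, base_mean=1.0, logfc=None):
    n = len(categories)
    return pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"g{i}" for i in range(n)],
            "cluster_id": clusters if clusters is not None else ["k1"] * n,
            "category": categories,
            "logfc": logfc if logfc is not None else [0.0] * n,
            "base_mean": base_mean,
        }
    )


def test_performance_hand_count():
    """20 tests, 4 true DS; 5 called of which 3 true -> TPR 0.75, FDR 0.4."""
    cats = ["DE"] * 4 + ["EE"] * 16
    # 3 true positives and 2 false positives called at 0.05
    p = [0.001, 0.001, 0.001, 0.5, 0.001, 0.001] + [0.8] * 14
    res = ds.adjust_pvalues(make_result(np.array(p) / 10))  # keep BH below cutoff
    perf = ds.compute_performance(res, _truth(cats), cutoffs=(0.05,))
    row = perf[(perf.category == "DE") & (perf.scope == "local")].iloc[0]
    assert row["TPR"] == pytest.approx(0.75)
    assert row["FDR"] == pytest.approx(0.4)
    assert row["n_called"] == 5 and row["n_true"] == 4


def test_performance_no_calls_and_default_cutoffs():
    res = ds.adjust_pvalues(make_result([0.9, 0.8, 0.7, 0.95]))
    perf = ds.compute_performance(res, _truth(["DE", "DE", "EE", "EE"]))
    assert sorted(perf["cutoff"].unique()) == [0.01, 0.05, 0.10]
    assert (perf["TPR"] == 0).all() and (perf["FDR"] == 0).all()


def test_performance_mean_filter_excludes_low_expression():
    truth = _truth(["DE", "EE"], base_mean=[0.05, 1.0])
    res = ds.adjust_pvalues(make_result([0.001, 0.9]))
    perf = ds.compute_performance(res, truth, cutoffs=(0.05,))
    # the DE gene sits below the 0.1 mean filter: nothing left to detect
    assert perf[perf.category == "DS"].iloc[0]["n_true"] == 0


def test_performance_monotone_in_cutoff():
    rng = np.random.default_rng(1)
    p = rng.random(200) ** 3
    cats = rng.choice(["DE", "EE"], 200).tolist()
    res = ds.adjust_pvalues(make_result(p))
    perf = ds.compute_performance(res, _truth(cats))
    for cat in perf["category"].unique():
        sub = perf[(perf.category == cat) & (perf.scope == "local")].sort_values("cutoff")
        assert sub["n_called"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# KS and logFC concordance
# ---------------------------------------------------------------------------


def test_ks_uniformity_examples():
    assert ds.ks_uniformity([0.25, 0.75]) == pytest.approx(0.25)
    assert ds.ks_uniformity([1.0]) == pytest.approx(1.0)
    n = 20
    grid = (np.arange(1, n + 1) - 0.5) / n
    assert ds.ks_uniformity(grid) == pytest.approx(0.5 / n)
    with pytest.raises(ds.DStateError):
        ds.ks_uniformity([])


def test_logfc_concordance_identity_attenuation_and_na():
    sim = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
    truth = _truth(["DE"] * 5, logfc=sim)
    res = make_result([0.01] * 5, logfc=sim)
    out = ds.logfc_concordance(res, truth).set_index("category")
    assert out.loc["DE", "pearson_r"] == pytest.approx(1.0)
    assert out.loc["DE", "slope"] == pytest.approx(1.0)
    res_half = make_result([0.01] * 5, logfc=0.5 * sim)
    out_half = ds.logfc_concordance(res_half, truth).set_index("category")
    assert out_half.loc["DE", "slope"] == pytest.approx(0.5)
    # AD-style methods without estimates: NA rows, not an error
    res_na = make_result([0.01] * 5, logfc=[np.nan] * 5)
    out_na = ds.logfc_concordance(res_na, truth).set_index("category")
    assert np.isnan(out_na.loc["DE", "slope"]) and out_na.loc["DE", "n"] == 0


# ---------------------------------------------------------------------------
# top-n intersections
# ---------------------------------------------------------------------------


def _res_with_hits(hits, all_genes, method):
    """Result where `hits` get tiny ordered p-values and the rest are null."""
    p = [1e-6 * (hits.index(g) + 1) if g in hits else 0.9 for g in all_genes]
    return ds.adjust_pvalues(make_result(p, genes=all_genes, method=method))


def test_intersections_hand_enumeration():
    genes = [f"g{i}" for i in range(10)]
    truth = _truth(["DE"] * 3 + ["EE"] * 7, genes=genes)  # n1 = 3
    res_a = _res_with_hits(["g0", "g1", "g2"], genes, "A")  # n2 = 3 -> top {x,y,z}
    res_b = _res_with_hits(["g0", "g5"], genes, "B")  # n2 = 2 -> top {x,w}
    out = ds.intersect_top_hits({"A": res_a, "B": res_b}, truth)
    patterns = {row["methods"]: row["count"] for _, row in out.iterrows()}
    assert patterns == {("A", "B"): 1, ("A",): 2, ("B",): 1}
    both = out[out["methods"] == ("A", "B")].iloc[0]
    assert both["categories"] == {"DE": 1}


def test_intersections_identical_results_single_pattern():
    genes = [f"g{i}" for i in range(8)]
    truth = _truth(["DE"] * 2 + ["EE"] * 6, genes=genes)
    res = _res_with_hits(["g0", "g1"], genes, "A")
    res2 = DSResult("B", res.table.copy())
    out = ds.intersect_top_hits({"A": res, "B": res2}, truth)
    assert len(out) == 1 and out.iloc[0]["count"] == 2
    assert out.iloc[0]["methods"] == ("A", "B")


def test_intersections_zero_call_method_has_empty_set():
    genes = [f"g{i}" for i in range(6)]
    truth = _truth(["DE"] * 2 + ["EE"] * 4, genes=genes)
    res_a = _res_with_hits(["g0", "g1"], genes, "A")
    res_b = _res_with_hits([], genes, "B")
    out = ds.intersect_top_hits({"A": res_a, "B": res_b}, truth)
    assert all("B" not in row for row in out["methods"])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_dd_category_weights():
    w = ds.dd_category_weights()
    assert w == {"DE": 0.75, "DP": 0.125, "DM": 0.125, "DB": 0.05}


def _perf_row(method, cat, tpr, fdr):
    return {
        "method": method, "category": cat, "cutoff": 0.05, "scope": "local",
        "TPR": tpr, "FDR": fdr, "n_called": 10, "n_true": 10,
    }


def test_score_methods_ratings_and_ranking():
    perf = pd.DataFrame(
        [_perf_row("good_m", c, 0.9, 0.01) for c in ("DE", "DP", "DM", "DB")]
        + [_perf_row("mid_m", c, 0.5, 0.07) for c in ("DE", "DP", "DM", "DB")]
    )
    lfc = pd.DataFrame(
        {"method": ["good_m"] * 4 + ["mid_m"] * 4, "category": list("....") * 2,
         "slope": [1.0] * 4 + [0.5] * 4}
    )
    flags = {m: {"complex_design": "good", "speed": "good"} for m in ("good_m", "mid_m")}
    card = ds.score_methods(perf, {"good_m": 0.05, "mid_m": 0.2}, lfc, flags)
    assert card.ratings.loc["good_m"].eq("good").all()
    assert card.ratings.loc["mid_m", "TPR_DE"] == "intermediate"  # 1/3 < 0.5 < 2/3
    assert card.ratings.loc["mid_m", "null_simulation"] == "intermediate"
    assert card.ranks["good_m"] == 1
    assert card.scores["good_m"] == pytest.approx(3.0)  # good everywhere, encoding 3


def test_score_methods_figure_encoding_and_unknown_criterion():
    perf = pd.DataFrame([_perf_row("m", c, 0.9, 0.01) for c in ("DE", "DP", "DM", "DB")])
    card = ds.score_methods(perf, {"m": 0.05}, encoding="figure")
    assert card.scores["m"] < 3.0  # good = 2 under the figure encoding
    with pytest.raises(ds.DStateError, match="unknown criterion"):
        ds.ScoreCard(pd.DataFrame({"bogus": ["good"]}, index=["m"]), {"x": 1.0}, "methods")


def test_result_schema_enforced():
    with pytest.raises(ds.DStateError, match="missing columns"):
        DSResult("m", pd.DataFrame({"gene": ["g1"]}))
    cols = {c: [0.5] for c in RESULT_COLUMNS}
    cols["p_val"] = [1.5]
    with pytest.raises(ds.DStateError, match="p-values"):
        DSResult("m", pd.DataFrame(cols))
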