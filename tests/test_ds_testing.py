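import itertools

import numpy as np
import pandas as pd
import pytest

import dstate as ds
from dstate.ds_testing import voom_weights, _ad_permutation_p
from conftest import make_pseudobulk


def _design(samples_a, samples_b):
    samples = samples_a + samples_b
    groups = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    return ds.DesignSpec(samples, groups, ("A", "B"))


# ---------------------------------------------------------------------------
# NB quasi-likelihood engine
# ---------------------------------------------------------------------------


def test_nbql_two_group_logfc_worked_example():
    """Equal offsets, A pb = (10,12), B pb = (40,44): logFC = log2(42/11)."""
    # filler gene equalizes the column totals so that offsets are equal
    mat = pd.DataFrame(
        {"a1": [10, 90], "a2": [12, 88], "b1": [40, 60], "b2": [44, 56]},
        index=["g_target", "g_filler"],
    )
    pb = make_pseudobulk(mat, "sum_counts", _design(["a1", "a2"], ["b1", "b2"]))
    res = ds.fit_nb_ql(pb, normalization="libsize")
    row = res.table.set_index("gene").loc["g_target"]
    assert row["logfc"] == pytest.approx(np.log2(42 / 11), abs=0.01)
    assert row["logfc"] == pytest.approx(1.933, abs=0.01)


def test_nbql_identical_groups_null(two_group_design):
    rng = np.random.default_rng(0)
    base = rng.poisson(100.0, size=(30, 1))
    mat = pd.DataFrame(
        np.tile(base, (1, 6)), columns=two_group_design.sample_ids,
        index=[f"g{i}" for i in range(30)],
    )
    pb = make_pseudobulk(mat, "sum_counts", two_group_design)
    res = ds.fit_nb_ql(pb)
    np.testing.assert_allclose(res.table["logfc"], 0.0, atol=1e-8)
    assert (res.table["p_val"] > 0.99).all()


def test_nbql_squeeze_limit_continuity(two_group_design):
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(
        rng.poisson(50.0, size=(40, 6)) + 1, columns=two_group_design.sample_ids,
        index=[f"g{i}" for i in range(40)],
    )
    pb = make_pseudobulk(mat, "sum_counts", two_group_design)
    r0 = ds.fit_nb_ql(pb, ql_prior_df=0.0)
    r_eps = ds.fit_nb_ql(pb, ql_prior_df=1e-12)
    r_def = ds.fit_nb_ql(pb)
    np.testing.assert_allclose(r0.table["stat"], r_eps.table["stat"], rtol=1e-6)
    # moderation changes the statistics but never the fold-change estimates
    np.testing.assert_allclose(r0.table["logfc"], r_def.table["logfc"])
    assert not np.allclose(r0.table["stat"], r_def.table["stat"])


def test_nbql_rejects_bad_input(sim_de):
    pb = ds.aggregate(sim_de, "logcounts", "mean")
    with pytest.raises(ds.DStateError, match="sum-of-counts"):
        ds.fit_nb_ql(pb)


def test_nbql_skips_subpop_with_single_sample_per_group():
    mat = pd.DataFrame({"a1": [5, 6], "b1": [9, 1]}, index=["g0", "g1"])
    pb = make_pseudobulk(mat, "sum_counts", _design(["a1"], ["b1"]))
    with pytest.warns(UserWarning, match="fewer than 2"):
        res = ds.fit_nb_ql(pb)
    assert not res.table["tested"].any()


# ---------------------------------------------------------------------------
# moderated-t engines
# ---------------------------------------------------------------------------


def test_trend_lm_reduces_to_classical_t(two_group_design):
    """A=(1,2,3), B=(3,4,5) without moderation: t = 2.449, p = 0.0705."""
    mat = pd.DataFrame(
        [[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]], columns=two_group_design.sample_ids,
        index=["g0"],
    )
    pb = make_pseudobulk(mat, "mean_logcounts", two_group_design)
    row = ds.fit_trend_lm(pb, moderate=False).table.iloc[0]
    assert row["logfc"] == pytest.approx(2.0)
    assert row["stat"] == pytest.approx(2.449, abs=1e-3)
    assert row["p_val"] == pytest.approx(0.0705, abs=1e-3)


def test_trend_lm_prior_df_zero_equals_classical(two_group_design):
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(25, 6)), columns=two_group_design.sample_ids,
        index=[f"g{i}" for i in range(25)],
    )
    pb = make_pseudobulk(mat, "mean_logcounts", two_group_design)
    classical = ds.fit_trend_lm(pb, moderate=False).table
    limit = ds.fit_trend_lm(pb, moderate=True, prior_df=0.0).table
    np.testing.assert_allclose(classical["stat"], limit["stat"], rtol=1e-8)
    np.testing.assert_allclose(classical["p_val"], limit["p_val"], rtol=1e-8)


def test_trend_lm_infinite_prior_uses_trend_variance_only(two_group_design):
    """d0 -> inf: statistics scale purely with the effect estimates."""
    rng = np.random.default_rng(3)
    base = rng.normal(10.0, 0.5, size=(20, 6))
    base[:, 3:] += np.linspace(0.5, 2.0, 20)[:, None]
    mat = pd.DataFrame(base, columns=two_group_design.sample_ids,
                       index=[f"g{i}" for i in range(20)])
    pb = make_pseudobulk(mat, "mean_logcounts", two_group_design)
    res = ds.fit_trend_lm(pb, trend=False, prior_df=np.inf).table
    # with a flat prior variance shared by all genes, t is proportional to logFC
    ratio = res["stat"] / res["logfc"]
    np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-6)


def test_trend_lm_identical_groups_boundary(two_group_design):
    mat = pd.DataFrame(
        np.tile([[4.0], [7.0]], (1, 6)), columns=two_group_design.sample_ids,
        index=["g0", "g1"],
    )
    pb = make_pseudobulk(mat, "mean_logcounts", two_group_design)
    res = ds.fit_trend_lm(pb).table
    np.testing.assert_allclose(res["logfc"], 0.0, atol=1e-9)
    np.testing.assert_allclose(res["p_val"], 1.0, atol=1e-5)


def test_voom_constant_counts_no_signal(two_group_design):
    mat = pd.DataFrame(
        np.tile([[50], [100]], (1, 6)), columns=two_group_design.sample_ids,
        index=["g0", "g1"],
    )
    pb = make_pseudobulk(mat, "sum_counts", two_group_design)
    res = ds.fit_voom_lm(pb).table
    assert np.isfinite(res["stat"]).all()
    np.testing.assert_allclose(res["logfc"], 0.0, atol=1e-8)


def test_voom_weights_increase_with_expression(two_group_design):
    """Precision weights fall as expression falls (count mean-variance)."""
    rng = np.random.default_rng(4)
    means = np.logspace(0.5, 4, 60)
    r = 1 / 0.1
    y = rng.negative_binomial(r, r / (r + np.tile(means[:, None], (1, 6))))
    lib = y.sum(axis=0).astype(float)
    logcpm = np.log2((y + 0.5) / (lib + 1.0)[None, :] * 1e6)
    X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
    w = voom_weights(logcpm, lib, X).mean(axis=1)
    lo, hi = w[:20].mean(), w[-20:].mean()
    assert hi > lo


def test_voom_agrees_with_unweighted_fit_for_high_counts(two_group_design):
    """Uniformly high counts: weights are near-constant, logFC matches OLS."""
    rng = np.random.default_rng(5)
    base = rng.integers(90_000, 110_000, size=(30, 6))
    mat = pd.DataFrame(base, columns=two_group_design.sample_ids,
                       index=[f"g{i}" for i in range(30)])
    pb = make_pseudobulk(mat, "sum_counts", two_group_design)
    res = ds.fit_voom_lm(pb, normalization="libsize").table.set_index("gene")
    y = mat.values.astype(float)
    lib = y.sum(axis=0)
    logcpm = np.log2((y + 0.5) / (lib + 1.0)[None, :] * 1e6)
    ols_logfc = logcpm[:, 3:].mean(axis=1) - logcpm[:, :3].mean(axis=1)
    assert np.max(np.abs(res.loc[mat.index, "logfc"].values - ols_logfc)) < 0.1


# ---------------------------------------------------------------------------
# Anderson-Darling
# ---------------------------------------------------------------------------


def brute_force_ad(values, labels):
    """Direct per-value-class evaluation of the midrank AD criterion."""
    vals = np.asarray(values, float)
    labs = np.asarray(labels)
    N = len(vals)
    total = 0.0
    for gi in sorted(set(labs.tolist())):
        ni = (labs == gi).sum()
        inner = 0.0
        for z in sorted(set(vals.tolist())):
            lj = (vals == z).sum()
            Bj = (vals < z).sum() + lj / 2
            Mij = ((vals < z) & (labs == gi)).sum() + ((vals == z) & (labs == gi)).sum() / 2
            denom = Bj * (N - Bj) - N * lj / 4
            if denom > 0:
                inner += (lj / N) * (N * Mij - ni * Bj) ** 2 / denom
        total += inner / ni
    return (N - 1) / N * total


def test_ad_statistic_label_symmetry():
    v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
    g1 = np.array(["a", "a", "a", "b", "b", "b"])
    g2 = np.array(["b", "b", "b", "a", "a", "a"])
    assert ds.ad_ksample_statistic(v, g1) == pytest.approx(ds.ad_ksample_statistic(v, g2))


def test_ad_exhaustive_enumeration_small_instance():
    """{1,2} vs {3,4}: the observed split is maximal; exact p = 2/6."""
    values = np.array([1.0, 2.0, 3.0, 4.0])
    obs = ds.ad_ksample_statistic(values, np.array(["a", "a", "b", "b"]))
    stats = []
    for combo in itertools.combinations(range(4), 2):
        labels = np.array(["b"] * 4)
        labels[list(combo)] = "a"
        stats.append(ds.ad_ksample_statistic(values, labels))
    assert obs == pytest.approx(max(stats))
    p_exact = np.mean([s >= obs - 1e-12 for s in stats])
    assert p_exact == pytest.approx(2 / 6)


def test_ad_statistic_matches_brute_force():
    rng = np.random.default_rng(6)
    for _ in range(50):
        k = rng.integers(2, 4)
        sizes = rng.integers(3, 8, size=k)
        values = rng.integers(0, 5, size=sizes.sum()).astype(float)  # ties likely
        labels = np.repeat([f"s{i}" for i in range(k)], sizes)
        assert ds.ad_ksample_statistic(values, labels) == pytest.approx(
            brute_force_ad(values, labels)
        )


def test_ad_requires_two_nonempty_groups():
    with pytest.raises(ds.DStateError):
        ds.ad_ksample_statistic(np.array([1.0, 2.0]), np.array(["a", "a"]))


def test_ad_tied_values_give_p_one():
    stat, p = _ad_permutation_p(
        np.zeros(10), np.array([0] * 5 + [1] * 5), 2, 100, np.random.default_rng(0)
    )
    assert stat == 0.0 and p == 1.0


def _ad_dataset(gene_rows, samples, groups):
    values = np.asarray(gene_rows)
    cells = [f"c{i}" for i in range(values.shape[1])]
    cm = ds.CountMatrix(values, [f"g{i}" for i in range(values.shape[0])], cells)
    ann = pd.DataFrame(
        {"sample_id": samples, "cluster_id": ["k1"] * len(cells), "group_id": groups},
        index=cells,
    )
    return ds.SimulatedDataset(cm, ann, truth=pd.DataFrame())


def test_ad_low_expression_gene_flagged_untested():
    """Expressed in 9 cells at a 10-cell threshold: flagged, not dropped."""
    rng = np.random.default_rng(7)
    n = 24
    sparse_gene = np.zeros(n, int)
    sparse_gene[:9] = 1
    dense_gene = rng.poisson(5.0, n) + 1
    samples = np.repeat(["s1", "s2", "s3", "s4"], 6)
    groups = np.repeat(["A", "A", "B", "B"], 6)
    data = _ad_dataset([sparse_gene, dense_gene], samples, groups)
    cfg = ds.TestConfig(n_permutations=100, seed=5)
    res = ds.test_ad(data, "group", cfg)
    tab = res.table.set_index("gene")
    assert not tab.loc["g0", "tested"] and bool(tab.loc["g1", "tested"])
    assert np.isnan(tab.loc["g0", "p_val"])


def test_ad_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(8)
    n = 48
    genes = rng.poisson(5.0, size=(40, n)) + 1
    samples = np.repeat(["s1", "s2", "s3", "s4"], 12)
    groups = np.repeat(["A", "A", "B", "B"], 12)
    data = _ad_dataset(genes, samples, groups)
    cfg = ds.TestConfig(n_permutations=200, seed=6, min_cells_per_instance=10)
    res = ds.test_ad(data, "group", cfg)
    p = res.table.loc[res.table["tested"], "p_val"].values
    assert 0.35 < np.mean(p) < 0.65
    assert ds.ks_uniformity(p) < 0.25


def test_ad_sample_grouping_sees_within_group_heterogeneity():
    """Samples differing inside each group: sid statistic exceeds gid."""
    rng = np.random.default_rng(9)
    vals = np.concatenate([
        rng.normal(0, 0.3, 20), rng.normal(5, 0.3, 20),  # s1, s2 (group A)
        rng.normal(0, 0.3, 20), rng.normal(5, 0.3, 20),  # s3, s4 (group B)
    ])
    samples = np.repeat(["s1", "s2", "s3", "s4"], 20)
    groups = np.repeat(["A", "B"], 40)
    assert ds.ad_ksample_statistic(vals, samples) > ds.ad_ksample_statistic(vals, groups)


# ---------------------------------------------------------------------------
# cross-engine properties
# ---------------------------------------------------------------------------


def test_gene_order_invariance(sim_de):
    pb = ds.aggregate(sim_de, "counts", "sum")
    res1 = ds.fit_nb_ql(pb)
    flipped = ds.Pseudobulk(
        {k: m.iloc[::-1] for k, m in pb.matrices.items()},
        pb.assay_type, pb.n_cells, pb.instance_libsize, pb.design,
    )
    res2 = ds.fit_nb_ql(flipped)
    a = res1.table.set_index(["gene", "cluster_id"]).sort_index()
    b = res2.table.set_index(["gene", "cluster_id"]).sort_index()
    # lowess tie-handling makes the trends order-sensitive at machine scale
    np.testing.assert_allclose(a["p_val"], b["p_val"], rtol=1e-5, atol=1e-12)


def test_logfc_sign_concordance_on_de_simulation():
    """Pseudobulk engines recover the simulated DE direction >= 95% of the time."""
    spec = ds.ToyReferenceSpec(n_genes=400, n_cells_per_instance=150, n_subpops=2, seed=15)
    _, params = ds.make_toy_reference(spec)
    cfg = ds.SimConfig(n_subpops=2, n_genes=300, cells_per_instance=200, seed=16)
    sim = ds.simulate_dataset(params, cfg)
    for method in ("pb-nbql", "pb-trend"):
        res = ds.run_method(sim, method)
        m = res.table.merge(sim.truth, on=["gene", "cluster_id"])
        de = m[(m["category"] == "DE") & m["tested"]]
        agree = np.sign(de["logfc_x"]) == np.sign(de["logfc_y"])
        assert agree.mean() >= 0.95, method


def test_run_method_dispatch_and_reserved(sim_de):
    assert ds.run_method(sim_de, "pb-voom").method == "pb-voom"
    with pytest.raises(ds.DStateError, match="reserved"):
        ds.run_method(sim_de, "mm-dream")
    with pytest.raises(ds.DStateError, match="unknown"):
        ds.run_method(sim_de, "nonsense")
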