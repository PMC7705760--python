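"""Per-cell effect coefficients: which cells carry the population response?

After pseudobulk DS detection, each cell's normalized log-expression is
projected onto its subpopulation's logFC vector over the detected DS genes
and scaled to max |1|.  Well-separated coefficient distributions between the
groups mean most cells respond; overlap means only a subset does.
"""

import dstate as ds

_, params = ds.make_toy_reference(ds.ToyReferenceSpec(n_genes=600, n_subpops=2, seed=8))
sim = ds.simulate_dataset(
    params, ds.SimConfig(n_subpops=2, n_genes=400, cells_per_instance=150, seed=9)
)
res = ds.adjust_pvalues(ds.run_method(sim, "pb-nbql"))
eff = ds.compute_effect_coefficients(sim, res, fdr_cutoff=0.05, logfc_cutoff=1.0)

for k, sub in eff.cells.dropna(subset=["coefficient"]).groupby("cluster_id", observed=True):
    means = sub.groupby("group_id", observed=True)["coefficient"].mean()
    n_ds = len(eff.ds_genes[k])
    print(f"{k}: {n_ds} DS genes (FDR<0.05, |logFC|>1); mean coefficient "
          f"A={means.get('A', float('nan')):+.3f}  B={means.get('B', float('nan')):+.3f}")
print("Group B carries the simulated state change, so its cells score higher —")
print("the separation mirrors per-sample violin panels used to judge response homogeneity.")
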