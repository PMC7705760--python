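"""Pseudobulk differential-state testing with the three aggregation engines.

Aggregates a simulated dataset per subpopulation and sample, runs the NB
quasi-likelihood, moderated-t (trend) and precision-weighted (voom) engines,
adjusts p-values within each subpopulation, and prints the detection
performance of each engine against the simulation ground truth.
"""

import dstate as ds

_, params = ds.make_toy_reference(ds.ToyReferenceSpec(n_genes=800, n_subpops=2, seed=3))
sim = ds.simulate_dataset(
    params, ds.SimConfig(n_subpops=2, n_genes=500, cells_per_instance=150, seed=4)
)

for method in ("pb-nbql", "pb-trend", "pb-voom"):
    res = ds.adjust_pvalues(ds.run_method(sim, method))
    perf = ds.compute_performance(res, sim.truth, cutoffs=(0.05,))
    row = perf[(perf.category == "DS") & (perf.scope == "local")].iloc[0]
    print(f"{method:9s}  TPR={row.TPR:.3f}  FDR={row.FDR:.3f}  "
          f"({row.n_called} called, {row.n_true} truly differential)")
print("TPR = fraction of true DS genes detected at adjusted p < 0.05;")
print("FDR = fraction of the calls that are actually EE/EP.  The count-based")
print("engines use TMM offsets and keep FDR near the nominal level; the")
print("mean-logcounts engine normalizes each cell by its raw library size and")
print("inherits compositional bias from the differential genes.")
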