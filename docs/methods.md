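# Methods

## Model and scope

`dstate` targets differential **state** analysis: per cell subpopulation,
testing for expression changes between two conditions where *samples* are
the experimental units.  Cell-level counts are modeled as negative binomial,

    y_gc ~ NB(mu_gc, phi_g),    mu_gc = exp(beta_g^{s(c)}) * lambda_c,

with `beta_g^s` the log relative abundance of gene g in sample s (natural
log), `lambda_c` the cell's library size, and `phi_g` the gene's dispersion
in the var = mu + phi·mu² parameterization (phi = 0 is Poisson; we state
this explicitly to avoid confusion with the reciprocal "size"
parameterization).

## Reference estimation

* **Filtering** (defaults): cells with < 200 detected genes, then genes
  detected in < 100 cells, then (sample, subpopulation) instances with
  < 100 cells are removed, stagewise, with a logged tally.
* **beta** is the ratio of totals, `ln(sum_c y_gc / sum_c lambda_c)` per
  sample — the Poisson MLE with library-size offsets, consistent for the NB
  mean, closed-form, and adequate because simulation treats beta as a
  plug-in.  All-zero genes in a sample are flagged missing and excluded
  from the simulation-eligible pool rather than imputed (avoids −inf
  means).
* **phi** is a genewise profile maximum likelihood with the plug-in means
  held fixed, computed on a 60-point log-spaced grid over [1e-8, 100] with
  one parabolic refinement step, followed by a lowess trend of
  log-dispersion on log-mean and shrinkage of the genewise values toward
  the trend with a prior weight equivalent to 10 genewise degrees of
  freedom (configurable).  This mimics trend-plus-shrinkage dispersion
  estimation without porting any particular implementation; it is not
  bit-identical to any.  Estimates are clamped to [0, 100].

## Simulation

For each subpopulation a reference subpopulation is drawn, and for each
simulated sample a reference sample (without replacement when the pool
allows, with replacement otherwise — logged; a paired design reuses one
reference-sample set for both groups).  Each (sample, subpopulation)
instance resamples `cells_per_instance` library sizes from the matching
reference pool with replacement.  Gene identities: a fraction `p_type` of
gene slots is mapped to subpopulation-specific reference genes (pairwise
disjoint across subpopulations); the rest share one mapping.

Differential-distribution categories per (gene, subpopulation) are i.i.d.
draws from `(p_EE, p_EP, p_DE, p_DP, p_DM, p_DB)`.  |log2 FC| ~
Gamma(shape 4, rate 4/(r_k·mu_logFC)) with equal-probability sign; the
affected group is fixed to group B, the direction being carried entirely by
the sign (distributionally equivalent to randomizing the group and simpler
to book-keep).  Per-cell mean multipliers: EE — 1 everywhere; EP — the same
fraction (`ep_fraction`, default 0.5) of cells in *both* groups at FC; DE —
all affected-group cells at FC; DP — fraction a of group A and b of group B
at FC (defaults 0.3/0.7); DM — a random half of the affected group at FC
(re-drawn per gene); DB — the affected group at FC/2 and the other group
split into equal halves at 1 and FC.  Component sizes are rounded to the
nearest integer with at least one cell in any nonempty component.  The
truth table records category, signed log2 FC, and the base mean (average
simulated mu over the subpopulation's cells), which drives the evaluation
mean filter.

## Synthetic ground-truth references

`make_toy_reference` generates the reference a simulation is anchored to:
gene-level beta ~ Uniform(beta_range) plus N(0, beta_sample_sd) per-sample
effects, normalized so each sample's relative abundances sum to one;
phi drawn from a small set of levels; lambda log-normal (defaults meanlog 9,
sdlog 0.3 ≈ 8000 counts/cell, droplet scale).  Defaults: 8 reference
samples — the scale of a typical multi-patient anchor — so an unpaired
3 vs 3 design draws distinct reference samples; reusing a reference sample
for several simulated samples duplicates its mean vector and breaks the
independent-replicates assumption every sample-level engine relies on.
`beta_sample_sd` defaults to 0.2 (natural log), a replicate-level
variability typical of biological replicates.  What the toy reference does
*not* emulate: empirical mean–variance trends of any particular tissue,
zero inflation, batch effects, or subpopulation-specific mean shifts.
Passing tests on it therefore demonstrates correctness of the machinery and
calibration under the stated model, not performance on any real dataset.

## Aggregation

Three pseudobulk flavors per subpopulation (gene × sample):

* `counts` + `sum` — integer sums; columns conserve the instance library
  size Λ_sk = Σ_g Σ_c y_gc exactly.
* `logcounts` + `mean` — cell-level `log2(y · (mean lambda / lambda_c) + 1)`
  averaged per instance.  The normalization constant is the mean library
  size (not 1e6) so values stay on a counts-like scale; pseudo-count 1.
* `scalecpm` + `sum` — per-cell CPM summed over the instance, then scaled
  by Λ_sk·1e-6 back to the counting scale (so Σ_g CPM*_sk = C_sk·Λ_sk).
  The cell-level reading of "CPM of a sample and subpopulation" is used:
  rescaled pseudobulk-level CPM would algebraically collapse back to raw
  summed counts and carry no information.

Other assay/statistic combinations are rejected.  Samples with no cells in
a subpopulation are dropped for that subpopulation only.

## Testing engines

All pseudobulk engines test a two-group contrast with ≥ 2 samples per
group (subpopulations failing this are skipped with a warning; their rows
are flagged untested, never dropped).

* **NB quasi-likelihood (`fit_nb_ql`)** — offsets are log effective library
  sizes: pseudobulk column sums times trimmed-mean-of-M-values (TMM)
  factors (30% log-ratio / 5% abundance trim, reference column by upper
  quartile).  TMM is on by default: with 10% DE genes at an average
  fold change of ~5, raw column totals of the affected group are inflated
  ~19%, which biases every non-DE gene and inflates the observed FDR
  several-fold; `normalization="libsize"` restores plain offsets.
  Genewise dispersions are Cox–Reid-adjusted profile ML (the 0.5·log
  det(X'WX) correction removes the downward bias of plug-in ML at six
  samples), smoothed by lowess into a trended dispersion used for the
  per-gene NB GLM fits (Fisher scoring, vectorized across genes).
  Quasi-likelihood dispersions are residual deviance / residual df,
  squeezed toward an intensity trend by empirical Bayes (log-variance
  moment matching of a scaled-F prior; trigamma inversion by Newton); the
  quasi-F statistic uses the likelihood-ratio deviance over the squeezed
  dispersion with 1 and d0 + residual df degrees of freedom.  This is an
  edgeR-*inspired* engine, documented as such, not a bit-identical port.
* **Moderated t on mean log-counts (`fit_trend_lm`)** — OLS per gene,
  residual variances moderated with an intensity-dependent prior trend
  (lowess span 0.5), prior df by the same moment matching; with
  `moderate=False` it reduces exactly to the classical pooled t.  Note the
  cell-level log-normalization divides by raw cell library sizes, so this
  engine inherits compositional bias from strong differential genes.
* **Precision-weighted (`fit_voom_lm`)** — pseudobulk log2-CPM (prior
  count 0.5, TMM effective libraries), a lowess trend of sqrt(residual SD)
  versus average log-count evaluated at each observation's fitted
  log-count, weights = inverse fourth power, then weighted least squares
  and the same moderation without a prior trend (the weights already
  absorb the mean–variance relation).
* **Anderson–Darling (`test_ad`)** — the ties-adjusted (midrank) k-sample
  AD criterion on cell-level log-counts, grouping cells by sample (sid) or
  condition (gid); p-values by label permutation with (b+1)/(B+1)
  (default B = 1000, configurable; the count and the permutation-vs-exact
  choice are design decisions — no authoritative value exists).  Genes
  expressed in fewer than 10 cells of a subpopulation are flagged
  untested.  Fully tied data yield statistic 0 and p = 1.

## Evaluation

* **Adjustment**: Benjamini–Hochberg, *locally* (within each
  subpopulation's G tests) and *globally* (across all G × K).
* **Performance**: rows with simulated base mean < 0.1 are excluded; each
  DS category (DE/DP/DM/DB, plus the pooled "DS" stratum) is scored
  against the same EE + EP negative set at cutoffs 1/5/10%; FDR is defined
  as 0 when nothing is called.
* **Null calibration**: one-sample two-sided KS distance of raw p-values
  from Uniform(0,1).
* **logFC concordance**: per-category Pearson r and the slope of estimated
  on simulated logFC; methods without estimates get NA rows.
* **Top-n intersections**: per method the top n = min(n1, n2) hits by raw
  p (n1 = simulated differential combinations, n2 = called at FDR < 0.05),
  with every observed membership pattern counted and annotated by true
  category.
* **Score card**: ratings good/intermediate/poor from mean TPR (> 2/3,
  > 1/3), mean FDR (< 0.05, < 0.1) and mean null KS (< 0.1, < 0.25);
  logFC estimation rated from the median concordance slope (> 2/3 good,
  > 1/3 intermediate, no estimates NA) — a quantitative stand-in for
  what is otherwise a visual judgement; complex-design and speed are
  qualitative caller-supplied flags, never measured, since runtimes are
  hardware-dependent.  TPR/FDR criteria carry modality-derived weights
  (unimodal 0.75 → DE; bimodal 0.25 split equally → DP, DM 0.125 each;
  trimodal 0.05 → DB), all other criteria 0.5; encoding good = 3 /
  intermediate = 2 / poor = NA = 0 by default, with a `figure` switch for
  the alternative 2/1/0 coding.  The weighted average of encodings ranks
  the methods.

## Effect coefficients

Per cell: the dot product of its normalized log-expression with the
subpopulation's logFC vector over the detected DS genes (FDR < 0.05,
|logFC| > 1 by default), scaled to a maximum absolute value of 1 within
each subpopulation (per-panel scaling; global scaling is an option).
Subpopulations without DS genes get all-NA coefficients, flagged rather
than erroring.

## Numerical choices and degenerate inputs

Dispersion grids span [1e-8, 100] in log space; edge maxima collapse to
phi = 0.  GLM coefficients are clipped to ±50, Fisher-scoring tolerance
1e-8.  Likelihood-ratio deviances below 1e-8 are treated as exact zeros and
the QL dispersion is floored at 1e-8, so genes identical across groups
report F = 0, p = 1 instead of amplified round-off.  Lowess span is 0.5
throughout; trends with fewer than 5 finite points fall back to the mean.
Component-membership rounding is nearest-integer with a 1-cell minimum.
The prior df of every variance squeeze can be overridden (0 disables
moderation; inf uses the trend alone), which the tests use to check the
classical limits.

## Problem sizes

The shipped benchmark configuration simulates K = 3 subpopulations,
3 vs 3 samples, 200 cells per instance (3600 cells) and 2000 genes from a
3000-gene synthetic reference, with 5 replicates for error-control
measurements and 3 for null calibration — sizes chosen so the whole suite
and the acceptance script each complete in minutes on a single core while
keeping Monte-Carlo error well below the decision thresholds.

## Known limitations

* Two experimental groups only; blocking beyond paired samples, batch
  effects, zero inflation, > 2 groups and hierarchical type genes are out
  of scope.
* The QL, trend and voom engines match their bulk-RNA-seq archetypes in
  structure, not bit-for-bit.
* Mixed-model engines are not implemented; their method ids are reserved
  in the results schema for interoperability.
* With well-calibrated engines and exchangeable simulated subpopulations,
  the difference between local and global adjustment is at most a
  discovery or two per replicate; its per-replicate sign is sampling
  noise even though the expected direction (global more conservative) is
  reproduced on average.
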