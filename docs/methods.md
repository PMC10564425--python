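# Methods

## Scope and data model

All stages operate on three plain containers: an `ExpressionMatrix`
(genes × samples, log2 scale unless tagged `counts`; duplicate gene rows are
collapsed by arithmetic mean at read time, missing values are rejected
rather than imputed), a `GeneSetCollection` (standard GMT), and
`CohortAnnotations` (group label, survival time in days > 0, event 0/1,
arbitrary covariates). Gene symbols are matched case-sensitively after
whitespace trimming; no alias mapping is attempted. Matrices are always
oriented features × samples.

## Single-sample enrichment

**ssGSEA.** Per sample, genes are ordered by decreasing expression (exact
ties broken by stable gene-id order, so scores are deterministic). With
ordinal rank values N..1 down the list, the score is
ES = Σ_i [P_in(i) − P_out(i)], where P_in accumulates rank^α over in-set
genes (normalized to 1 at the end of the list) and P_out accumulates
uniformly over out-of-set genes. α defaults to 0.25, the original ssGSEA
convention. "Normalized" scores divide the whole set × sample matrix by its
global range, the common ssGSEA-norm convention. A set covering every gene
is rejected (the out-of-set accumulator would be empty), as is a set with
no genes in the matrix.

**GSVA-style scores.** Each gene's expression is first standardized across
samples by a kernel CDF: gaussian with bandwidth SD/4 (the published
default), poisson with rate x+0.5 for counts, or the empirical CDF with
average ranks for ties. Per sample the standardized values become ranks,
centred into the symmetric statistic |N/2 − rank| that up-weights both
extremes, and a KS-like walk down the ranked list accumulates in-set weight
|r|^τ (τ = 1) against a uniform out-of-set penalty. The score is the
max-positive minus |max-negative| deviation (`max_diff`, the published
default) or the signed maximum deviation. At least 4 samples are required
for the cross-sample CDF to be meaningful.

Because the kernel CDF standardizes *within each gene across samples*, GSVA
scores are inherently relative: a gene set cannot score positive in every
sample, only in the samples where its genes sit high in their own
cross-sample distributions. Tests therefore check the monotone property (a
planted cross-sample trend in the set genes is tracked by the scores) rather
than a sign that the construction cannot produce.

**Two-group GSEA.** Genes are ranked by signal-to-noise
(m₁−m₀)/(s₁+s₀), with each class SD floored at max(0.2·|mean|, 0.2) to
guard near-constant genes. The enrichment score is the signed maximum of
the weighted KS walk (weight exponent 1). The null distribution permutes
sample labels (mandatory seed; no hidden global randomness); NES divides
the observed ES by the mean |null ES| of matching sign, and the two-sided
p-value is the add-one estimator (1 + #{|null| ≥ |ES|})/(n_perm + 1). Sets
outside [min_size, max_size] = [10, 500] after intersection with the matrix
are excluded and reported. A pre-ranked entry point (`gsea_preranked`)
accepts an arbitrary gene ranking and permutes gene labels instead.

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
(monotone, capped at 1, ties preserved) and cross-checked against
statsmodels in the tests.

## Ferroptosis potential index

FPI_j = ES(positive regulators, j) − ES(negative regulators, j), linear in
the enrichment rows. Standardization is min–max to [0, 1]; stratification
assigns `low` strictly below the cutoff and `high` at or above it, and the
cutoff must leave both groups non-empty. The shipped starter panel has 12
positive regulators (LPCAT3, NCOA4, ACSL4, GPX4, SLC3A2, ALOX15, SLC7A11,
NOX5, NFE2L2, NOX3, NOX1, NOX4) and 4 negative regulators (FDFT1, COQ10A,
HMGCR, COQ10B). The negative list is known to be incomplete and the
positive list includes genes (GPX4, SLC7A11, NFE2L2) whose canonical
biology is anti-ferroptotic; the panel is shipped as a documented starter
fixture and production analyses should supply their own GMT. The pipeline
standardizes the FPI before cutpoint selection and logs that choice.

## Survival analysis

Kaplan–Meier uses the product-limit estimator over distinct event times.
The two-group log-rank statistic is the standard observed-minus-expected
chi-square with 1 df, implemented vectorized over event times so the
cutpoint scan stays fast; it agrees with lifelines to 1e-8 in the tests.
`optimal_cutpoint` evaluates every observed score value whose strict-less
split keeps both groups at ≥ minprop (default 0.10, the survminer
convention) of the cohort and returns the maximizing cutoff, ties toward
the smaller value. No multiplicity correction is applied to the selected
split's p-value; `candidates_evaluated` is recorded so users can correct
for the selection themselves. Contingency tables use the Pearson chi-square
without continuity correction (scipy backend); this convention reproduces
the published clinicopathologic p-values the tests pin.

## Immune infiltration and correlation

Infiltration of each cell type is the ssGSEA enrichment of its
surface-marker set — a relative enrichment, not a cell proportion (no
CIBERSORT-style deconvolution). Scores are z-standardized per cell type,
then correlated with the FPI: plain Pearson with a two-sided t-based p by
default, or partial Pearson (residualizing both variables on the supplied
numeric controls plus intercept, df = n − 2 − k) when confounders are
given; with no controls the partial path reduces exactly to plain Pearson.
p-values are BH-adjusted across cell types, and `network_edges` exports the
significant rows as an FPI-centred edge list sorted by |r|. No default
control covariate is imposed.

## Moderated differential analysis

Per feature, the effect is the plain difference of class means (log2 fold
change for expression input; score difference for pathway scores — only
variances are shrunk, never effects). The pooled within-class variance s²
on d = n₁ + n₀ − 2 df is shrunk to s̃² = (d₀s₀² + d·s²)/(d₀ + d), with the
prior (d₀, s₀²) fitted by matching the mean and variance of log s² to a
scaled F distribution: the trigamma equation is solved by bisection to
1e-8, d₀ = ∞ (full shrinkage) when the spread of log variances does not
exceed chi-square noise, and nonpositive sample variances are excluded
from the fit. The moderated t = effect/(s̃·√(1/n₁ + 1/n₀)) has d₀ + d df.
If the fit is infeasible the test falls back to d₀ = 0 — the classical
equal-variance t — with a logged warning; `prior_df=0` forces that limit.
Selection is two-sided: |effect| ≥ threshold and BH-adjusted p < α
(defaults 1.5 and 0.05 for genes; 0.1 for pathway scores, which are not
log-ratios). The literal threshold value 1.5 is exposed as a parameter
since "fold change ≥ 1.5" conventions vary between the log2 and raw-ratio
readings. No intensity trend (limma-trend), design matrices beyond two
groups, or voom-style weighting.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, making
every downstream claim testable without external data:

- latent activity f_j ~ N(0, 1); positive regulators shift by +γ·f_j,
  negative by −γ·f_j (γ = 1 log2 unit by default) around Uniform(2, 10)
  baselines with N(0, noise_sd²) noise, noise_sd = 1;
- each of 24 immune cell types owns a 5-gene marker block built as
  ρ·f_j + √(1−ρ²)·noise, so the block's shared component correlates with
  the latent factor at the target ρ. Defaults encode the expected ordering:
  B cells 0.70, CD8 T 0.50, T helper 0.45, Th17 0.40, NK CD56bright 0.35,
  NK CD56dim 0.30, all remaining types 0.10;
- survival T_j ~ Exponential(rate = h₀·exp(−β·f_j)) with h₀ = 1/1000
  events/day and β = 0.7 (higher ferroptosis activity is protective),
  censored by independent Uniform(0, 3000 days); exponential rather than
  Weibull for closed-form hazard control;
- background genes are pure noise; one root seed drives a single generator
  stream, so identical configs are bit-identical.

The effect sizes are free parameters of the simulation, not estimates of
any real cohort. The generator does not emulate scRNA-seq count sparsity,
batch effects, tumor purity, or correlated censoring — so passing tests
demonstrate that the pipeline recovers the planted structure under clean
conditions, not that it is robust to those real-data complications.

## Single-cell QC

`qc_filter_cells` keeps cells with detected-gene counts in [500, 4000] and
mitochondrial count fraction strictly below 5% (mitochondrial genes
identified by the "MT-" prefix); the report tallies every rule a cell
breaks. It requires an explicit `counts` scale tag and is exercised on
synthetic count matrices only.

## Numerical choices and problem sizes

Expression ties: average ranks in the GSVA CDF; stable gene-id order in
walk positions. Permutation p-values use add-one estimators. The test
suite validates walks against independent literal-loop oracles at 1e-12 on
≤ 6-gene fixtures, permutation p-values against exhaustive enumeration at
n = 8 (70 label assignments), the cutpoint against a brute-force
lifelines scan at n = 50, and calibration by simulation: 100 replicates at
n = 500 for cutpoint recovery (±0.05 around a planted hazard step at 0.5),
200 replicates at n = 500 for the correlation-ordering claim, 1000
replicates for log-rank type-I error, 200 datasets for GSEA type-I error,
and 40 replicates of 2000-feature null matrices for moderated-t
calibration. These sizes keep the full suite under a minute of simulation
time while leaving Monte-Carlo standard errors well inside the asserted
bands; rate assertions on ≈ 95% properties widen by two MC standard errors
of the replicate count.

## Known limitations

- The FPI cutpoint is data-derived; no universal threshold ships with the
  package, and the starter regulator panel is explicitly incomplete.
- Only two-group contrasts are supported throughout (GSEA metric,
  moderated t, log-rank); no Cox or multivariable survival modelling.
- GSVA poisson-kernel input is assumed to be raw counts; nothing checks
  overdispersion.
- Marker-set infiltration scoring measures relative enrichment and cannot
  be compared across cell types with very different marker-set sizes.
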