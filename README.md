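# ferroscore

Ferroptosis-potential-index (FPI) analysis for bulk and single-cell
transcriptomics, built for studies that ask how ferroptosis activity in a
tumor relates to immune infiltration and patient survival — the
lung-adenocarcinoma setting where low ferroptosis activity marks poor
prognosis and weak B-cell infiltration is the motivating use case.

The package is a library first: every stage is an importable function over
plain containers (genes × samples matrices, GMT gene sets, sample
annotations), with a thin `ferroscore` CLI for shell use and `examples/`
scripts that walk each capability.

## The model

For a sample *j* with expression ranked in decreasing order, the ssGSEA
enrichment score of a gene set *S* is the accumulated difference between the
weighted in-set and uniform out-of-set cumulative fractions,

ES(S, j) = Σ_i [ P_in(i) − P_out(i) ],  with P_in weighting gene ranks by
rank^α (α = 0.25).

The ferroptosis potential index is the enrichment difference between
positive and negative ferroptosis regulators:

FPI_j = ES(FRG⁺, j) − ES(FRG⁻, j)

Downstream, the package provides:

- **GSVA-style scoring** — kernel-CDF standardization (gaussian bandwidth
  SD/4, poisson for counts, or empirical CDF) followed by a KS-like walk,
  one pathway score per sample;
- **maximally selected survival cutpoint** — the FPI threshold maximizing
  the two-group log-rank statistic over all admissible splits
  (x-tile / `surv_cutpoint` style, min group proportion 0.10);
- **immune-infiltration correlation** — ssGSEA scores of 24 immune-cell
  marker sets, (partial) Pearson correlation with the FPI, BH-adjusted;
- **moderated differential analysis** — empirical-Bayes shrunken-variance t
  (prior fitted by moment-matching log variances to a scaled F), applied to
  gene matrices and pathway score matrices alike;
- **two-group GSEA** with a signal-to-noise ranking and label-permutation
  null; **Kaplan–Meier / log-rank / Pearson chi-square** statistics;
- a **synthetic cohort generator** that plants a latent ferroptosis
  activity driving regulator genes, correlated immune marker blocks
  (B cells strongest), and exponential survival with hazard
  ∝ exp(−β·activity), so the whole pipeline is testable without external
  data.

## Worked example

```python
import numpy as np
from ferroscore import (CohortConfig, generate_cohort, ssgsea_scores,
                        compute_fpi, standardize_fpi, starter_frg_sets)

expr, ann, sets = generate_cohort(CohortConfig(n_samples=200, seed=2))
frg = starter_frg_sets()
fpi = compute_fpi(ssgsea_scores(expr, frg.as_collection(), alpha=0.25), frg)
std = standardize_fpi(fpi)
print(np.corrcoef(fpi.fpi, ann.table["latent_factor"])[0, 1])
```

prints `0.943...` — the FPI recovers the planted per-sample ferroptosis
activity almost perfectly at n = 200. Continuing with survival
stratification (`examples/03_survival_cutpoint.py`):

```text
optimal cutoff 0.478 (log-rank statistic 56.4 over 241 candidates)
log-rank p between FPI groups: 5.98e-14
  low-FPI group: S(500 days) = 0.45
  high-FPI group: S(500 days) = 0.80
```

The low-FPI group's lower 500-day survival reproduces the planted
direction: less ferroptosis activity, worse prognosis. The
`examples/` directory has one script per capability (simulation, scoring,
cutpoint, immune correlation, differential analysis, full pipeline,
contingency tables); each prints its numbers with a line on what they mean.

The same flow runs from the shell:

```sh
ferroscore simulate --out cohort/ --seed 2
ferroscore score --method ssgsea --expr cohort/expression.tsv --gmt cohort/sets.gmt --out scores.tsv
ferroscore fpi --scores scores.tsv --out fpi.tsv
ferroscore survival --fpi fpi.tsv --ann cohort/annotations.tsv --out cutpoint.json
```

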