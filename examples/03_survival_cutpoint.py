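"""Stratify a cohort at the maximally selected survival cutpoint.

Every admissible FPI threshold is scanned for the split that maximizes the
two-group log-rank statistic (x-tile / surv_cutpoint style); with a positive
protective effect planted, the low-FPI group shows worse survival.
"""

import pandas as pd

from ferroscore import (
    CohortAnnotations,
    CohortConfig,
    assign_groups,
    compute_fpi,
    generate_cohort,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    ssgsea_scores,
    standardize_fpi,
    starter_frg_sets,
)

expr, ann, sets = generate_cohort(CohortConfig(n_samples=300, beta=0.7, seed=3))
frg = starter_frg_sets()
fpi = standardize_fpi(compute_fpi(ssgsea_scores(expr, frg.as_collection()), frg))

cut = optimal_cutpoint(fpi.fpi, ann, minprop=0.10)
grouped = assign_groups(fpi, cut.cutoff)
print(f"optimal cutoff {cut.cutoff:.3f} "
      f"(log-rank statistic {cut.statistic:.1f} over {cut.candidates_evaluated} candidates)")

strata = CohortAnnotations(
    pd.DataFrame(
        {"group": grouped.group, "time": ann.time, "event": ann.event},
        index=pd.Index(list(ann.sample_ids), name="sample_id"),
    )
)
lr = logrank_test(strata, ("low", "high"))
print(f"log-rank p between FPI groups: {lr.pvalue:.2e}")
for name in ("low", "high"):
    curve = km_estimate(strata, name)
    print(f"  {name}-FPI group: S(500 days) = {curve.survival_at(500):.2f}")
print("A lower 500-day survival in the low-FPI group reproduces the planted "
      "direction: less ferroptosis activity, worse prognosis.")
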