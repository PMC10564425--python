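"""Correlate immune-cell infiltration with the ferroptosis index.

Each of the 24 cell types is scored by ssGSEA over its marker set; Pearson
correlations with the FPI are Benjamini-Hochberg adjusted and exported as an
FPI-centred edge list.  B cells are planted as the strongest partner.
"""

from ferroscore import (
    CohortConfig,
    compute_fpi,
    correlate_fpi_infiltration,
    generate_cohort,
    infiltration_scores,
    network_edges,
    ssgsea_scores,
    starter_frg_sets,
)

expr, ann, sets = generate_cohort(CohortConfig(n_samples=300, seed=4))
frg = starter_frg_sets()
fpi = compute_fpi(ssgsea_scores(expr, frg.as_collection()), frg)

markers = sets.subset([n for n in sets.names if not n.startswith("FRG_")])
infil = infiltration_scores(expr, markers)
table = correlate_fpi_infiltration(fpi, infil)

print("top five cell types by |correlation| with FPI:")
for _, row in table.head(5).iterrows():
    print(f"  {row.cell_type:22s} r = {row.r:+.3f}  padj = {row.padj:.2e}")

edges = network_edges(table, padj_cutoff=0.05)
print(f"{len(edges)} cell types significantly associated with the FPI")
print("B cells at the top mirrors the planted correlation ordering "
      "(rho 0.70 for B cells vs 0.50 for the runner-up).")
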