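"""Chi-square association tests for clinicopathologic 2x2 tables.

Counts of high/low marker staining split by a clinical feature are tested
for independence with the Pearson statistic (no continuity correction).
"""

from ferroscore import chisq_independence

tables = {
    "primary tumor location (left/right)": [[9, 47], [1, 41]],
    "tumor size (<5cm / >=5cm)": [[7, 65], [3, 23]],
    "lymph node metastasis (neg/pos)": [[5, 47], [5, 41]],
    "TNM stage (I+II / III+IV)": [[5, 61], [5, 27]],
}

for label, counts in tables.items():
    res = chisq_independence(counts)
    flag = "*" if res.pvalue < 0.05 else " "
    print(f"{flag} {label:38s} chi2 = {res.statistic:6.3f}  p = {res.pvalue:.4f}")
print("\nOnly tumor location shows a significant association (p < 0.05): "
      "high staining concentrates in left-lung tumors in this table.")
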