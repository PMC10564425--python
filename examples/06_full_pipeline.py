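"""Run the whole analysis end to end from one config and print the report.

Equivalent to `ferroscore run --config cfg.yaml --out DIR`.
"""

from ferroscore import CohortConfig, PipelineConfig, make_report, run_pipeline

cfg = PipelineConfig(
    simulation=CohortConfig(n_samples=200, n_background_genes=100, seed=6),
)
bundle = run_pipeline(cfg)
print(make_report(bundle))
print("Fixed config + seed gives byte-identical summaries across runs; "
      "pass outdir= to write every intermediate table.")
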