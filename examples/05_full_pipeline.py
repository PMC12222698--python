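"""One-call pipeline run: synthetic inputs through every analysis stage.

Equivalent to ``indoair report --seed 1 --output-dir indoair-output`` on the
command line; per-stage CSVs plus a consolidated report.json land in the
output directory.
"""

from indoair import RunConfig, run_pipeline

cfg = RunConfig(seed=1, output_dir="indoair-output", mc_iterations=50_000)
bundle = run_pipeline(cfg)

print("stages in bundle:", ", ".join(k for k in bundle if k not in ("units", "provenance", "schema_version")))
print("annual projection (ug/m3):",
      {k: round(v, 1) for k, v in bundle["annual_projection_ug_m3"].items()})
print("annual hazard index:", round(bundle["deterministic"]["hazard_index_annual_cpcb"], 2))
lcr = bundle["probabilistic"]["lcr_by_cohort"][0]
print(f"male 16-21 LCR: det {lcr['deterministic_LCR']:.3g}, "
      f"MC mean {lcr['probabilistic_LCR_mean']:.3g} "
      f"({lcr['percent_difference']:+.2f}%)")
print("provenance:", bundle["provenance"])
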