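"""One-call orchestration: the complete analysis as a JSON-able report.

describe -> homoscedastic transform -> correlogram -> model ladder
(M1 attempted, M2/M3/M0 fitted) -> nested tests -> residual
diagnostics -> verdict.  The report is deterministic for a given panel.
"""

import memlag as ml

dataset, _ = ml.simulate_panel(ml.default_config(seed=1))
report = ml.run_full_analysis(dataset)

v = report.verdict
print("stages:", " -> ".join(report.stages_log))
print(f"chosen model:       {v['chosen_model']}")
print(f"overall fit ok:     {v['overall_fit_ok']}")
print(f"terms significant:  {v['all_terms_significant']} (lags individually, "
      "day-of-week as a block)")
print(f"AIC(M2) < AIC(M3):  {v['aic_m2_below_m3']}")
print(f"residuals ok:       {v['residuals_ok']}")
print(f"R2 of daily counts: {v['r2']:.3f}")
print()
print("write the full report with report.to_json('report.json')")
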