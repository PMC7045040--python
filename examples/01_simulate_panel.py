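"""Simulate a study-scale diary panel and summarise its structure.

The default configuration emulates a 62-smoker daily diary: record
lengths 69-91 days with mode 84, subject-specific means and scales, a
shared seasonal autoregression at lags {1, 2, 7, ..., 56} plus weekday
effects, and ~1% missing records.
"""

import memlag as ml

dataset, truth = ml.simulate_panel(ml.default_config(seed=1))
summary = ml.summarize_panel(dataset)

print(f"subjects:          {summary.n_subjects}")
print(f"daily records:     {summary.n_observations}")
print(f"record lengths:    {summary.length_min}-{summary.length_max} (mode {summary.length_mode})")
print(f"missing fraction:  {summary.missing_fraction:.4f}")
print(f"gender split:      {summary.gender_counts}")
print(f"innovation SD:     {truth['innovation_sd']:.4f}  (solved so the latent "
      "within-subject stationary variance is 1)")

# The counts are the raw (per-subject scaled) series; each subject's
# ground-truth latent mean and scale are in the truth record.
one = next(iter(truth["subjects"]))
info = truth["subjects"][one]
print(f"subject {one}: {info['n_days']} days, latent mean {info['mean']:.2f}, "
      f"scale {info['scale']:.2f}, starts on {info['start_weekday']}")
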