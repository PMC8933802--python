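# Variant of the reference scenario in which the mismatch surcharge is an
# exact +50% at every severity: mismatched/moderate = 1.25 * 1.5 = 1.875
# instead of the default 1.8.
illnesses: [gastric ulcer, pneumonia, heart failure]
severities: [mild, moderate, severe]
weights:
  matched: {mild: 1.0, moderate: 1.25, severe: 1.5}
  mismatched: {mild: 1.5, moderate: 1.875, severe: 2.25}
wards:
  - {id: A, specialty: gastric ulcer, capacity: 40}
  - {id: B, specialty: pneumonia, capacity: 40}
  - {id: C, specialty: heart failure, capacity: 40}
arrivals_per_day: 7
mean_los_days: 14
n_days: 10
multiplier_range: [1.0, 2.0]
seed: 0
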