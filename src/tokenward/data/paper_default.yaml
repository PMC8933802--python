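# Reference scenario: a small hospital of 3 wards x 40 beds, 3 illnesses x
# 3 severities, 7 emergency arrivals per day, geometric length of stay with
# mean 14 days, 10-day sessions, specialty acceptance multiplier U(1.0, 2.0).
# Note mismatched/moderate ships as the printed 1.8 (an exact +50% surcharge
# on 1.25 would be 1.875; see surcharge_exact.yaml).
illnesses: [gastric ulcer, pneumonia, heart failure]
severities: [mild, moderate, severe]
weights:
  matched: {mild: 1.0, moderate: 1.25, severe: 1.5}
  mismatched: {mild: 1.5, moderate: 1.8, severe: 2.25}
wards:
  - {id: A, specialty: gastric ulcer, capacity: 40}
  - {id: B, specialty: pneumonia, capacity: 40}
  - {id: C, specialty: heart failure, capacity: 40}
arrivals_per_day: 7
mean_los_days: 14
n_days: 10
multiplier_range: [1.0, 2.0]
# arrival_distribution omitted -> uniform over the 9 (illness, severity) patterns
policies:
  A: {kind: constant, params: {base: 5.0}}
  B: {kind: constant, params: {base: 5.0}}
  C: {kind: constant, params: {base: 5.0}}
seed: 0
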