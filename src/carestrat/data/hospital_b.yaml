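# Example high-performing hospital (one of six conditions above the
# peer-group-2 mean readmission target; cumulative HRRP penalty 0.2%).
# The dollar penalty is an assumed figure scaled from hospital A's by the
# penalty percentages and cost baselines; see docs/methods.md.
hospital_id: B
annual_penalty: 49000.0
decision_period: 3 months
conditions:
- id: AMI
  target_rate: 0.1597
  hospital_mean_rate: 0.1769
  lambda: 0.25
  n_patients: 18
  cost_triangular: [8439, 10548, 26370]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: PN
  target_rate: 0.1537
  hospital_mean_rate: 0.1469
  lambda: 0.25
  n_patients: 69
  cost_triangular: [7897, 9871, 24678]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: HF
  target_rate: 0.2048
  hospital_mean_rate: 0.1499
  lambda: 0.25
  n_patients: 44
  cost_triangular: [7494, 9367, 23418]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: HK
  target_rate: 0.0801
  hospital_mean_rate: 0.0341
  lambda: 0.25
  n_patients: 76
  cost_triangular: [4196, 9001, 25542]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: COPD
  target_rate: 0.1867
  hospital_mean_rate: 0.1711
  lambda: 0.25
  n_patients: 22
  cost_triangular: [8082, 10102, 25255]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: CABG
  target_rate: 0.1515
  hospital_mean_rate: 0.1236
  lambda: 0.25
  n_patients: 7
  cost_triangular: [47382, 67664, 196103]
  n_plans: 10
  tier_sizes: [3, 4, 3]
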