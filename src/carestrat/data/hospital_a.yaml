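# Example low-performing hospital (five of six conditions above the
# peer-group-2 mean readmission target; cumulative HRRP penalty 1.35%).
# The dollar penalty is an assumed figure consistent with the ~$0.62M gap
# between the with- and without-penalty baselines; see docs/methods.md.
hospital_id: A
annual_penalty: 620000.0
decision_period: 3 months
conditions:
- id: AMI
  target_rate: 0.1597
  hospital_mean_rate: 0.2121
  lambda: 0.25
  n_patients: 52
  cost_triangular: [6745, 8431, 21078]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: PN
  target_rate: 0.1537
  hospital_mean_rate: 0.1901
  lambda: 0.25
  n_patients: 132
  cost_triangular: [6312, 7890, 19725]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: HF
  target_rate: 0.2048
  hospital_mean_rate: 0.2243
  lambda: 0.25
  n_patients: 126
  cost_triangular: [5990, 7487, 18718]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: HK
  target_rate: 0.0801
  hospital_mean_rate: 0.0421
  lambda: 0.25
  n_patients: 96
  cost_triangular: [3585, 9359, 31814]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: COPD
  target_rate: 0.1867
  hospital_mean_rate: 0.1956
  lambda: 0.25
  n_patients: 47
  cost_triangular: [6460, 8075, 20188]
  n_plans: 10
  tier_sizes: [3, 4, 3]
- id: CABG
  target_rate: 0.1515
  hospital_mean_rate: 0.1733
  lambda: 0.25
  n_patients: 21
  cost_triangular: [39864, 56297, 161385]
  n_plans: 10
  tier_sizes: [3, 4, 3]
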