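# Desk-scale end-to-end run: simulate -> edit -> REML -> curves -> EBV -> validate.
# Reproducible: rerunning with the same seed yields identical output checksums.
seed: 20240101

basis:
  order: 3
  first_day: 5
  last_day: 305

sim:
  n_herds: 8
  cows_per_herd_year: 6
  first_year: 2000
  last_year: 2007
  n_base_sires: 10
  n_base_dams: 150

edits:
  herd_min: 0        # the study-scale defaults (500/1000) would wipe a desk dataset
  year_min: 0
  min_records: 2

reml:
  enabled: true
  max_iter: 15
  tol: 1.0e-3

validation:
  first_cut_year: 2005
  min_daughters: 5
  cohort_rule: max
  n_boot: 2000
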