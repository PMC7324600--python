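# Desk-scale configuration for the full selection pipeline on a sampled
# synthetic cohort (seeded; byte-reproducible).
seed: 17
table:
  sample:
    n_per_group: {N_F: 18, FD_F: 14, N_M: 16, FD_M: 12}
prune:
  threshold: 0.9
cv:
  k: 5
  repeats: 2
boosting:
  learning_rate: 0.1
  n_stumps: 60
step2:
  grid: [1, 10, 30, 60]
  tolerance: 0.005
select:
  auc_tolerance: 0.005
  combine_tolerance: 0.01
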