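# 40 subjects, 6 blocks of 10 reinforced lever-sucrose pairings.
design:
  builder: {name: acquisition, n_trials: 60, trials_per_block: 10}
population:
  n_subjects: 40
  alpha_distribution: {family: beta, params: [2, 2]}
  beta_distribution: {family: beta, params: [2, 2]}
  count_scale: 20
seed: 0
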