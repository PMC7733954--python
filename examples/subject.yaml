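# One goal-tracking subject: 20 reinforced trials, alpha .3 vs beta .5.
design:
  builder: {name: acquisition, n_trials: 20, n_epochs: 1}
subject:
  alpha: {CS: 0.3}
  beta: {US: 0.5}
seed: 0
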