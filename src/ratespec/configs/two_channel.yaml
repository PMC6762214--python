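# Two-channel (hyperexponential) creation: bursty, super-Poisson timing.
# Mean creation time 0.5/gamma; the rate spectrum is positive and
# monotonically decreasing.
model: renewal_birth_death
params:
  reaction_time: {variant: multi_channel, probs: [0.5, 0.5], rates: [1.2, 12.0]}
  gamma: 1.0
run:
  seed: 1
  n_traj: 200
  t_total: 220.0
  dt_record: 0.05
  burn_in: 20.0
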