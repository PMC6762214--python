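# Single vibrant catalytic step: rate k0*exp(-alpha*Gamma) with Gamma a
# standard Ornstein-Uhlenbeck coordinate relaxing at lam = 0.1*k0.
# Product decay gamma = 5*k0.  Time unit: 1/k0.
model: modulated_rate
params:
  rate: {k0: 1.0, alpha: 0.5, lam: 0.1}
  gamma: 5.0
  thinning_dt: 0.001
run:
  seed: 1
  n_traj: 100
  t_total: 400.0
  dt_record: 0.05
  burn_in: 60.0
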