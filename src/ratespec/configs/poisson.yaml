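# Poisson birth-death: one-step creation at rate 2*gamma, decay at gamma.
# The product-number spectrum is the pure Lorentzian 2<R>/(omega^2+gamma^2)
# and the rate spectrum vanishes at every frequency.
model: renewal_birth_death
params:
  reaction_time: {variant: single_exponential, k: 2.0}
  gamma: 1.0
run:
  seed: 1
  n_traj: 200
  t_total: 220.0
  dt_record: 0.05
  burn_in: 20.0
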