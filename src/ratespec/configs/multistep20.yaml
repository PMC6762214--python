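# 20-step sequential creation (Erlang-20 reaction time), mean 0.5/gamma:
# strongly sub-Poisson timing; the rate spectrum is negative at low
# frequency and non-monotonic.
model: renewal_birth_death
params:
  reaction_time: {variant: multi_step, rates: [40.0, 40.0, 40.0, 40.0, 40.0,
    40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0, 40.0,
    40.0, 40.0, 40.0]}
  gamma: 1.0
run:
  seed: 1
  n_traj: 200
  t_total: 220.0
  dt_record: 0.05
  burn_in: 20.0
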