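# Vibrant gene expression: same Bmal1a-like promoter, but the active-gene
# transcription rate is itself stochastic (lognormal, driven by an
# Ornstein-Uhlenbeck coordinate) with relative variance 0.1 and relaxation
# rate 0.01/min, around the same mean rate as the constant-rate model.
model: gene_expression
params:
  promoter:
    on: {variant: single_exponential, k: 0.3}
    off: {variant: multi_step, rates: [0.0993, 0.0993, 0.0993, 0.0993,
      0.0993, 0.0993, 0.23]}
  modulated_k_TX: {mean_rate: 2.0, eta2: 0.1, lam: 0.01}
  thinning_dt: 0.01
  gamma_m: 0.2
  k_TL: 5.0
  gamma_p: 0.05
record: mRNA
run:
  seed: 1
  n_traj: 100
  t_total: 8000.0
  dt_record: 2.0
  burn_in: 1000.0
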