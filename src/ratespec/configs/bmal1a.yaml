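# Luciferase expression under the Bmal1a promoter in mouse fibroblasts:
# gene activation is a 7-step sequential process (rates in 1/min:
# k1..k6 = 9.93e-2, k7 = 0.23; mean inactive period ~64.8 min) and
# deactivation is one-step.  The activation rates fix the promoter cycle
# at ~68 min, i.e. a spectral peak near 2*pi/68 ~ 0.1 rad/min.  The
# on-state deactivation rate (0.3/min, mean burst ~3.3 min) and the short
# reporter mRNA/protein lifetimes (5 and 20 min) are set to the few-minute
# bursts and destabilized-reporter lifetimes characteristic of this
# system; they are not constrained by the activation rates.
model: gene_expression
params:
  promoter:
    on: {variant: single_exponential, k: 0.3}
    off: {variant: multi_step, rates: [0.0993, 0.0993, 0.0993, 0.0993,
      0.0993, 0.0993, 0.23]}
  k_TX: 2.0
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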