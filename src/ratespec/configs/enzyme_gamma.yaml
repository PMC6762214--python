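# Ten independent enzymes, each cycling association (rate 1 per mean ES
# lifetime), gamma-distributed ES complex lifetime (shape 4), and catalysis
# with probability 1/2.  Time unit: mean ES lifetime (a*b = 1); product
# decay gamma = 5.
model: enzyme_network
params:
  k1S: 1.0
  p2: 0.5
  es: {variant: gamma, a: 4.0, b: 0.25}
  n_enzymes: 10
  gamma: 5.0
run:
  seed: 1
  n_traj: 100
  t_total: 60.0
  dt_record: 0.01
  burn_in: 10.0
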