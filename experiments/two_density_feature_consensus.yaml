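# Two-density family (5 layers <k>=4, 5 layers <k>=8) at minimal overlap:
# the mixed window where only the dense set reaches consensus.
kind: two_density
N: 625
F_low: 5
F_high: 5
k_low: 4.0
k_high: 8.0
grid:
  q: [20, 40, 50, 60, 70, 80, 90, 110, 130, 150]
  beta: [0.0]
replicates: 20
max_epochs: 300000
absorption_check_interval: 100
base_seed: 12
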