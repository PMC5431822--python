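# Layered model at q=2: S vs measured overlap, crossing near 2/F.
# p values chosen so the predicted overlap spans 0.10..0.40 in steps of 0.05
# (invert with multiplex_axelrod.rewiring_probability_for_overlap).
kind: rewired
N: 625
F: 10
k_mean: 4.0
grid:
  q: [2]
  p: [1.0, 0.56701, 0.40001, 0.30000, 0.23333, 0.18571, 0.15000]
replicates: 20
max_epochs: 150000
absorption_check_interval: 100
base_seed: 20260925
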