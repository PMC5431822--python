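# Classical dynamics on the full-overlap multiplex (aggregate = single ER,
# <k>=4): S vs q brackets the monoculture/multiculture transition.
kind: rewired
N: 625
F: 10
k_mean: 4.0
grid:
  mode: [classical]
  q: [50, 80, 90, 100, 105, 110, 115, 120, 130, 140, 200]
  p: [0.0]
replicates: 20
max_epochs: 500000
absorption_check_interval: 100
base_seed: 11
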