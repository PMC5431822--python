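# Cultural drift: the fragmented low-overlap phase survives noise, the
# full-overlap system coarsens to monoculture.  With r > 0 the S column
# holds the quasi-stationary tail average.
kind: rewired
N: 625
F: 10
k_mean: 4.0
q: 2
grid:
  p: [0.0, 1.0]
  r: [0.0, 0.0001, 0.001]
replicates: 10
max_epochs: 16000
absorption_check_interval: 200
base_seed: 13
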