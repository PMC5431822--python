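# Sweep configurations

Each YAML file defines a `SweepSpec` consumed by the `sweep` subcommand:

    multiplex-axelrod sweep --config experiments/critical_overlap_q2.yaml --out results/oc_q2.csv

Sweeps are resumable: re-running the command appends only missing
(cell, replicate) rows, and a finished sweep is never recomputed.
Analyse the output with `multiplex_axelrod.estimate_threshold` on the
`o_measured` (or `q`) means per cell.

* `critical_overlap_q2.yaml` — layered model, q=2, measured overlap spanning
  [0.1, 0.4]: locates the critical overlap o_c ~ 2/F below which
  multiculturality is unavoidable.
* `classical_qc_full_overlap.yaml` — classical model on the full-overlap
  multiplex (aggregate = one ER graph, <k>=4): brackets the classical
  critical trait number q_c ~ 10^2.  The fine grid near the transition is
  the slow part; refine by adding q values to the grid and resuming.
* `two_density_feature_consensus.yaml` — two-density family at minimal
  overlap: the feature-level-consensus (mixed) window between the sparse-set
  and dense-set transitions.
* `drift_stability.yaml` — layered model with cultural drift: fragmented
  low-overlap states persist under noise while the full-overlap system
  coarsens to monoculture.
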