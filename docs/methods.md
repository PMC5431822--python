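# Methods

## Model

Agents sit on a multiplex network of `F` undirected, unweighted simple
layers over `N` nodes; layer `f` carries the interactions relevant to
cultural feature `f`.  Each agent `i` holds a profile
`s_i = (s_i^[1], ..., s_i^[F])`, `s_i^[f] in {1..q}`; traits are nominal
(every statistic is invariant under per-feature relabelling, and this is
tested).

Time advances in *epochs*.  One epoch visits every agent once in a fresh
uniform random permutation; for each focal agent `i`:

1. pick `j` uniformly among the *aggregate* neighbours of `i` (nodes
   linked to `i` on at least one layer);
2. interact with probability equal to the layered cultural overlap
   `omega_ij = (1/F) sum_f a_ij^[f] delta(s_i^[f], s_j^[f])`;
3. on interaction, `j` copies `s_i^[f]` on one feature `f` drawn uniformly
   among layers where the pair is linked **and** the traits differ.

The *classical* mode is the reference single-network model run on the
aggregate graph: the interaction probability is the full-profile
similarity `(1/F) sum_f delta(s_i^[f], s_j^[f])` and any differing feature
may be copied, regardless of which layer carried the link.  At `o = 1`
(identical layers) the two modes are the same stochastic process — with a
common seed they produce bit-identical trajectories, and ensemble means of
`S` agree within sampling error (tested at `q = 2` and `q = 20`).

A state is *absorbed* when every aggregate-connected pair has
`omega_ij = 0` or `omega_ij = o_ij`; with zero drift the absorbed state is
an exact fixed point.  Note the asymmetric corollary: a pair that differs
on its only linked feature has `omega_ij = 0` and is frozen in
disagreement — single-feature subsystems never evolve at all.

### Conventions where the model leaves room

* **Schedule** — a random permutation per epoch (each agent focal exactly
  once) rather than `N` independent uniform draws; the difference is a
  time-unit convention, not a change of the embedded jump chain.
* **Imitation direction** — the focal agent influences the sampled
  neighbour (`s_j <- s_i`).
* **Feature choice** — restricted to linked *differing* features.
  Allowing already-equal linked features only inserts no-op moves: the
  embedded chain over states is unchanged and convergence is strictly
  faster.  The no-op variant is available via
  `ModelConfig(allow_noop_features=True)` for fidelity checks.
* **One attempt per focal agent** — no re-sampling of `j` after a
  rejected interaction.

## Cultural drift

Drift models spontaneous mutation: after each elementary agent-update,
with probability `r` one uniform agent resets one uniform feature (out of
all `F`, irrespective of layer activity — mutation is intrinsic, not
interaction-mediated) to a uniform trait in `{1..q}`.  The current value
may be redrawn, so the effective mutation rate is `r (1 - 1/q)`.  `r` is
therefore *per elementary update*: with `N = 625`, `r = 1e-4` means one
mutation every ~16 epochs.  Because the event-unit convention is a free
choice, drift results are treated as ordering statements (which phases
survive noise), never as numeric critical-rate estimates.

With `r > 0` no absorbing state exists; runs last `max_epochs` and report
the *quasi-stationary* average of `S` over trajectory samples from the
second half of the run (sampled every `absorption_check_interval` epochs).
The drift budget used in the validation (16 000 epochs at `r = 1e-4`,
`q = 2`) leaves the full-overlap system time to coarsen to monoculture
while the low-overlap system sits in its frozen fragmented state.

## Order parameters

* `S` — size/N of the largest *cultural component*: agents sharing all
  `F` traits, connected through aggregate edges whose endpoints also share
  the full profile.  The connecting path is confined to same-profile
  agents (the cultural-domain convention); a permissive variant
  (`permissive=True`) allows paths through unlike agents.  For `q = 1`,
  `S` equals the aggregate giant-component fraction — full consensus can
  never exceed the reach of the network.
* `S^[f]` — the same construction on layer `f` with trait `f` alone.  The
  population standard deviation of `S^[f]` across layers is the
  feature-level-consensus signature: ~0 when all layers agree on the
  phase, ~0.5 when half the layers hold consensus the other half has lost.
* Thresholds (`q_c`, `o_c`) are located by linear interpolation of the
  first crossing of the ensemble-mean response through 0.5; the grid
  spacing is the resolution of the estimate.

Both component observables are implemented with sparse connected-component
calls and are verified exactly against hand-rolled BFS oracles on hundreds
of random small instances, as are the overlap algebra and the absorption
predicate.

## Synthetic ensembles

**Rewired identical-ER multiplexes.**  One ER graph `G(N, K)` with
`K = round(N k / 2)` edges (fixed edge count, so `o = 1` at `p = 0` is
exact) is copied to all `F` layers; each edge of each layer is then
independently rewired with probability `p` to a uniformly random node pair
not already linked on that layer, conserving every layer's edge count.
Neglecting collisions (two edges rewired to the same pair), an original
edge position survives with multiplicity `m ~ Binomial(F, 1-p)` and each
rewired copy occupies a fresh position, giving the closed form

    o(p, F) = 1 / sum_{m=0..F} C(F,m) (1-p)^m p^(F-m) (1 - delta_{0,m} + F - m),

exact at both endpoints (`o(0) = 1`, `o(1) = 1/F`) and biased low by
`O(1/N)` in between.  The package treats the closed form as a prediction
to validate, not a target: sweeps are always indexed by the overlap
*measured* on the generated instance, and `rewire_collision_bias_bound`
gives an a-priori bound on the collision excess
(`<= o_pred * p (FK)^2 / (P K_pred)`, `P = N(N-1)/2`) used as the
tolerance allowance in the ensemble validation.  At `N = 625`, `F = 10`,
`k = 4` the worst measured deviation across `p` is ~3e-3.

**Two-density family.**  `F_high = 5` identical layers at `<k> = 8` plus
`F_low = 5` identical layers at `<k> = 4`; a fraction `beta` of the sparse
edge set is drawn from the dense edge pool, the rest from pairs outside
it.  `beta = 0` gives disjoint sets (minimal overlap, here exactly 0.5)
and the system decouples into two independent 5-layer blocks with
different densities — hence different critical `q` — producing the mixed
phase; `beta = 1` nests the sparse set in the dense one (overlap 0.75).

These generators emulate the homogeneous random substrate of the model
study.  They do **not** reproduce degree heterogeneity, clustering,
communities, degree-correlated interlayer activity or temporal ties of
real social networks, so passing tests validate the mechanism (overlap
controls the phase), not quantitative predictions for any empirical
system.  Empirical multiplexes can be loaded from plain-text edge lists
(weighted layers are binarised; analysis is restricted to the aggregate
giant component) and run through the identical machinery.

## Ensemble sizes and numerical choices

The validation suite and `scripts/acceptance.py` use `N = 625`, `F = 10`,
`<k> = 4` (the two-density family as above; `N = 225` for the
layered/classical equivalence ensembles, 50–100 replicates per mode), with
20 replicates per sweep cell, an epoch budget of 1.5–3e5 with absorption
checks every 100 epochs, and fixed seeds.  Runs that exhaust the budget
unabsorbed are recorded with `absorbed = False` and their final `S`, never
silently truncated; near the `q = 2` critical overlap a few percent of
replicates do so.  Every run derives all randomness (initial traits,
schedule, neighbour/feature/acceptance draws, drift) from a single seed,
so identical configurations are bit-reproducible; sweep rows derive their
seeds from `(base_seed, cell, replicate)` and are independent of execution
order, which makes sweeps resumable and embarrassingly parallel.

Degenerate inputs are handled explicitly: an edgeless multiplex has
undefined structural overlap (error); isolated agents are retained (inert
in the dynamics, counted in normalisations); giant-component ties break
to the component with the lexicographically smallest label; `q = 1`
absorbs at epoch zero.

## Known limitations

* Axelrod critical points are sensitive to update-rule conventions and
  system size.  Under the conventions above the classical transition on
  the full-overlap `<k> = 4` multiplex sits near `q ~ 110` (the
  acceptance script reports the measured crossing), and the two-density
  mixed window spans roughly `q ~ 45–110`; literature values obtained
  with other conventions place these somewhat higher.  Ordering and
  phase-structure statements are robust; absolute critical values carry
  a convention-dependent factor.
* The closed-form `o(p, F)` is collisionless and biased low by `O(1/N)`;
  always use measured overlaps for quantitative work.
* Drift critical lines are not estimated (event-unit convention, above).
* Out of scope: weighted/directed/temporal dynamics, interlayer replica
  couplings, coevolving topologies, bounded-confidence kernels, and
  cluster-size statistics beyond the largest component.
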