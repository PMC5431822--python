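import numpy as np
import pytest

from multiplex_axelrod import (
    CultureState,
    ModelConfig,
    MultiplexNetwork,
    apply_drift,
    cultural_overlap,
    epoch_classical,
    epoch_layered,
    identical_er_multiplex,
    init_culture,
    is_absorbed,
    run,
)

from conftest import random_instance
from oracles import cultural_overlap_brute, is_absorbed_brute


class TestInitCulture:
    def test_q_one_all_equal(self):
        state = init_culture(10, 3, 1, seed=0)
        assert np.all(state.traits == 1)

    def test_seed_reproducible(self):
        a = init_culture(30, 4, 7, seed=5)
        b = init_culture(30, 4, 7, seed=5)
        assert np.array_equal(a.traits, b.traits)

    def test_uniform_trait_frequencies(self):
        # 1e5 entries at q=10: each trait count within 4 s.e. of n/q.
        q, n = 10, 100_000
        state = init_culture(n // 10, 10, q, seed=1)
        counts = np.bincount(state.traits.ravel(), minlength=q + 1)[1:]
        expected = n / q
        se = np.sqrt(n * (1 / q) * (1 - 1 / q))
        assert np.all(np.abs(counts - expected) <= 4 * se)

    def test_invalid_traits_rejected(self):
        with pytest.raises(ValueError):
            CultureState(np.array([[0, 1]]), q=2)
        with pytest.raises(ValueError):
            init_culture(5, 2, 0)


class TestCulturalOverlap:
    def test_frozen_bond_toy(self, pair_net):
        # linked on 2 of 3 layers with equal traits there, differing on the
        # unlinked third: omega = 2/3 = o_ij, so the bond is frozen.
        state = CultureState(np.array([[1, 2, 3], [1, 2, 4]]), q=4)
        assert cultural_overlap(pair_net, state, "i", "j") == pytest.approx(2 / 3)
        assert pair_net.edge_overlap("i", "j") == pytest.approx(2 / 3)

    def test_all_linked_traits_differ(self, pair_net):
        state = CultureState(np.array([[1, 2, 3], [4, 5, 3]]), q=5)
        assert cultural_overlap(pair_net, state, "i", "j") == 0.0

    def test_identical_profiles_give_edge_overlap(self, rng):
        for _ in range(5):
            net, state = random_instance(rng)
            state.traits[1] = state.traits[0]
            u, v = net.nodes[0], net.nodes[1]
            assert cultural_overlap(net, state, u, v) == pytest.approx(net.edge_overlap(u, v))

    def test_bounded_by_edge_overlap_and_matches_brute(self, rng):
        for _ in range(10):
            net, state = random_instance(rng)
            for _ in range(10):
                a, b = rng.choice(net.N, size=2, replace=False)
                u, v = net.nodes[a], net.nodes[b]
                w = cultural_overlap(net, state, u, v)
                assert w <= net.edge_overlap(u, v) + 1e-12
                assert w == pytest.approx(cultural_overlap_brute(net, state, u, v))

    def test_unknown_node(self, pair_net):
        state = CultureState(np.ones((2, 3), dtype=int), q=1)
        with pytest.raises(ValueError):
            cultural_overlap(pair_net, state, "i", "nope")


class TestEpochs:
    def test_absorbed_state_is_fixed_point(self, rng):
        # an absorbed state stays bit-identical over 100 further epochs
        net = identical_er_multiplex(30, 3, 3, seed=2)
        res = run(net, ModelConfig(q=2, mode="layered", seed=3, record_trajectory=False))
        assert res.absorbed
        frozen = res.state.traits.copy()
        total = 0
        for _ in range(100):
            _, changed = epoch_layered(net, res.state, seed=None)
            total += changed
        assert total == 0
        assert np.array_equal(res.state.traits, frozen)

    def test_zero_overlap_pair_is_frozen(self):
        # differing on the only linked feature means omega = 0: the bond
        # is inactive and the disagreement persists forever
        net = MultiplexNetwork(["i", "j"], [[("i", "j")], []])
        state = CultureState(np.array([[1, 1], [2, 2]]), q=2)
        assert is_absorbed(net, state, "layered")
        _, changed = epoch_layered(net, state, seed=0)
        assert changed == 0 and np.array_equal(state.traits, [[1, 1], [2, 2]])

    def test_partially_similar_pair_aligns_linked_features_only(self):
        # agreeing on one of two linked layers (omega = 1/3 > 0), the pair
        # converges to agreement on both linked features; the unlinked
        # third feature is never touched
        net = MultiplexNetwork(["i", "j"], [[("i", "j")], [("i", "j")], []])
        state = CultureState(np.array([[1, 2, 3], [2, 2, 4]]), q=4)
        for step in range(200):
            if is_absorbed(net, state, "layered"):
                break
            epoch_layered(net, state, seed=step)
        assert is_absorbed(net, state, "layered")
        assert state.traits[0, 0] == state.traits[1, 0]
        assert state.traits[0, 1] == state.traits[1, 1] == 2
        assert state.traits[0, 2] == 3 and state.traits[1, 2] == 4

    def test_classical_full_similarity_pair_never_changes(self):
        net = MultiplexNetwork(["i", "j"], [[("i", "j")]] * 2)
        state = CultureState(np.array([[3, 4], [3, 4]]), q=4)
        for step in range(20):
            epoch_classical(net, state, seed=step)
        assert np.array_equal(state.traits, [[3, 4], [3, 4]])

    def test_trait_support_never_grows(self, rng):
        # imitation only copies existing values: per feature, the set of
        # traits present can only shrink under drift-free dynamics
        net, state = random_instance(rng, q=4)
        before = [set(state.traits[:, f]) for f in range(net.F)]
        for step in range(50):
            epoch_layered(net, state, seed=1000 + step)
        for f in range(net.F):
            assert set(state.traits[:, f]) <= before[f]

    def test_epoch_determinism(self, rng):
        net, state = random_instance(rng, q=3)
        s1, s2 = state.copy(), state.copy()
        _, c1 = epoch_layered(net, s1, seed=99)
        _, c2 = epoch_layered(net, s2, seed=99)
        assert c1 == c2 and np.array_equal(s1.traits, s2.traits)


class TestDrift:
    def test_zero_rate_never_changes(self, rng):
        state = init_culture(20, 3, 5, seed=0)
        before = state.traits.copy()
        apply_drift(state, 0.0, rng, n_updates=10_000)
        assert np.array_equal(state.traits, before)

    def test_q_one_mutations_are_invisible(self, rng):
        state = init_culture(20, 3, 1, seed=0)
        apply_drift(state, 1.0, rng, n_updates=1000)
        assert np.all(state.traits == 1)

    def test_event_rate_convention(self, rng):
        # r per elementary update: over 1e6 updates at r=1e-3 roughly 1e3
        # events; with a huge q and a huge trait matrix nearly every event
        # changes a distinct entry, so changed entries ~ Binomial(1e6, r).
        n_updates, r = 1_000_000, 1e-3
        state = init_culture(100_000, 10, 1_000_000_000, seed=7)
        before = state.traits.copy()
        apply_drift(state, r, rng, n_updates=n_updates)
        changed = int((state.traits != before).sum())
        mean = n_updates * r
        se = np.sqrt(n_updates * r * (1 - r))
        assert abs(changed - mean) <= 3 * se + 2  # +2: same-trait redraws / cell collisions

    def test_negative_rate_rejected(self, rng):
        state = init_culture(5, 2, 2, seed=0)
        with pytest.raises(ValueError):
            apply_drift(state, -0.1, rng)


class TestAbsorption:
    def test_partially_aligned_pair_frozen_only_in_layered(self, pair_net):
        # equal on both linked features, differing on the unlinked one:
        # the layered bond is frozen, the classical bond still active.
        state = CultureState(np.array([[1, 2, 3], [1, 2, 4]]), q=4)
        assert is_absorbed(pair_net, state, "layered")
        assert not is_absorbed(pair_net, state, "classical")

    def test_uniform_population_absorbed_in_both_modes(self, rng):
        net, _ = random_instance(rng)
        state = CultureState(np.ones((net.N, net.F), dtype=int) * 2, q=3)
        assert is_absorbed(net, state, "layered")
        assert is_absorbed(net, state, "classical")

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            net, state = random_instance(rng)
            for mode in ("layered", "classical"):
                assert is_absorbed(net, state, mode) == is_absorbed_brute(net, state, mode)


class TestRun:
    def test_q_one_absorbs_immediately_at_giant_component_consensus(self):
        import networkx as nx

        net = identical_er_multiplex(30, 2, 3, seed=1)
        res = run(net, ModelConfig(q=1, seed=0))
        assert res.absorbed and res.epochs_run == 0
        giant = max(len(c) for c in nx.connected_components(net.aggregate()))
        assert res.trajectory["S"].iloc[0] == pytest.approx(giant / 30)

    def test_fully_linked_pair_reaches_an_absorbing_endpoint(self):
        net = MultiplexNetwork(["i", "j"], [[("i", "j")]] * 3)
        res = run(net, ModelConfig(q=2, mode="layered", seed=4, record_trajectory=False))
        assert res.absorbed
        t = res.state.traits
        assert np.all(t[0] == t[1]) or np.all(t[0] != t[1])

    def test_unabsorbed_budget_flagged_not_raised(self):
        net = identical_er_multiplex(200, 8, 4, seed=6)
        res = run(net, ModelConfig(q=30, mode="layered", seed=6, max_epochs=1,
                                   absorption_check_interval=1, record_trajectory=False))
        assert not res.absorbed and res.epochs_run == 1

    def test_run_determinism(self):
        net = identical_er_multiplex(60, 4, 4, seed=8)
        cfg = ModelConfig(q=5, mode="layered", seed=123, record_trajectory=False)
        a = run(net, cfg)
        b = run(net, cfg)
        assert a.epochs_run == b.epochs_run
        assert np.array_equal(a.state.traits, b.state.traits)

    def test_drift_raises_late_time_activity(self):
        # with r=0 the system freezes (no changes in the last chunk);
        # at r=1e-2 mutation keeps bonds active indefinitely
        net = identical_er_multiplex(100, 5, 4, seed=9)
        quiet = run(net, ModelConfig(q=2, seed=10, max_epochs=5000,
                                     absorption_check_interval=50))
        noisy = run(net, ModelConfig(q=2, r=1e-2, seed=10, max_epochs=5000,
                                     absorption_check_interval=50))
        assert quiet.absorbed  # r=0 activity is exactly zero from here on
        assert noisy.trajectory["changed"].tail(10).mean() > 0

    def test_quasi_stationary_tail_reported(self):
        net = identical_er_multiplex(50, 3, 4, seed=11)
        res = run(net, ModelConfig(q=2, r=1e-3, seed=12, max_epochs=400,
                                   absorption_check_interval=50))
        assert res.tail_mean_S is not None and 0 < res.tail_mean_S <= 1
        assert res.epochs_run == 400

    def test_shape_mismatch_rejected(self):
        net = identical_er_multiplex(30, 2, 3, seed=1)
        bad = init_culture(10, 2, 3, seed=0)
        with pytest.raises(ValueError, match="shape"):
            run(net, ModelConfig(q=3, seed=0), initial_state=bad)
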