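import numpy as np
import pytest

from kellerdfc.simulate import (
    BenchmarkScenario,
    TrueCoefficientTrajectory,
    build_trajectory,
    generate_topology,
    label_benchmark_dynamic,
    simulate_benchmark,
    simulate_var1,
    sliding_var_coefficients,
)


class TestGenerateTopology:
    def test_er_sparsity_in_range(self):
        for seed in range(5):
            adj = generate_topology("erdos_renyi", 5, (0.4, 0.7), seed=seed)
            iu = np.triu_indices(5, 1)
            sparsity = 1.0 - adj[iu].mean()
            assert 0.4 <= sparsity <= 0.7
            np.testing.assert_array_equal(adj, adj.T)
            assert not adj.diagonal().any()

    def test_two_nodes_at_most_one_edge(self):
        adj = generate_topology("erdos_renyi", 2, (0.0, 1.0), seed=0)
        assert adj[0, 1] in (False, True)

    def test_preferential_attachment_heavy_tail(self):
        hits = 0
        n = 30
        for seed in range(n):
            adj = generate_topology("scale_free", 20, (0.4, 0.7), seed=seed)
            deg = adj.sum(0)
            hits += deg.max() >= 2 * np.median(deg)
        assert hits / n >= 0.8

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_topology("smallworld", 5)


class TestBuildTrajectory:
    def test_static_single_state_scenario_constant(self):
        sc = BenchmarkScenario(n_states=1, modulation_prob=0.0, seed=4)
        traj = build_trajectory(sc)
        np.testing.assert_allclose(traj.A, np.broadcast_to(traj.A[0], traj.A.shape))

    def test_strengths_inside_range_and_stable(self):
        sc = BenchmarkScenario(seed=8)
        traj = build_trajectory(sc)
        iu = np.triu_indices(sc.p, 1)
        off = traj.A[:, iu[0], iu[1]][traj.support[:, iu[0], iu[1]]]
        lo, hi = sc.strength_range
        assert off.min() >= lo * traj.scale - 1e-12
        assert off.max() <= hi * traj.scale + 1e-12
        radii = [np.abs(np.linalg.eigvals(traj.A[t])).max() for t in range(0, 300, 25)]
        assert max(radii) < 1.0

    def test_emerging_edge_ramps_up(self):
        # an edge absent in state s-1 and present in state s must ramp upward
        sc = BenchmarkScenario(seed=8)
        traj = build_trajectory(sc)
        L = sc.samples_per_state
        iu = np.triu_indices(sc.p, 1)
        strictly_up = 0
        for s in range(1, sc.n_states):
            for i, j in zip(*iu):
                if traj.support[s * L, i, j] and not traj.support[s * L - 1, i, j]:
                    seg = traj.A[s * L : (s + 1) * L, i, j]
                    # an edge that immediately leaves again stays at the floor
                    assert seg[-1] >= seg[0]
                    strictly_up += seg[-1] > seg[0]
        assert strictly_up >= 1

    def test_continuity_across_state_boundaries(self):
        sc = BenchmarkScenario(seed=8)
        traj = build_trajectory(sc)
        L = sc.samples_per_state
        jumps = np.abs(traj.A[L] - traj.A[L - 1]).max()
        # continuing edges meet at the boundary; entering/leaving edges step
        # at most by the activation floor
        assert jumps <= sc.strength_range[0] * traj.scale + 1e-9


class TestSimulateVar1:
    def test_no_coupling_gives_white_noise(self):
        T, p = 300, 4
        traj = TrueCoefficientTrajectory(A=np.zeros((T, p, p)), support=np.zeros((T, p, p), bool))
        Y = simulate_var1(traj, seed=0)
        X = Y.values
        ac = [np.corrcoef(X[:-1, i], X[1:, i])[0, 1] for i in range(p)]
        assert np.abs(ac).max() < 0.15

    def test_strong_self_coupling_autocorrelation(self):
        T, p = 300, 3
        A = np.zeros((T, p, p))
        A[:, np.arange(p), np.arange(p)] = 0.9
        traj = TrueCoefficientTrajectory(A=A, support=np.zeros((T, p, p), bool))
        X = simulate_var1(traj, seed=1).values
        ac = [np.corrcoef(X[:-1, i], X[1:, i])[0, 1] for i in range(p)]
        assert np.abs(np.array(ac) - 0.9).max() < 0.1

    def test_same_seed_bit_identical(self):
        traj = build_trajectory(BenchmarkScenario(seed=2))
        a = simulate_var1(traj, seed=5).values
        b = simulate_var1(traj, seed=5).values
        np.testing.assert_array_equal(a, b)

    def test_no_variance_blowup_within_states(self):
        for seed in range(10):
            traj, Y = simulate_benchmark(BenchmarkScenario(seed=seed))
            assert Y.values.std(axis=0).max() < 20.0


class TestSlidingVarCoefficients:
    def test_recovers_static_coefficients(self):
        T, p = 400, 3
        A = np.zeros((T, p, p))
        A[:, np.arange(p), np.arange(p)] = 0.5
        A[:, 0, 1] = 0.4
        traj = TrueCoefficientTrajectory(A=A, support=np.zeros((T, p, p), bool))
        X = simulate_var1(traj, seed=3).values
        Ahat = sliding_var_coefficients(X, window=200)
        assert abs(Ahat[:, 0, 1].mean() - 0.4) < 0.1
        assert abs(Ahat[:, 0, 0].mean() - 0.5) < 0.1


class TestBenchmarkLabels:
    def test_constant_edges_labeled_static(self, static_var_series):
        traj, Y = static_var_series
        labels = label_benchmark_dynamic(traj, Y.values, n_surrogates=100, seed=0)
        assert not labels.dynamic.any()  # zero true modulation SD everywhere

    def test_full_range_ramp_labeled_dynamic(self):
        T = 300
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            A = np.zeros((T, 3, 3))
            A[:, np.arange(3), np.arange(3)] = 0.7
            A[:, 0, 1] = np.linspace(0.1, 0.75, T)
            sup = np.zeros((T, 3, 3), bool)
            sup[:, 0, 1] = sup[:, 1, 0] = True
            traj = TrueCoefficientTrajectory(A=A, support=sup)
            Y = simulate_var1(traj, seed=seed)
            labels = label_benchmark_dynamic(traj, Y.values, n_surrogates=150, seed=seed)
            hits += bool(labels.dynamic[0])
        assert hits >= n_seeds - 1

    def test_default_scenario_labels_most_modulated_edges(self):
        traj, Y = simulate_benchmark(BenchmarkScenario(seed=6))
        labels = label_benchmark_dynamic(traj, Y.values, n_surrogates=200, seed=1)
        iu = np.triu_indices(5, 1)
        true_sd = traj.A[:, iu[0], iu[1]].std(axis=0, ddof=1)
        strong = true_sd > 0.15
        if strong.any():
            assert (labels.dynamic & strong).sum() / strong.sum() >= 0.5

    def test_too_few_surrogates_rejected(self, static_var_series):
        traj, Y = static_var_series
        with pytest.raises(ValueError):
            label_benchmark_dynamic(traj, Y.values, n_surrogates=10)


def test_default_scenario_matches_experimental_frame():
    sc = BenchmarkScenario()
    assert (sc.p, sc.n_states, sc.samples_per_state, sc.T) == (5, 3, 100, 300)
    traj, Y = simulate_benchmark(sc)
    assert Y.values.shape == (300, 5)
    assert Y.tr == 1.0
    # support changes only at the two change points t = 100 and 200
    change = np.where(np.any(traj.support[1:] != traj.support[:-1], axis=(1, 2)))[0] + 1
    assert set(change).issubset({100, 200})
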