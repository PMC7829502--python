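import numpy as np
import pytest

from oracle_util import eq1_modularity, exhaustive_max_q, random_multilayer

from dynbrain.modularity import (
    ModularityParams,
    build_multilayer,
    ensemble,
    louvain_run,
    modularity_q,
)


def two_clique_layer():
    """Single layer, two disconnected 2-cliques (edges (1,2) and (3,4), weight 1)."""
    A = np.zeros((1, 4, 4))
    A[0, 0, 1] = A[0, 1, 0] = 1.0
    A[0, 2, 3] = A[0, 3, 2] = 1.0
    return A


class TestBuild:
    def test_negative_weights_are_zeroed(self):
        A = np.zeros((1, 3, 3))
        A[0, 0, 1] = A[0, 1, 0] = 0.5
        A[0, 1, 2] = A[0, 2, 1] = -0.3
        mg = build_multilayer(A, ModularityParams())
        assert mg.layers[0, 0, 1] == 0.5
        assert mg.layers[0, 1, 2] == 0.0

    def test_two_clique_strengths_and_totals(self):
        mg = build_multilayer(two_clique_layer(), ModularityParams(omega=0.0))
        assert np.all(mg.strengths == 1.0)
        assert mg.layer_totals[0] == 4.0

    def test_omega_zero_coupling_contributes_nothing_to_mu(self):
        A = np.tile(two_clique_layer(), (3, 1, 1)).reshape(3, 4, 4)
        mg0 = build_multilayer(A, ModularityParams(omega=0.0))
        mg1 = build_multilayer(A, ModularityParams(omega=1.0))
        assert mg0.two_mu == 12.0
        assert mg1.two_mu == 12.0 + 2 * 1.0 * 4 * 2

    def test_all_zero_layer_is_an_error(self):
        A = np.zeros((2, 3, 3))
        A[0, 0, 1] = A[0, 1, 0] = 1.0
        with pytest.raises(ValueError, match="layer 2"):
            build_multilayer(A, ModularityParams())


class TestModularityQ:
    def test_two_clique_partition_scores_one_half(self):
        mg = build_multilayer(two_clique_layer(), ModularityParams(omega=0.0))
        labels = np.array([[1, 1, 2, 2]])
        assert modularity_q(mg, labels) == pytest.approx(0.5)

    def test_q_matches_brute_force_evaluator_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            layers = random_multilayer(rng, 3, 2)
            params = ModularityParams(gamma=float(rng.uniform(0.5, 1.5)),
                                      omega=float(rng.uniform(0, 1.5)))
            mg = build_multilayer(layers, params)
            labels = rng.integers(1, 4, size=(2, 3))
            assert modularity_q(mg, labels) == pytest.approx(
                eq1_modularity(mg.layers, labels, params.gamma, params.omega),
                abs=1e-12,
            )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        layers = random_multilayer(rng, 4, 2)
        mg = build_multilayer(layers, ModularityParams())
        labels = rng.integers(1, 4, size=(2, 4))
        perm = {1: 7, 2: 3, 3: 12}
        permuted = np.vectorize(perm.get)(labels)
        assert modularity_q(mg, labels) == pytest.approx(modularity_q(mg, permuted))

    def test_identical_layers_uncoupled_equal_single_layer_q(self):
        # 2 identical layers, omega = 0, all-one-module: Q equals the
        # single-layer value under the summed normalization
        A1 = two_clique_layer()
        A2 = np.tile(A1, (2, 1, 1)).reshape(2, 4, 4)
        p = ModularityParams(omega=0.0)
        ones1 = np.ones((1, 4), dtype=int)
        ones2 = np.ones((2, 4), dtype=int)
        q1 = modularity_q(build_multilayer(A1, p), ones1)
        q2 = modularity_q(build_multilayer(A2, p), ones2)
        assert q2 == pytest.approx(q1)


class TestLouvain:
    def test_recovers_two_cliques_and_matches_exhaustive_search(self):
        params = ModularityParams(omega=0.0, n_runs=5, seed=2)
        mg = build_multilayer(two_clique_layer(), params)
        best = ensemble(mg, params).best
        q_max, _ = exhaustive_max_q(mg.layers, 1.0, 0.0)
        assert best.q == pytest.approx(q_max, abs=1e-9)
        labels = best.labels[0]
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_coupling_aligns_labels_across_identical_layers(self):
        # 3-node path graph repeated in 2 layers; omega = 1 rewards equal
        # labels for each node's copies, confirmed against exhaustive search
        A = np.zeros((2, 3, 3))
        for s in range(2):
            A[s, 0, 1] = A[s, 1, 0] = 1.0
            A[s, 1, 2] = A[s, 2, 1] = 1.0
        params = ModularityParams(omega=1.0, n_runs=10, seed=4)
        mg = build_multilayer(A, params)
        best = ensemble(mg, params).best
        q_max, lab_max = exhaustive_max_q(mg.layers, 1.0, 1.0)
        assert best.q == pytest.approx(q_max, abs=1e-9)
        assert np.all(best.labels[0] == best.labels[1])

    def test_omega_zero_decouples_layers(self):
        # different clique structure per layer; uncoupled optimum finds each
        A = np.zeros((2, 4, 4))
        A[0, 0, 1] = A[0, 1, 0] = A[0, 2, 3] = A[0, 3, 2] = 1.0  # {12|34}
        A[1, 0, 2] = A[1, 2, 0] = A[1, 1, 3] = A[1, 3, 1] = 1.0  # {13|24}
        params = ModularityParams(omega=0.0, n_runs=10, seed=6)
        mg = build_multilayer(A, params)
        best = ensemble(mg, params).best
        l0, l1 = best.labels
        assert l0[0] == l0[1] and l0[2] == l0[3] and l0[0] != l0[2]
        assert l1[0] == l1[2] and l1[1] == l1[3] and l1[0] != l1[1]

    def test_large_omega_forces_constant_labels_across_layers(self):
        rng = np.random.default_rng(8)
        layers = random_multilayer(rng, 5, 4)
        params = ModularityParams(omega=100.0, n_runs=5, seed=3)
        mg = build_multilayer(layers, params)
        best = ensemble(mg, params).best
        assert np.all(best.labels == best.labels[0])

    def test_ensemble_is_deterministic_given_master_seed(self):
        rng = np.random.default_rng(12)
        layers = random_multilayer(rng, 5, 3)
        params = ModularityParams(n_runs=4, seed=99)
        mg = build_multilayer(layers, params)
        e1 = ensemble(mg, params)
        e2 = ensemble(mg, params)
        assert e1.n_runs == 4
        for p1, p2 in zip(e1.partitions, e2.partitions):
            assert np.array_equal(p1.labels, p2.labels)
            assert p1.q == p2.q

    def test_singleton_ensemble(self):
        params = ModularityParams(n_runs=1, omega=0.0, seed=0)
        mg = build_multilayer(two_clique_layer(), params)
        assert ensemble(mg, params).n_runs == 1

    def test_smallest_buildable_graph_is_deterministic_one_module(self):
        # 2 nodes, 1 edge, single layer: both nodes end in one module
        A = np.zeros((1, 2, 2))
        A[0, 0, 1] = A[0, 1, 0] = 1.0
        params = ModularityParams(omega=0.0, n_runs=3, seed=1)
        mg = build_multilayer(A, params)
        best = ensemble(mg, params).best
        assert best.labels[0, 0] == best.labels[0, 1]

    def test_never_exceeds_exhaustive_maximum(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            layers = random_multilayer(rng, 3, 2)
            params = ModularityParams(
                gamma=float(rng.choice([0.8, 1.0, 1.2])),
                omega=float(rng.choice([0.0, 0.5, 1.0])),
                n_runs=5, seed=int(rng.integers(1000)),
            )
            mg = build_multilayer(layers, params)
            q_max, _ = exhaustive_max_q(layers, params.gamma, params.omega)
            assert ensemble(mg, params).best.q <= q_max + 1e-9
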