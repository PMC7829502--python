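import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynbrain.metrics import (
    change_counts,
    change_events,
    compute_metrics,
    connection_stability,
    flexibility,
    network_aggregate,
)
from dynbrain.modularity import ModularityParams, Partition, PartitionEnsemble
from dynbrain.synth import synthetic_atlas


def make_ensemble(*label_arrays):
    parts = tuple(Partition(labels=np.asarray(a), q=0.0) for a in label_arrays)
    return PartitionEnsemble(partitions=parts, params=ModularityParams(n_runs=len(parts)))


class TestConnectionStability:
    def test_single_module_everywhere_gives_all_ones(self):
        ens = make_ensemble(np.ones((4, 3), dtype=int))
        assert np.all(connection_stability(ens) == 1.0)

    def test_never_coassigned_pair_scores_zero(self):
        labels = np.tile([1, 2], (5, 1))
        assert connection_stability(make_ensemble(labels))[0, 1] == 0.0

    def test_half_of_layers_shared_gives_one_half(self):
        # pair co-assigned in 73 of 146 layers in every run
        labels = np.ones((146, 2), dtype=int)
        labels[73:, 1] = 2
        stab = connection_stability(make_ensemble(labels, labels))
        assert stab[0, 1] == pytest.approx(0.5)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(0)
        ens = make_ensemble(rng.integers(1, 4, (6, 5)), rng.integers(1, 4, (6, 5)))
        stab = connection_stability(ens)
        assert np.allclose(stab, stab.T)
        assert np.all(np.diag(stab) == 1.0)


class TestFlexibility:
    def test_constant_label_is_zero(self):
        assert flexibility(make_ensemble(np.ones((10, 3), dtype=int)))[0] == 0.0

    def test_alternating_label_is_one(self):
        labels = np.array([[1], [2], [1], [2]])
        assert flexibility(make_ensemble(labels))[0] == 1.0

    def test_one_change_in_145_transitions(self):
        labels = np.ones((146, 1), dtype=int)
        labels[100:] = 2
        assert flexibility(make_ensemble(labels))[0] == pytest.approx(1 / 145)

    def test_single_layer_is_an_error(self):
        with pytest.raises(ValueError, match="2 layers"):
            flexibility(make_ensemble(np.ones((1, 3), dtype=int)))


class TestChangeClassification:
    def test_shared_source_and_destination_is_cohesive(self):
        labels = np.array([[1, 1, 3], [2, 2, 3]])
        events = {e.node: e.kind for e in change_events(labels)}
        assert events == {0: "cohesive", 1: "cohesive"}

    def test_lone_mover_is_disjoint(self):
        labels = np.array([[1, 1, 1], [1, 1, 3]])
        events = {e.node: e.kind for e in change_events(labels)}
        assert events == {2: "disjoint"}

    def test_same_source_different_destination_is_disjoint(self):
        # nodes 1 (A->B) and 2 (A->C) at one transition: both disjoint
        labels = np.array([[1, 1], [2, 3]])
        events = {e.node: e.kind for e in change_events(labels)}
        assert events == {0: "disjoint", 1: "disjoint"}

    def test_three_node_scenario_disjointness_over_two_transitions(self):
        # nodes 1,2 move A->B together; node 3 moves alone A->C; then static
        labels = np.array([[1, 1, 1], [2, 2, 3], [2, 2, 3]])
        table = compute_metrics(make_ensemble(labels))
        assert table.disjointness.tolist() == [0.0, 0.0, 0.5]
        assert table.cohesion_strength.tolist() == [0.5, 0.5, 0.0]

    def test_static_node_has_zero_disjointness_and_cohesion(self):
        labels = np.array([[1, 2], [1, 3], [1, 2]])
        table = compute_metrics(make_ensemble(labels))
        assert table.disjointness[0] == 0.0
        assert table.cohesion_strength[0] == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_flexibility_identity_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 5, size=(6, 8))
        d, c, _ = change_counts(labels)
        changes = (labels[:-1] != labels[1:]).sum(axis=0)
        # identity: every change is exactly one of disjoint / cohesive
        assert np.array_equal(d + c, changes)
        # consistent relabeling within each layer leaves all metrics unchanged
        perm = rng.permutation(10) + 20
        permuted = perm[labels]
        t1 = compute_metrics(make_ensemble(labels))
        t2 = compute_metrics(make_ensemble(permuted))
        assert t1.disjointness == pytest.approx(t2.disjointness)
        assert t1.cohesion_strength == pytest.approx(t2.cohesion_strength)
        assert t1.flexibility == pytest.approx(t2.flexibility)
        assert t1.connection_stability == pytest.approx(t2.connection_stability)


class TestNetworkAggregate:
    def test_single_network_mean_equals_grand_mean(self):
        atlas = synthetic_atlas(6, 1)
        rng = np.random.default_rng(1)
        table = compute_metrics(make_ensemble(rng.integers(1, 3, (5, 6))))
        nets = network_aggregate(table, atlas)
        assert nets.loc["SM", "disjointness"] == pytest.approx(table.disjointness.mean())
        assert table.global_disjointness == pytest.approx(table.disjointness.mean())

    def test_all_ones_stability_gives_network_mean_one(self):
        atlas = synthetic_atlas(6, 2)
        table = compute_metrics(make_ensemble(np.ones((4, 6), dtype=int)))
        nets = network_aggregate(table, atlas)
        assert np.all(nets["connection_stability"] == 1.0)

    def test_three_node_network_pairwise_mean(self):
        # within-network pair stabilities {1, 0, 0.5} -> mean 0.5
        atlas = synthetic_atlas(3, 1)
        table = compute_metrics(make_ensemble(np.ones((2, 3), dtype=int)))
        table.connection_stability = np.array(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.5], [0.0, 0.5, 1.0]]
        )
        nets = network_aggregate(table, atlas)
        assert nets.loc["SM", "connection_stability"] == pytest.approx(0.5)
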