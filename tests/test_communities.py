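import numpy as np
import pandas as pd
import pytest

from conftest import network_from_edges
from morbnet.communities import (
    CommunityPartition,
    align_partition,
    community_bootstrap,
    modularity_matrix_eigenvalues,
    name_communities,
    walktrap,
)
from morbnet.ising import EstimatorConfig
from morbnet.synthetic import sample_ising_gibbs
from oracles import best_partition_exhaustive, modularity_of


class TestWalktrap:
    def test_two_cliques_recover_exhaustive_modularity_optimum(self, two_clique_network):
        part = walktrap(two_clique_network, t=4)
        groups = {}
        for node, c in part.membership.items():
            groups.setdefault(c, set()).add(node)
        assert set(map(frozenset, groups.values())) == {
            frozenset({"v0", "v1", "v2"}), frozenset({"v3", "v4", "v5"})
        }
        best_q, best_groups = best_partition_exhaustive(np.abs(two_clique_network.weights))
        assert part.modularity == pytest.approx(best_q, abs=1e-9)
        assert part.modularity == pytest.approx(2 * (3 / 7 - 0.25), abs=1e-9)

    def test_empty_graph_gives_singletons(self):
        net = network_from_edges(4, {})
        part = walktrap(net)
        assert part.n_communities == 4
        assert part.modularity == 0.0

    def test_no_community_spans_disconnected_components(self):
        net = network_from_edges(6, {(0, 1): 1.0, (1, 2): 1.0, (3, 4): 1.0, (4, 5): 1.0})
        part = walktrap(net)
        left = {part.membership[f"v{i}"] for i in (0, 1, 2)}
        right = {part.membership[f"v{i}"] for i in (3, 4, 5)}
        assert left.isdisjoint(right)

    def test_isolated_node_is_singleton(self):
        net = network_from_edges(4, {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        part = walktrap(net)
        assert sum(1 for c in part.membership.values()
                   if c == part.membership["v3"]) == 1

    def test_node_permutation_permutes_membership(self, two_clique_network):
        perm = [3, 4, 5, 0, 1, 2]
        W = two_clique_network.weights[np.ix_(perm, perm)]
        net2 = network_from_edges(6, {})
        net2.weights = W
        net2.nodes = [two_clique_network.nodes[i] for i in perm]
        a = walktrap(two_clique_network)
        b = walktrap(net2)
        groups_a = {frozenset(n for n, c in a.membership.items() if c == cc)
                    for cc in set(a.membership.values())}
        groups_b = {frozenset(n for n, c in b.membership.items() if c == cc)
                    for cc in set(b.membership.values())}
        assert groups_a == groups_b

    def test_modularity_range_validated(self):
        with pytest.raises(ValueError):
            CommunityPartition({"a": 0}, 4, 1.5)


class TestAlignment:
    def test_self_alignment_is_identity_with_full_agreement(self):
        ref = np.array([0.0, 0, 1, 1, 2])
        out = align_partition(ref, ref.copy())
        assert np.array_equal(out, ref)

    def test_permuted_labels_align_back(self):
        ref = np.array([0.0, 0, 1, 1, 2, 2])
        cand = np.array([2.0, 2, 0, 0, 1, 1])
        assert np.array_equal(align_partition(ref, cand), ref)

    def test_missing_nodes_stay_missing(self):
        ref = np.array([0.0, 0, 1, 1])
        cand = np.array([1.0, 1, np.nan, 0])
        out = align_partition(ref, cand)
        assert np.isnan(out[2])
        assert out[0] == out[1] == 0.0

    def test_extra_communities_get_fresh_labels(self):
        ref = np.array([0.0, 0, 0, 0])
        cand = np.array([0.0, 0, 1, 2])
        out = align_partition(ref, cand)
        assert len(set(out)) == 3
        assert out[0] == 0.0


def two_block_frame(n=1500, seed=0, w=1.5):
    W = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        W[i, j] = W[j, i] = w
    for i, j in [(3, 4), (3, 5), (4, 5)]:
        W[i, j] = W[j, i] = w
    X = sample_ising_gibbs(W, np.full(6, -1.0), n, seed=seed)
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])


class TestCommunityBootstrap:
    def test_strong_two_block_structure_is_stable(self):
        df = two_block_frame(seed=13)
        stab = community_bootstrap(
            df, EstimatorConfig(n_lambda=30), n_boot=30, seed=14,
            nodes=tuple(df.columns),
        )
        assert np.nanmean(stab.agreement) >= 0.9
        assert stab.is_stable()
        assert stab.memberships.shape == (30, 6)

    def test_noise_is_flagged_unstable(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            (rng.random((1500, 6)) < 0.3).astype(float),
            columns=[f"v{i}" for i in range(6)],
        )
        stab = community_bootstrap(
            df, EstimatorConfig(n_lambda=30), n_boot=30, seed=16,
            nodes=tuple(df.columns),
        )
        assert not stab.is_stable()

    def test_zero_bootstraps_rejected(self):
        df = two_block_frame(seed=17)
        with pytest.raises(ValueError, match="n_boot"):
            community_bootstrap(df, n_boot=0, nodes=tuple(df.columns))

    def test_eigen_summary_shape_and_order(self):
        df = two_block_frame(seed=18)
        stab = community_bootstrap(
            df, EstimatorConfig(n_lambda=30), n_boot=5, seed=19,
            nodes=tuple(df.columns),
        )
        assert stab.eigen_summary.shape == (5, 6)
        diffs = np.diff(stab.eigen_summary, axis=1)
        assert (diffs <= 1e-9).all()  # spectra sorted descending


class TestNaming:
    def test_auto_names_concatenate_members(self):
        part = CommunityPartition({"parkinsons": 0, "alzheimers": 0, "copd": 1}, 4, 0.0)
        names = name_communities(part)
        assert names[0] == "parkinsons–alzheimers"
        assert names[1] == "copd"

    def test_five_communities_emit_five_labels(self, two_clique_network):
        part = walktrap(two_clique_network)
        extra = CommunityPartition(
            {f"n{i}": i for i in range(5)}, 4, 0.0
        )
        assert len(name_communities(extra)) == 5

    def test_label_permutation_gives_identical_names(self):
        a = CommunityPartition({"x": 0, "y": 0, "z": 1}, 4, 0.0)
        b = CommunityPartition({"x": 5, "y": 5, "z": 2}, 4, 0.0)
        assert set(name_communities(a).values()) == set(name_communities(b).values())

    def test_user_names_must_cover_communities(self):
        part = CommunityPartition({"x": 0, "z": 1}, 4, 0.0)
        with pytest.raises(KeyError):
            name_communities(part, naming={0: "first"})


def test_modularity_matrix_eigenvalues_sum_to_trace(two_clique_network):
    ev = modularity_matrix_eigenvalues(two_clique_network)
    A = np.abs(two_clique_network.weights)
    B = A - np.outer(A.sum(1), A.sum(1)) / A.sum()
    assert ev.sum() == pytest.approx(np.trace(B), abs=1e-9)


def test_exhaustive_partition_oracle_on_random_small_graphs():
    """The merge-tree cut is near-optimal on small random weighted graphs."""
    rng = np.random.default_rng(20)
    for _ in range(5):
        p = 6
        W = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < 0.5:
                    W[i, j] = W[j, i] = rng.uniform(0.3, 1.5)
        net = network_from_edges(p, {})
        net.weights = W
        part = walktrap(net)
        best_q, _ = best_partition_exhaustive(np.abs(W))
        labels = part.labels_for(net.nodes)
        groups = [list(np.flatnonzero(labels == c)) for c in set(labels)]
        assert modularity_of(np.abs(W), groups) == pytest.approx(part.modularity, abs=1e-9)
        assert part.modularity <= best_q + 1e-9
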