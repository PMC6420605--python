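from itertools import product

import networkx as nx
import numpy as np
import pytest

from coopnet import (
    consensus_partition,
    filter_small_modules,
    label_modules,
    louvain_partition,
    signed_modularity,
)
from coopnet.community import Partition, _relabel, consensus_edge_frame


def two_cliques(k=3, weight=1.0):
    """Two disconnected positive k-cliques."""
    n = 2 * k
    w = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for a in block:
            for b in block:
                if a != b:
                    w[a, b] = weight
    return w


def all_partitions(n):
    """Every set partition of n items as label arrays (Bell-number many)."""
    if n == 1:
        yield np.array([0])
        return
    for rest in all_partitions(n - 1):
        k = rest.max() + 1
        for target in range(k + 1):
            yield np.append(rest, target)


def small_llr_networks(rng, count, min_nodes=4, max_nodes=6):
    """Tiny signed LLR networks built from random respondent draws.

    These are the weight matrices the optimizer actually faces: complete
    signed graphs whose weights derive from co-mention counts.
    """
    from coopnet import build_coop_network, build_vocabulary
    from coopnet.io import EMOTION_LABELS, ResponseRecord

    out = []
    while len(out) < count:
        vocab_size = int(rng.integers(min_nodes, max_nodes + 1))
        vocab = [f"v{k}" for k in range(vocab_size)]
        recs = []
        for r in range(20):
            assoc = tuple(
                rng.choice(vocab, size=min(5, vocab_size), replace=False)
            )
            assoc = assoc + ("",) * (5 - len(assoc))
            labels = tuple(
                tuple(rng.choice(EMOTION_LABELS, 2, replace=False)) if a else ()
                for a in assoc
            )
            recs.append(ResponseRecord(f"r{r}", assoc, labels))
        v = build_vocabulary(recs, 1)
        if not (min_nodes <= len(v.retained) <= max_nodes):
            continue
        net = build_coop_network(recs, v)
        if np.abs(net.weights).sum() == 0:
            continue
        out.append(net.weights)
    return out


def newman_girvan_oracle(w, labels):
    """Brute-force weighted modularity for all-positive networks."""
    v = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += w[i, j] - s[i] * s[j] / v
    return q / v


class TestSignedModularity:
    def test_single_module_partition_is_zero(self, rng):
        w = rng.normal(size=(12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        assert signed_modularity(w, [0] * 12) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_cliques_split_gives_half(self):
        w = two_cliques(4)
        q = signed_modularity(w, [0] * 4 + [1] * 4)
        assert q == pytest.approx(0.5)

    def test_all_positive_matches_newman_girvan_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            w = rng.uniform(0, 1, size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            labels = rng.integers(0, 3, size=n)
            assert signed_modularity(w, labels) == pytest.approx(
                newman_girvan_oracle(w, labels), rel=1e-10
            )

    def test_relabel_and_reorder_invariance(self, rng):
        w = rng.normal(size=(10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = rng.integers(0, 3, size=10)
        q = signed_modularity(w, labels)
        assert signed_modularity(w, labels + 7) == pytest.approx(q)
        perm = rng.permutation(10)
        assert signed_modularity(
            w[np.ix_(perm, perm)], labels[perm]
        ) == pytest.approx(q)

    def test_negative_between_blocks_rewards_split(self):
        w = two_cliques(3)
        w[:3, 3:] = -1.0
        w[3:, :3] = -1.0
        np.fill_diagonal(w, 0)
        split = signed_modularity(w, [0, 0, 0, 1, 1, 1])
        merged = signed_modularity(w, [0] * 6)
        assert split > merged

    def test_asymmetric_input_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            signed_modularity(w, [0, 0, 0])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            signed_modularity(np.zeros((4, 4)), [0, 0, 1, 1])


class TestLouvain:
    def test_two_cliques_recovered_for_every_seed(self):
        w = two_cliques(4)
        for seed in range(20):
            part = louvain_partition(w, seed=seed)
            assert part.n_modules == 2
            assert len(set(part.labels[:4])) == 1
            assert len(set(part.labels[4:])) == 1
            assert part.modularity == pytest.approx(0.5)

    def test_attains_enumerated_optimum_on_llr_networks(self, rng):
        """Louvain Q equals the maximum over every partition (4-6 nodes)."""
        for w in small_llr_networks(rng, 12):
            n = w.shape[0]
            best = max(
                signed_modularity(w, labels) for labels in all_partitions(n)
            )
            part = louvain_partition(w, seed=0)
            assert part.modularity == pytest.approx(best, abs=1e-10)

    def test_never_exceeds_enumerated_optimum(self, rng):
        """On arbitrary signed matrices Louvain's Q is a valid lower bound."""
        for trial in range(8):
            n = int(rng.integers(4, 7))
            w = rng.uniform(-1, 1, size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            best = max(
                signed_modularity(w, labels) for labels in all_partitions(n)
            )
            part = louvain_partition(w, seed=trial)
            assert part.modularity <= best + 1e-10

    def test_single_positive_edge_merges_nodes(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 1.0
        part = louvain_partition(w, seed=0)
        assert part.n_modules == 1

    def test_reported_q_self_consistent(self, planted_network):
        _, _, net = planted_network
        part = louvain_partition(net.weights, seed=3)
        assert part.modularity == pytest.approx(
            signed_modularity(net.weights, part.labels)
        )

    def test_all_positive_agrees_with_networkx_louvain(self, rng):
        """Independent optimizer reaches the same Q on easy positive graphs."""
        w = two_cliques(5, weight=2.0)
        g = nx.from_numpy_array(w)
        communities = nx.community.louvain_communities(g, weight="weight", seed=9)
        labels = np.empty(10, dtype=int)
        for m, nodes in enumerate(communities):
            for v in nodes:
                labels[v] = m
        ours = louvain_partition(w, seed=9)
        assert signed_modularity(w, labels) == pytest.approx(ours.modularity)


class TestConsensus:
    def test_planted_blocks_recovered_unanimously(self, planted_network):
        _, _, net = planted_network
        res = consensus_partition(net.weights, n_runs=100, n_check=25, seed=5)
        assert res.partition.n_modules == 3
        assert res.rounds >= 1
        # groups are identified by the lemma prefixes of the generator
        blocks = {}
        for lemma, m in zip(net.nodes, res.partition.labels):
            blocks.setdefault(lemma[:2], set()).add(m)
        assert all(len(mods) == 1 for mods in blocks.values())

    def test_consensus_matrix_is_frequency_matrix(self, planted_network):
        _, _, net = planted_network
        res = consensus_partition(net.weights, n_runs=40, n_check=15, seed=6)
        c = res.consensus_matrix
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0.0 and c.max() <= 1.0

    def test_unambiguous_network_equals_single_run(self):
        w = two_cliques(4)
        res = consensus_partition(w, n_runs=30, n_check=10, seed=0)
        single = louvain_partition(w, seed=0)
        assert np.array_equal(
            _relabel(res.partition.labels), _relabel(single.labels)
        )
        assert res.mean_modularity == pytest.approx(0.5)

    def test_consensus_idempotent(self, planted_network):
        _, _, net = planted_network
        first = consensus_partition(net.weights, n_runs=60, n_check=20, seed=7)
        again = consensus_partition(net.weights, n_runs=60, n_check=20, seed=8)
        assert np.array_equal(
            _relabel(first.partition.labels), _relabel(again.partition.labels)
        )


class TestModuleLabels:
    def test_two_most_frequent_lemmas(self):
        part = Partition(labels=np.array([0, 0, 0, 1]), modularity=0.1)
        nodes = ["war", "refugee", "help", "unity"]
        freqs = {"war": 120, "refugee": 97, "help": 40, "unity": 3}
        labels = label_modules(part, nodes, freqs)
        assert labels[0] == "War & Refugee"
        assert labels[1] == "Unity"

    def test_tie_breaks_lexicographically(self):
        part = Partition(labels=np.array([0, 0, 0]), modularity=0.0)
        labels = label_modules(part, ["war", "border", "alpha"], [5, 3, 3])
        assert labels[0] == "War & Alpha"

    def test_small_module_filter(self):
        part = Partition(labels=np.array([0, 0, 1, 2, 3]), modularity=0.1)
        _, excluded = filter_small_modules(part)
        assert sorted(excluded) == [1, 2, 3]
        _, none_excluded = filter_small_modules(part, min_distinct=1)
        assert none_excluded == []


def test_consensus_edge_frame_thresholds():
    c = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.45], [0.1, 0.45, 1.0]])
    frame = consensus_edge_frame(c, ["a", "b", "c"], threshold=0.4)
    pairs = set(zip(frame.node_i, frame.node_j))
    assert pairs == {("a", "b"), ("b", "c")}
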