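"""Opinion-module detection on signed LLR networks.

Modularity is generalized to signed weights by giving the positive
(attractive) and negative (repulsive) layers separate configuration-model
expectations:

    Q = 1/(v+ + v-) * sum_ij [ (w+_ij - s+_i s+_j / v+)
                               - (w-_ij - s-_i s-_j / v-) ] * delta(M_i, M_j)

where w+/w- are the positive/negative parts of the weight matrix, s+/s- the
corresponding node strengths (row sums) and v+/v- the total layer weights
(sums over ordered pairs). A good partition packs positive weight inside
modules and pushes negative weight between them.

Q is optimized by a signed-weight Louvain: repeated greedy local moves
followed by aggregation of modules into supernodes, with the node visit
order shuffled per run. Because single runs can land in different local
optima, a consensus partition is derived from many independent runs via
their co-classification matrix, re-partitioned until a set of repartitions
agrees unanimously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AssociationVocabulary

__all__ = [
    "Partition",
    "ConsensusResult",
    "signed_modularity",
    "louvain_partition",
    "consensus_partition",
    "label_modules",
    "filter_small_modules",
    "consensus_edge_frame",
]


@dataclass(frozen=True)
class Partition:
    """Node -> module assignment (contiguous integer ids) with its Q."""

    labels: np.ndarray  # int array, one module id per node
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def members(self, module: int) -> np.ndarray:
        return np.where(self.labels == module)[0]

    def to_frame(
        self, nodes: Sequence[str], frequencies: Sequence[int] | None = None
    ) -> pd.DataFrame:
        df = pd.DataFrame({"lemma": list(nodes), "module_id": self.labels})
        if frequencies is not None:
            df["frequency"] = list(frequencies)
        return df


def _split_layers(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(weights, dtype=float)
    return np.clip(w, 0.0, None), np.clip(-w, 0.0, None)


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    return w


def signed_modularity(
    weights: np.ndarray, labels: Sequence[int] | np.ndarray
) -> float:
    """Signed modularity Q of a partition on a symmetric weight matrix.

    The diagonal must be zero at the original-network level (no self-edges).
    Returns 0 for the all-in-one partition by construction.
    """
    w = _validate_weights(weights)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (w.shape[0],):
        raise ValueError("one module label required per node")
    wp, wn = _split_layers(w)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        raise ValueError("degenerate input: all edge weights are zero")
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = (wp[same].sum() - wn[same].sum())
    if vp > 0:
        q -= (sp[:, None] * sp[None, :] / vp)[same].sum()
    if vn > 0:
        q += (sn[:, None] * sn[None, :] / vn)[same].sum()
    return float(q / (vp + vn))


def _local_moves(
    wp: np.ndarray,
    wn: np.ndarray,
    sp: np.ndarray,
    sn: np.ndarray,
    vp: float,
    vn: float,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> bool:
    """Greedy move phase; mutates ``labels``. Returns True if anything moved."""
    n = len(labels)
    n_comm = labels.max() + 1
    # community aggregate strengths
    comm_sp = np.bincount(labels, weights=sp, minlength=n_comm)
    comm_sn = np.bincount(labels, weights=sn, minlength=n_comm)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            ci = labels[i]
            # strength of i toward each community (self-loop excluded)
            kp = np.bincount(labels, weights=wp[i], minlength=n_comm)
            kn = np.bincount(labels, weights=wn[i], minlength=n_comm)
            kp[ci] -= wp[i, i]
            kn[ci] -= wn[i, i]
            comm_sp[ci] -= sp[i]
            comm_sn[ci] -= sn[i]
            gain = kp - kn
            if vp > 0:
                gain = gain - sp[i] * comm_sp / vp
            if vn > 0:
                gain = gain + sn[i] * comm_sn / vn
            best = int(np.argmax(gain))
            if gain[best] <= gain[ci] + 1e-12:
                best = ci
            comm_sp[best] += sp[i]
            comm_sn[best] += sn[i]
            if best != ci:
                labels[i] = best
                moved = improved = True
    return improved


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map module ids to contiguous 0..k-1 in order of first appearance."""
    _, inv = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty_like(labels)
    nxt = 0
    for pos, lab in enumerate(labels):
        if lab not in order:
            order[lab] = nxt
            nxt += 1
        out[pos] = order[lab]
    return out


def louvain_partition(
    weights: np.ndarray, seed: int | None = None
) -> Partition:
    """One Louvain run maximizing signed modularity.

    Two phases repeat until Q stops improving: greedy local moves in a
    shuffled node order (derived from ``seed``), then aggregation of modules
    into supernodes whose self-loops carry the internal weight.
    """
    w = _validate_weights(weights)
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    membership = np.arange(n)  # original node -> current module
    # the positive and negative layers are carried separately: between two
    # supernodes both layers can hold weight at once, and collapsing them
    # to a net value would corrupt the per-layer configuration models
    wp, wn = _split_layers(w)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        raise ValueError("degenerate input: all edge weights are zero")
    while True:
        sp, sn = wp.sum(axis=1), wn.sum(axis=1)
        labels = np.arange(wp.shape[0])
        improved = _local_moves(wp, wn, sp, sn, vp, vn, labels, rng)
        labels = _relabel(labels)
        membership = labels[membership]
        if not improved:
            break
        # aggregate each layer: supernode self-loops carry internal weight
        k = labels.max() + 1
        agg = np.zeros((k, wp.shape[0]))
        agg[labels, np.arange(wp.shape[0])] = 1.0
        wp = agg @ wp @ agg.T
        wn = agg @ wn @ agg.T
        if k == len(labels):
            break
    membership = _relabel(membership)
    return Partition(
        labels=membership, modularity=signed_modularity(w, membership)
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of consensus partitioning over many Louvain runs."""

    partition: Partition
    consensus_matrix: np.ndarray  # co-classification frequencies of the runs
    mean_modularity: float  # mean Q over the initial runs
    n_runs: int
    rounds: int  # re-partitioning rounds until unanimous agreement


def _coclassification(all_labels: np.ndarray) -> np.ndarray:
    """Fraction of runs in which each node pair shares a module.

    ``all_labels`` has shape (n_runs, n_nodes).
    """
    n_runs, n = all_labels.shape
    counts = np.zeros((n, n))
    for row in all_labels:
        same = row[:, None] == row[None, :]
        counts += same
    return counts / n_runs


def consensus_partition(
    weights: np.ndarray,
    n_runs: int = 5000,
    n_check: int = 100,
    seed: int | None = None,
    max_rounds: int = 50,
) -> ConsensusResult:
    """Consensus module structure from repeated Louvain runs.

    ``n_runs`` independent Louvain runs on the signed network yield a
    co-classification (consensus) matrix; that non-negative matrix is then
    re-partitioned ``n_check`` times per round, replacing it with the new
    co-classification matrix until all ``n_check`` partitions agree.
    Per-run seeds are spawned deterministically from ``seed``.
    """
    w = _validate_weights(weights)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs = np.empty((n_runs, w.shape[0]), dtype=int)
    qs = np.empty(n_runs)
    for r in range(n_runs):
        part = louvain_partition(w, seed=int(seeds[r]))
        runs[r] = part.labels
        qs[r] = part.modularity
    consensus = _coclassification(runs)
    initial_consensus = consensus.copy()

    for round_no in range(1, max_rounds + 1):
        mat = consensus.copy()
        np.fill_diagonal(mat, 0.0)  # no self-edges in the partitioned graph
        check_seeds = rng.integers(0, 2**31 - 1, size=n_check)
        check = np.empty((n_check, w.shape[0]), dtype=int)
        for r in range(n_check):
            check[r] = louvain_partition(mat, seed=int(check_seeds[r])).labels
        canonical = np.array([_relabel(row) for row in check])
        if (canonical == canonical[0]).all():
            final = Partition(
                labels=canonical[0],
                modularity=signed_modularity(w, canonical[0]),
            )
            return ConsensusResult(
                partition=final,
                consensus_matrix=initial_consensus,
                mean_modularity=float(qs.mean()),
                n_runs=n_runs,
                rounds=round_no,
            )
        consensus = _coclassification(check)
    raise RuntimeError(
        f"consensus did not converge within {max_rounds} rounds "
        f"(last round had {len(np.unique(canonical, axis=0))} distinct "
        "partitions)"
    )


def label_modules(
    partition: Partition,
    nodes: Sequence[str],
    frequencies: Mapping[str, int] | Sequence[int],
) -> dict[int, str]:
    """Name each module after its two most frequent lemmas ("War & Refugee").

    Single-lemma modules are named by that lemma. Frequency ties break
    lexicographically so labels are deterministic.
    """
    if isinstance(frequencies, Mapping):
        freq = [frequencies[v] for v in nodes]
    else:
        freq = list(frequencies)
    labels_out: dict[int, str] = {}
    for module in np.unique(partition.labels):
        members = partition.members(int(module))
        ranked = sorted(members, key=lambda k: (-freq[k], nodes[k]))
        top = [nodes[k].capitalize() for k in ranked[:2]]
        labels_out[int(module)] = " & ".join(top)
    return labels_out


def filter_small_modules(
    partition: Partition, min_distinct: int = 2
) -> tuple[Partition, list[int]]:
    """Flag modules with fewer than ``min_distinct`` lemmas for exclusion.

    Returns the unchanged partition plus the list of excluded module ids;
    downstream attitude analyses skip the excluded modules, but network
    membership is untouched.
    """
    excluded = [
        int(m)
        for m in np.unique(partition.labels)
        if (partition.labels == m).sum() < min_distinct
    ]
    return partition, excluded


def consensus_edge_frame(
    consensus_matrix: np.ndarray,
    nodes: Sequence[str],
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Visualization edge list: pairs co-classified at least ``threshold``.

    Mirrors the convention of drawing an edge when two associations fall in
    a common module in at least 40% of the consensus runs.
    """
    c = np.asarray(consensus_matrix)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = c[iu, ju] >= threshold
    return pd.DataFrame(
        {
            "node_i": [nodes[i] for i in iu[keep]],
            "node_j": [nodes[j] for j in ju[keep]],
            "coclassification": c[iu[keep], ju[keep]],
        }
    )
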