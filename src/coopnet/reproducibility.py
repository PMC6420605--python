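"""Cross-sample comparison machinery for CoOp networks.

Two independently collected samples yield two networks over partially
overlapping vocabularies. Comparisons always restrict both networks to the
shared node set first, then operate at two levels:

* edge level — Spearman correlation of the LLR values over shared node
  pairs, with significance from the quadratic assignment procedure (QAP):
  jointly permuting rows and columns of one matrix preserves the
  within-node dependence of edges that would fool an ordinary correlation
  test;
* module level — normalized mutual information (nMI) between the two
  consensus partitions, referenced against edge-, weight- and
  strength-preserving random networks (connection switching per sign layer
  followed by strength-targeted weight reassignment).

The threshold sweep repeats both comparisons while the minimum-occurrence
filter rises, tracing how discarding rare peripheral associations
stabilizes the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .community import Partition, consensus_partition, louvain_partition
from .io import ResponseRecord, build_vocabulary
from .llr import CoOpNetwork, build_coop_network

__all__ = [
    "QAPResult",
    "NullModelReport",
    "StabilityCurve",
    "qap_correlation",
    "nmi",
    "generate_null_model",
    "modular_similarity_test",
    "threshold_sweep",
    "shared_nodes",
]


def shared_nodes(net1: CoOpNetwork, net2: CoOpNetwork) -> list[str]:
    """Node intersection in net1's order (the comparison vocabulary)."""
    in2 = set(net2.nodes)
    return [v for v in net1.nodes if v in in2]


# ---------------------------------------------------------------------------
# QAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QAPResult:
    coefficient: float
    n_pairs: int
    n_permutations: int
    p_qap: float  # include-observed convention: p >= 1/(n_perm+1)
    null_abs_mean: float
    null_abs_q95: float


def qap_correlation(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
) -> QAPResult:
    """Spearman matrix correlation with QAP permutation significance.

    ``A`` and ``B`` must already be restricted to the shared node set in
    the same order. The null distribution comes from jointly permuting the
    rows and columns of ``A`` and re-correlating; the p-value is the
    include-observed fraction of permutations with |rho| >= |observed|.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and share node ordering")
    m = A.shape[0]
    if m < 3:
        raise ValueError(f"shared node set too small for QAP ({m} < 3)")
    iu, ju = np.triu_indices(m, k=1)
    b_vals = B[iu, ju]
    obs = float(spearmanr(A[iu, ju], b_vals).statistic)
    rng = np.random.default_rng(seed)
    null_abs = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(m)
        Ap = A[np.ix_(perm, perm)]
        null_abs[k] = abs(spearmanr(Ap[iu, ju], b_vals).statistic)
    p = (int((null_abs >= abs(obs)).sum()) + 1) / (n_perm + 1)
    return QAPResult(
        coefficient=obs,
        n_pairs=len(iu),
        n_permutations=n_perm,
        p_qap=p,
        null_abs_mean=float(null_abs.mean()),
        null_abs_q95=float(np.quantile(null_abs, 0.95)),
    )


# ---------------------------------------------------------------------------
# nMI
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(
    p1: Partition | Sequence[int] | np.ndarray,
    p2: Partition | Sequence[int] | np.ndarray,
) -> float:
    """Normalized mutual information of two partitions of the same nodes.

    nMI = 2 * (H(M1) + H(M2) - H(M1, M2)) / (H(M1) + H(M2)), relabeling-
    invariant and symmetric, in [0, 1]. When both partitions are trivial
    (single module) the limit 1 is returned; when exactly one is trivial, 0.
    """
    l1 = np.asarray(p1.labels if isinstance(p1, Partition) else p1, dtype=int)
    l2 = np.asarray(p2.labels if isinstance(p2, Partition) else p2, dtype=int)
    if l1.shape != l2.shape or l1.size == 0:
        raise ValueError("partitions must cover the same non-empty node set")
    _, i1 = np.unique(l1, return_inverse=True)
    _, i2 = np.unique(l2, return_inverse=True)
    contingency = np.zeros((i1.max() + 1, i2.max() + 1))
    np.add.at(contingency, (i1, i2), 1.0)
    h1 = _entropy(contingency.sum(axis=1))
    h2 = _entropy(contingency.sum(axis=0))
    h12 = _entropy(contingency.ravel())
    if h1 + h2 == 0.0:
        return 1.0  # both trivial: identical partitions
    return float(2.0 * (h1 + h2 - h12) / (h1 + h2))


def average_pairwise_nmi(
    weights1: np.ndarray,
    weights2: np.ndarray,
    n_runs_each: int = 100,
    n_pairs: int = 5000,
    seed: int | None = None,
) -> float:
    """Mean nMI over sampled cross pairs of independent Louvain runs.

    The module agreement of two samples can be summarized as the average
    nMI over pairs of stochastic partitions, one from each network.
    Enumerating all pairs of a large run ensemble is infeasible, so a
    seeded random sample of ``n_pairs`` cross pairs estimates the average
    without bias.
    """
    rng = np.random.default_rng(seed)
    runs1 = [
        louvain_partition(weights1, seed=int(s)).labels
        for s in rng.integers(0, 2**31 - 1, size=n_runs_each)
    ]
    runs2 = [
        louvain_partition(weights2, seed=int(s)).labels
        for s in rng.integers(0, 2**31 - 1, size=n_runs_each)
    ]
    pick1 = rng.integers(0, n_runs_each, size=n_pairs)
    pick2 = rng.integers(0, n_runs_each, size=n_pairs)
    return float(
        np.mean([nmi(runs1[a], runs2[b]) for a, b in zip(pick1, pick2)])
    )


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------


def _signed_connection_switch(
    w: np.ndarray, rng: np.random.Generator, n_swaps_factor: float
) -> np.ndarray:
    """Sign-structure-preserving connection switching on a signed matrix.

    Repeatedly draws four distinct nodes (a, b, c, d); whenever the pair
    weights satisfy sign(w_ab) = sign(w_cd) and sign(w_ad) = sign(w_cb)
    with the two signs differing, the weights are exchanged across the
    quadrilateral: w_ab <-> w_ad and w_cd <-> w_cb. Each accepted switch
    leaves every node's positive degree, negative degree, and both layers'
    weight multisets exactly unchanged while randomizing which pairs carry
    which sign - the appropriate rewiring for dense signed networks where
    ordinary double-edge swaps have no empty slots to move into.
    """
    out = w.copy()
    n = out.shape[0]
    n_edges = int((np.triu(out, 1) != 0).sum())
    attempts = max(1, int(n_swaps_factor * n_edges))
    quads = rng.integers(0, n, size=(attempts, 4))
    for a, b, c, d in quads:
        if len({a, b, c, d}) < 4:
            continue
        s_ab, s_cd = np.sign(out[a, b]), np.sign(out[c, d])
        s_ad, s_cb = np.sign(out[a, d]), np.sign(out[c, b])
        if s_ab == s_cd and s_ad == s_cb and s_ab != s_ad:
            out[a, b], out[a, d] = out[a, d], out[a, b]
            out[b, a], out[d, a] = out[a, b], out[a, d]
            out[c, d], out[c, b] = out[c, b], out[c, d]
            out[d, c], out[b, c] = out[c, d], out[c, b]
    return out


def _assign_weights(
    adj: np.ndarray,
    weights: np.ndarray,
    strengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Strength-targeted weight reassignment on a rewired layer.

    The original weight multiset is handed out edge by edge: at each step a
    random unassigned edge is ranked by the product of its endpoints'
    residual strengths, and receives the weight of the same rank among the
    remaining weights; the endpoints' residuals then shrink by that weight.
    This steers node strengths toward the originals while preserving the
    weight multiset exactly.
    """
    iu, ju = np.where(np.triu(adj, k=1) > 0)
    ws = np.sort(np.asarray(weights, dtype=float))[::-1]  # descending
    w_alive = np.ones(len(ws), dtype=bool)
    e_alive = np.ones(len(iu), dtype=bool)
    resid = strengths.astype(float).copy()
    out = np.zeros_like(adj, dtype=float)
    for _ in range(len(iu)):
        alive_idx = np.flatnonzero(e_alive)
        expect = resid[iu[alive_idx]] * resid[ju[alive_idx]]
        pick = int(rng.integers(len(alive_idx)))
        # rank of the picked edge among remaining (0 = largest expectation)
        rank = int((expect > expect[pick]).sum())
        w_idx = np.flatnonzero(w_alive)[rank]
        w = ws[w_idx]
        w_alive[w_idx] = False
        i, j = int(iu[alive_idx[pick]]), int(ju[alive_idx[pick]])
        e_alive[alive_idx[pick]] = False
        out[i, j] = out[j, i] = w
        resid[i] -= w
        resid[j] -= w
    return out


def generate_null_model(
    coop: CoOpNetwork, seed: int | None = None, n_swaps_factor: float = 10.0
) -> CoOpNetwork:
    """Edge-, weight- and strength-preserving randomization of a signed network.

    The sign structure is first randomized by connection switching (weight
    exchanges across node quadrilaterals with complementary sign patterns),
    which preserves every node's positive and negative degree; each layer's
    weight multiset is then reallocated over its rewired structure with the
    strength-targeted procedure, so node strengths approximate the
    originals. Signed degree sequences and per-layer weight multisets are
    preserved exactly. Layers with fewer than 4 edges cannot be switched
    and are effectively copied.
    """
    rng = np.random.default_rng(seed)
    w = coop.weights
    switched = _signed_connection_switch(w, rng, n_swaps_factor)
    out = np.zeros_like(w)
    for sign, orig_layer, new_layer in (
        (1.0, np.clip(w, 0, None), np.clip(switched, 0, None)),
        (-1.0, np.clip(-w, 0, None), np.clip(-switched, 0, None)),
    ):
        iu, ju = np.where(np.triu(orig_layer, k=1) > 0)
        if len(iu) == 0:
            continue
        adj = (new_layer > 0).astype(float)
        new_w = _assign_weights(
            adj, orig_layer[iu, ju], orig_layer.sum(axis=1), rng
        )
        out += sign * new_w
    return CoOpNetwork(
        nodes=coop.nodes,
        weights=out,
        n=coop.n,
        node_frequencies=coop.node_frequencies.copy(),
        min_occurrence=coop.min_occurrence,
    )


# ---------------------------------------------------------------------------
# Modular similarity vs null models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullModelReport:
    observed_nmi: float
    null_nmi: np.ndarray
    p_value: float  # include-observed fraction of null >= observed
    n_null: int


def modular_similarity_test(
    net1: CoOpNetwork,
    net2: CoOpNetwork,
    n_null: int = 5000,
    n_runs: int = 200,
    n_check: int = 20,
    seed: int | None = None,
    null_consensus: bool = False,
) -> NullModelReport:
    """Is the cross-sample module agreement higher than chance?

    The observed nMI compares the two consensus partitions on the shared
    node set. Each null draw pairs a randomized version of each network,
    partitions both (single seeded Louvain by default; full consensus when
    ``null_consensus``), and records their nMI. The networks are declared
    significantly similar when the observed nMI exceeds 95% of the null.
    """
    common = shared_nodes(net1, net2)
    if len(common) < 3:
        raise ValueError(f"shared node set too small ({len(common)} < 3)")
    rng = np.random.default_rng(seed)
    sub1, sub2 = net1.subnetwork(common), net2.subnetwork(common)

    def _partition(weights: np.ndarray) -> Partition:
        if null_consensus:
            return consensus_partition(
                weights,
                n_runs=n_runs,
                n_check=n_check,
                seed=int(rng.integers(0, 2**31 - 1)),
            ).partition
        return louvain_partition(weights, seed=int(rng.integers(0, 2**31 - 1)))

    part1 = consensus_partition(
        sub1.weights, n_runs=n_runs, n_check=n_check,
        seed=int(rng.integers(0, 2**31 - 1)),
    ).partition
    part2 = consensus_partition(
        sub2.weights, n_runs=n_runs, n_check=n_check,
        seed=int(rng.integers(0, 2**31 - 1)),
    ).partition
    observed = nmi(part1, part2)

    null_vals = np.empty(n_null)
    for k in range(n_null):
        null1 = generate_null_model(sub1, seed=int(rng.integers(0, 2**31 - 1)))
        null2 = generate_null_model(sub2, seed=int(rng.integers(0, 2**31 - 1)))
        null_vals[k] = nmi(_partition(null1.weights), _partition(null2.weights))
    p = (int((null_vals >= observed).sum()) + 1) / (n_null + 1)
    return NullModelReport(
        observed_nmi=observed, null_nmi=null_vals, p_value=p, n_null=n_null
    )


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityCurve:
    thresholds: tuple[int, ...]
    edge_spearman: tuple[float, ...]  # NaN where a point could not be computed
    modular_nmi: tuple[float, ...]
    n_shared_nodes: tuple[int, ...]
    edge_trend: float = field(default=float("nan"))  # Spearman of curve vs threshold
    modular_trend: float = field(default=float("nan"))


def threshold_sweep(
    records1: Sequence[ResponseRecord],
    records2: Sequence[ResponseRecord],
    thresholds: Sequence[int] = tuple(range(3, 14)),
    n_runs: int = 200,
    n_check: int = 20,
    seed: int | None = None,
) -> StabilityCurve:
    """Edge- and module-level cross-sample similarity as the filter rises.

    For each minimum-occurrence threshold both networks are rebuilt, the
    shared-node edge Spearman and the consensus-partition nMI recorded.
    Thresholds leaving fewer than 3 shared nodes are flagged as missing
    (NaN). The trend statistics are the Spearman correlations of each curve
    against the threshold values.
    """
    rng = np.random.default_rng(seed)
    edge_r: list[float] = []
    mod_nmi: list[float] = []
    n_shared: list[int] = []
    for thr in thresholds:
        try:
            net1 = build_coop_network(records1, build_vocabulary(records1, thr))
            net2 = build_coop_network(records2, build_vocabulary(records2, thr))
        except ValueError:
            edge_r.append(float("nan"))
            mod_nmi.append(float("nan"))
            n_shared.append(0)
            continue
        common = shared_nodes(net1, net2)
        n_shared.append(len(common))
        if len(common) < 3:
            edge_r.append(float("nan"))
            mod_nmi.append(float("nan"))
            continue
        sub1, sub2 = net1.subnetwork(common), net2.subnetwork(common)
        iu, ju = np.triu_indices(len(common), k=1)
        edge_r.append(
            float(spearmanr(sub1.weights[iu, ju], sub2.weights[iu, ju]).statistic)
        )
        p1 = consensus_partition(
            sub1.weights, n_runs=n_runs, n_check=n_check,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).partition
        p2 = consensus_partition(
            sub2.weights, n_runs=n_runs, n_check=n_check,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).partition
        mod_nmi.append(nmi(p1, p2))

    def _trend(curve: list[float]) -> float:
        vals = np.array(curve)
        ok = ~np.isnan(vals)
        if ok.sum() < 3 or np.allclose(vals[ok], vals[ok][0]):
            return float("nan")  # flat curve: no trend defined
        return float(spearmanr(np.asarray(thresholds)[ok], vals[ok]).statistic)

    return StabilityCurve(
        thresholds=tuple(int(t) for t in thresholds),
        edge_spearman=tuple(edge_r),
        modular_nmi=tuple(mod_nmi),
        n_shared_nodes=tuple(n_shared),
        edge_trend=_trend(edge_r),
        modular_trend=_trend(mod_nmi),
    )
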