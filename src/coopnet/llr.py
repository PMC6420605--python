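"""Signed log-likelihood-ratio (LLR) co-occurrence networks.

For two associations i and j mentioned by i_n and j_n of n respondents, with
k11 respondents mentioning both, the Dunning-style likelihood ratio compares
a single-binomial null (the rate of j is the same whether or not i is
present) against the two-binomial maximum-likelihood alternative:

    lambda = L(k11; i_n, j_n/n) * L(j_n - k11; n - i_n, j_n/n)
             -----------------------------------------------------------
             L(k11; i_n, k11/i_n) * L(j_n - k11; n - i_n, (j_n-k11)/(n-i_n))

    LLR = -ln(lambda)  if k11/n >= (i_n/n)*(j_n/n)   (attraction, >= 0)
           ln(lambda)  otherwise                     (repulsion,  <= 0)

Binomial coefficients cancel in the ratio, so only the k*ln(p) +
(n-k)*ln(1-p) kernels are evaluated, with the continuity convention
0*ln(0) = 0. Natural logarithms throughout; 2*|LLR| is the G statistic of
the 2x2 respondent contingency table and is chi-square distributed with one
degree of freedom under independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import AssociationVocabulary, ResponseRecord

__all__ = [
    "CoOpNetwork",
    "compute_llr",
    "expected_cooccurrence",
    "llr_to_chi2_pvalue",
    "build_coop_network",
]


def _binom_kernel(k: float, n: float, p: float) -> float:
    """log of the binomial likelihood kernel p^k (1-p)^(n-k), 0*ln 0 = 0."""
    out = 0.0
    if k > 0:
        out += k * math.log(p)
    if n - k > 0:
        out += (n - k) * math.log1p(-p)
    return out


def _check_counts(i_n: int, j_n: int, k11: int, n: int) -> None:
    if n <= 0:
        raise ValueError(f"total respondent count must be positive, got {n}")
    if not (0 <= i_n <= n and 0 <= j_n <= n):
        raise ValueError(f"marginal counts ({i_n}, {j_n}) outside [0, {n}]")
    if not (max(0, i_n + j_n - n) <= k11 <= min(i_n, j_n)):
        raise ValueError(
            f"joint count {k11} incompatible with margins ({i_n}, {j_n}, n={n})"
        )


def compute_llr(i_n: int, j_n: int, k11: int, n: int) -> float:
    """Signed LLR for one association pair from respondent counts.

    Parameters
    ----------
    i_n, j_n
        Respondents mentioning association i, resp. j.
    k11
        Respondents mentioning both.
    n
        Total respondents.

    Returns
    -------
    float
        Positive when the pair co-occurs more often than the independence
        expectation n*(i_n/n)*(j_n/n) (attraction), negative when less
        (repulsion), exactly 0 at equality.
    """
    _check_counts(i_n, j_n, k11, n)
    if i_n == 0 or j_n == 0:
        return 0.0
    if k11 * n == i_n * j_n:
        return 0.0  # exact independence: lambda = 1, both branches give ln 1
    n_not_i = n - i_n
    k21 = j_n - k11  # respondents mentioning j but not i
    p = j_n / n
    ln_lambda = (
        _binom_kernel(k11, i_n, p)
        + _binom_kernel(k21, n_not_i, p)
        - _binom_kernel(k11, i_n, k11 / i_n)
        - (_binom_kernel(k21, n_not_i, k21 / n_not_i) if n_not_i > 0 else 0.0)
    )
    expected = i_n * j_n / n
    # lambda <= 1 always; the sign flip makes attraction positive.
    return -ln_lambda if k11 >= expected else ln_lambda


def expected_cooccurrence(i_n: int, j_n: int, n: int) -> tuple[int, float]:
    """Independence expectation of the joint respondent count.

    Returns ``(truncated, exact)``: the integer part (truncation toward
    zero, matching how such counts are conventionally printed) and the exact
    value n*(i_n/n)*(j_n/n).
    """
    if n <= 0:
        raise ValueError(f"total respondent count must be positive, got {n}")
    if not (0 <= i_n <= n and 0 <= j_n <= n):
        raise ValueError(f"marginal counts ({i_n}, {j_n}) outside [0, {n}]")
    exact = i_n * j_n / n
    return math.trunc(exact), exact


def llr_to_chi2_pvalue(llr: float) -> float:
    """Two-sided independence p-value from 2*|LLR| ~ chi-square(1)."""
    from scipy.stats import chi2

    return float(chi2.sf(2.0 * abs(llr), df=1))


@dataclass(frozen=True)
class CoOpNetwork:
    """Complete weighted signed graph over the retained association vocabulary.

    ``weights`` is symmetric with zero diagonal (no self-edges); entry
    [i, j] is the signed LLR in nats. ``node_frequencies`` are respondent
    counts per node; ``n`` the total respondent count; ``min_occurrence``
    the vocabulary filter the network was built with.
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    n: int
    node_frequencies: np.ndarray
    min_occurrence: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, node: str) -> int:
        return self.nodes.index(node)

    def edge_frame(self) -> pd.DataFrame:
        """Upper-triangle edge list: node_i, node_j, llr (full precision)."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "node_i": [self.nodes[i] for i in iu],
                "node_j": [self.nodes[j] for j in ju],
                "llr": self.weights[iu, ju],
            }
        )

    def to_networkx(self) -> nx.Graph:
        """networkx view with 'llr' edge weights and 'frequency' node attrs."""
        g = nx.Graph(n_respondents=self.n, min_occurrence=self.min_occurrence)
        for idx, node in enumerate(self.nodes):
            g.add_node(node, frequency=int(self.node_frequencies[idx]))
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            g.add_edge(
                self.nodes[i], self.nodes[j], llr=float(self.weights[i, j])
            )
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def subnetwork(self, nodes: Sequence[str]) -> "CoOpNetwork":
        """Restriction to a node subset (order as given), weights re-indexed."""
        idx = np.array([self.nodes.index(v) for v in nodes], dtype=int)
        return CoOpNetwork(
            nodes=tuple(nodes),
            weights=self.weights[np.ix_(idx, idx)].copy(),
            n=self.n,
            node_frequencies=self.node_frequencies[idx].copy(),
            min_occurrence=self.min_occurrence,
        )


def build_coop_network(
    records: Sequence[ResponseRecord], vocabulary: AssociationVocabulary
) -> CoOpNetwork:
    """Build the CoOp network over the retained vocabulary.

    Joint counts are respondent-level: a pair co-occurs when one respondent
    mentions both lemmas anywhere among their five slots. Every retained
    pair carries a weight (the network is complete); pruning near-zero edges
    is left to export options.
    """
    nodes = vocabulary.retained
    if len(nodes) < 2:
        raise ValueError(
            f"need at least 2 retained associations, got {len(nodes)}"
        )
    node_index = {v: k for k, v in enumerate(nodes)}
    n = len(records)
    # respondent x lemma incidence (deduplicated within respondent)
    incidence = np.zeros((n, len(nodes)), dtype=np.int64)
    for r, rec in enumerate(records):
        for lemma in rec.distinct_associations():
            k = node_index.get(lemma)
            if k is not None:
                incidence[r, k] = 1
    freqs = incidence.sum(axis=0)
    joint = incidence.T @ incidence
    weights = np.zeros((len(nodes), len(nodes)), dtype=float)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            w = compute_llr(int(freqs[i]), int(freqs[j]), int(joint[i, j]), n)
            weights[i, j] = weights[j, i] = w
    return CoOpNetwork(
        nodes=nodes,
        weights=weights,
        n=n,
        node_frequencies=freqs,
        min_occurrence=vocabulary.min_occurrence,
    )
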