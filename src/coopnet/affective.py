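"""Emotion-label profiles and the affective-similarity validation of LLR edges.

Each respondent tags each of their associations with two labels from the
fixed 20-label inventory. Pooling those tags over respondents gives each
retained association an empirical label distribution; the affective
similarity of two associations is

    sim(i, j) = 2 - sum_e | P(e|i) - P(e|j) |

i.e. 2 minus the L1 distance between the normalized 20-bin distributions:
2 for identical label usage, 0 for disjoint.

The co-occurrence validation correlates affective similarity against the
signed LLR after binning the LLR axis into equal-width intervals, which
keeps the mass of near-zero co-occurrence pairs from swamping the tails;
significance comes from a QAP permutation that relabels the nodes of the
affective matrix and re-runs the identical binning pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import EMOTION_LABELS, AssociationVocabulary, ResponseRecord
from .llr import CoOpNetwork

__all__ = [
    "emotion_profiles",
    "affective_similarity",
    "affective_matrix",
    "BinnedCorrelation",
    "binned_llr_affect_correlation",
]


def emotion_profiles(
    records: list[ResponseRecord], vocabulary: AssociationVocabulary
) -> pd.DataFrame:
    """Label-count matrix E: rows = 20 labels, columns = retained lemmas.

    Every mention contributes its (up to two) labels; a respondent who
    repeats a lemma in several slots contributes the labels of each slot.
    """
    nodes = vocabulary.retained
    node_index = {v: k for k, v in enumerate(nodes)}
    counts = np.zeros((len(EMOTION_LABELS), len(nodes)), dtype=np.int64)
    label_index = {lab: e for e, lab in enumerate(EMOTION_LABELS)}
    for rec in records:
        for assoc, labels in zip(rec.associations, rec.emotion_labels):
            j = node_index.get(assoc)
            if j is None:
                continue
            for lab in labels:
                counts[label_index[lab], j] += 1
    return pd.DataFrame(counts, index=list(EMOTION_LABELS), columns=list(nodes))


def affective_similarity(E: pd.DataFrame | np.ndarray, i: int, j: int) -> float:
    """2 minus the L1 distance of two associations' label distributions."""
    M = np.asarray(E, dtype=float)
    ci, cj = M[:, i], M[:, j]
    si, sj = ci.sum(), cj.sum()
    if si == 0 or sj == 0:
        raise ValueError(
            "association with zero emotion-label counts (unfiltered rare "
            f"association at column {i if si == 0 else j})"
        )
    return float(2.0 - np.abs(ci / si - cj / sj).sum())


def affective_matrix(
    records: list[ResponseRecord], vocabulary: AssociationVocabulary
) -> np.ndarray:
    """Symmetric affective-similarity matrix over the retained vocabulary.

    Diagonal entries are 2 (an association is affectively identical to
    itself); all entries lie in [0, 2].
    """
    E = emotion_profiles(records, vocabulary).to_numpy(dtype=float)
    sums = E.sum(axis=0)
    if (sums == 0).any():
        bad = [vocabulary.retained[k] for k in np.where(sums == 0)[0]]
        raise ValueError(f"retained associations without emotion labels: {bad}")
    P = E / sums
    # pairwise L1 distances between columns; clip float residue to [0, 2]
    diff = np.abs(P[:, :, None] - P[:, None, :]).sum(axis=0)
    return np.clip(2.0 - diff, 0.0, 2.0)


@dataclass(frozen=True)
class BinnedCorrelation:
    """Binned LLR-vs-affect correlation with QAP significance.

    ``df`` is (number of non-empty bins) - 2, the convention used when the
    coefficient is reported as r_s(df).
    """

    coefficient: float
    df: int
    p_qap: float
    n_bins: int
    n_nonempty_bins: int
    n_permutations: int
    bin_edges: np.ndarray
    bin_mean_llr: np.ndarray
    bin_mean_affect: np.ndarray
    permutation_order: str = "permute-then-bin"

    def bin_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_llr": self.bin_mean_llr,
                "mean_affect": self.bin_mean_affect,
            }
        )


def _binned_spearman(
    llr_vals: np.ndarray, aff_vals: np.ndarray, edges: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean LLR / mean affect per non-empty bin, and their Spearman rho."""
    # right-most bin closed so the maximum is not dropped
    idx = np.clip(np.digitize(llr_vals, edges[1:-1], right=False), 0, len(edges) - 2)
    n_bins = len(edges) - 1
    sums_l = np.bincount(idx, weights=llr_vals, minlength=n_bins)
    sums_a = np.bincount(idx, weights=aff_vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    mean_l = sums_l[nonempty] / counts[nonempty]
    mean_a = sums_a[nonempty] / counts[nonempty]
    if len(mean_l) < 2 or np.allclose(mean_a, mean_a[0]):
        return float("nan"), mean_l, mean_a
    rho = spearmanr(mean_l, mean_a).statistic
    return float(rho), mean_l, mean_a


def binned_llr_affect_correlation(
    coop: CoOpNetwork,
    aff: np.ndarray,
    n_bins: int = 100,
    n_perm: int = 5000,
    seed: int | None = None,
) -> BinnedCorrelation:
    """Correlate LLR edges with affective similarity over equal-width LLR bins.

    Off-diagonal pairs are binned by LLR into ``n_bins`` equal-width
    intervals over the observed range; per-bin means of both quantities are
    Spearman-correlated over the non-empty bins. The QAP null jointly
    permutes the rows and columns of the affective matrix and re-runs the
    same bin-then-correlate pipeline; the p-value is the include-observed
    fraction of permutations whose |rho| reaches the observed |rho|.
    """
    aff = np.asarray(aff, dtype=float)
    if aff.shape != coop.weights.shape:
        raise ValueError("LLR and affect matrices must share node ordering")
    iu, ju = np.triu_indices(coop.n_nodes, k=1)
    llr_vals = coop.weights[iu, ju]
    edges = np.linspace(llr_vals.min(), llr_vals.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise ValueError("degenerate input: all LLR values identical")

    aff_vals = aff[iu, ju]
    rho, mean_l, mean_a = _binned_spearman(llr_vals, aff_vals, edges)
    if len(mean_l) < 3:
        raise ValueError(
            f"degenerate input: only {len(mean_l)} non-empty LLR bins"
        )
    if np.isnan(rho):
        raise ValueError("degenerate input: constant affect means across bins")

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(coop.n_nodes)
        aff_perm = aff[np.ix_(perm, perm)]
        rho_p, _, _ = _binned_spearman(llr_vals, aff_perm[iu, ju], edges)
        if not np.isnan(rho_p) and abs(rho_p) >= abs(rho):
            n_ge += 1
    p = (n_ge + 1) / (n_perm + 1)
    return BinnedCorrelation(
        coefficient=rho,
        df=len(mean_l) - 2,
        p_qap=p,
        n_bins=n_bins,
        n_nonempty_bins=len(mean_l),
        n_permutations=n_perm,
        bin_edges=edges,
        bin_mean_llr=mean_l,
        bin_mean_affect=mean_a,
    )
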