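"""Respondent-to-module assignment and weighted attitude comparisons.

A respondent is assigned to the module holding the strict majority of their
retained associations; the number of such associations becomes the
respondent's weight. Respondents tied between modules, or with no retained
association, are discarded. Per module M the weighted attitude mean and
variance are

    WAM_M = sum_i w_i x_i / sum_i w_i
    WAV_M = sum_i w_i (x_i - WAM_M)^2 / sum_i w_i

and module pairs are compared with an independent weighted t test built
from those moments (pooled variance by default, Welch optionally), with
Cohen's d from the same pooled SD. Degrees of freedom use respondent
counts, not summed weights. The companion power computation answers how
many respondents per module are needed to detect a medium standardized
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import Partition
from .io import AssociationVocabulary, ResponseRecord

__all__ = [
    "RespondentAssignment",
    "assign_respondents",
    "weighted_moments",
    "weighted_t_test",
    "required_n_per_group",
    "module_attitude_report",
]


@dataclass(frozen=True)
class RespondentAssignment:
    """respondent -> (module, weight); tied or empty respondents discarded."""

    module: Mapping[str, int]
    weight: Mapping[str, int]
    discarded_tied: tuple[str, ...]
    discarded_empty: tuple[str, ...]

    @property
    def n_assigned(self) -> int:
        return len(self.module)


def assign_respondents(
    records: Sequence[ResponseRecord],
    partition: Partition,
    vocabulary: AssociationVocabulary,
) -> RespondentAssignment:
    """Majority-rule assignment of respondents to modules.

    Counts each respondent's distinct retained associations per module; the
    module with the strict maximum count wins and the count is the weight.
    Equal maxima discard the respondent from attitude analyses.
    """
    node_module = {
        lemma: int(m) for lemma, m in zip(vocabulary.retained, partition.labels)
    }
    module: dict[str, int] = {}
    weight: dict[str, int] = {}
    tied: list[str] = []
    empty: list[str] = []
    for rec in records:
        counts: dict[int, int] = {}
        for lemma in rec.distinct_associations():
            m = node_module.get(lemma)
            if m is not None:
                counts[m] = counts.get(m, 0) + 1
        if not counts:
            empty.append(rec.respondent_id)
            continue
        best = max(counts.values())
        winners = [m for m, c in counts.items() if c == best]
        if len(winners) > 1:
            tied.append(rec.respondent_id)
            continue
        module[rec.respondent_id] = winners[0]
        weight[rec.respondent_id] = best
    return RespondentAssignment(
        module=module,
        weight=weight,
        discarded_tied=tuple(tied),
        discarded_empty=tuple(empty),
    )


def weighted_moments(
    scores: Sequence[float], weights: Sequence[float]
) -> tuple[float, float, int, float]:
    """(WAM, WAV, respondent count, total weight) of one module's scores."""
    x = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("degenerate input: empty module")
    if x.shape != w.shape or (w <= 0).any():
        raise ValueError("scores and positive weights must align")
    total = w.sum()
    wam = float((w * x).sum() / total)
    wav = float((w * (x - wam) ** 2).sum() / total)
    return wam, wav, int(x.size), float(total)


def weighted_t_test(
    scores_a: Sequence[float],
    weights_a: Sequence[float],
    scores_b: Sequence[float],
    weights_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float, float]:
    """Independent weighted two-sample t test: returns (t, df, p, d).

    Group moments are the weighted mean/variance above; the test statistic
    uses a pooled weighted variance (or Welch's separate variances) with
    degrees of freedom from respondent counts. Cohen's d is the absolute
    standardized mean difference on the pooled SD.
    """
    wam_a, wav_a, n_a, _ = weighted_moments(scores_a, weights_a)
    wam_b, wav_b, n_b, _ = weighted_moments(scores_b, weights_b)
    if n_a + n_b < 3:
        raise ValueError("too few respondents for a t test")
    # sample (n-1) variances from the weighted population variances
    var_a = wav_a * n_a / (n_a - 1) if n_a > 1 else 0.0
    var_b = wav_b * n_b / (n_b - 1) if n_b > 1 else 0.0
    if welch:
        se2 = var_a / n_a + var_b / n_b
        if se2 == 0:
            raise ValueError("degenerate input: zero variance in both groups")
        t = (wam_a - wam_b) / np.sqrt(se2)
        df = se2**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
        pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    else:
        pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        if pooled_var == 0:
            raise ValueError("degenerate input: zero pooled variance")
        t = (wam_a - wam_b) / np.sqrt(pooled_var * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    d = abs(wam_a - wam_b) / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    return float(t), float(df), float(p), float(d)


def _power_two_sample(n: int, d: float, alpha: float) -> float:
    """Power of the two-sided two-sample t test at per-group size n."""
    df = 2 * n - 2
    ncp = d * np.sqrt(n / 2.0)
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def required_n_per_group(
    d: float = 0.5, alpha: float = 0.05, power: float = 0.8, n_max: int = 10**6
) -> int:
    """Smallest per-group n giving the target power for effect size d.

    Uses the noncentral-t formulation of the two-sided independent t test
    (normal outcomes, common SD, mean difference d standard deviations).
    """
    if not (0 < alpha < 1 and 0 < power < 1 and d > 0):
        raise ValueError("require 0 < alpha < 1, 0 < power < 1, d > 0")
    for n in range(2, n_max + 1):
        if _power_two_sample(n, d, alpha) >= power:
            return n
    raise ValueError(
        f"power {power} unattainable for d={d} within n <= {n_max}"
    )


def module_attitude_report(
    records: Sequence[ResponseRecord],
    assignment: RespondentAssignment,
    scales: Sequence[str] = ("pot", "gm", "sdo"),
    excluded_modules: Sequence[int] = (),
    welch: bool = False,
    power_d: float = 0.5,
    power_alpha: float = 0.05,
    power_target: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module weighted moments and all pairwise weighted t tests.

    Returns ``(module_table, pair_table)``. Modules listed in
    ``excluded_modules`` (e.g. single-lemma modules) are dropped from both.
    The ``powered`` flag marks pairs where both groups reach the per-group n
    required for the reference effect size.
    """
    by_id = {rec.respondent_id: rec for rec in records}
    data: dict[tuple[int, str], tuple[list[float], list[float]]] = {}
    for rid, module in assignment.module.items():
        if module in excluded_modules:
            continue
        rec = by_id[rid]
        for scale in scales:
            if scale in rec.attitude_scores:
                xs, ws = data.setdefault((module, scale), ([], []))
                xs.append(rec.attitude_scores[scale])
                ws.append(assignment.weight[rid])

    n_required = required_n_per_group(power_d, power_alpha, power_target)
    mod_rows, pair_rows = [], []
    modules = sorted({m for (m, _) in data})
    for scale in scales:
        for m in modules:
            if (m, scale) not in data:
                continue
            xs, ws = data[(m, scale)]
            wam, wav, count, total = weighted_moments(xs, ws)
            mod_rows.append(
                {
                    "module_id": m,
                    "scale": scale,
                    "wam": wam,
                    "wav": wav,
                    "n_respondents": count,
                    "total_weight": total,
                }
            )
        for m_a, m_b in combinations(modules, 2):
            if (m_a, scale) not in data or (m_b, scale) not in data:
                continue
            xa, wa = data[(m_a, scale)]
            xb, wb = data[(m_b, scale)]
            try:
                t, df, p, d = weighted_t_test(xa, wa, xb, wb, welch=welch)
            except ValueError:
                continue
            pair_rows.append(
                {
                    "module_a": m_a,
                    "module_b": m_b,
                    "scale": scale,
                    "t": t,
                    "df": df,
                    "p": p,
                    "cohen_d": d,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "powered": len(xa) >= n_required and len(xb) >= n_required,
                }
            )
    return pd.DataFrame(mod_rows), pd.DataFrame(pair_rows)
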