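# Methods

`coopnet` turns multiple-response free-association surveys into signed
co-occurrence networks, finds opinion modules in them, and validates those
modules three ways: against the emotional labels respondents attach to
their own associations, against a second independent sample, and against
attitude questionnaires. This note describes the statistical machinery, the
choices that were genuinely open, and what the synthetic benchmark does and
does not establish.

## Data model

One respondent contributes five free associations to a single cue, two
emotion labels per association from a fixed 20-label inventory (ten
positive/negative pairs: interest-alarm, empathy-contempt,
surprise-indifference, hope-fear, gratitude-anger, joy-sadness,
calmness-relief, pride-shame, generosity-envy, love/sympathy-hate/antipathy),
and optional Likert attitude scores: perceived outgroup threat (POT, 1-5),
group malleability (GM, 1-6), social dominance orientation (SDO, 1-7).

All counting is respondent-level: a respondent who repeats a lemma in
several slots (for example after lemma-map merging) counts once toward that
lemma's frequency and once toward any pair involving it. Associations
mentioned by fewer than `min_occurrence` respondents (default 3) are
dropped before network construction; they are idiosyncratic periphery
rather than shared representation, and their co-occurrence counts are too
unstable to carry a statistic.

## The signed LLR edge weight

For associations *i*, *j* with respondent counts *i_n*, *j_n*, joint count
*k₁₁* and total *n*, the edge weight is a Dunning-style log-likelihood
ratio comparing the single-binomial null (the rate of *j* is unchanged by
the presence of *i*) with the two-binomial alternative, signed by the
direction of the deviation:

    LLR = -ln λ   if k₁₁ ≥ i_n·j_n/n   (attraction, ≥ 0)
           ln λ   otherwise            (repulsion, ≤ 0)

Binomial coefficients cancel in λ, so only `k·ln p + (n-k)·ln(1-p)` kernels
are evaluated, with `0·ln 0 ≡ 0`. Logarithms are natural: the worked
repulsive-pair values −7.27 and −8.41 (from counts 93/97/6/505 and
99/146/13/505) are reproduced only in nats. `2·|LLR|` is exactly the G
statistic of the 2×2 respondent contingency table (χ² with 1 df under
independence); the test suite verifies this identity to 1e-9 relative
tolerance against a brute-force observed·ln(observed/expected) oracle.

Numerical conventions: exact independence (`k₁₁·n = i_n·j_n`) returns
exactly 0.0 rather than float residue; the printed integer expected
co-occurrence truncates toward zero (93·97/505 = 17.86 → 17), with the
continuous value always reported alongside. The network is complete — every
retained pair carries its signed weight, including near-zero ones — because
both the modularity objective and the binned affect correlation consume the
full weight distribution; pruning is an export option only.

## Affective similarity

Each association accumulates a 20-bin emotion-label count vector over the
respondents who mention it (two labels per mention). Affective similarity
is `2 − L1` between the two normalized label distributions: 2 for identical
usage, 0 for disjoint. Retained associations always have at least
`2·min_occurrence` label counts, so the normalization is well defined.

The attraction/affect correlation bins the off-diagonal LLR values into 100
equal-width intervals over the observed range (right-most bin closed,
empty bins dropped) and Spearman-correlates per-bin mean LLR against
per-bin mean similarity. Binning rebalances the mass of near-zero
co-occurrence pairs that would otherwise dominate the correlation.
Significance comes from a QAP permutation: the affective matrix's rows and
columns are jointly permuted and the *entire* bin-then-correlate pipeline
is re-run per permutation, so observed and null statistics are computed
identically (the permute-then-bin order is recorded in the result). The
degrees of freedom reported with the coefficient are (non-empty bins) − 2.

## Signed modularity, Louvain, consensus

Modularity is generalized to signed weights by giving the positive and
negative layers separate configuration models:

    Q = 1/(v⁺+v⁻) · Σᵢⱼ [(w⁺ᵢⱼ − s⁺ᵢs⁺ⱼ/v⁺) − (w⁻ᵢⱼ − s⁻ᵢs⁻ⱼ/v⁻)]·δ(Mᵢ,Mⱼ)

with strengths *s±* the layer row sums and *v±* the layer totals over
ordered pairs. The all-in-one partition scores exactly 0; two equal
disconnected positive cliques correctly split score 0.5 (the 1 − 1/k
closed form at k = 2); on all-positive input Q reduces to Newman–Girvan
weighted modularity (tested against an independent brute-force oracle and
against networkx's Louvain).

The optimizer is a two-phase Louvain: greedy single-node moves in a
seed-shuffled visit order, then aggregation of modules into supernodes.
The two sign layers are aggregated **separately** — between supernodes both
layers can carry weight simultaneously, and collapsing them to a net value
would corrupt the per-layer null models (this is the one subtle
implementation point; the test suite pins it via the enumerated-optimum
checks). Resolution is fixed at 1 and configurable.

A known limitation, shared by every greedy Louvain variant: on adversarial
dense random signed matrices the enumerated global optimum can be
unreachable by any sequence of single-node improving moves from the
singleton start (we found 6-node instances where 2,000 restarts all
converge to the same suboptimal attractor). On co-occurrence networks of
the kind this package builds — where the sign pattern derives from count
data rather than independent coin flips — enumerated optimality held in
every small instance we generated (120/120 with single runs). Stochastic
restarts plus consensus are the method's own answer to local optima.

Consensus partitioning runs `n_runs` independent Louvain restarts (default
5,000, matching the method's standard setting; per-run seeds are spawned
deterministically from the master seed), forms the co-classification
frequency matrix, then repeatedly re-partitions that non-negative matrix
`n_check` times (default 100) until all `n_check` partitions agree,
replacing the matrix with their co-classification otherwise; `max_rounds`
(default 50) guards termination. No threshold is applied to the consensus
matrix before re-partitioning. Both the consensus partition's own Q and the
mean Q of the initial runs are reported, since the two need not coincide.
Modules are labeled by their two most frequent lemmas (lexicographic
tie-break); modules with fewer than two distinct lemmas are flagged and
excluded from attitude analyses while keeping their network membership.
For visualization, pairs co-classified in at least 40% of runs (the
configurable consensus edge threshold) are exported as edges.

## Cross-sample reproducibility

Comparisons first restrict both networks to their shared vocabulary.

*Edge level.* Spearman correlation over shared off-diagonal pairs, with
significance from QAP: jointly permuting the rows and columns of one matrix
5,000 times (default) and counting permutations whose |ρ| reaches the
observed |ρ|. All permutation p-values use the add-one (include-observed)
convention, so p ≥ 1/(n_perm+1) and p = 0 never occurs.

*Module level.* Normalized mutual information between partitions,
`nMI = 2(H₁+H₂−H₁₂)/(H₁+H₂)`, computed from module-size and contingency
entropies; relabel-invariant, symmetric, in [0, 1]. Degenerate limits:
both partitions trivial → 1; exactly one trivial → 0. The implementation
agrees with scikit-learn's arithmetic-mean NMI to 1e-10 (cross-checked in
tests, not delegated). Because the consensus procedure is stochastic, the
cross-sample agreement can also be summarized as the mean nMI over pairs of
independent runs; enumerating all pairs of two 5,000-run ensembles is
infeasible, so a seeded random sample of cross pairs estimates that average
without bias, and the consensus-vs-consensus nMI is reported alongside.

*Null models.* The reference distribution for nMI comes from edge-,
weight- and strength-preserving randomizations. Connection switching picks
node quadrilaterals (a, b, c, d) whose pair weights show complementary
signs and exchanges them (`w_ab ↔ w_ad`, `w_cd ↔ w_cb`); each accepted
switch preserves every node's positive and negative degree and both weight
multisets exactly, and — unlike vacant-slot double-edge swaps — still mixes
dense networks, where almost every pair carries an edge of one sign or the
other. Attempted switches default to 10× the edge count. Each layer's
weight multiset is then re-dealt over its switched structure: at each step
a random unassigned edge is ranked by the product of its endpoints'
residual strengths and receives the equally-ranked remaining weight,
steering strengths toward the originals (node-strength correlations with
the original are ≈ 0.99 on 150-node benchmarks, and > 0.9 is asserted in
tests). Null nMI values pair a randomization of each sample; by default
each null network is partitioned by a single seeded Louvain run (full
consensus per null network is available but costs 100-fold more), and the
empirical p is the include-observed fraction of null nMI ≥ observed.

*Threshold sweep.* Both networks are rebuilt at minimum-occurrence
thresholds 3…13; the shared-node edge Spearman and consensus nMI trace how
excluding rare associations stabilizes the method. Points with fewer than
3 shared nodes are flagged missing; each curve's Spearman against the
threshold summarizes the trend (undefined for flat curves).

## Attitude comparisons

A respondent joins the module holding the strict majority of their distinct
retained associations, weighted by that count; ties and respondents with no
retained association are discarded and reported. Module statistics are the
weighted mean `WAM = Σwᵢxᵢ/Σwᵢ` and weighted population variance
`WAV = Σwᵢ(xᵢ−WAM)²/Σwᵢ`. Pairwise tests are independent two-sample t
tests built from these moments with pooled variance (Welch optional),
degrees of freedom from respondent counts (n_a + n_b − 2), not summed
weights — weights express association multiplicity, not extra independent
observations, and uniformly rescaling all weights leaves t unchanged.
Cohen's d uses the same pooled SD. With unit weights everything reduces to
the textbook pooled t test (asserted against scipy). No multiple-testing
correction is applied; the report carries the comparison count. The power
helper inverts the noncentral-t power function of the two-sided test by
bracketing the smallest per-group n (d = 0.5, α = .05, power .8 → 64;
cross-checked against statsmodels' continuous solver).

## Synthetic populations

The generator emulates the survey's data shape, not its lexical content.
Each latent opinion group has a Zipf-weighted vocabulary (exponent 1.0 —
free-association frequencies are heavy-tailed, and the rank-frequency
profile of generated samples is checked for negative log-log slope and
convexity), an emotion-label distribution concentrating probability
`emotion_concentration` (default 0.8) on a characteristic label pair, and
normal attitude scores truncated into the scale range by resampling.
Respondents draw a group, five distinct associations, two distinct labels
per association, and their scores; ground truth is returned separately.

The reference benchmark (`planted_three_group_config`) uses 505
respondents, three equal groups with disjoint 40-word vocabularies, and a
planted POT gradient (means 2.0 / 3.0 / 4.2, SD 0.8 — pairwise separations
of roughly 1.3-2.8 SD, comparable to the between-module contrasts the
method is meant to resolve). `generate_paired_samples` draws two waves from
one population; a `drift` parameter perturbs the second wave's vocabulary
weighting and emotion concentration to emulate between-wave change, and
`single_group_config` provides the no-structure null.

What the benchmark shows: under planted polarization the pipeline recovers
the group partition (nMI ≥ 0.9, typically 1.0), the affect correlation is
strongly positive with small QAP p, all pairwise POT tests point in the
planted direction, and cross-sample similarity rises as the occurrence
threshold climbs. What it does not show: real respondents share vocabulary
across opinion groups, mix frames within their five slots, and violate the
independence of association draws; recovery on cleanly separated synthetic
groups is a correctness check of the machinery, not a field-validity claim.

## Problem sizes and determinism

Library defaults keep the method's standard settings (5,000 Louvain runs,
100 agreement checks, 5,000 permutations and null models). The test suite
and the acceptance script run the same code paths at reduced ensemble sizes
(tens to hundreds of runs, hundreds of permutations), which the consensus
experiments above show is already past the saturation point for the
benchmark networks (~120-160 nodes). Every stochastic component takes a
seed; master seeds spawn per-run seeds deterministically, so identical
configurations reproduce identical artifacts byte for byte.
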