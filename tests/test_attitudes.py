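import numpy as np
import pytest
from scipy import stats

from coopnet import (
    assign_respondents,
    build_vocabulary,
    module_attitude_report,
    required_n_per_group,
    weighted_moments,
    weighted_t_test,
)
from coopnet.community import Partition
from conftest import make_record


def make_partition(vocab, mapping):
    labels = np.array([mapping[l] for l in vocab.retained])
    return Partition(labels=labels, modularity=0.0)


@pytest.fixture
def two_module_setup():
    """Lemmas a1,a2,a3 in module 0; b1,b2,b3 in module 1."""
    recs = []
    for k in range(3):
        recs.append(make_record(f"fa{k}", ["a1", "a2", "a3"]))
        recs.append(make_record(f"fb{k}", ["b1", "b2", "b3"]))
    vocab = build_vocabulary(recs, 3)
    mapping = {l: (0 if l.startswith("a") else 1) for l in vocab.retained}
    return recs, vocab, make_partition(vocab, mapping)


class TestAssignment:
    def test_majority_rule(self, two_module_setup):
        recs, vocab, part = two_module_setup
        extra = make_record("maj", ["a1", "a2", "b1"])
        assignment = assign_respondents(recs + [extra], part, vocab)
        assert assignment.module["maj"] == 0
        assert assignment.weight["maj"] == 2

    def test_tied_respondent_discarded(self, two_module_setup):
        recs, vocab, part = two_module_setup
        tied = make_record("tie", ["a1", "a2", "b1", "b2"])
        assignment = assign_respondents(recs + [tied], part, vocab)
        assert "tie" not in assignment.module
        assert "tie" in assignment.discarded_tied

    def test_all_in_one_module_full_weight(self, two_module_setup):
        recs, vocab, part = two_module_setup
        full = make_record("full", ["a1", "a2", "a3", "a1", "a2"])
        assignment = assign_respondents(recs + [full], part, vocab)
        # duplicates deduplicate: 3 distinct retained associations
        assert assignment.weight["full"] == 3

    def test_no_retained_association_discarded(self, two_module_setup):
        recs, vocab, part = two_module_setup
        stray = make_record("stray", ["unseen1", "unseen2"])
        assignment = assign_respondents(recs + [stray], part, vocab)
        assert "stray" in assignment.discarded_empty


class TestWeightedMoments:
    def test_unit_weights_reduce_to_plain_moments(self, rng):
        x = rng.normal(size=12)
        wam, wav, n, total = weighted_moments(x, np.ones(12))
        assert wam == pytest.approx(x.mean())
        assert wav == pytest.approx(x.var())  # population variance
        assert (n, total) == (12, 12.0)

    def test_hand_worked_example(self):
        wam, wav, n, total = weighted_moments([2, 4], [3, 1])
        assert wam == pytest.approx(2.5)
        assert wav == pytest.approx(0.75)

    def test_identical_scores_zero_variance(self):
        _, wav, _, _ = weighted_moments([3, 3, 3], [1, 2, 5])
        assert wav == 0.0

    def test_wam_bounded_by_scores(self, rng):
        x = rng.uniform(1, 5, size=9)
        w = rng.integers(1, 6, size=9)
        wam, _, _, _ = weighted_moments(x, w)
        assert x.min() <= wam <= x.max()

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_moments([], [])


class TestWeightedTTest:
    def test_identical_groups_null_case(self):
        x = [1.0, 2.0, 3.0, 4.0]
        t, df, p, d = weighted_t_test(x, [1] * 4, x, [1] * 4)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert d == pytest.approx(0.0)

    def test_equal_weights_match_scipy_pooled_t(self, rng):
        a = rng.normal(0, 1, size=15)
        b = rng.normal(0.8, 1, size=12)
        t, df, p, d = weighted_t_test(a, np.ones(15), b, np.ones(12))
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_ref)
        assert df == 25
        assert p == pytest.approx(p_ref)

    def test_weight_doubling_leaves_t_unchanged(self, rng):
        a = rng.normal(0, 1, size=10)
        b = rng.normal(1, 1, size=10)
        wa = rng.integers(1, 5, size=10).astype(float)
        wb = rng.integers(1, 5, size=10).astype(float)
        t1, df1, _, d1 = weighted_t_test(a, wa, b, wb)
        t2, df2, _, d2 = weighted_t_test(a, 2 * wa, b, 2 * wb)
        assert t1 == pytest.approx(t2)
        assert df1 == df2
        assert d1 == pytest.approx(d2)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            weighted_t_test([2, 2], [1, 1], [2, 2], [1, 1])

    def test_welch_close_to_pooled_for_balanced_data(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(0.5, 1, size=20)
        t_p, _, _, _ = weighted_t_test(a, np.ones(20), b, np.ones(20))
        t_w, df_w, _, _ = weighted_t_test(a, np.ones(20), b, np.ones(20), welch=True)
        assert t_w == pytest.approx(t_p)
        assert df_w <= 38.0 + 1e-9


class TestPower:
    def test_medium_effect_needs_64_per_group(self):
        assert required_n_per_group(0.5, 0.05, 0.8) == 64

    def test_agrees_with_statsmodels_solver(self):
        from statsmodels.stats.power import TTestIndPower

        n_cont = TTestIndPower().solve_power(
            effect_size=0.5, alpha=0.05, power=0.8, alternative="two-sided"
        )
        assert required_n_per_group(0.5, 0.05, 0.8) == int(np.ceil(n_cont))

    def test_huge_effect_saturates(self):
        assert required_n_per_group(10.0, 0.05, 0.8) <= 3

    def test_returned_n_brackets_target_power(self):
        from coopnet.attitudes import _power_two_sample

        n = required_n_per_group(0.4, 0.05, 0.9)
        assert _power_two_sample(n, 0.4, 0.05) >= 0.9
        assert _power_two_sample(n - 1, 0.4, 0.05) < 0.9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            required_n_per_group(0.5, 1.5, 0.8)


class TestReport:
    def test_report_tables_consistent(self, two_module_setup):
        recs, vocab, part = two_module_setup
        scored = []
        for k, rec in enumerate(recs):
            scored.append(
                make_record(
                    rec.respondent_id,
                    [a for a in rec.associations if a],
                    scores={"pot": 2.0 if rec.respondent_id.startswith("fa") else 4.0 + 0.1 * k},
                )
            )
        assignment = assign_respondents(scored, part, vocab)
        mod_table, pair_table = module_attitude_report(scored, assignment)
        assert set(mod_table.module_id) == {0, 1}
        assert len(pair_table) == 1
        row = pair_table.iloc[0]
        assert row.t < 0 and row.p < 0.05
        assert not row.powered  # 3 respondents per module << 64

    def test_excluded_modules_dropped(self, two_module_setup):
        recs, vocab, part = two_module_setup
        scored = [
            make_record(r.respondent_id, [a for a in r.associations if a], scores={"pot": 3.0})
            for r in recs
        ]
        assignment = assign_respondents(scored, part, vocab)
        mod_table, pair_table = module_attitude_report(
            scored, assignment, excluded_modules=[1]
        )
        assert set(mod_table.module_id) == {0}
        assert pair_table.empty
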