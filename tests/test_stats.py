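"""Contingency construction, exact tests, odds ratios, kappa, summaries."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from paencase import (
    Cohort,
    build_relation_table,
    cohens_kappa,
    fisher_exact,
    group_summary,
    odds_ratio_vs_baseline,
    two_sample_t,
    wilcoxon_rank_sum,
)
from paencase.core import ANALYZABLE_RELATIONS

from conftest import D, DC, E, IM, P, make_record


class TestRelationTable:
    def test_published_margins_fixture(self, reconstruction):
        t = build_relation_table(reconstruction)
        assert t.matrix().tolist() == [[8, 2, 10], [58, 27, 4]]
        assert t.excluded == {"benign": 3, "malignant": 3}
        assert t.analyzed("benign") == 20
        assert t.analyzed("malignant") == 74
        assert t.dual_count == {"benign": 0, "malignant": 15}

    def test_single_penetration_lesion(self):
        c = Cohort(records=(make_record("x", "benign", (P,), None),))
        t = build_relation_table(c)
        assert t.matrix().sum() == 1 and t.count(P, "benign") == 1

    def test_only_disconnection_lesions_all_excluded(self):
        c = Cohort(records=tuple(
            make_record(f"x{i}", "benign", (DC,), None) for i in range(3)))
        t = build_relation_table(c)
        assert t.matrix().sum() == 0 and t.excluded["benign"] == 3

    def test_lesion_conservation(self, reconstruction):
        t = build_relation_table(reconstruction)
        for g in ("benign", "malignant"):
            assert t.analyzed(g) + t.excluded[g] == t.total[g]
            assert t.records(g) == t.analyzed(g) + t.dual_count[g]


def brute_force_fisher_2x2(a, b, c, d):
    """Oracle: hypergeometric probability-mass sum over the 2x2 margin lattice."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_2x2_against_enumeration_oracle(self):
        assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(
            brute_force_fisher_2x2(1, 9, 11, 3), rel=1e-9)

    def test_2x2_matches_scipy(self):
        for table in ([[1, 9], [11, 3]], [[3, 0], [0, 4]], [[2, 7], [8, 2]]):
            assert fisher_exact(table) == pytest.approx(
                sps.fisher_exact(table)[1], rel=1e-9)

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_2x2_oracle_equivalence_over_small_margin_lattice(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(1.0)
        else:
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                brute_force_fisher_2x2(a, b, c, d), rel=1e-9)

    def test_published_2x3_table_is_highly_significant(self):
        p = fisher_exact([[8, 2, 10], [58, 27, 4]])
        assert p < 0.001

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestOddsRatio:
    def test_encasement_vs_penetration_published_values(self):
        r = odds_ratio_vs_baseline(58, 8, 4, 10)
        assert r.odds_ratio == pytest.approx(18.125)
        assert r.ci_low == pytest.approx(4.6, abs=0.05)
        assert r.ci_high == pytest.approx(71.7, abs=0.05)

    def test_displacement_vs_penetration_published_values(self):
        r = odds_ratio_vs_baseline(27, 2, 4, 10)
        assert r.odds_ratio == pytest.approx(33.75)
        assert r.ci_low == pytest.approx(5.3, abs=0.05)

    def test_symmetric_table_gives_unit_odds(self):
        assert odds_ratio_vs_baseline(5, 5, 5, 5).odds_ratio == pytest.approx(1.0)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_row_and_column_swap_invariances(self, cells):
        a, b, c, d = cells
        base = odds_ratio_vs_baseline(a, b, c, d)
        both = odds_ratio_vs_baseline(d, c, b, a)  # swap rows and columns
        one = odds_ratio_vs_baseline(b, a, d, c)  # swap columns only
        assert both.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        assert one.odds_ratio == pytest.approx(1.0 / base.odds_ratio, rel=1e-12)

    def test_zero_cell_needs_continuity_correction(self):
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio_vs_baseline(5, 0, 3, 4)
        r = odds_ratio_vs_baseline(5, 0, 3, 4, continuity=True)
        assert r.odds_ratio > 0 and r.ci_low < r.odds_ratio < r.ci_high


def brute_force_rank_sum_p(x, y):
    """Oracle: exact two-sided P by enumerating all rank assignments."""
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestRankSumAndT:
    def test_extreme_ranking_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(brute_force_rank_sum_p([1, 2, 3], [4, 5, 6]))

    def test_single_observation_each(self):
        _, p = wilcoxon_rank_sum([10], [20])
        assert p == pytest.approx(1.0)

    def test_identical_tied_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        x, y = [1.0, 4.0, 6.0, 9.0], [2.0, 3.0, 8.0]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_rank_sum_p(x, y), rel=1e-9)

    def test_pooled_t_matches_hand_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, p = two_sample_t(x, y)
        sp2 = (np.var(x, ddof=1) * 3 + np.var(y, ddof=1) * 3) / 6
        expected = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(expected)
        assert t == pytest.approx(-1.095445, abs=1e-6)

    def test_identical_groups_give_p_one(self):
        _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_zero_variance_guarded(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([0.0, 0.0], [1.0, 1.0])


class TestCohensKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa(np.diag([10, 5, 7]))
        assert r.kappa == pytest.approx(1.0)
        assert r.grade == "very_good"

    def test_independent_raters_give_zero(self):
        marg1, marg2 = np.array([4, 6, 10]), np.array([8, 7, 5])
        table = np.outer(marg1, marg2)
        assert cohens_kappa(table).kappa == pytest.approx(0.0, abs=1e-12)

    def test_published_kappa_grades_substantial(self):
        from paencase.stats import grade_kappa

        assert grade_kappa(0.639).value == "substantial"
        assert grade_kappa(0.612).value == "substantial"
        assert grade_kappa(0.15).value == "poor"
        assert grade_kappa(0.85).value == "very_good"

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        table = rng.integers(0, 20, size=(4, 4))
        table[0, 0] += 30  # make it non-degenerate
        mine = cohens_kappa(table)
        ref = sm_kappa(table, return_results=True)
        assert mine.kappa == pytest.approx(ref.kappa, rel=1e-9)
        # statsmodels uses z = 1.959964 where we use 1.96; same variance formula
        assert mine.ci_low == pytest.approx(max(-1, ref.kappa_low), abs=1e-4)

    def test_invariant_under_joint_category_permutation(self, rng):
        table = rng.integers(0, 15, size=(3, 3)) + np.diag([5, 5, 5])
        perm = [2, 0, 1]
        permuted = table[np.ix_(perm, perm)]
        assert cohens_kappa(permuted).kappa == pytest.approx(
            cohens_kappa(table).kappa, rel=1e-12)

    def test_degenerate_marginals_raise(self):
        with pytest.raises(ValueError, match="p_e"):
            cohens_kappa([[7, 0], [0, 0]])


class TestGroupSummary:
    def test_mean_and_sample_sd(self):
        c = Cohort(records=(
            make_record("a", "benign", (E,), 40.0),
            make_record("b", "benign", (E,), 60.0),
            make_record("c", "malignant", (P,), None),
        ))
        s = group_summary(c)["benign"]
        assert s.degree_mean == pytest.approx(50.0)
        assert s.degree_sd == pytest.approx(math.sqrt(200.0))

    def test_single_value_has_no_sd(self):
        c = Cohort(records=(make_record("a", "benign", (E,), 40.0),
                            make_record("c", "malignant", (P,), None)))
        assert group_summary(c)["benign"].degree_sd is None

    def test_empty_group_warns_and_is_absent(self):
        c = Cohort(records=(make_record("a", "benign", (E,), 40.0),))
        with pytest.warns(UserWarning, match="malignant"):
            out = group_summary(c)
        assert out["malignant"] is None
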