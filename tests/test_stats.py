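"""Evaluation statistics: reference standard, exact CIs, weighted kappa,
McNemar, down-rating and descriptive summaries.

Independent oracles: brute-force tallies, scipy binomial tail root-finding
for Clopper-Pearson, a matrix-free double-loop kappa, and statsmodels for
kappa variance and the continuity-corrected McNemar test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy import stats as sps

from eyetriage.chart import UrgencyGrade
from eyetriage.stats import (
    Confusion2x2,
    CrossTabKxK,
    accuracy,
    clopper_pearson,
    combine_reference,
    confusion,
    crosstab,
    downrate_analysis,
    kappa_band,
    likert_summary,
    mcnemar_cc,
    over_under_estimation,
    percent_agreement_urgent,
    reference_urgent,
    weighted_kappa,
)

GRADES = ["A", "B", "C", "D"]
grade_st = st.sampled_from(GRADES)


class TestReferenceStandard:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [("B", "C", "B"), ("A", "A", "A"), ("D", "B", "B"), ("C", "D", "C")],
    )
    def test_more_urgent_grade_wins(self, g1, g2, expected):
        assert combine_reference(g1, g2) is UrgencyGrade(expected)

    @settings(derandomize=True)
    @given(g1=grade_st, g2=grade_st)
    def test_combined_grade_at_least_as_urgent_as_each_input(self, g1, g2):
        combined = combine_reference(g1, g2)
        assert combined >= UrgencyGrade(g1)
        assert combined >= UrgencyGrade(g2)
        assert combine_reference(g1, g2) is combine_reference(g2, g1)

    @pytest.mark.parametrize(
        "g1, g2, urgent", [("C", "B", True), ("C", "D", False), ("A", "D", True)]
    )
    def test_urgent_iff_at_least_one_reviewer_urgent(self, g1, g2, urgent):
        assert reference_urgent(g1, g2) is urgent

    def test_missing_reviewer_grade_rejected(self):
        with pytest.raises(ValueError):
            reference_urgent(None, "B")


class TestConfusion:
    def test_all_concordant_positives(self):
        c = confusion([True] * 5, [True] * 5)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 0)

    @settings(max_examples=200, derandomize=True)
    @given(
        pairs=st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=8)
    )
    def test_matches_bruteforce_pairwise_tally(self, pairs):
        pred = [p for p, _ in pairs]
        ref = [r for _, r in pairs]
        c = confusion(pred, ref)
        assert c.tp == sum(p and r for p, r in pairs)
        assert c.fp == sum(p and not r for p, r in pairs)
        assert c.fn == sum(not p and r for p, r in pairs)
        assert c.tn == sum(not p and not r for p, r in pairs)
        assert c.n == len(pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestClopperPearson:
    def test_bounds_match_binomial_tail_roots(self):
        """Oracle: the exact interval endpoints solve the binomial tail
        equations P(X >= x | p=lower) = alpha/2, P(X <= x | p=upper) = alpha/2."""
        for x, n in [(65, 76), (47, 206), (58, 76), (132, 206), (3, 10), (1, 50)]:
            lo, hi = clopper_pearson(x, n)
            root_lo = optimize.brentq(
                lambda p: sps.binom.sf(x - 1, n, p) - 0.025, 1e-12, 1 - 1e-12
            )
            root_hi = optimize.brentq(
                lambda p: sps.binom.cdf(x, n, p) - 0.025, 1e-12, 1 - 1e-12
            )
            assert lo == pytest.approx(root_lo, abs=1e-9)
            assert hi == pytest.approx(root_hi, abs=1e-9)

    def test_boundary_counts(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(float(sps.beta.ppf(0.025, 10, 1)))
        lo0, hi0 = clopper_pearson(0, 10)
        assert lo0 == 0.0
        assert 0 < hi0 < 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 0)
        with pytest.raises(ValueError):
            clopper_pearson(11, 10)


class TestAccuracy:
    def test_point_estimates_and_interval_ordering(self):
        res = accuracy(Confusion2x2(tp=65, fp=159, fn=11, tn=47))
        assert res.sensitivity == pytest.approx(65 / 76)
        assert res.specificity == pytest.approx(47 / 206)
        assert res.ci_sens[0] <= res.sensitivity <= res.ci_sens[1]
        assert res.ci_spec[0] <= res.specificity <= res.ci_spec[1]

    def test_complement_swaps_sensitivity_and_specificity(self):
        c = Confusion2x2(tp=30, fp=12, fn=5, tn=40)
        swapped = Confusion2x2(tp=c.tn, fp=c.fn, fn=c.fp, tn=c.tp)
        assert accuracy(c).sensitivity == accuracy(swapped).specificity
        assert accuracy(c).ci_sens == accuracy(swapped).ci_spec

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            accuracy(Confusion2x2(tp=0, fp=5, fn=0, tn=5))


class TestPercentAgreement:
    def test_identical_dichotomies_agree_fully(self):
        ref = [True, False, True]
        assert percent_agreement_urgent(["A", "C", "B"], ref) == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        grades=st.lists(grade_st, min_size=1, max_size=20),
        data=st.data(),
    )
    def test_equals_confusion_identity(self, grades, data):
        ref = data.draw(
            st.lists(st.booleans(), min_size=len(grades), max_size=len(grades))
        )
        pred = [g in ("A", "B") for g in grades]
        c = confusion(pred, ref)
        assert percent_agreement_urgent(grades, ref) == pytest.approx(
            (c.tp + c.tn) / c.n
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement_urgent([], [])


def _kappa_double_loop(table, weights="quadratic"):
    """Matrix-free oracle: explicit double loops over the k x k table."""
    k = len(table)
    n = sum(sum(row) for row in table)
    row_m = [sum(table[i][j] for j in range(k)) / n for i in range(k)]
    col_m = [sum(table[i][j] for i in range(k)) / n for j in range(k)]
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            if weights == "quadratic":
                w = (i - j) ** 2 / (k - 1) ** 2
            else:
                w = abs(i - j) / (k - 1)
            num += w * table[i][j] / n
            den += w * row_m[i] * col_m[j]
    return 1.0 - num / den


class TestWeightedKappa:
    def test_perfect_agreement_gives_one(self):
        res = weighted_kappa(CrossTabKxK(np.diag([5, 3, 7, 2])))
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_independence_table_gives_zero(self):
        row = np.array([10, 20, 30, 40], dtype=float)
        col = np.array([25, 25, 25, 25], dtype=float)
        tab = np.outer(row, col) / 100
        res = weighted_kappa(CrossTabKxK(tab))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_k2_quadratic_reduces_to_unweighted_cohen_kappa(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            t = rng.integers(1, 30, (2, 2)).astype(float)
            n = t.sum()
            po = (t[0, 0] + t[1, 1]) / n
            pe = (t[0].sum() * t[:, 0].sum() + t[1].sum() * t[:, 1].sum()) / n**2
            plain = (po - pe) / (1 - pe)
            assert weighted_kappa(CrossTabKxK(t)).kappa == pytest.approx(plain, abs=1e-12)

    def test_matches_double_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t = rng.integers(0, 25, (4, 4))
            if t.sum() == 0 or _kappa_is_degenerate(t):
                continue
            expected = _kappa_double_loop(t.tolist())
            assert weighted_kappa(CrossTabKxK(t)).kappa == pytest.approx(
                expected, abs=1e-12
            )

    def test_symmetric_under_transpose(self):
        rng = np.random.default_rng(23)
        t = rng.integers(0, 20, (4, 4))
        assert weighted_kappa(CrossTabKxK(t)).kappa == pytest.approx(
            weighted_kappa(CrossTabKxK(t.T)).kappa
        )

    def test_point_and_se_match_statsmodels(self):
        sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.integers(1, 30, (4, 4))
            res = weighted_kappa(CrossTabKxK(t))
            ref = sm_ir.cohens_kappa(t, wt="quadratic")
            assert res.kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert res.se == pytest.approx(math.sqrt(ref.var_kappa), abs=1e-10)

    def test_bootstrap_ci_close_to_asymptotic(self):
        rng = np.random.default_rng(19)
        t = rng.integers(5, 30, (4, 4))
        asym = weighted_kappa(CrossTabKxK(t))
        boot = weighted_kappa(
            CrossTabKxK(t), ci_method="bootstrap", bootstrap_reps=800,
            rng=np.random.default_rng(3),
        )
        assert boot.kappa == pytest.approx(asym.kappa)
        assert boot.ci[0] == pytest.approx(asym.ci[0], abs=0.1)
        assert boot.ci[1] == pytest.approx(asym.ci[1], abs=0.1)

    def test_degenerate_marginals_raise_with_message(self):
        t = np.zeros((4, 4))
        t[2, 2] = 30  # both raters constant on one category
        with pytest.raises(ValueError, match="degenerate"):
            weighted_kappa(CrossTabKxK(t))

    def test_kappa_one_iff_no_offdiagonal_mass(self):
        t = np.diag([5, 3, 7, 2]).astype(float)
        t[0, 1] = 1
        assert weighted_kappa(CrossTabKxK(t)).kappa < 1.0


def _kappa_is_degenerate(t):
    n = t.sum()
    p = t / n
    pe = 0.0
    for i in range(4):
        for j in range(4):
            pe += (1 - (i - j) ** 2 / 9) * p[i].sum() * p[:, j].sum()
    return math.isclose(pe, 1.0, abs_tol=1e-12)


class TestCrossTab:
    def test_counts_align_raters_and_conserve_n(self):
        tab = crosstab(["A", "B", "B", "D"], ["A", "C", "B", "D"])
        assert tab.counts[0, 0] == 1 and tab.counts[1, 2] == 1
        assert tab.total == 4

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            crosstab(["A"], ["A", "B"])


class TestKappaBand:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.22, "fair"),
            (0.38, "fair"),
            (-0.05, "no agreement"),
            (0.0, "no agreement"),
            (0.01, "none to slight"),
            (0.20, "none to slight"),
            (0.204, "none to slight"),  # rounds to 0.20
            (0.41, "moderate"),
            (0.61, "substantial"),
            (0.91, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_printed_cutoffs(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.2)


class TestMcNemar:
    def test_balanced_discordance(self):
        stat, p = mcnemar_cc(5, 5)
        assert stat == pytest.approx(0.1)
        assert p == pytest.approx(float(sps.chi2.sf(0.1, 1)))

    def test_worked_example(self):
        stat, p = mcnemar_cc(20, 5)
        assert stat == pytest.approx(7.84)
        assert p == pytest.approx(float(sps.chi2.sf(7.84, 1)))

    def test_statistic_symmetric_on_exhaustive_grid(self):
        for b in range(21):
            for c in range(21):
                if b + c == 0:
                    continue
                expected = (abs(b - c) - 1) ** 2 / (b + c)
                stat_bc, _ = mcnemar_cc(b, c)
                stat_cb, _ = mcnemar_cc(c, b)
                assert stat_bc == pytest.approx(expected)
                assert stat_bc == stat_cb

    def test_matches_statsmodels_continuity_corrected(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(20, 5), (3, 9), (1, 1), (17, 2)]:
            stat, p = mcnemar_cc(b, c)
            ref = sm_ct.mcnemar([[10, b], [c, 10]], exact=False, correction=True)
            assert stat == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue))

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_cc(0, 0)


class TestDownrate:
    def test_identical_raters_downrate_nothing(self):
        grades = ["A", "B", "C", "B"]
        n, prop = downrate_analysis(grades, grades)
        assert (n, prop) == (0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(data=st.data())
    def test_matches_bruteforce_filter_and_count(self, data):
        n = data.draw(st.integers(min_value=1, max_value=15))
        comp = data.draw(st.lists(grade_st, min_size=n, max_size=n))
        against = data.draw(st.lists(grade_st, min_size=n, max_size=n))
        urgent_rows = [i for i, g in enumerate(against) if g in ("A", "B")]
        if not urgent_rows:
            with pytest.raises(ValueError):
                downrate_analysis(comp, against)
            return
        expected = sum(comp[i] in ("C", "D") for i in urgent_rows)
        got_n, got_prop = downrate_analysis(comp, against)
        assert got_n == expected
        assert got_prop == pytest.approx(expected / len(urgent_rows))

    def test_no_urgent_rows_rejected(self):
        with pytest.raises(ValueError):
            downrate_analysis(["C", "D"], ["C", "D"])


class TestOverUnder:
    def test_identical_grades_give_zero_both_ways(self):
        assert over_under_estimation(["A", "C"], ["A", "C"]) == (0.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(data=st.data())
    def test_over_under_exact_partition(self, data):
        n = data.draw(st.integers(min_value=1, max_value=20))
        g = data.draw(st.lists(grade_st, min_size=n, max_size=n))
        ref = data.draw(st.lists(grade_st, min_size=n, max_size=n))
        over, under = over_under_estimation(g, ref)
        exact = sum(a == b for a, b in zip(g, ref)) / n
        assert over + under + exact == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            over_under_estimation([], [])


class TestLikert:
    def test_basic_summary(self):
        mean, sd, n, top2 = likert_summary([5, 5, 4])
        assert mean == pytest.approx(4.667, abs=1e-3)
        assert n == 3
        assert top2 == 1.0

    def test_single_value_has_undefined_sd(self):
        mean, sd, n, top2 = likert_summary([3])
        assert (mean, sd, n, top2) == (3.0, None, 1, 0.0)

    def test_missing_values_dropped(self):
        mean, sd, n, top2 = likert_summary([4, None, float("nan"), 2])
        assert n == 2
        assert mean == 3.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            likert_summary([None, float("nan")])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            likert_summary([6])
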