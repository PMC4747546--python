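"""Statistical engine against enumeration oracles and simulations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import fisher_exact_oracle, mann_whitney_exact_oracle

import neovent as nv
from neovent.stats import (anova_on_ranks_with_posthoc, normal_approx_sample_size,
                           wilcoxon_paired)


class TestSummarizeGroup:
    def test_small_example(self):
        med, iqr, n = nv.summarize_group([1, 2, 3, 4, 5])
        assert (med, iqr, n) == (3.0, 2.0, 5)

    def test_constant_list(self):
        med, iqr, _ = nv.summarize_group([7.0] * 10)
        assert med == 7.0 and iqr == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nv.summarize_group([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           st.floats(-100, 100))
    def test_median_bounds_and_iqr_shift_invariance(self, xs, shift):
        med, iqr, _ = nv.summarize_group(xs)
        assert min(xs) <= med <= max(xs)
        med2, iqr2, _ = nv.summarize_group([x + shift for x in xs])
        assert med2 == pytest.approx(med + shift, abs=1e-6)
        assert iqr2 == pytest.approx(iqr, abs=1e-6)


class TestMannWhitney:
    def test_tiny_exact_example(self):
        # a < b completely separated: U = 0, p = 2/6 by enumeration
        u, p = nv.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_centre_of_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = nv.mann_whitney_u(a, a)
        assert u == len(a) ** 2 / 2
        assert p > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nv.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_normal_approximation_close_to_exact(self, n):
        """Continuity-corrected approximation within 0.02 of enumeration."""
        rng = np.random.default_rng(n)
        for _ in range(5):
            a = rng.normal(0, 1, n)
            b = rng.normal(0.5, 1, n)
            p_exact = mann_whitney_exact_oracle(a, b)
            _, p_approx = nv.mann_whitney_u(a, b, exact_max_n=0)  # force asymptotic
            assert abs(p_approx - p_exact) < 0.02

    def test_wilcoxon_paired_available(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        _, p = wilcoxon_paired(a, a + rng.normal(2, 0.5, 30))
        assert p < 1e-4


class TestWelchT:
    def test_identical_groups(self):
        t, _, p = nv.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # equal variances: Welch and pooled coincide: t = -3.674, p ~ 0.021
        t, df, p = nv.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=0.001)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=0.001)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            nv.welch_t([1.0], [2.0, 3.0])


class TestAnovaSNK:
    def test_identical_groups_no_rejections(self):
        g = [1.0, 2.0, 3.0]
        res = anova_on_ranks_with_posthoc([g, g, g])
        assert res.p_value == pytest.approx(1.0)
        assert not any(d.significant for d in res.posthoc)

    def test_snk_separates_the_shifted_group(self):
        res = anova_on_ranks_with_posthoc([[1, 2, 3], [1, 2, 3], [10, 11, 12]])
        assert res.p_value < 0.001
        sig = {(d.group_i, d.group_j): d.significant for d in res.posthoc}
        assert sig[(0, 2)] and sig[(1, 2)]
        assert not sig[(0, 1)]

    def test_rank_path_matches_kruskal(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 12) for m in (0, 0, 1.5)]
        res = anova_on_ranks_with_posthoc(groups, parametric=False)
        h, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h)
        assert res.p_value == pytest.approx(p)

    def test_familywise_error_under_complete_null(self):
        """SNK keeps the FWER near alpha with 4 null groups (2,000 reps)."""
        rng = np.random.default_rng(2024)
        n_rej = 0
        reps = 2000
        for _ in range(reps):
            groups = rng.normal(0, 1, (4, 10))
            res = anova_on_ranks_with_posthoc(list(groups))
            n_rej += any(d.significant for d in res.posthoc)
        assert n_rej / reps <= 0.05 + 0.02

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_on_ranks_with_posthoc([[1.0, 2.0]])


class TestCategorical:
    def test_balanced_table_chi2_path(self):
        stat, p, method = nv.categorical_test([[10, 10], [10, 10]])
        assert method.startswith("chi")
        assert p == pytest.approx(1.0)

    def test_fisher_path_matches_enumeration(self):
        table = [[1, 9], [9, 1]]
        _, p, method = nv.categorical_test(table)
        assert method == "fisher"
        assert p == pytest.approx(fisher_exact_oracle(table), abs=1e-9)
        assert p == pytest.approx(0.0011, abs=2e-4)

    def test_specialist_title_table(self):
        """72.5% vs 47.5% specialists among 51 vs 59: p ~ 0.013 (Yates chi2)."""
        _, p, method = nv.categorical_test([[37, 14], [28, 31]])
        assert method.startswith("chi")
        assert p == pytest.approx(0.013, abs=0.002)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nv.categorical_test([[1, -2], [3, 4]])


class TestSampleSize:
    def test_study_design_numbers(self):
        """delta 1.0 mL, sd 1.2 mL, power 0.8, alpha 0.05: n in [23, 25]."""
        n0 = normal_approx_sample_size(1.0, 1.2)
        assert n0 == pytest.approx(22.6, abs=0.2)
        n = nv.required_sample_size(1.0, 1.2)
        assert 23 <= n <= 25

    def test_limit_cases(self):
        assert nv.required_sample_size(1.0, 1.0, power=0.5, alpha=0.9) <= 3
        assert normal_approx_sample_size(1.0, 2.4) == pytest.approx(
            4 * normal_approx_sample_size(1.0, 1.2))

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            nv.required_sample_size(0.0, 1.0)


def test_t_test_power_at_design_point():
    """Rejection rate ~ 0.80 at n=25/group, delta 1.0, sd 1.2 (2,000 reps).

    The exact noncentral-t power at this design point is ~0.82; the
    Monte-Carlo rate must agree with it, and with the nominal 0.80 design
    power within the simulation margin.
    """
    from neovent.stats import two_sample_t_power

    exact = two_sample_t_power(25, 1.0, 1.2)
    assert exact == pytest.approx(0.80, abs=0.03)
    rng = np.random.default_rng(99)
    reps, n = 2000, 25
    a = rng.normal(0.0, 1.2, (reps, n))
    b = rng.normal(1.0, 1.2, (reps, n))
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt((va + vb) / n)
    df = (va + vb) ** 2 / (va ** 2 + vb ** 2) * (n - 1)
    p = 2 * sps.t.sf(np.abs(t), df)
    assert (p < 0.05).mean() == pytest.approx(exact, abs=0.025)
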