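"""Shared statistics: hand-worked oracles and structural identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scentstress.stats import (
    bh_fdr,
    oneway_anova,
    pearson_with_p,
    rm_anova_two_way,
    tukey_kramer,
    two_sample_t,
)


def brute_force_bh(p, alpha):
    """Literal step-up definition: reject all p <= p_(k*) with
    k* = max{k : p_(k) <= k*alpha/m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[p <= p[order[k_star - 1]]] = True
    return reject


class TestTwoSampleT:
    def test_matches_hand_computation(self):
        # pooled t on two 4-value samples, worked by hand:
        # a: mean 5, ss 20; b: mean 9, ss 4; sp2 = 24/6 = 4; t = -4/sqrt(2)
        a = [2, 4, 6, 8]
        b = [8, 8, 10, 10]
        sp2 = (20 + 4) / 6
        expected_t = (5 - 9) / np.sqrt(sp2 * (0.25 + 0.25))
        res = two_sample_t(a, b)
        assert res.statistic == pytest.approx(expected_t)
        assert res.df == 6
        assert res.direction == -1

    def test_antisymmetric_in_arguments(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_identical_groups_give_t_zero_p_one(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0
        assert res.p == 1

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestOnewayAnova:
    def test_matches_bruteforce_sums_of_squares(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 5), (1, 7), (0.5, 6)]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = 3, allv.size
        f_expected = (ss_between / (k - 1)) / (ss_within / (n - k))
        res = oneway_anova(groups)
        assert res.statistic == pytest.approx(f_expected)
        assert res.df == (2, n - k)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        f = oneway_anova([a, b])
        t = two_sample_t(a, b)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p == pytest.approx(t.p)

    def test_zero_variance_everywhere_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            oneway_anova([[1, 1], [1, 1]])


class TestTukeyKramer:
    def test_two_groups_matches_t_test(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 6)
        p = tukey_kramer([a, b])
        # with two groups the studentized range reduces to |t|*sqrt(2)
        assert p[0, 1] == pytest.approx(two_sample_t(a, b).p, rel=1e-6)
        assert np.isnan(p[0, 0])

    def test_symmetric_matrix(self, rng):
        groups = [rng.normal(m, 1, 7) for m in (0, 0.4, 1.2)]
        p = tukey_kramer(groups)
        assert p[0, 1] == p[1, 0]
        assert p.shape == (3, 3)


class TestRmAnovaTwoWay:
    @staticmethod
    def _bruteforce(data: np.ndarray, group: np.ndarray):
        """Mixed-design ANOVA from first-principles SS partitioning."""
        n, t = data.shape
        levels = sorted(set(group))
        grand = data.mean()
        subj_means = data.mean(axis=1)
        time_means = data.mean(axis=0)
        ss_between_subj = t * ((subj_means - grand) ** 2).sum()
        ss_group = sum(
            t * (group == g).sum() * (data[group == g].mean() - grand) ** 2 for g in levels
        )
        ss_subj_within = ss_between_subj - ss_group
        ss_time = n * ((time_means - grand) ** 2).sum()
        ss_cells = sum(
            (group == g).sum() * ((data[group == g].mean(axis=0) - grand) ** 2).sum()
            for g in levels
        )
        ss_interaction = ss_cells - ss_group - ss_time
        ss_total = ((data - grand) ** 2).sum()
        ss_error = ss_total - ss_between_subj - ss_time - ss_interaction
        k = len(levels)
        df_g, df_t = k - 1, t - 1
        df_gt = df_g * df_t
        df_sw, df_err = n - k, (n - k) * (t - 1)
        f_g = (ss_group / df_g) / (ss_subj_within / df_sw)
        f_t = (ss_time / df_t) / (ss_error / df_err)
        f_gt = (ss_interaction / df_gt) / (ss_error / df_err)
        return f_g, f_t, f_gt, (df_g, df_sw), (df_t, df_err), (df_gt, df_err)

    def test_matches_bruteforce_partitioning(self, rng):
        n, t = 12, 4
        group = np.repeat(["a", "b", "c"], 4)
        data = rng.normal(0, 1, (n, t)) + np.linspace(0, 1, t)
        res = rm_anova_two_way(pd.DataFrame(data), group)
        f_g, f_t, f_gt, df_g, df_t, df_gt = self._bruteforce(data, group)
        assert res["group"].statistic == pytest.approx(f_g, rel=1e-6)
        assert res["time"].statistic == pytest.approx(f_t, rel=1e-6)
        assert res["group x time"].statistic == pytest.approx(f_gt, rel=1e-6)
        assert res["group"].df == df_g
        assert res["time"].df == df_t
        assert res["group x time"].df == df_gt

    def test_duplicated_groups_have_no_group_effect(self, rng):
        block = rng.normal(0, 1, (5, 3))
        data = np.vstack([block, block])
        group = np.repeat(["a", "b"], 5)
        res = rm_anova_two_way(pd.DataFrame(data), group)
        assert res["group"].statistic == pytest.approx(0, abs=1e-10)

    def test_missing_cells_raise(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_two_way(df, ["a", "a", "b", "b"])


class TestPearson:
    def test_matches_hand_computation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        r_hand = (((x - 3) * (y - y.mean())).sum()
                  / np.sqrt(((x - 3) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        res = pearson_with_p(x, y)
        assert res.statistic == pytest.approx(r_hand)
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(abs(t), 3))

    def test_affine_relation_gives_unit_magnitude(self):
        x = np.array([0.0, 1, 2, 3])
        assert pearson_with_p(x, x).statistic == pytest.approx(1.0)
        assert pearson_with_p(x, -2 * x + 3).statistic == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestBhFdr:
    def test_worked_example_all_rejected(self):
        rejected, q = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        # p_(4) = 0.04 <= 4*0.05/4 so the step-up rejects everything
        assert rejected.all()
        assert np.all(q <= 0.05)

    def test_all_ones_reject_nothing(self):
        rejected, q = bh_fdr([1.0, 1.0, 1.0])
        assert not rejected.any()
        assert np.all(q == 1.0)

    def test_single_p_reduces_to_plain_threshold(self):
        rejected, _ = bh_fdr([0.04], alpha=0.05)
        assert rejected.all()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
        st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    def test_matches_bruteforce_stepup(self, pvals, alpha):
        rejected, q = bh_fdr(pvals, alpha=alpha)
        expected = brute_force_bh(pvals, alpha)
        assert np.array_equal(rejected, expected)
        # rejection at level alpha is equivalent to q <= alpha
        assert np.array_equal(q <= alpha, expected)
        assert np.all(q >= np.asarray(pvals) - 1e-12)

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 1, 40)
        r1, _ = bh_fdr(p, alpha=0.05)
        r2, _ = bh_fdr(p, alpha=0.2)
        assert np.all(r2 | ~r1)  # r1 subset of r2

    def test_null_pvalues_roughly_uniform(self, rng):
        # sanity: the t test's null p distribution feeds BH correctly
        from scipy.stats import kstest

        pv = []
        for _ in range(500):
            a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
            pv.append(two_sample_t(a, b).p)
        assert kstest(pv, "uniform").pvalue > 1e-3
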