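"""Test-selection battery: gate, exact Mann-Whitney, omnibus tests, Bonferroni."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from qrelax.stats import (
    normality_gate,
    two_sample_compare,
    exact_mannwhitney,
    multi_group,
    bonferroni_adjust,
)


def naive_exact_mwu_p(a, b):
    """Independent brute force: two-sided exact permutation p for U (mid-ranks)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    nb = b.size
    off = nb * (nb + 1) / 2
    u_obs = ranks[a.size:].sum() - off
    us = [sum(ranks[list(c)]) - off for c in combinations(range(pooled.size), nb)]
    total = len(us)
    le = sum(u <= u_obs + 1e-9 for u in us)
    ge = sum(u >= u_obs - 1e-9 for u in us)
    return min(1.0, 2 * min(le, ge) / total)


class TestGate:
    def test_tiny_group_forces_nonparametric(self):
        assert normality_gate([1, 2, 3, 4, 5], [1.0, 2.0]) == "nonparametric"

    def test_normal_samples_route_parametric(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 19), rng.normal(0.5, 1, 19)
        assert normality_gate(a, b) == "parametric"

    def test_heavy_tailed_sample_routes_nonparametric(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            a = rng.standard_cauchy(19)
            b = rng.normal(0, 1, 19)
            hits += normality_gate(a, b) == "nonparametric"
        assert hits >= 16  # high power against Cauchy at n = 19

    def test_gate_deterministic(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=19), rng.normal(size=19)
        routes = {normality_gate(a, b) for _ in range(5)}
        assert len(routes) == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normality_gate([], [1, 2, 3])


class TestExactMannWhitney:
    def test_extreme_19_vs_2_configuration(self):
        """Both migraine values above all free values: p = 2 / C(21, 2) = 2/210."""
        a = np.arange(19, dtype=float)
        b = np.array([30.0, 31.0])
        res = exact_mannwhitney(a, b)
        assert res.p_value == pytest.approx(2 / 210, rel=1e-12)
        assert res.test_used == "mann_whitney_exact"

    def test_identical_multisets_degenerate(self):
        res = exact_mannwhitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.normal(0, 1, 19)
            b = rng.normal(rng.uniform(-2, 2), 1, 2)
            ours = exact_mannwhitney(a, b).p_value
            ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="exact")
            # scipy's two-sided exact p is 2*min-tail as well for continuous data
            assert ours == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_naive_enumeration_with_ties(self):
        cases = [
            ([1, 2, 2, 3, 4, 4, 4], [2, 4]),
            ([1, 1, 1, 2, 2], [1, 2]),
            ([5, 6, 7, 8], [6, 6, 7]),
        ]
        for a, b in cases:
            assert exact_mannwhitney(a, b).p_value == pytest.approx(
                naive_exact_mwu_p(a, b), rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 12), min_size=2, max_size=12),
        b=st.lists(st.integers(0, 12), min_size=1, max_size=3),
    )
    def test_enumeration_property_small_samples(self, a, b):
        res = exact_mannwhitney(a, b)
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == pytest.approx(naive_exact_mwu_p(a, b), rel=1e-12)

    def test_enumeration_size_guard(self):
        with pytest.raises(ValueError, match="enumeration limited"):
            exact_mannwhitney(np.arange(50), np.arange(50))

    def test_type_i_error_conservative_under_null(self):
        """Discreteness keeps the exact test at or below nominal level."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(0, 1, 19)
            b = rng.normal(0, 1, 2)
            if exact_mannwhitney(a, b).p_value <= 0.05 + 1e-12:
                rejections += 1
        # smallest attainable p is 2/210 ~ 0.0095; attainable level below 0.05
        # is P(U in rejection region) <= 0.05; allow 3 binomial SDs of slack
        assert rejections / n_sim <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)


class TestTwoSampleCompare:
    def test_auto_route_small_group_uses_exact_test(self):
        rng = np.random.default_rng(5)
        res = two_sample_compare(rng.normal(0, 1, 19), rng.normal(3, 1, 2))
        assert res.test_used == "mann_whitney_exact"
        assert res.n_per_group == (19, 2)

    def test_parametric_route_is_welch(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 19), rng.normal(1, 3, 19)
        res = two_sample_compare(a, b, route="parametric")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.test_used == "welch_t"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_data_flagged(self):
        res = two_sample_compare([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.p_value == 1.0 and res.degenerate

    def test_parametric_needs_two_per_group(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_compare([1.0, 2.0, 3.0], [1.5], route="parametric")


class TestMultiGroup:
    def test_two_groups_consistent_with_two_sample_family(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        omnibus, posthoc = multi_group([a, b], route="nonparametric")
        assert omnibus.test_used == "kruskal_wallis"
        assert len(posthoc) == 1
        assert posthoc[0][2].test_used == "mann_whitney_exact"
        assert posthoc[0][2].p_adjusted == posthoc[0][2].p_value  # one pair family

    def test_identical_groups_degenerate(self):
        omnibus, posthoc = multi_group([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert omnibus.p_value == 1.0 and omnibus.degenerate

    def test_parametric_route_is_anova_with_bonferroni_posthoc(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.0, 2.0)]
        omnibus, posthoc = multi_group(groups, route="parametric")
        ref = sps.f_oneway(*groups)
        assert omnibus.test_used == "anova"
        assert omnibus.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        assert len(posthoc) == 3
        for _, _, r in posthoc:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_value))

    def test_shift_detection_rate_against_simulation(self):
        """With a 2-sigma mean offset at n = 12 the omnibus test should
        reject often; under the null it should not."""
        rng = np.random.default_rng(10)
        hits_alt = sum(
            multi_group([rng.normal(0, 1, 12), rng.normal(2, 1, 12)],
                        route="parametric")[0].p_value < 0.05
            for _ in range(100))
        hits_null = sum(
            multi_group([rng.normal(0, 1, 12), rng.normal(0, 1, 12)],
                        route="parametric")[0].p_value < 0.05
            for _ in range(100))
        assert hits_alt > 90
        assert hits_null < 15


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 2, 0.4)],
    )
    def test_adjustment_values(self, p, m, expected):
        assert bonferroni_adjust([p], m=m) == [pytest.approx(expected)]

    def test_vector_matches_direct_recomputation(self):
        rng = np.random.default_rng(12)
        ps = rng.uniform(0, 1, 20).tolist()
        adj = bonferroni_adjust(ps)
        assert adj == [min(1.0, 20 * p) for p in ps]
        assert all(x >= p for x, p in zip(adj, ps))
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= 0)  # monotone in p

    def test_validation(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bonferroni_adjust([1.2])
        with pytest.raises(ValueError, match="family size"):
            bonferroni_adjust([0.1, 0.2], m=1)
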