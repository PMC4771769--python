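"""ANOVA stack, planned comparisons, Tukey-Kramer, Bonferroni t-tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import balanced_twoway_ss, studentized_range_cdf_quadrature
from aisquant.stats import (
    bonferroni_planned,
    bonferroni_t_tests,
    one_way_anova,
    tukey_kramer,
    two_way_anova,
)


def _balanced_design(cell_means, sd, n, seed):
    rng = np.random.default_rng(seed)
    y, loc, area = [], [], []
    for (lo, ar), mu in cell_means.items():
        y.extend(rng.normal(mu, sd, n))
        loc.extend([lo] * n)
        area.extend([ar] * n)
    return np.array(y), np.array(loc), np.array(area)


class TestTwoWayAnova:
    def test_degenerate_zero_variance_is_missing_with_warning(self):
        cells = {(lo, ar): 10.0 for lo in ("AIS", "NON_AIS") for ar in ("a", "b", "c")}
        y, loc, area = _balanced_design(cells, 0.0, 4, 0)
        with pytest.warns(UserWarning, match="zero residual variance"):
            tab = two_way_anova(y, loc, area)
        assert math.isnan(tab.loc["location", "F"])
        assert math.isnan(tab.loc["interaction", "p"])

    def test_balanced_design_matches_closed_form_oracle(self):
        cells = {("AIS", "a"): 10.0, ("AIS", "b"): 10.0,
                 ("NON_AIS", "a"): 10.0, ("NON_AIS", "b"): 20.0}
        y, loc, area = _balanced_design(cells, 1.0, 50, 13)
        tab = two_way_anova(y, loc, area)
        want = balanced_twoway_ss(y, loc, area)
        for effect in ("location", "brain_area", "interaction", "residual"):
            assert tab.loc[effect, "ss"] == pytest.approx(want[effect], rel=1e-8)
        f_int = (want["interaction"] / 1) / (want["residual"] / (200 - 4))
        assert tab.loc["interaction", "F"] == pytest.approx(f_int, rel=1e-8)

    def test_unbalanced_runs_with_valid_p_values(self, rng):
        y, loc, area = [], [], []
        sizes = {("AIS", "a"): 43, ("AIS", "b"): 69, ("NON_AIS", "a"): 51,
                 ("NON_AIS", "b"): 60}
        for (lo, ar), n in sizes.items():
            y.extend(rng.normal(0, 1, n))
            loc.extend([lo] * n)
            area.extend([ar] * n)
        tab = two_way_anova(np.array(y), np.array(loc), np.array(area))
        for effect in ("location", "brain_area", "interaction"):
            assert 0.0 <= tab.loc[effect, "p"] <= 1.0
            assert tab.loc[effect, "ms"] == pytest.approx(
                tab.loc[effect, "ss"] / tab.loc[effect, "df"])

    def test_empty_cell_rejected(self):
        y = np.arange(6.0)
        loc = np.array(["AIS", "AIS", "AIS", "NON_AIS", "NON_AIS", "NON_AIS"])
        area = np.array(["a", "a", "b", "a", "a", "a"])  # (NON_AIS, b) empty
        with pytest.raises(ValueError, match="empty cells"):
            two_way_anova(y, loc, area)

    def test_missing_responses_dropped_listwise(self):
        cells = {("AIS", "a"): 1.0, ("AIS", "b"): 2.0,
                 ("NON_AIS", "a"): 3.0, ("NON_AIS", "b"): 4.0}
        y, loc, area = _balanced_design(cells, 1.0, 20, 3)
        y_nan = y.copy()
        y_nan[:5] = np.nan
        tab = two_way_anova(y_nan, loc, area)
        assert tab.loc["residual", "df"] == (len(y) - 5) - 4


class TestOneWayAnova:
    def test_identical_groups_are_degenerate(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            tab = one_way_anova(np.array([5.0, 5.0, 5.0, 5.0]),
                                np.array(["a", "a", "b", "b"]))
        assert math.isnan(tab.loc["group", "F"])

    def test_textbook_three_groups_matches_ss_oracle(self):
        groups = {"a": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "b": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "c": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        y = np.concatenate([groups[g] for g in "abc"])
        g = np.repeat(list("abc"), 6)
        tab = one_way_anova(y, g)
        grand = y.mean()
        ssb = sum(6 * (np.mean(groups[k]) - grand) ** 2 for k in "abc")
        ssw = sum(((np.asarray(groups[k]) - np.mean(groups[k])) ** 2).sum() for k in "abc")
        assert tab.loc["group", "ss"] == pytest.approx(ssb, rel=1e-10)
        assert tab.loc["residual", "ss"] == pytest.approx(ssw, rel=1e-10)
        f = (ssb / 2) / (ssw / 15)
        assert tab.loc["group", "F"] == pytest.approx(f, rel=1e-10)
        # cross-check against the scipy implementation
        assert tab.loc["group", "F"] == pytest.approx(
            sps.f_oneway(*[groups[k] for k in "abc"]).statistic, rel=1e-10)

    def test_two_group_f_equals_squared_t(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.7, 1, 30)
        tab = one_way_anova(np.concatenate([x, y]),
                            np.repeat(["x", "y"], [25, 30]))
        t = sps.ttest_ind(x, y, equal_var=True).statistic
        assert tab.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)


class TestBonferroni:
    def test_adjustment_arithmetic_and_cap(self):
        assert bonferroni_planned([0.01], 6) == [pytest.approx(0.06)]
        assert bonferroni_planned([0.5], 6) == [1.0]

    def test_monotone_in_raw_p(self, rng):
        ps = np.sort(rng.uniform(0, 1, 20))
        adj = bonferroni_planned(ps, 25)
        assert all(a2 >= a1 for a1, a2 in zip(adj, adj[1:]))
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_family_size_contract(self):
        with pytest.raises(ValueError, match="n_comparisons"):
            bonferroni_planned([0.1, 0.2], 1)

    def test_familywise_error_controlled_under_null(self):
        """FWER of 6 Bonferroni-adjusted t-tests stays at or below ~0.05."""
        rng = np.random.default_rng(99)
        reps, n, fam = 2000, 20, 6
        x = rng.normal(size=(reps, n, fam))
        y = rng.normal(size=(reps, n, fam))
        p = sps.ttest_ind(x, y, axis=1).pvalue  # (reps, fam)
        fw = np.mean([min(bonferroni_planned(row, fam)) <= 0.05 for row in p])
        assert fw <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


class TestTukeyKramer:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        res = tukey_kramer({"a": base, "b": base.copy()})
        assert res[0].estimate == pytest.approx(0.0)
        assert res[0].p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_known_q_and_quadrature_oracle_p(self):
        """q follows hand arithmetic exactly; p matches direct quadrature of
        the studentized range distribution to 1e-4."""
        groups = {"a": np.array([1.0, 2.0, 3.0, 4.0]),
                  "b": np.array([3.0, 4.0, 5.0, 6.0]),
                  "c": np.array([6.0, 7.0, 8.0, 9.0])}
        res = tukey_kramer(groups)
        mse = 5.0 / 3.0  # pooled within variance: each group has SS=5, df=3
        dof, k = 9, 3
        for cmp_ in res:
            means = {g: groups[g].mean() for g in groups}
            diff = means[cmp_.pair[0]] - means[cmp_.pair[1]]
            q_hand = abs(diff) / math.sqrt(mse / 2 * (1 / 4 + 1 / 4))
            p_oracle = 1.0 - studentized_range_cdf_quadrature(q_hand, k, dof)
            assert cmp_.estimate == pytest.approx(diff, abs=1e-12)
            assert cmp_.p_adjusted == pytest.approx(p_oracle, abs=1e-4)

    def test_unequal_n_uses_kramer_form(self):
        groups = {"a": np.arange(5.0), "b": np.arange(8.0) + 1.0}
        res = tukey_kramer(groups)
        ns = {"a": 5, "b": 8}
        mse = (np.var(groups["a"], ddof=1) * 4 + np.var(groups["b"], ddof=1) * 7) / 11
        q = abs(groups["a"].mean() - groups["b"].mean()) / math.sqrt(
            mse / 2 * (1 / ns["a"] + 1 / ns["b"]))
        assert res[0].p_adjusted == pytest.approx(
            float(sps.studentized_range.sf(q, 2, 11)), rel=1e-9)

    def test_all_pairs_reported(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(0, 1, 10) for g in "abcdef"}
        res = tukey_kramer(groups)
        assert len(res) == len(list(itertools.combinations("abcdef", 2)))


class TestBonferroniTTests:
    def test_identical_samples_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bonferroni_t_tests({"m1": (x, x.copy())})
        assert res[0].estimate == 0.0
        assert res[0].p_adjusted == 1.0

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(2.0, 1.0, 40)  # 2 sd shift
        res = bonferroni_t_tests({"m1": (x, y), "m2": (x, x + 0.01), "r": (x, y)})
        by = {c.pair[0].split(":")[0]: c for c in res}
        assert by["m1"].p_adjusted < 0.001
        assert by["r"].p_adjusted < 0.001

    def test_t_squared_equals_one_way_f(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 20)
        res = bonferroni_t_tests({"m": (x, y)})
        tab = one_way_anova(np.concatenate([x, y]), np.repeat(["x", "y"], 20))
        t = sps.ttest_ind(x, y, equal_var=True)
        assert res[0].p_raw == pytest.approx(float(t.pvalue), rel=1e-12)
        assert float(t.statistic) ** 2 == pytest.approx(tab.loc["group", "F"], rel=1e-10)

    def test_constant_unequal_samples_are_undefined(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = bonferroni_t_tests({"m": (np.full(3, 1.0), np.full(3, 2.0))})
        assert math.isnan(res[0].p_adjusted)
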