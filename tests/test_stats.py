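"""Mann-Whitney exactness, Sidak adjustment, the mixed repeated-measures
ANOVA, baseline-change transform and the a-priori sample size."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from husphen import PowerSpec, change_from_baseline, mann_whitney, sidak
from husphen.errors import (
    DesignError,
    InfeasibilityError,
    MissingDataError,
    ValidationError,
)
from husphen.stats import (
    rm_mixed_anova,
    sample_size_ttest,
    stars,
    wilcoxon_signed_rank,
)


def exhaustive_mw_p(a, b):
    """Oracle: two-sided Mann-Whitney p by enumerating group assignments.

    U is counted directly from pairwise wins (ties count half), without
    ranks, so the oracle is independent of the implementation path.
    """
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(subset):
        g_a = [pooled[i] for i in subset]
        g_b = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in g_a for y in g_b)

    observed = u_of(tuple(range(n_a)))
    dist = [u_of(s) for s in
            itertools.combinations(range(len(pooled)), n_a)]
    lo = sum(u <= observed + 1e-9 for u in dist) / len(dist)
    hi = sum(u >= observed - 1e-9 for u in dist) / len(dist)
    return min(1.0, 2.0 * min(lo, hi))


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.100, abs=1e-12)
        assert res.test_name == "mann-whitney-exact"
        assert res.direction == "a<b"

    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_raw == 1.0 and res.direction == "a=b"

    @pytest.mark.parametrize("n_a, n_b, seed, ties",
                             [(2, 2, 0, False), (3, 4, 1, False),
                              (5, 5, 2, False), (4, 6, 3, True),
                              (3, 3, 4, True), (5, 4, 5, True)])
    def test_exact_p_equals_enumeration_oracle(self, n_a, n_b, seed, ties):
        rng = np.random.default_rng(seed)
        if ties:
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
        else:
            a, b = rng.normal(size=n_a), rng.normal(size=n_b)
        res = mann_whitney(a, b)
        assert res.p_raw == pytest.approx(exhaustive_mw_p(a, b), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        """Exact and scipy asymptotic p agree within 0.02 for 8 vs 8."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(6)
        a, b = rng.normal(size=8), rng.normal(0.8, 1.0, size=8)
        exact = mann_whitney(a, b).p_raw
        approx = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(7)
        res = mann_whitney(rng.normal(size=12), rng.normal(size=12))
        assert res.test_name == "mann-whitney-normal"
        assert 0.0 <= res.p_raw <= 1.0

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1, 2])
        with pytest.raises(ValidationError):
            mann_whitney([1], [1, 2])


class TestSidak:
    @settings(deadline=None, max_examples=100)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 30))
    def test_adjustment_bounds(self, p, m):
        adj = sidak(p, m)
        assert adj >= p - 1e-12
        assert adj <= min(1.0, m * p) + 1e-9   # Sidak <= Bonferroni
        assert 0.0 <= adj <= 1.0

    def test_single_comparison_unchanged(self):
        assert sidak(0.037, 1) == pytest.approx(0.037)


class TestMixedAnova:
    def _long(self, y, groups, times):
        rows = []
        for s, (g, series) in enumerate(zip(groups, y)):
            for t, val in zip(times, series):
                rows.append({"subject": f"s{s}", "diet": g, "age": t,
                             "value": val})
        return pd.DataFrame(rows)

    @staticmethod
    def splitplot_oracle(df):
        """Hand-computed balanced split-plot sums of squares."""
        piv = df.pivot_table(index=["diet", "subject"], columns="age",
                             values="value")
        groups = piv.index.get_level_values(0).to_numpy()
        y = piv.to_numpy()
        n_subj, t = y.shape
        g_levels = sorted(set(groups))
        g = len(g_levels)
        grand = y.mean()
        ss_bsubj = t * ((y.mean(1) - grand) ** 2).sum()
        ss_diet = t * sum((groups == lvl).sum()
                          * (y[groups == lvl].mean() - grand) ** 2
                          for lvl in g_levels)
        ss_serr = ss_bsubj - ss_diet
        ss_age = n_subj * ((y.mean(0) - grand) ** 2).sum()
        ss_cells = sum((groups == lvl).sum()
                       * ((y[groups == lvl].mean(0) - grand) ** 2).sum()
                       for lvl in g_levels)
        ss_int = ss_cells - ss_diet - ss_age
        ss_werr = ((y - grand) ** 2).sum() - ss_bsubj - ss_age - ss_int
        f_diet = (ss_diet / (g - 1)) / (ss_serr / (n_subj - g))
        f_age = (ss_age / (t - 1)) / (ss_werr / ((t - 1) * (n_subj - g)))
        f_int = (ss_int / ((g - 1) * (t - 1))) / (
            ss_werr / ((t - 1) * (n_subj - g)))
        return f_diet, f_age, f_int

    def test_all_equal_values_give_null_result(self):
        df = self._long([[5, 5, 5]] * 8, ["SD"] * 4 + ["WD"] * 4, [8, 16, 24])
        table, post = rm_mixed_anova(df, "value", "age", "subject", "diet")
        assert (table.F == 0).all() and (table.p == 1).all()
        assert (post.p_sidak == 1).all()

    def test_pure_additive_effects_without_noise(self):
        """Noise-free additive diet+age effects: diet p below 1e-12,
        interaction exactly null."""
        times = [8, 16, 24]
        y = [[t * 0.1 for t in times]] * 4 + [[2 + t * 0.1 for t in times]] * 4
        df = self._long(y, ["SD"] * 4 + ["WD"] * 4, times)
        table, _ = rm_mixed_anova(df, "value", "age", "subject", "diet")
        table = table.set_index("effect")
        assert table.loc["diet", "p"] < 1e-12
        assert table.loc["interaction", "F"] == 0.0
        assert table.loc["interaction", "p"] == 1.0

    def test_f_statistics_match_splitplot_oracle(self):
        rng = np.random.default_rng(3)
        times = [8, 16, 24]
        y = rng.normal(size=(12, 3)) + np.array([0, 0.4, 0.9])
        y[6:] += 1.0
        df = self._long(y, ["SD"] * 6 + ["WD"] * 6, times)
        table, _ = rm_mixed_anova(df, "value", "age", "subject", "diet")
        table = table.set_index("effect")
        f_diet, f_age, f_int = self.splitplot_oracle(df)
        assert table.loc["diet", "F"] == pytest.approx(f_diet, rel=1e-6)
        assert table.loc["age", "F"] == pytest.approx(f_age, rel=1e-6)
        assert table.loc["interaction", "F"] == pytest.approx(f_int,
                                                              rel=1e-6)
        # GG-corrected dfs are fractional and bounded by the nominal ones
        assert 1.0 <= table.loc["age", "df1"] <= 2.0

    def test_subject_in_both_diets_rejected(self):
        df = self._long([[1, 2, 3]] * 4, ["SD"] * 2 + ["WD"] * 2, [8, 16, 24])
        df.loc[df.subject == "s0", "subject"] = "s2"
        with pytest.raises(DesignError):
            rm_mixed_anova(df, "value", "age", "subject", "diet")

    def test_incomplete_subjects_dropped_not_fatal(self):
        rng = np.random.default_rng(5)
        times = [8, 16, 24]
        y = rng.normal(size=(10, 3))
        df = self._long(y, ["SD"] * 5 + ["WD"] * 5, times)
        df = df[~((df.subject == "s0") & (df.age == 24))]
        table, post = rm_mixed_anova(df, "value", "age", "subject", "diet")
        assert len(table) == 3 and len(post) == 3

    def test_null_type_one_error_calibrated(self):
        """Null data: the diet-effect rejection rate at alpha 0.05 stays in
        0.05 +/- 0.02 over 1000 seeds (n = 8/group, 3 timepoints)."""
        times = [8, 16, 24]
        groups = ["SD"] * 8 + ["WD"] * 8
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = self._long(rng.normal(size=(16, 3)), groups, times)
            table, _ = rm_mixed_anova(df, "value", "age", "subject", "diet",
                                      posthoc=False)
            hits += table.set_index("effect").loc["diet", "p"] < 0.05
        assert abs(hits / n_seeds - 0.05) <= 0.02


class TestChangeFromBaseline:
    def test_deltas_and_baseline_drop(self):
        df = pd.DataFrame({"subject": "s1", "age": [8, 16, 24],
                           "value": [10.0, 14.0, 13.0]})
        out = change_from_baseline(df, "value", "subject", "age")
        assert out.value.tolist() == [4.0, 3.0]
        assert 8 not in out.age.tolist()

    def test_constant_series_all_zero(self):
        df = pd.DataFrame({"subject": "s1", "age": [8, 16, 24],
                           "value": [7.0, 7.0, 7.0]})
        assert (change_from_baseline(df, "value", "subject",
                                     "age").value == 0).all()

    def test_shift_invariance(self):
        df = pd.DataFrame({"subject": ["a"] * 3 + ["b"] * 3,
                           "age": [8, 16, 24] * 2,
                           "value": [1.0, 2.0, 4.0, 3.0, 5.0, 6.0]})
        shifted = df.copy()
        shifted.loc[shifted.subject == "a", "value"] += 11.0
        pd.testing.assert_frame_equal(
            change_from_baseline(df, "value", "subject", "age"),
            change_from_baseline(shifted, "value", "subject", "age"))

    def test_missing_baseline_rejected(self):
        df = pd.DataFrame({"subject": ["a", "a", "b"], "age": [8, 16, 16],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(MissingDataError, match="b"):
            change_from_baseline(df, "value", "subject", "age")


class TestSampleSize:
    def test_study_specification_gives_seven_and_eight(self):
        n, n_infl = sample_size_ttest(PowerSpec())
        assert (n, n_infl) == (7, 8)

    def test_quadratic_in_sd(self):
        n20, _ = sample_size_ttest(PowerSpec(sd=20.0))
        n40, _ = sample_size_ttest(PowerSpec(sd=40.0))
        assert n40 == 28 and n20 == 7   # 4x before ceiling

    def test_monotone_in_effect_size(self):
        ns = [sample_size_ttest(PowerSpec(mean_test=100.0 - d))[0]
              for d in (10.0, 20.0, 30.0, 50.0)]
        assert ns == sorted(ns, reverse=True)

    def test_monotone_in_power_and_sd(self):
        n_low = sample_size_ttest(PowerSpec(power=0.6))[0]
        n_high = sample_size_ttest(PowerSpec(power=0.95))[0]
        assert n_low <= n_high

    def test_zero_effect_infeasible(self):
        with pytest.raises(InfeasibilityError):
            sample_size_ttest(PowerSpec(mean_test=100.0))


class TestMisc:
    def test_star_thresholds(self):
        assert stars(0.2) == ""
        assert stars(0.03) == "*"
        assert stars(0.004) == "**"
        assert stars(5e-4) == "***"
        assert stars(5e-5) == "****"

    def test_wilcoxon_contract(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 4, 5, 7])
        assert res.p_raw < 0.1 and res.direction == "a<b"
        assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]).p_raw == 1.0
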