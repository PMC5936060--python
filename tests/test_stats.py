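"""Summary statistics, ANOVA family, post-hoc tests, power analysis.

Cross-checks run against scipy / pingouin / statsmodels on raw data and
against Monte-Carlo simulation; the implementation under test works from
(n, mean, sd) summaries.
"""

import math

import numpy as np
import pingouin as pg
import pytest
from scipy import stats as sps

from ishquant.stats import (
    GroupSummary,
    chi_square,
    cohen_d,
    games_howell,
    levene,
    one_way_anova,
    pooled_t_from_summaries,
    power_two_sample_t,
    required_n_two_sample_t,
    sqrt_transform_if_needed,
    summarize,
    tukey_hsd,
    welch_anova,
    welch_t,
)

# Two-group densitometry summaries: control vs morphant scores
# (mean 29 / 37.2, CVs 34% / 26%, n = 16 each).
CONTROL = GroupSummary("control", 16, 29.0, 0.34 * 29.0)
MORPHANT = GroupSummary("morphant", 16, 37.2, 0.26 * 37.2)

# Three-genotype clutch summaries (WT / HET / MUT intensity scores).
CLUTCH = [
    GroupSummary("WT", 32, 54.0, 0.24 * 54.0),
    GroupSummary("HET", 62, 50.1, 0.22 * 50.1),
    GroupSummary("MUT", 36, 26.3, 0.21 * 26.3),
]


class TestSummaries:
    def test_constant_sample(self):
        s = summarize([10, 10, 10], "c")
        assert (s.mean, s.sd, s.cv) == (10.0, 0.0, 0.0)

    def test_cv_definition(self):
        assert CONTROL.cv == pytest.approx(0.34)

    def test_matches_two_pass_loop_oracle(self, rng):
        x = rng.normal(50, 8, size=37)
        s = summarize(x)
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.sd == pytest.approx(math.sqrt(var), rel=1e-12)

    def test_zero_mean_cv_undefined(self):
        assert summarize([-1.0, 1.0]).cv is None


class TestTwoSampleT:
    def test_morphant_comparison_from_printed_summaries(self):
        res = pooled_t_from_summaries(CONTROL, MORPHANT)
        assert abs(res.statistic) == pytest.approx(2.375, abs=0.005)
        assert res.df == 30
        assert res.p_value < 0.05

    def test_identical_groups(self):
        g = GroupSummary("g", 10, 5.0, 1.0)
        res = pooled_t_from_summaries(g, g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pooled_matches_scipy_on_raw_data(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.5, 25)
        res = pooled_t_from_summaries(summarize(a), summarize(b))
        t_ref, p_ref = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_welch_matches_scipy_on_raw_data(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3.0, 12)
        res = welch_t(summarize(a), summarize(b))
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_welch_df_approaches_pooled_for_equal_variances(self):
        a = GroupSummary("a", 15, 10.0, 2.0)
        b = GroupSummary("b", 15, 12.0, 2.0)
        assert welch_t(a, b).df == pytest.approx(28, abs=0.01)

    def test_welch_df_limit_with_one_degenerate_group(self):
        a = GroupSummary("a", 10, 5.0, 0.0)
        b = GroupSummary("b", 21, 6.0, 2.0)
        assert welch_t(a, b).df == pytest.approx(20, abs=1e-9)

    def test_zero_variance_unequal_means_flagged_infinite(self):
        a = GroupSummary("a", 5, 1.0, 0.0)
        b = GroupSummary("b", 5, 2.0, 0.0)
        res = pooled_t_from_summaries(a, b)
        assert math.isinf(res.statistic) and res.note


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = GroupSummary("g", 10, 5.0, 1.0)
        res = one_way_anova([g, g, g])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_standard_f_matches_scipy_on_raw_data(self, rng):
        groups = [rng.normal(m, 2, 15) for m in (0, 1, 3)]
        res = one_way_anova([summarize(g) for g in groups])
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_two_group_equivalences_with_t(self):
        a, b = CONTROL, MORPHANT
        assert welch_anova([a, b]).statistic == pytest.approx(
            welch_t(a, b).statistic ** 2, abs=1e-6
        )
        assert one_way_anova([a, b]).statistic == pytest.approx(
            pooled_t_from_summaries(a, b).statistic ** 2, abs=1e-6
        )

    def test_welch_matches_pingouin_on_raw_data(self, rng):
        import pandas as pd

        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 20), (1, 3, 15), (2, 0.5, 30)]]
        res = welch_anova([summarize(g) for g in groups])
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [20, 15, 30]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(ref["F"][0], rel=1e-6)
        assert res.df[1] == pytest.approx(ref["ddof2"][0], rel=1e-6)
        assert res.p_value == pytest.approx(ref["p_unc"][0], rel=1e-6)

    def test_clutch_summaries_give_large_welch_f(self):
        """Welch F from the three-genotype summaries: order 1e2, df (2, ~70).

        Cross-checked against a direct evaluation of the Welch formula
        written out term by term.
        """
        res = welch_anova(CLUTCH)
        n = np.array([g.n for g in CLUTCH], float)
        m = np.array([g.mean for g in CLUTCH])
        v = np.array([g.sd**2 for g in CLUTCH])
        w = n / v
        mw = (w * m).sum() / w.sum()
        lam = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
        f_ref = ((w * (m - mw) ** 2).sum() / 2) / (1 + 2 * 1 / 8 * lam)
        assert res.statistic == pytest.approx(f_ref, rel=1e-12)
        assert 100 < res.statistic < 200
        assert res.df[0] == 2
        assert 60 < res.df[1] < 80
        assert res.p_value < 1e-10

    def test_welch_rejects_zero_variance_group(self):
        with pytest.raises(ValueError):
            welch_anova([GroupSummary("a", 5, 1.0, 0.0), CONTROL])


class TestLevene:
    def test_all_constant_convention(self):
        res = levene([[5, 5, 5], [7, 7, 7]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_p_values_are_uniform(self):
        """Equal-variance groups: Levene p should be U(0,1) (KS check)."""
        rng = np.random.default_rng(7)
        ps = [
            levene([rng.normal(0, 1, 20) for _ in range(3)]).p_value
            for _ in range(300)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_tenfold_variance_ratio(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            levene([rng.normal(0, 1, 50), rng.normal(0, math.sqrt(10), 50)]).p_value
            < 0.05
            for _ in range(100)
        )
        assert rejections > 90

    def test_median_centering_is_brown_forsythe(self, rng):
        a, b = rng.normal(0, 1, 25), rng.exponential(2, 25)
        res = levene([a, b], center="median")
        w_ref, p_ref = sps.levene(a, b, center="median")
        assert res.statistic == pytest.approx(w_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)


class TestPostHoc:
    def test_studentized_range_critical_value(self):
        """q(0.95; k=3, df=10) = 3.88 from published tables."""
        assert sps.studentized_range.ppf(0.95, 3, 10) == pytest.approx(3.88, abs=0.01)

    def test_games_howell_approaches_tukey_under_homoscedasticity(self, rng):
        # limit agreement: large equal n, equal variances
        groups = [summarize(rng.normal(m, 2, 200), str(m)) for m in (0, 0.2, 0.4)]
        tk = {t.groups: t.p_value for t in tukey_hsd(groups)}
        gh = {t.groups: t.p_value for t in games_howell(groups)}
        for pair in tk:
            assert gh[pair] == pytest.approx(tk[pair], rel=0.10)

    def test_tukey_matches_scipy_on_raw_data(self, rng):
        groups = [rng.normal(m, 2, 20) for m in (0, 1.5, 2)]
        ours = tukey_hsd([summarize(g, str(i)) for i, g in enumerate(groups)])
        ref = sps.tukey_hsd(*groups)
        for t in ours:
            i, j = int(t.groups[0]), int(t.groups[1])
            assert t.p_value == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_games_howell_matches_pingouin_on_raw_data(self, rng):
        import pandas as pd

        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 20), (1, 3, 15), (2.5, 0.5, 25)]]
        ours = {
            t.groups: t for t in games_howell(
                [summarize(g, lab) for g, lab in zip(groups, "abc")]
            )
        }
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [20, 15, 25]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for _, row in ref.iterrows():
            t = ours[(row["A"], row["B"])]
            assert t.df == pytest.approx(row["df"], rel=1e-6)
            assert t.p_value == pytest.approx(row["pval"], abs=1e-6)

    def test_clutch_posthoc_structure(self):
        """Mutant contrasts overwhelmingly significant, WT-HET not."""
        res = {t.groups: t.p_value for t in games_howell(CLUTCH)}
        assert res[("WT", "MUT")] < 0.001
        assert res[("HET", "MUT")] < 0.001
        assert res[("WT", "HET")] > 0.05


class TestChiSquare:
    def test_uniform_table_has_zero_statistic(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_pearson_2x2(self):
        # [[20,5],[5,20]]: expected all 12.5, chi2 = 4 * 7.5^2/12.5 = 18
        res = chi_square([[20, 5], [5, 20]], continuity_correction=False)
        assert res.statistic == pytest.approx(18.0, abs=1e-9)
        assert res.df == 1

    def test_yates_correction_shrinks_statistic(self):
        plain = chi_square([[20, 5], [5, 20]], continuity_correction=False)
        yates = chi_square([[20, 5], [5, 20]], continuity_correction=True)
        assert yates.statistic < plain.statistic
        assert "Yates" in yates.note

    def test_correction_ignored_for_larger_tables(self):
        res = chi_square([[10, 5, 3], [2, 8, 9]], continuity_correction=True)
        assert res.df == 2 and "Yates" not in res.note

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestSqrtTransform:
    def test_normal_samples_mostly_untouched(self):
        untransformed = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(50, 5, 100)
            _, applied, _ = sqrt_transform_if_needed(x)
            untransformed += not applied
        assert untransformed >= 18  # >= 90% of replicates

    def test_skewed_sample_transformed(self):
        x = np.random.default_rng(0).normal(3, 1, 200) ** 2
        out, applied, _ = sqrt_transform_if_needed(x)
        assert applied
        np.testing.assert_allclose(out**2, x)

    def test_negative_scores_block_transform(self):
        x = np.concatenate(
            [np.random.default_rng(0).normal(2, 1, 100) ** 2, [-1.0]]
        )
        out, applied, why = sqrt_transform_if_needed(x)
        assert not applied and "negative" in why
        np.testing.assert_array_equal(out, x)


class TestPower:
    D = cohen_d(CONTROL, MORPHANT)

    def test_cohen_d_value(self):
        assert self.D == pytest.approx(0.84, abs=0.005)

    def test_cohen_d_properties(self):
        g = GroupSummary("g", 10, 5.0, 1.0)
        assert cohen_d(g, g) == 0.0
        a = GroupSummary("a", 10, 0.0, 2.0)
        b = GroupSummary("b", 10, 1.0, 2.0)
        a2 = GroupSummary("a", 10, 0.0, 4.0)
        b2 = GroupSummary("b", 10, 1.0, 4.0)
        assert cohen_d(a2, b2) == pytest.approx(cohen_d(a, b) / 2, rel=1e-12)

    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample_t(0.0, 20, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_posthoc_power_of_morphant_experiment(self):
        assert power_two_sample_t(self.D, 16) == pytest.approx(0.63, abs=0.01)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d, n in [(0.3, 20), (0.84, 16), (1.2, 8)]:
            ref = TTestIndPower().power(d, n, 0.05, ratio=1.0)
            assert power_two_sample_t(d, n) == pytest.approx(ref, abs=1e-6)

    def test_matches_monte_carlo_rejection_rate(self):
        """Simulated two-sample experiments as an independent oracle."""
        rng = np.random.default_rng(99)
        d, n, reps = 0.7, 12, 200_000
        a = rng.normal(0, 1, (reps, n))
        b = rng.normal(d, 1, (reps, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        sp2 = (va + vb) / 2
        t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
        tc = sps.t.ppf(0.975, 2 * n - 2)
        mc = (np.abs(t) > tc).mean()
        se = math.sqrt(mc * (1 - mc) / reps)
        assert power_two_sample_t(d, n) == pytest.approx(mc, abs=max(3 * se, 0.005))

    def test_required_n_for_90_percent_power(self):
        assert required_n_two_sample_t(self.D, 0.90) == 31

    def test_required_n_minimality_and_round_trip(self):
        for d, p in [(0.5, 0.8), (0.84, 0.9), (1.1, 0.95)]:
            n = required_n_two_sample_t(d, p)
            assert power_two_sample_t(d, n) >= p
            assert n == 2 or power_two_sample_t(d, n - 1) < p

    def test_inverse_square_scaling_in_effect_size(self):
        n1 = required_n_two_sample_t(0.4, 0.9)
        n2 = required_n_two_sample_t(0.8, 0.9)
        assert n1 / n2 == pytest.approx(4, rel=0.15)

    def test_power_monotone_in_n_and_d(self):
        ns = [power_two_sample_t(0.5, n) for n in range(5, 40, 5)]
        ds = [power_two_sample_t(d, 20) for d in np.linspace(0.1, 1.5, 8)]
        assert all(a < b for a, b in zip(ns, ns[1:]))
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_zero_effect_has_no_finite_n(self):
        with pytest.raises(ValueError):
            required_n_two_sample_t(0.0, 0.9)
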