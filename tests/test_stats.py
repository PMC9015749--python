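import math

import numpy as np
import pytest
import scipy.stats as sps
from _oracles import realize_summary

from homesense import stats
from homesense.errors import DataError


class TestLevene:
    def test_identical_groups_w_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = stats.levene([g, list(g)])
        assert res.W == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_location_shift_invariance(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 2, 25)
        res1 = stats.levene([a, b])
        res2 = stats.levene([a + 100.0, b])
        assert res1.W == pytest.approx(res2.W, rel=1e-10)

    def test_manual_formula_oracle(self):
        # classic Levene W computed by hand from the definition
        groups = [[12.0, 15.0, 11.0, 19.0, 13.0], [24.0, 18.0, 22.0, 30.0, 27.0]]
        z = [np.abs(np.array(g) - np.mean(g)) for g in groups]
        N = sum(len(g) for g in groups)
        k = len(groups)
        zbar = np.concatenate(z).mean()
        num = sum(len(zi) * (zi.mean() - zbar) ** 2 for zi in z) / (k - 1)
        den = sum(((zi - zi.mean()) ** 2).sum() for zi in z) / (N - k)
        expected_w = num / den
        res = stats.levene(groups, center="mean")
        assert res.W == pytest.approx(expected_w, rel=1e-12)
        assert res.p == pytest.approx(sps.f.sf(expected_w, k - 1, N - k), rel=1e-12)

    def test_median_center_variant(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 3, 20)
        assert stats.levene([a, b], center="median").W != pytest.approx(
            stats.levene([a, b], center="mean").W
        )

    def test_degenerate_group_errors(self):
        with pytest.raises(DataError):
            stats.levene([[1.0], [2.0, 3.0]])
        with pytest.raises(DataError):
            stats.levene([[5.0, 5.0], [5.0, 5.0]])


class TestAnovaOneway:
    def test_equal_means_f_zero(self):
        res = stats.anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_unit_rescaling_invariance(self, rng):
        groups = [rng.normal(480, 60, 20), rng.normal(450, 55, 25), rng.normal(500, 70, 22)]
        res_min = stats.anova_oneway(groups)
        res_hr = stats.anova_oneway([g / 60.0 for g in groups])
        assert res_min.F == pytest.approx(res_hr.F, rel=1e-10)
        assert res_min.ss_between == pytest.approx(res_hr.ss_between * 3600.0, rel=1e-10)

    def test_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 18), rng.normal(0.5, 1, 23)
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        res = stats.anova_oneway([a, b])
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0.3, 1, 12), rng.normal(-0.2, 1, 19)]
        F, p = sps.f_oneway(*groups)
        res = stats.anova_oneway(groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_degenerate_errors(self):
        with pytest.raises(DataError):
            stats.anova_oneway([[1.0, 1.0], [1.0, 1.0]])  # zero within variance
        with pytest.raises(DataError):
            stats.anova_oneway([[1.0, 2.0]])


class TestAnovaFromSummary:
    def test_two_identical_summaries_f_zero(self):
        s = [stats.GroupSummary("a", 10, 5.0, 1.0), stats.GroupSummary("b", 10, 5.0, 1.0)]
        assert stats.anova_oneway_from_summary(s).F == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_raw_construction(self, rng):
        # construction oracle: raw groups realizing the summaries exactly
        specs = [("a", 21, 480.0, 60.0), ("b", 34, 455.0, 48.0), ("c", 27, 512.0, 75.0)]
        raw = [realize_summary(n, m, s, rng) for _, n, m, s in specs]
        summaries = [stats.summarize(lab, g) for (lab, *_), g in zip(specs, raw)]
        res_raw = stats.anova_oneway(raw)
        res_sum = stats.anova_oneway_from_summary(summaries)
        assert res_sum.F == pytest.approx(res_raw.F, rel=1e-9)
        assert res_sum.ss_between == pytest.approx(res_raw.ss_between, rel=1e-9)
        assert res_sum.ss_within == pytest.approx(res_raw.ss_within, rel=1e-9)

    def test_summary_validation(self):
        with pytest.raises(DataError):
            stats.GroupSummary("a", 1, 0.0, 1.0)
        with pytest.raises(DataError):
            stats.GroupSummary("a", 5, 0.0, -1.0)
        with pytest.raises(DataError):
            stats.anova_oneway_from_summary([stats.GroupSummary("a", 5, 0.0, 1.0)])


class TestAnovaTwowayAdditive:
    def test_balanced_type2_equals_type1(self, rng):
        # balanced-design identity: Type II == sequential SS
        levels_a, levels_b, reps = ["a1", "a2", "a3"], ["b1", "b2"], 6
        fa, fb, y = [], [], []
        effects_a = {"a1": 0.0, "a2": 1.0, "a3": -0.5}
        effects_b = {"b1": 0.0, "b2": 2.0}
        for la in levels_a:
            for lb in levels_b:
                for _ in range(reps):
                    fa.append(la)
                    fb.append(lb)
                    y.append(effects_a[la] + effects_b[lb] + rng.normal())
        y = np.array(y)
        res = stats.anova_twoway_additive(y, fa, fb)
        # sequential (Type I) SS, A first then B
        ones = np.ones((len(y), 1))
        da = np.array([[la == "a2", la == "a3"] for la in fa], dtype=float)
        db = np.array([[lb == "b2"] for lb in fb], dtype=float)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        ss_a_seq = rss(ones) - rss(np.hstack([ones, da]))
        ss_b_seq = rss(np.hstack([ones, da])) - rss(np.hstack([ones, da, db]))
        assert res["A"].ss_between == pytest.approx(ss_a_seq, rel=1e-9)
        assert res["B"].ss_between == pytest.approx(ss_b_seq, rel=1e-9)

    def test_unbalanced_matches_statsmodels(self, rng):
        statsmodels_api = pytest.importorskip("statsmodels.api")
        import pandas as pd
        from statsmodels.formula.api import ols

        n_per = {("a1", "b1"): 7, ("a1", "b2"): 3, ("a2", "b1"): 4, ("a2", "b2"): 9, ("a3", "b1"): 5, ("a3", "b2"): 6}
        rows = []
        for (la, lb), n in n_per.items():
            for _ in range(n):
                rows.append({"A": la, "B": lb, "y": rng.normal(loc=(la == "a2") + 2 * (lb == "b2"))})
        df = pd.DataFrame(rows)
        res = stats.anova_twoway_additive(df["y"], df["A"], df["B"])
        model = ols("y ~ C(A) + C(B)", data=df).fit()
        table = statsmodels_api.stats.anova_lm(model, typ=2)
        assert res["A"].ss_between == pytest.approx(table.loc["C(A)", "sum_sq"], rel=1e-8)
        assert res["B"].ss_between == pytest.approx(table.loc["C(B)", "sum_sq"], rel=1e-8)
        assert res["A"].ss_within == pytest.approx(table.loc["Residual", "sum_sq"], rel=1e-8)
        assert res["A"].F == pytest.approx(table.loc["C(A)", "F"], rel=1e-8)
        assert res["A"].df_within == int(table.loc["Residual", "df"])

    def test_null_factor_rejection_rate(self):
        # simulation oracle: factor B has no effect; its F should exceed the
        # 5% critical value about 5% of the time
        rng = np.random.default_rng(99)
        n_sims, rejections = 500, 0
        fa = ["a1"] * 10 + ["a2"] * 10 + ["a3"] * 10
        fb = (["b1", "b2"] * 15)[:30]
        eff = np.array([0.0] * 10 + [1.5] * 10 + [-1.0] * 10)
        crit = sps.f.isf(0.05, 1, 30 - 1 - 2 - 1)
        for _ in range(n_sims):
            y = eff + rng.normal(size=30)
            if stats.anova_twoway_additive(y, fa, fb)["B"].F > crit:
                rejections += 1
        # binomial 95% band around 0.05 with n=500
        assert 0.03 <= rejections / n_sims <= 0.08

    def test_rank_deficiency_errors(self):
        # factors perfectly confounded
        fa = ["a1", "a1", "a2", "a2"]
        fb = ["b1", "b1", "b2", "b2"]
        with pytest.raises(DataError):
            stats.anova_twoway_additive([1.0, 2.0, 3.0, 4.0], fa, fb)


class TestTukeyKramer:
    def test_equal_means_q_zero_p_one(self):
        s = [stats.GroupSummary("a", 10, 5.0, 1.0), stats.GroupSummary("b", 12, 5.0, 1.2)]
        pair = stats.tukey_kramer(s)[0]
        assert pair.q == 0.0
        assert pair.p_adj == pytest.approx(1.0)

    def test_equal_n_reduces_to_classic(self):
        s = [stats.GroupSummary("a", 20, 1.0, 1.0), stats.GroupSummary("b", 20, 2.0, 1.0)]
        pair = stats.tukey_kramer(s, ms_within=1.0, df_within=38)[0]
        assert pair.se == pytest.approx(math.sqrt(1.0 / 20))
        assert pair.q == pytest.approx(1.0 / math.sqrt(1.0 / 20))

    def test_q_symmetric_in_pair(self):
        s1 = stats.GroupSummary("a", 15, 3.0, 1.0)
        s2 = stats.GroupSummary("b", 25, 7.0, 2.0)
        q12 = stats.tukey_kramer([s1, s2], ms_within=2.0, df_within=38)[0].q
        q21 = stats.tukey_kramer([s2, s1], ms_within=2.0, df_within=38)[0].q
        assert q12 == pytest.approx(q21)

    def test_p_monotone_decreasing_in_q(self):
        qs = np.array([0.5, 1.5, 3.0, 5.0])
        ps = sps.studentized_range.sf(qs, 4, 100)
        base = [
            stats.GroupSummary("a", 10, 0.0, 1.0),
            stats.GroupSummary("b", 10, 0.0, 1.0),
        ]
        computed = []
        for q in qs:
            shifted = [base[0], stats.GroupSummary("b", 10, q * math.sqrt(1.0 / 10), 1.0)]
            computed.append(stats.tukey_kramer(shifted, ms_within=1.0, df_within=100)[0].p_adj)
        assert all(computed[i] > computed[i + 1] for i in range(len(qs) - 1))
        assert computed == pytest.approx(list(sps.studentized_range.sf(qs, 2, 100)), rel=1e-6)
        assert list(ps) == sorted(ps, reverse=True)

    def test_ci_symmetric_about_diff(self):
        s = [stats.GroupSummary("a", 9, 10.0, 2.0), stats.GroupSummary("b", 14, 6.0, 2.5)]
        pair = stats.tukey_kramer(s)[0]
        assert (pair.ci_low + pair.ci_high) / 2 == pytest.approx(pair.diff, rel=1e-9)

    def test_raw_route_consistent_with_summary_route(self, rng):
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0.8, 1, 17),
            "c": rng.normal(-0.3, 1, 14),
        }
        raw_pairs = stats.tukey_kramer_raw(groups)
        an = stats.anova_oneway(list(groups.values()))
        sum_pairs = stats.tukey_kramer(
            [stats.summarize(k, v) for k, v in groups.items()], an.ms_within, an.df_within
        )
        for rp, sp in zip(raw_pairs, sum_pairs):
            assert rp.q == pytest.approx(sp.q, rel=1e-9)
            assert rp.diff == pytest.approx(sp.diff, rel=1e-9)


class TestGrandWeightedMean:
    def test_single_group(self):
        assert stats.grand_weighted_mean([stats.GroupSummary("a", 5, 3.3, 1.0)]) == 3.3

    def test_weighted(self):
        s = [stats.GroupSummary("a", 2, 0.0, 1.0), stats.GroupSummary("b", 6, 4.0, 1.0)]
        assert stats.grand_weighted_mean(s) == pytest.approx(3.0)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            stats.grand_weighted_mean([])
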