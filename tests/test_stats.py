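"""Group statistics: sums-of-squares and quadrature oracles, calibration."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from bodymeta import (bayes_t_one_sample, bf_oneway_rm, mixed_anova_gg,
                      nonparametric_tests, rm_anova_gg, sequential_bf)
from bodymeta.design import ValidationError
from bodymeta.sdt import EstimationError
from bodymeta.stats import cohen_d, t_one_sample


def rouder_bf_oracle(t, n, rscale):
    """Independent JZS BF10 via the g-integral formulation."""
    nu = n - 1

    def integrand(g):
        return ((1 + n * g) ** -0.5
                * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
                * (rscale ** 2 / 2) ** 0.5 / np.sqrt(np.pi)
                * g ** -1.5 * np.exp(-rscale ** 2 / (2 * g)))

    num, _ = quad(integrand, 0, np.inf, limit=400)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den


class TestRMAnova:
    def test_null_data_give_zero_F(self):
        x = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        res = rm_anova_gg(x)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_two_conditions_epsilon_is_one(self, rng):
        res = rm_anova_gg(rng.normal(0, 1, (10, 2)))
        assert res.gg_epsilon == 1.0
        assert not res.corrected

    def test_matches_direct_sums_of_squares(self, rng):
        x = rng.normal(0, 1, (14, 5)) + rng.normal(0, 0.5, (14, 1))
        res = rm_anova_gg(x)
        n, k = x.shape
        # brute-force oracle over cell deviations
        gm = x.mean()
        ss_c = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
        ss_s = sum(k * (x[i].mean() - gm) ** 2 for i in range(n))
        ss_e = sum((x[i, j] - x[:, j].mean() - x[i].mean() + gm) ** 2
                   for i in range(n) for j in range(k))
        F = (ss_c / (k - 1)) / (ss_e / ((n - 1) * (k - 1)))
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.eta_p_sq == pytest.approx(ss_c / (ss_c + ss_e), abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        x = rng.normal(0, 1, (12, 4)) + np.array([0, .2, .4, .3])
        res = rm_anova_gg(x)
        df = pd.DataFrame(x).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y")
        aov = pg.rm_anova(data=df, dv="y", within="cond", subject="index",
                          correction=True, effsize="np2").iloc[0]
        assert res.F == pytest.approx(aov["F"], abs=1e-8)
        assert res.gg_epsilon == pytest.approx(aov["eps"], abs=1e-8)
        assert res.eta_p_sq == pytest.approx(aov["np2"], abs=1e-8)
        assert res.p == pytest.approx(aov["p_GG_corr"], abs=1e-8)

    def test_missing_cells_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            rm_anova_gg(x)


class TestMixedAnova:
    def test_between_effect_detected(self, rng):
        g1 = rng.normal(1.0, 1, (16, 4))
        g2 = rng.normal(0.0, 1, (16, 4))
        res = mixed_anova_gg({"a": g1, "b": g2})
        assert res["between"].p < 0.05
        assert set(res) == {"between", "within", "interaction"}

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        g1 = rng.normal(0.5, 1, (10, 3)) + np.array([0, .3, .6])
        g2 = rng.normal(0.0, 1, (12, 3)) + np.array([0, .3, .6])
        res = mixed_anova_gg({"a": g1, "b": g2})
        rows = []
        for gname, mat in (("a", g1), ("b", g2)):
            for i, row in enumerate(mat):
                for j, v in enumerate(row):
                    rows.append({"group": gname, "subject": f"{gname}{i}",
                                 "cond": j, "y": v})
        df = pd.DataFrame(rows)
        aov = pg.mixed_anova(data=df, dv="y", within="cond",
                             subject="subject", between="group")
        pg_between = aov[aov.Source == "group"].iloc[0]
        pg_within = aov[aov.Source == "cond"].iloc[0]
        pg_inter = aov[aov.Source == "Interaction"].iloc[0]
        assert res["between"].F == pytest.approx(pg_between["F"], abs=1e-8)
        assert res["within"].F == pytest.approx(pg_within["F"], abs=1e-8)
        assert res["interaction"].F == pytest.approx(pg_inter["F"], abs=1e-8)


class TestBayesT:
    def test_null_t_favours_null(self, rng):
        x = rng.normal(0, 1, 32)
        x = x - x.mean()  # force t = 0
        res = bayes_t_one_sample(x)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.bf10 < 1.0

    @pytest.mark.parametrize("t,n,r", [(2.3, 24, 0.707), (-1.1, 40, 0.5),
                                       (4.2, 12, 1.0), (0.3, 60, 0.707)])
    def test_matches_quadrature_oracle(self, t, n, r):
        # build data with this exact t statistic
        x = np.zeros(n)
        x[0], x[1] = 1.0, -1.0
        x = x / x.std(ddof=1)
        x = x + t / np.sqrt(n)
        tt, _ = t_one_sample(x)
        assert tt == pytest.approx(t, abs=1e-10)
        res = bayes_t_one_sample(x, rscale=r)
        oracle = rouder_bf_oracle(t, n, r)
        assert res.bf10 == pytest.approx(oracle, rel=1e-4)

    def test_prior_collapse_gives_unit_bf(self, rng):
        x = rng.normal(0.3, 1, 20)
        res = bayes_t_one_sample(x, rscale=1e-4)
        assert res.bf10 == pytest.approx(1.0, abs=1e-3)

    def test_directional_bf_concentrates_for_positive_mean(self, rng):
        x = np.abs(rng.normal(0.8, 0.5, 25))
        res = bayes_t_one_sample(x, direction="positive")
        assert res.bf_plus0 > res.bf10  # half-prior mass on the right sign
        assert res.bf_plus0 >= res.bf10 / 2

    def test_frequentist_parts_match_direct_formulas(self, rng):
        x = rng.normal(0.4, 1.3, 18)
        t, p = t_one_sample(x)
        t_direct = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert t == pytest.approx(t_direct, abs=1e-10)
        assert cohen_d(x) == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-10)

    def test_one_sided_type_one_error_calibrated(self, rng):
        n, reps = 16, 10_000
        x = rng.normal(0, 1, (reps, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        p = sps.t.sf(t, n - 1)
        rate = float((p < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            bayes_t_one_sample(np.ones(10))

    def test_sequential_is_thin_loop(self, rng):
        x = rng.normal(0.5, 1, 10)
        seq = sequential_bf(x, min_n=3)
        assert list(seq["n"]) == list(range(3, 11))
        final = bayes_t_one_sample(x, direction="positive")
        assert seq["bf_plus0"].iloc[-1] == pytest.approx(final.bf_plus0, rel=1e-9)


class TestBFOnewayRM:
    def test_strong_effect_crushes_null(self, rng):
        x = rng.normal(0, 0.3, (16, 3)) + np.array([0, 1.0, 2.0])
        assert bf_oneway_rm(x, seed=1) < 1e-6

    def test_null_data_favour_null(self):
        bfs = [bf_oneway_rm(np.random.default_rng(s).normal(0, 1, (16, 5)),
                            seed=s) for s in range(20)]
        assert np.median(bfs) > 1.0

    def test_monte_carlo_integration_stable(self):
        x = np.random.default_rng(9).normal(0, 1, (16, 5))
        b1 = bf_oneway_rm(x, n_mc=20_000, seed=3)
        b2 = bf_oneway_rm(x, n_mc=40_000, seed=4)
        assert abs(np.log(b1) - np.log(b2)) < 0.05

    def test_matches_dense_marginal_oracle(self):
        # same g draws through the generic linear-algebra marginal
        from bodymeta.stats import (_marginal_loglik, _orthonormal_contrasts)
        x = np.random.default_rng(5).normal(0, 1, (8, 3))
        n, k = x.shape
        y = x.ravel() - x.mean()
        Zs = np.kron(_orthonormal_contrasts(n), np.ones((k, 1)))
        Zc = np.kron(np.ones((n, 1)), _orthonormal_contrasts(k))
        rng = np.random.default_rng(0)
        gs = 1.0 / (2.0 * rng.gamma(0.5, 1.0, 400))
        gc = 0.25 / (2.0 * rng.gamma(0.5, 1.0, 400))
        Xf = np.hstack([Zs, Zc])

        def logmean(v):
            m = v.max()
            return m + np.log(np.mean(np.exp(v - m)))

        lln = np.array([_marginal_loglik(y, Zs, np.full(n - 1, g)) for g in gs])
        llf = np.array([_marginal_loglik(
            y, Xf, np.concatenate([np.full(n - 1, g1), np.full(k - 1, g2)]))
            for g1, g2 in zip(gs, gc)])
        oracle = np.exp(logmean(lln) - logmean(llf))
        mine = bf_oneway_rm(x, n_mc=100_000, seed=11)
        assert np.log(mine) == pytest.approx(np.log(oracle), abs=0.1)

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            bf_oneway_rm(np.ones((10, 1)))


class TestNonparametric:
    def test_identical_groups_give_zero_H(self):
        g = {"a": np.arange(10.0), "b": np.arange(10.0)}
        tab = nonparametric_tests(g)
        h = tab[tab.test == "kruskal_wallis"].statistic.iloc[0]
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_matches_rank_formula(self, rng):
        # no ties: distinct values
        vals = rng.permutation(np.arange(60, dtype=float))
        groups = {"a": vals[:20], "b": vals[20:45], "c": vals[45:]}
        tab = nonparametric_tests(groups)
        h = tab[tab.test == "kruskal_wallis"].statistic.iloc[0]
        allv = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(allv)
        n = allv.size
        start = 0
        s = 0.0
        for g in groups.values():
            r = ranks[start:start + g.size]
            s += r.sum() ** 2 / g.size
            start += g.size
        h_direct = 12.0 / (n * (n + 1)) * s - 3 * (n + 1)
        assert h == pytest.approx(h_direct, abs=1e-8)

    def test_ks_calibrated_on_normal_samples(self):
        ok = 0
        for s in range(20):
            x = np.random.default_rng(1000 + s).normal(0, 1, 10_000)
            tab = nonparametric_tests({"a": x, "b": x + 0.0})
            p = tab[tab.test == "ks_normality"].p.iloc[0]
            ok += p > 0.01
        assert ok >= 19

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            nonparametric_tests({"a": [1.0], "b": [1.0, 2.0]})
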