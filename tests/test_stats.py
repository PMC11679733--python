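"""Inferential stage: normality, mixed ANOVA vs GLM oracle, JZS BF, power."""

import numpy as np
import pytest

from affectflex import stats
from affectflex.errors import (
    DegenerateInputError,
    DesignError,
    InvalidParameterError,
    MissingDataError,
)

from conftest import glm_mixed_anova_oracle


class TestNormalityTests:
    def test_null_retention_rate(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 500)
            hits += stats.normality_tests(x)["shapiro_p"] > 0.05
        assert hits >= 90

    def test_power_against_exponential(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(1.0, 500)
            hits += stats.normality_tests(x)["shapiro_p"] < 0.01
        assert hits >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            stats.normality_tests(np.full(30, 2.0))

    def test_statistics_in_unit_interval(self):
        out = stats.normality_tests(np.random.default_rng(0).normal(0, 1, 50))
        for key in ("shapiro_W", "shapiro_p", "ks_D", "ks_p"):
            assert 0.0 <= out[key] <= 1.0


class TestMixedAnova:
    def test_published_group_sizes_give_df_41(self):
        rng = np.random.default_rng(0)
        g = np.array(["Average"] * 23 + ["Extreme"] * 20)
        res = stats.mixed_anova_2x2(rng.normal(size=43), rng.normal(size=43), g)
        for eff in res.effects.values():
            assert (eff.df1, eff.df2) == (1, 41)

    def test_no_change_gives_zero_time_and_interaction(self):
        rng = np.random.default_rng(1)
        y0 = rng.normal(size=12)
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = stats.mixed_anova_2x2(y0, y0.copy(), g)
        assert res.time.F == 0.0
        assert res.interaction.F == 0.0

    def test_matches_glm_oracle(self):
        """Means/differences decomposition equals the design-matrix GLM."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(2, 30))
            n2 = int(rng.integers(2, 30))
            g = np.array(["A"] * n1 + ["B"] * n2)
            y0 = rng.normal(0, 1, n1 + n2)
            y1 = rng.normal(0.3, 1.2, n1 + n2) + 0.5 * (g == "B")
            res = stats.mixed_anova_2x2(y0, y1, g)
            f_time, f_group, f_inter = glm_mixed_anova_oracle(y0, y1, g)
            assert res.time.F == pytest.approx(f_time, rel=1e-8, abs=1e-10)
            assert res.group.F == pytest.approx(f_group, rel=1e-8, abs=1e-10)
            assert res.interaction.F == pytest.approx(f_inter, rel=1e-8,
                                                      abs=1e-10)

    def test_group_and_interaction_match_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        g = np.array(["Average"] * 23 + ["Extreme"] * 20)
        y0 = rng.normal(50, 10, 43)
        y1 = y0 + rng.normal(5, 8, 43) + 4 * (g == "Extreme")
        res = stats.mixed_anova_2x2(y0, y1, g)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(43), 2),
                "time": np.repeat(["T0", "T1"], 43),
                "group": np.tile(g, 2),
                "y": np.concatenate([y0, y1]),
            }
        )
        aov = pg.mixed_anova(df, dv="y", within="time", between="group",
                             subject="subject").set_index("Source")
        assert res.group.F == pytest.approx(float(aov.loc["group", "F"]),
                                            rel=1e-9)
        assert res.interaction.F == pytest.approx(
            float(aov.loc["Interaction", "F"]), rel=1e-9
        )

    def test_interaction_type_i_error_calibrated(self):
        """Under the null the interaction rejects at ~alpha."""
        rng = np.random.default_rng(2024)
        g = np.array(["a"] * 12 + ["b"] * 10)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            y0 = rng.normal(0, 1, 22)
            y1 = 0.5 * y0 + rng.normal(0, 1, 22)  # correlated, no effects
            res = stats.mixed_anova_2x2(y0, y1, g)
            rejections += res.interaction.p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_small_group_rejected(self):
        g = np.array(["a", "a", "a", "b"])
        with pytest.raises(DesignError):
            stats.mixed_anova_2x2(np.zeros(4), np.ones(4), g)

    def test_missing_values_require_listwise(self):
        g = np.array(["a"] * 3 + ["b"] * 3)
        y0 = np.array([1.0, 2.0, np.nan, 3.0, 4.0, 5.0])
        y1 = np.arange(6, dtype=float)
        with pytest.raises(MissingDataError):
            stats.mixed_anova_2x2(y0, y1, g)
        res = stats.mixed_anova_2x2(y0, y1, g, listwise=True)
        assert sum(res.n_by_group.values()) == 5


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "f,expected",
        [(4.92, 0.107), (6.630, 0.139), (4.46, 0.098), (6.140, 0.130)],
    )
    def test_published_identities(self, f, expected):
        assert round(stats.partial_eta_sq(f, 1, 41), 3) == expected

    def test_zero_f(self):
        assert stats.partial_eta_sq(0.0, 1, 41) == 0.0

    def test_negative_f_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.partial_eta_sq(-1.0, 1, 41)


class TestJzsBayesFactor:
    def test_identical_samples_favor_null(self):
        x = np.random.default_rng(0).normal(0, 1, 20)
        bf = stats.jzs_ttest_bf(x, x.copy())
        assert bf.t == pytest.approx(0.0)
        assert bf.bf01 > 1.0
        assert bf.bf01 * bf.bf10 == pytest.approx(1.0, rel=1e-9)

    def test_large_separation_overwhelms_null(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        y = rng.normal(3, 1, 20)  # ~3 pooled SDs apart
        assert stats.jzs_ttest_bf(x, y).bf10 > 100.0

    def test_monotone_in_t(self):
        """BF10 grows with |t| at fixed n (grid over synthetic t values)."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        x = (x - x.mean()) / x.std(ddof=1)
        bfs = []
        for shift in (0.0, 0.3, 0.6, 1.0, 1.5, 2.5):
            bfs.append(stats.jzs_ttest_bf(x + shift, x.copy()).bf10)
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_monte_carlo_integral(self):
        """Quadrature agrees with Monte-Carlo marginalization over g."""
        from scipy.stats import invgamma

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.7, 1, 20)
        bf = stats.jzs_ttest_bf(x, y)
        t, nu = bf.t, bf.df
        neff = 10.0
        r2 = bf.prior_scale**2
        g = invgamma.rvs(0.5, scale=r2 / 2.0, size=400_000,
                         random_state=np.random.default_rng(9))
        c = 1.0 + neff * g
        log_m1 = -0.5 * np.log(c) - (nu + 1) / 2 * np.log1p(t * t / (c * nu))
        log_m0 = -(nu + 1) / 2 * np.log1p(t * t / nu)
        mc = float(np.mean(np.exp(log_m1 - log_m0)))
        assert bf.bf10 == pytest.approx(mc, rel=0.03)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 18)
        y = rng.normal(0.5, 1.3, 25)
        bf = stats.jzs_ttest_bf(x, y)
        ref = float(pg.bayesfactor_ttest(bf.t, 18, 25, paired=False,
                                         r=bf.prior_scale))
        assert bf.bf10 == pytest.approx(ref, rel=1e-6)

    def test_null_simulation_favors_null_on_median(self):
        bf01s = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 20)
            y = rng.normal(0, 1, 20)
            bf01s.append(stats.jzs_ttest_bf(x, y).bf01)
        assert np.median(bf01s) > 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            stats.jzs_ttest_bf(np.full(5, 1.0), np.full(5, 1.0))


class TestSeOfMean:
    @pytest.mark.parametrize(
        "sd,n,expected",
        [(27.64, 23, 5.76), (18.79, 20, 4.20), (0.0, 10, 0.0)],
    )
    def test_published_table_values(self, sd, n, expected):
        assert round(stats.se_of_mean(sd, n), 2) == expected

    def test_invalid_n(self):
        with pytest.raises(InvalidParameterError):
            stats.se_of_mean(1.0, 0)


class TestRequiredN:
    def test_monotone_in_effect_size(self):
        assert stats.required_n_interaction(0.25) > stats.required_n_interaction(0.30)

    def test_matches_brute_force_sweep(self):
        """Closed procedure equals an exhaustive N sweep of noncentral-F power."""
        from scipy.stats import f as fdist
        from scipy.stats import ncf

        def sweep(f_eff, alpha, power, g=2, m=2, rho=0.5):
            n = g * 2
            while True:
                lam = n * f_eff**2 * m / (1 - rho)
                crit = fdist.ppf(1 - alpha, (g - 1) * (m - 1), (n - g) * (m - 1))
                if ncf.sf(crit, (g - 1) * (m - 1), (n - g) * (m - 1), lam) >= power:
                    return n
                n += g

        for f_eff, alpha, power in [(0.30, 0.05, 0.95), (0.25, 0.05, 0.80),
                                     (0.40, 0.01, 0.90)]:
            assert stats.required_n_interaction(f_eff, alpha, power) == sweep(
                f_eff, alpha, power
            )

    def test_minimality(self):
        n = stats.required_n_interaction(0.30, 0.05, 0.95)
        assert stats.interaction_power(n, 0.30, 0.05) >= 0.95
        assert stats.interaction_power(n - 2, 0.30, 0.05) < 0.95

    def test_infeasible_power_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.required_n_interaction(0.30, power=1.0)


class TestEffectDetection:
    def test_lfhf_interaction_detected_on_calibrated_cohorts(self):
        """Default cohorts carry a detectable LF/HF time-by-group interaction."""
        from affectflex import indices as ix
        from affectflex import synthcohort as sc

        cfg = ix.HrvConfig()
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            cohort = sc.gen_cohort(sc.CohortSpec(seed=50_000 + rep))
            y0, y1, grp = [], [], []
            for s in cohort.subjects:
                y0.append(ix.compute_all(s.rr_t0, cfg).spectral.lf_hf_ratio)
                y1.append(ix.compute_all(s.rr_t1, cfg).spectral.lf_hf_ratio)
                grp.append(s.group_truth)
            res = stats.mixed_anova_2x2(np.array(y0), np.array(y1),
                                        np.array(grp))
            rejections += res.interaction.p < 0.05
        assert rejections > n_rep / 2
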