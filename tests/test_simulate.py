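"""The retrospective cohort generator: intercept solving, marginal
distribution recovery, LD control, and exact-vs-rejection sampler agreement."""

import numpy as np
import pytest
from scipy import special, stats

import gxescreen as gx
from gxescreen.simulate import (
    CausalSpec,
    ExposureSpec,
    SimScenario,
    VariantSpec,
    sample_case_control,
    simulate_population,
    solve_intercept,
)


class TestIntercept:
    def test_all_null_is_logit_prevalence(self):
        sc = gx.power_scenario(or_ge=1.0, or_exposure=1.0)
        assert solve_intercept(sc) == pytest.approx(special.logit(1 / 1500), abs=1e-10)
        sc2 = sc.replace(prevalence=0.5)
        assert solve_intercept(sc2) == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_prevalence_check(self, rng):
        """A large population simulated at the solved intercept reproduces
        the target prevalence (MAF .05, OR_GE 3, exposure .20 / OR 1.5)."""
        sc = gx.power_scenario(or_ge=3.0)
        b0 = solve_intercept(sc)
        n = 2_000_000
        _, _, _, disease = simulate_population(sc, rng, n, intercept=b0)
        frac = disease.mean()
        se = np.sqrt(sc.prevalence * (1 - sc.prevalence) / n)
        assert abs(frac - sc.prevalence) < 3 * se

    def test_normal_covariate_effect_quadrature(self, rng):
        from gxescreen.simulate import CovariateSpec

        sc = gx.power_scenario(or_ge=1.0, or_exposure=1.0).replace(
            covariates=(CovariateSpec("PC1", "normal", effect_or=2.0),),
            prevalence=0.01,
        )
        b0 = solve_intercept(sc)
        _, _, _, disease = simulate_population(sc, rng, 1_000_000, intercept=b0)
        se = np.sqrt(0.01 * 0.99 / 1_000_000)
        assert abs(disease.mean() - 0.01) < 4 * se


class TestPopulation:
    def test_hwe_and_maf_recovered(self, rng):
        sc = SimScenario(variants=(VariantSpec(0.3, 0),), causal=(), exposures=(ExposureSpec("e", 0.2),))
        d, _, _, _ = simulate_population(sc, rng, 20_000, intercept=-5.0)
        g = d[:, 0]
        p_hat = g.mean() / 2
        assert abs(p_hat - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (2 * 20_000))
        counts = [(g == k).sum() for k in (0, 1, 2)]
        assert gx.hwe_exact_test(*counts) > 0.001

    def test_ld_zero_independent(self, rng):
        sc = SimScenario(
            variants=(VariantSpec(0.3, 0), VariantSpec(0.3, 0)), ld_rho=0.0,
            causal=(), exposures=(ExposureSpec("e", 0.2),),
        )
        d, _, _, _ = simulate_population(sc, rng, 10_000, intercept=-5.0)
        r2 = gx.genotype_r2(d[:, 0], d[:, 1])
        assert r2 < 0.002

    def test_ld_monotone_in_rho(self, rng):
        r2s = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            sc = SimScenario(
                variants=(VariantSpec(0.3, 0), VariantSpec(0.3, 0)), ld_rho=rho,
                causal=(), exposures=(ExposureSpec("e", 0.2),),
            )
            d, _, _, _ = simulate_population(sc, rng, 10_000, intercept=-5.0)
            r2s.append(gx.genotype_r2(d[:, 0], d[:, 1]))
        assert all(b > a for a, b in zip(r2s, r2s[1:]))
        assert r2s[-1] > 0.4

    def test_null_disease_independent_of_g_and_e(self, rng):
        sc = gx.power_scenario(or_ge=1.0, or_exposure=1.0).replace(prevalence=0.3)
        d, e, _, y = simulate_population(sc, rng, 30_000)
        for x in (d[:, 0], e["exposure"]):
            table = np.array(
                [[(y & (x == v)).sum() for v in np.unique(x)],
                 [((~y) & (x == v)).sum() for v in np.unique(x)]]
            )
            _, p, _, _ = stats.chi2_contingency(table)
            assert p > 1e-4


class TestCaseControl:
    def test_seed_determinism(self):
        sc = gx.power_scenario(seed=7)
        a = sample_case_control(sc)
        b = sample_case_control(sc)
        np.testing.assert_array_equal(a.genotype.dosage, b.genotype.dosage)
        assert a.cohort.df.equals(b.cohort.df)
        assert a.intercept == b.intercept

    def test_quotas_met_exactly(self):
        out = sample_case_control(gx.power_scenario(n_cases=381, n_controls=598))
        assert int(out.cohort.is_case().sum()) == 381
        assert out.cohort.n_samples == 979

    def test_missingness_rate(self, rng):
        sc = gx.power_scenario().replace(
            exposures=(ExposureSpec("exposure", 0.2, or_main=1.5, missing_rate=0.2),),
            n_cases=2000, n_controls=2000,
        )
        out = sample_case_control(sc, rng=rng)
        frac = out.cohort.df["exposure"].isna().mean()
        se = np.sqrt(0.2 * 0.8 / 4000)
        assert abs(frac - 0.2) < 3 * se

    def test_case_oversampling_of_risk_allele(self, rng):
        sc = gx.power_scenario(or_ge=1.0).replace(
            causal=(CausalSpec(0, "exposure", or_g=2.0, or_ge=1.0),)
        )
        out = sample_case_control(sc, rng=rng)
        g = out.genotype.dosage[:, 0]
        case_maf = g[out.cohort.is_case()].mean() / 2
        assert case_maf > 0.05  # population MAF

    def test_interaction_direction_in_exposed(self):
        """With OR_GE = 3 the exposed cases carry more alt alleles than the
        exposed controls (sign test over replicates)."""
        sc = gx.power_scenario(or_ge=3.0)
        wins = 0
        n_reps = 40
        for seed in range(n_reps):
            out = sample_case_control(sc.replace(seed=seed))
            e = out.cohort.exposure_indicator("exposure")
            y = out.cohort.is_case()
            g = out.genotype.dosage[:, 0]
            exposed = e == 1
            wins += g[exposed & y].mean() > g[exposed & ~y].mean()
        p = stats.binomtest(wins, n_reps, 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_exact_and_rejection_samplers_agree(self, rng):
        """The exact conditional sampler and the literal rejection sampler
        draw from the same joint (status, genotype, exposure) distribution."""
        sc = gx.power_scenario(or_ge=3.0).replace(
            prevalence=0.05, n_cases=400, n_controls=400
        )

        def cell_counts(method, seeds):
            tot = np.zeros((2, 3, 2))
            for s in seeds:
                out = sample_case_control(sc, rng=np.random.default_rng(s), method=method)
                g = out.genotype.dosage[:, 0]
                e = out.cohort.exposure_indicator("exposure")
                y = out.cohort.is_case()
                for yy in (0, 1):
                    for gg in (0, 1, 2):
                        for ee in (0, 1):
                            tot[yy, gg, ee] += ((y == yy) & (g == gg) & (e == ee)).sum()
            return tot.ravel()

        a = cell_counts("exact", range(15))
        b = cell_counts("rejection", range(1000, 1015))
        obs = np.vstack([a, b])
        keep = obs.sum(axis=0) > 5
        _, p, _, _ = stats.chi2_contingency(obs[:, keep])
        assert p > 0.001

    def test_rejection_cap_error(self):
        sc = gx.power_scenario().replace(max_population_draws=10_000)
        with pytest.raises(RuntimeError, match="max_population_draws"):
            sample_case_control(sc, method="rejection")

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            VariantSpec(0.6, 0)
        with pytest.raises(ValueError):
            ExposureSpec("e", 1.2)
        with pytest.raises(ValueError):
            SimScenario(n_cases=0)
        with pytest.raises(ValueError):
            SimScenario(causal=(CausalSpec(3, "exposure"),))
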