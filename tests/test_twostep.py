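"""The two-step analysis: screening, pruning against a brute-force oracle,
threshold arithmetic, interaction testing, and the model/results objects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxescreen as gx
from gxescreen.twostep import (
    GxEInteractionModel,
    ScreenHit,
    bonferroni_threshold,
    clump_independent,
    genotype_r2,
    round_sig,
    step_one_screen,
    step_two_test,
)

from .conftest import make_cohort, make_gm


class TestScreen:
    def test_monomorphic_skipped(self, rng):
        n = 200
        d = np.column_stack([np.zeros(n), rng.integers(0, 3, n)])
        gm = make_gm(d)
        cohort = make_cohort(rng.random(n) < 0.4, exposure=(rng.random(n) < 0.3).astype(float))
        hits = step_one_screen(gm, cohort, "exposure")
        assert [h.variant.id for h in hits] == ["v0001"]

    def test_too_few_exposed_raises(self, rng):
        n = 100
        gm = make_gm(rng.integers(0, 3, size=(n, 2)).astype(float))
        e = np.zeros(n)
        e[:5] = 1.0  # only 5 exposed
        cohort = make_cohort(rng.random(n) < 0.4, exposure=e)
        with pytest.raises(ValueError, match="screen not estimable"):
            step_one_screen(gm, cohort, "exposure")

    def test_null_p_values_uniform(self, rng):
        """No G-E dependence: screening p-values are uniform (KS test)."""
        n, m = 800, 2000
        p = rng.uniform(0.1, 0.5, size=m)
        gm = make_gm(rng.binomial(2, p, size=(n, m)).astype(float))
        cohort = make_cohort(rng.random(n) < 0.4, exposure=(rng.random(n) < 0.3).astype(float))
        hits = step_one_screen(gm, cohort, "exposure")
        pvals = np.array([h.p_screen for h in hits])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_ge_snv_ranks_first(self, rng):
        """A variant that shifts exposure odds (OR 2 per allele, MAF 0.3)
        attains the smallest screening p in nearly every replicate."""
        n, m = 1000, 300
        wins = 0
        reps = 30
        for _ in range(reps):
            p = rng.uniform(0.1, 0.5, size=m)
            p[0] = 0.3
            G = rng.binomial(2, p, size=(n, m)).astype(float)
            e = (rng.random(n) < 1 / (1 + np.exp(-(np.log(0.25) + np.log(2) * G[:, 0])))).astype(float)
            gm = make_gm(G)
            cohort = make_cohort(rng.random(n) < 0.4, exposure=e)
            hits = step_one_screen(gm, cohort, "exposure")
            best = min(hits, key=lambda h: h.p_screen)
            wins += best.variant.id == "v0000"
        assert wins >= 0.9 * reps


class TestR2:
    def test_identity_and_anticorrelation(self, rng):
        a = rng.integers(0, 3, 100).astype(float)
        assert genotype_r2(a, a) == pytest.approx(1.0)
        assert genotype_r2(a, 2 - a) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 5000).astype(float)
        b = rng.binomial(2, 0.3, 5000).astype(float)
        assert genotype_r2(a, b) < 0.01

    def test_zero_variance_nan(self):
        assert np.isnan(genotype_r2(np.zeros(10), np.arange(10.0) % 3))

    def test_pairwise_complete(self, rng):
        a = rng.integers(0, 3, 50).astype(float)
        b = a.copy()
        a[:5] = np.nan
        assert genotype_r2(a, b) == pytest.approx(1.0)


def clump_oracle(hits, gm, p_max, r2_max):
    """Independent re-implementation: explicit loops and the textbook
    covariance formula for r^2."""
    def r2(u, v):
        keep = np.isfinite(u) & np.isfinite(v)
        u, v = u[keep], v[keep]
        if len(u) < 2:
            return float("nan")
        su, sv = u - u.mean(), v - v.mean()
        den = (su**2).sum() * (sv**2).sum()
        if den == 0:
            return float("nan")
        return ((su * v).sum()) ** 2 / den

    pool = sorted(
        (h for h in hits if h.p_screen <= p_max),
        key=lambda h: (h.p_screen, h.variant.sort_key),
    )
    kept = []
    for h in pool:
        d = gm.dosage_of(h.variant.id)
        independent = True
        for k in kept:
            val = r2(d, gm.dosage_of(k.variant.id))
            if np.isnan(val) or val > r2_max:
                independent = False
        if independent:
            kept.append(h)
    return kept


class TestClump:
    def _hits(self, gm, pvals):
        return [
            ScreenHit(v, "e", 0.1, p, gm.n_samples)
            for v, p in zip(gm.variants, pvals)
        ]

    def test_single_hit_passthrough(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(50, 1)).astype(float))
        hits = self._hits(gm, [1e-7])
        assert clump_independent(hits, gm) == hits

    def test_perfectly_correlated_pair_keeps_smaller_p(self, rng):
        a = rng.integers(0, 3, 100).astype(float)
        gm = make_gm(np.column_stack([a, a]))
        hits = self._hits(gm, [1e-6, 1e-8])
        kept = clump_independent(hits, gm)
        assert [h.variant.id for h in kept] == ["v0001"]

    def test_p_max_filter(self, rng):
        gm = make_gm(rng.integers(0, 3, size=(100, 2)).astype(float))
        hits = self._hits(gm, [1e-6, 1e-4])
        kept = clump_independent(hits, gm, p_max=1e-5)
        assert [h.variant.id for h in kept] == ["v0000"]

    def test_matches_brute_force_oracle(self, rng):
        """Random hit sets of size <= 12 (with LD-correlated columns) agree
        with the independent re-implementation."""
        for trial in range(40):
            m = int(rng.integers(2, 13))
            n = 150
            base = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            # induce correlation between random column pairs
            for _ in range(m // 2):
                i, j = rng.integers(0, m, 2)
                if i != j:
                    mix = rng.random(n) < 0.8
                    base[mix, j] = base[mix, i]
            gm = make_gm(base)
            pvals = 10 ** rng.uniform(-9, -4, size=m)
            hits = self._hits(gm, pvals)
            got = clump_independent(hits, gm, p_max=1e-5, r2_max=0.6)
            want = clump_oracle(hits, gm, 1e-5, 0.6)
            assert [h.variant.id for h in got] == [h.variant.id for h in want]


class TestThreshold:
    @pytest.mark.parametrize(
        "m,expected,display",
        [
            (12, 0.05 / 12, 0.0042),
            (40, 0.00125, 0.0013),
            (11, 0.05 / 11, 0.0045),
            (7, 0.05 / 7, 0.0071),
            (20, 0.0025, 0.0025),
            (10, 0.005, 0.0050),
            (1, 0.05, 0.05),
        ],
    )
    def test_screening_derived_bonferroni(self, m, expected, display):
        thr = bonferroni_threshold(m)
        assert thr == pytest.approx(expected, rel=1e-12)
        assert round_sig(thr, 2) == pytest.approx(display, rel=1e-9)

    def test_zero_selected_rejected(self):
        with pytest.raises(ValueError, match="no SNVs selected"):
            bonferroni_threshold(0)


class TestStepTwo:
    def test_saturated_interaction_cross_ratio(self):
        """Binary-recoded genotype, saturated counts: exp(interaction
        coefficient) equals the ratio of the stratum odds ratios (= 9)."""
        rows = []
        # (g, n_case_exp, n_case_unexp, n_ctrl_exp, n_ctrl_unexp)
        for g, a, b, c, d in [(0, 50, 50, 50, 50), (1, 60, 20, 20, 60)]:
            rows += [(g, 1, 1)] * a + [(g, 1, 0)] * b + [(g, 0, 1)] * c + [(g, 0, 0)] * d
        arr = np.array(rows, dtype=float)
        gm = make_gm(arr[:, [0]])
        cohort = make_cohort(arr[:, 1], exposure=arr[:, 2])
        hits = [ScreenHit(gm.variants[0], "exposure", 0.0, 1e-9, len(arr))]
        res = step_two_test(gm, cohort, "exposure", hits, threshold=0.0045)
        assert res[0].or_ge == pytest.approx(9.0, abs=1e-6)
        assert np.log(res[0].or_ge) == pytest.approx(np.log(9.0), abs=1e-8)

    def test_significance_flags(self, rng):
        n = 400
        gm = make_gm(rng.integers(0, 3, size=(n, 1)).astype(float))
        cohort = make_cohort(rng.random(n) < 0.4, exposure=(rng.random(n) < 0.4).astype(float))
        hits = [ScreenHit(gm.variants[0], "exposure", 0.0, 1e-9, n)]
        res = step_two_test(gm, cohort, "exposure", hits, threshold=0.004545)
        r = res[0]
        # significant iff p below the full-precision threshold; implies suggestive
        assert r.significant == (r.p_ge < 0.004545)
        assert (not r.significant) or r.suggestive
        # a p of .0016 under the BMI threshold .05/11 is significant
        assert 0.0016 < bonferroni_threshold(11)

    def test_ci_consistent_with_or(self, rng):
        n = 600
        g = rng.integers(0, 3, n).astype(float)
        e = (rng.random(n) < 0.3).astype(float)
        y = rng.random(n) < 0.4
        gm = make_gm(g[:, None])
        cohort = make_cohort(y, exposure=e)
        hits = [ScreenHit(gm.variants[0], "exposure", 0.0, 1e-9, n)]
        (r,) = step_two_test(gm, cohort, "exposure", hits, threshold=0.05)
        assert r.ci_low <= r.or_ge <= r.ci_high
        assert r.ci_low * r.ci_high == pytest.approx(r.or_ge**2, rel=1e-10)

    def test_rank_deficient_recorded_not_dropped(self, rng):
        n = 200
        g = np.zeros(n)  # monomorphic -> collinear with intercept
        gm = make_gm(g[:, None])
        cohort = make_cohort(rng.random(n) < 0.5, exposure=(rng.random(n) < 0.5).astype(float))
        hits = [ScreenHit(gm.variants[0], "exposure", 0.0, 1e-9, n)]
        (r,) = step_two_test(gm, cohort, "exposure", hits, threshold=0.05)
        assert np.isnan(r.or_ge)
        assert r.na_reason != ""

    def test_covariates_expand_with_interactions(self, rng):
        n = 500
        g = rng.integers(0, 3, n).astype(float)
        e = (rng.random(n) < 0.4).astype(float)
        y = rng.random(n) < 0.4
        gm = make_gm(g[:, None])
        cohort = make_cohort(
            y, exposure=e,
            education=rng.choice(["low", "mid", "high"], size=n),
            PC1=rng.normal(size=n),
        )
        hits = [ScreenHit(gm.variants[0], "exposure", 0.0, 1e-9, n)]
        (r,) = step_two_test(
            gm, cohort, "exposure", hits, covariate_names=["education", "PC1"], threshold=0.05
        )
        assert np.isfinite(r.p_ge)
        assert r.na_reason == ""


class TestModelObjects:
    def _sim(self, seed=0):
        sc = gx.genome_scenario(
            n_null=60, causal_maf=0.3, exposure_prevalence=0.3, or_ge=3.0,
            n_cases=700, n_controls=700, seed=seed,
        )
        return gx.sample_case_control(sc)

    def test_fit_recovers_planted_interaction(self):
        out = self._sim(3)
        model = GxEInteractionModel(out.genotype, out.cohort, ["exposure"])
        res = model.fit()
        a = res["exposure"]
        assert a.threshold == pytest.approx(0.05 / a.n_selected)
        causal_id = out.genotype.variant_ids[0]
        assert any(r.variant.id == causal_id and r.significant for r in a.interactions)
        # invariant: significant implies suggestive, everywhere
        for r in a.interactions:
            assert (not r.significant) or r.suggestive

    def test_summary_frame_layout(self):
        out = self._sim(4)
        res = gx.run_two_step(out.genotype, out.cohort, ["exposure"])
        df = res.summary_frame()
        assert set(df.columns) >= {
            "exposure", "n_selected", "lowest_p_step_one", "threshold_step_two"
        }
        assert "Two-step" in res.summary()

    def test_exposure_with_no_exposed_recorded(self, rng):
        n = 300
        gm = make_gm(rng.integers(0, 3, size=(n, 5)).astype(float))
        cohort = make_cohort(rng.random(n) < 0.4, exposure=np.zeros(n))
        res = GxEInteractionModel(gm, cohort, ["exposure"]).fit()
        assert "screen not estimable" in res["exposure"].error
        with pytest.raises(ValueError, match="exposure"):
            GxEInteractionModel(gm, cohort, ["exposure"]).fit(on_error="raise")

    def test_all_null_family_wise_error_controlled(self, rng):
        """All-null genomes: the chance of any significant interaction is
        at most ~alpha (selection at 1e-5 rarely happens at all)."""
        false_hits = 0
        reps = 120
        for seed in range(reps):
            r = np.random.default_rng(seed + 5000)
            n, m = 500, 150
            p = r.uniform(0.1, 0.5, size=m)
            gm = make_gm(r.binomial(2, p, size=(n, m)).astype(float))
            cohort = make_cohort(r.random(n) < 0.4, exposure=(r.random(n) < 0.3).astype(float))
            res = gx.run_two_step(gm, cohort, ["exposure"])
            a = res["exposure"]
            false_hits += any(x.significant for x in a.interactions)
        fwer = false_hits / reps
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_screen_and_test_statistics_near_independent(self):
        """The screening statistic (G-E in the combined sample) and the
        interaction statistic carry nearly independent information under a
        pure interaction model with null marginal genotype effect."""
        from gxescreen.logistic import fit_logistic

        sc = gx.power_scenario(or_ge=3.0, maf=0.2, exposure_prevalence=0.3)
        z1s, z2s = [], []
        for seed in range(500):
            out = gx.sample_case_control(sc.replace(seed=seed))
            e = out.cohort.exposure_indicator("exposure")
            y = out.cohort.is_case().astype(float)
            g = out.genotype.dosage[:, 0]
            f1 = fit_logistic(np.column_stack([np.ones_like(g), g]), e, names=["c", "g"])
            X = np.column_stack([np.ones_like(g), e, g, e * g])
            f2 = fit_logistic(X, y, names=["c", "E", "G", "GxE"])
            z1s.append(f1["g"]["z"])
            z2s.append(f2["GxE"]["z"])
        r = np.corrcoef(z1s, z2s)[0, 1]
        assert abs(r) < 0.1
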