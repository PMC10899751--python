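"""Monte-Carlo power analysis for gene-environment interaction tests.

Power is estimated by simulation rather than an analytic expected-
information formula: each replicate draws a fresh retrospective
case-control dataset from a :class:`~gxescreen.simulate.SimScenario`, fits
``status ~ E + G + E:G`` by logistic regression, and applies the two-sided
Wald test to the interaction coefficient.  The replicate-level rejections
give the power estimate with a Wilson 95% Monte-Carlo interval.

:func:`two_step_design_power` compares the two-step screening design
against the exhaustive one-step Bonferroni scan on the same replicates
(paired), the experiment that motivates the two-step design when exposure
or risk allele are rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .logistic import batch_interaction_test, fit_logistic
from .simulate import SimScenario, sample_case_control
from .twostep import clump_independent, step_one_screen, step_two_test

__all__ = ["PowerResult", "empirical_power", "power_curve", "two_step_design_power"]


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate for one scenario / alpha pair."""

    scenario: SimScenario
    alpha: float
    n_reps: int
    n_rejections: int
    power_hat: float
    mc_ci95: tuple
    seed: int

    def __str__(self) -> str:
        lo, hi = self.mc_ci95
        return (
            f"power {self.power_hat:.3f} (95% MC CI {lo:.3f}-{hi:.3f}; "
            f"{self.n_rejections}/{self.n_reps} rejections at alpha={self.alpha})"
        )


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion."""
    from scipy import stats

    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _interaction_p(out) -> float:
    """Two-sided Wald p for E:G in ``status ~ E + G + E:G`` (no covariates)."""
    cohort = out.cohort
    name = out.scenario.exposures[0].name
    e = cohort.exposure_indicator(name)
    g = out.genotype.dosage[:, out.scenario.causal[0].variant_index]
    y = cohort.is_case().astype(float)
    keep = np.isfinite(e) & np.isfinite(g)
    X = np.column_stack([np.ones(keep.sum()), e[keep], g[keep], e[keep] * g[keep]])
    fit = fit_logistic(X, y[keep], names=["const", "E", "G", "GxE"])
    return float(fit["GxE"]["p"])


def empirical_power(
    scenario: SimScenario, alpha: float = 0.05, n_reps: int = 2000, seed: int = 0
) -> PowerResult:
    """Fraction of replicates rejecting the interaction Wald test at ``alpha``."""
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a meaningful power estimate")
    if len(scenario.causal) != 1:
        raise ValueError("power scenarios must have exactly one causal variant")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    k = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            out = sample_case_control(scenario, rng=rng)
            p = _interaction_p(out)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"power replicate {i} failed: {exc}") from exc
        if np.isfinite(p) and p < alpha:
            k += 1
    return PowerResult(
        scenario, alpha, n_reps, k, k / n_reps, wilson_interval(k, n_reps), seed
    )


_VARY_FIELDS = {"or_ge", "or_g", "or_exposure", "maf", "exposure_prevalence", "n_cases", "n_controls"}


def _vary(scenario: SimScenario, param: str, value) -> SimScenario:
    import dataclasses

    if param == "or_ge":
        causal = (dataclasses.replace(scenario.causal[0], or_ge=float(value)),)
        return scenario.replace(causal=causal)
    if param == "or_g":
        causal = (dataclasses.replace(scenario.causal[0], or_g=float(value)),)
        return scenario.replace(causal=causal)
    if param == "or_exposure":
        exposures = (dataclasses.replace(scenario.exposures[0], or_main=float(value)),)
        return scenario.replace(exposures=exposures)
    if param == "maf":
        variants = tuple(dataclasses.replace(v, maf=float(value)) for v in scenario.variants)
        return scenario.replace(variants=variants)
    if param == "exposure_prevalence":
        exposures = (dataclasses.replace(scenario.exposures[0], prevalence=float(value)),)
        return scenario.replace(exposures=exposures)
    if param in {"n_cases", "n_controls"}:
        return scenario.replace(**{param: int(value)})
    raise ValueError(f"cannot vary {param!r}; known parameters: {sorted(_VARY_FIELDS)}")


def power_curve(
    base_scenario: SimScenario,
    vary: dict,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
) -> list:
    """One :class:`PowerResult` per grid point of ``{param: [values...]}``.

    The same seed (hence common random numbers) is used at every grid
    point, which smooths the estimated curve.
    """
    if len(vary) != 1:
        raise ValueError("vary must map exactly one parameter to a grid of values")
    (param, values), = vary.items()
    if len(values) == 0:
        raise ValueError("empty parameter grid")
    return [
        empirical_power(_vary(base_scenario, param, v), alpha, n_reps, seed) for v in values
    ]


def two_step_design_power(
    genome_scenario: SimScenario,
    n_reps: int = 200,
    alpha: float = 0.05,
    p_max: float = 1e-5,
    r2_max: float = 0.6,
    seed: int = 0,
) -> dict:
    """Paired power of the two-step design vs the one-step Bonferroni scan.

    Per replicate: simulate the genome scenario; *two-step* detection means
    the causal variant survives screening (p <= ``p_max``, LD pruning) and
    its interaction p is below ``alpha / m`` for the m variants selected;
    *one-step* detection means its interaction p is below ``alpha / M`` for
    all M variants.  With no causal variant the same machinery yields
    paired family-wise error rates (any false detection).

    Returns a dict with ``two_step`` and ``one_step`` :class:`PowerResult`
    and the distribution of selected counts ``m``.
    """
    M = len(genome_scenario.variants)
    causal_idx = [c.variant_index for c in genome_scenario.causal if c.or_ge != 1.0]
    children = np.random.SeedSequence(seed).spawn(n_reps)
    k_two = k_one = 0
    m_counts = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        out = sample_case_control(genome_scenario, rng=rng)
        cohort = out.cohort
        name = out.scenario.exposures[0].name
        e = cohort.exposure_indicator(name)
        y = cohort.is_case().astype(float)
        keep = np.isfinite(e)
        G = out.genotype.dosage[keep]
        e_k, y_k = e[keep], y[keep]

        # step one + pruning on screen hits
        hits = step_one_screen(out.genotype, cohort, name)
        selected = clump_independent(hits, out.genotype, p_max=p_max, r2_max=r2_max)
        m = len(selected)
        m_counts.append(m)
        det_two = det_one = False
        if m:
            thr = alpha / m
            sel_ids = {h.variant.id for h in selected}
            res = step_two_test(out.genotype, cohort, name, selected, (), thr)
            if causal_idx:
                causal_id = out.genotype.variant_ids[causal_idx[0]]
                det_two = any(
                    r.variant.id == causal_id and r.significant for r in res
                ) and causal_id in sel_ids
            else:
                det_two = any(r.significant for r in res)
        # one-step benchmark
        thr_one = alpha / M
        if causal_idx:
            g = G[:, causal_idx[0]]
            Xr = np.column_stack([np.ones(len(e_k)), e_k, g, e_k * g])
            fit = fit_logistic(Xr, y_k, names=["const", "E", "G", "GxE"])
            det_one = float(fit["GxE"]["p"]) < thr_one
        else:
            scan = batch_interaction_test(G, e_k, y_k)
            finite = scan["p_ge"][np.isfinite(scan["p_ge"])]
            det_one = bool(finite.size and finite.min() < thr_one)
        k_two += det_two
        k_one += det_one

    m_arr = np.asarray(m_counts)
    return {
        "two_step": PowerResult(
            genome_scenario, alpha, n_reps, k_two, k_two / n_reps,
            wilson_interval(k_two, n_reps), seed,
        ),
        "one_step": PowerResult(
            genome_scenario, alpha, n_reps, k_one, k_one / n_reps,
            wilson_interval(k_one, n_reps), seed,
        ),
        "m_selected": m_arr,
        "m_median": float(np.median(m_arr)),
        "n_variants": M,
    }
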