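"""Retrospective case-control cohort simulation.

The generative model is the one the downstream analysis assumes: biallelic
variants in Hardy-Weinberg equilibrium, linkage disequilibrium within
blocks via a Gaussian-copula (thresholded latent AR(1)) haplotype model,
Bernoulli exposures and covariates, and disease risk that is log-additive
in allele dosage,

    logit P(D=1) = b0 + log(OR_G) g + log(OR_E) e + log(OR_GxE) g e + covariates.

The intercept ``b0`` is solved so the *population* disease probability
equals the scenario prevalence (exact enumeration over the discrete cells
of the risk model, Gauss-Hermite quadrature for any normal covariate with
an effect).  Cases and controls are then drawn retrospectively until the
scenario's fixed quotas are met.

Two samplers produce identical distributions:

* ``rejection`` - literally draws population individuals in vectorised
  batches until the quotas fill (general, but slow at low prevalence);
* ``exact`` - enumerates the joint cells of all risk-bearing discrete
  predictors, computes each cell's probability among cases and among
  controls by Bayes' rule, draws cell counts multinomially, and fills
  everything independent of disease from its marginal distribution.  Used
  automatically when the scenario permits it (all effects on discrete
  predictors; causal variants not LD-linked to other variants).

Exposure missingness is injected completely at random at the configured
per-exposure rate after sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .core import EXPOSED, UNEXPOSED, CohortTable, GenotypeMatrix, VariantRecord

__all__ = [
    "VariantSpec",
    "ExposureSpec",
    "CausalSpec",
    "CovariateSpec",
    "SimScenario",
    "SimOutput",
    "default_covariates",
    "power_scenario",
    "genome_scenario",
    "solve_intercept",
    "simulate_population",
    "sample_case_control",
]


@dataclass(frozen=True)
class VariantSpec:
    """One biallelic variant: population MAF and LD-block membership."""

    maf: float
    block_id: int

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class ExposureSpec:
    """A binary environmental exposure."""

    name: str
    prevalence: float
    or_main: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"exposure prevalence must be in (0,1), got {self.prevalence}")
        if self.or_main <= 0:
            raise ValueError("odds ratios must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")


@dataclass(frozen=True)
class CausalSpec:
    """A variant's direct and exposure-interaction effect on disease."""

    variant_index: int
    exposure_name: str
    or_g: float = 1.0
    or_ge: float = 1.0

    def __post_init__(self):
        if self.or_g <= 0 or self.or_ge <= 0:
            raise ValueError("odds ratios must be positive")


@dataclass(frozen=True)
class CovariateSpec:
    """A covariate; ``kind`` in {binary, categorical, normal}.

    ``effect_or`` is the per-unit odds ratio (per level step for ordered
    categorical covariates, per SD for normal ones); 1.0 means no effect.
    """

    name: str
    kind: str = "binary"
    probs: tuple = (0.5,)
    levels: tuple = ()
    effect_or: float = 1.0

    def __post_init__(self):
        if self.kind not in {"binary", "categorical", "normal"}:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.effect_or <= 0:
            raise ValueError("odds ratios must be positive")


def default_covariates() -> tuple:
    """Sex ~ Bernoulli(0.5); a 3-level maternal-education covariate with
    population weights 0.15/0.45/0.40; four ancestry PCs ~ N(0,1).
    All effects default to OR 1."""
    return (
        CovariateSpec("sex", "binary", probs=(0.5,), levels=("female", "male")),
        CovariateSpec(
            "education",
            "categorical",
            probs=(0.15, 0.45, 0.40),
            levels=("low", "intermediate", "high"),
        ),
        CovariateSpec("PC1", "normal"),
        CovariateSpec("PC2", "normal"),
        CovariateSpec("PC3", "normal"),
        CovariateSpec("PC4", "normal"),
    )


@dataclass(frozen=True)
class SimScenario:
    """Full generative specification of a retrospective case-control study."""

    n_cases: int = 381
    n_controls: int = 598
    prevalence: float = 1.0 / 1500.0
    variants: tuple = (VariantSpec(0.05, 0),)
    ld_rho: float = 0.0
    exposures: tuple = (ExposureSpec("exposure", 0.20, or_main=1.5),)
    causal: tuple = (CausalSpec(0, "exposure", or_g=1.0, or_ge=3.0),)
    covariates: tuple = ()
    seed: int = 0
    max_population_draws: int = 50_000_000

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0,1)")
        names = [e.name for e in self.exposures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate exposure names")
        for c in self.causal:
            if not 0 <= c.variant_index < len(self.variants):
                raise ValueError(f"causal variant_index {c.variant_index} out of range")
            if c.exposure_name not in names:
                raise ValueError(f"causal exposure {c.exposure_name!r} not declared")

    def replace(self, **kw) -> "SimScenario":
        return dataclasses.replace(self, **kw)

    # -- which predictors carry disease risk -------------------------
    def active_variants(self) -> list:
        idx = set()
        for c in self.causal:
            if c.or_g != 1.0 or c.or_ge != 1.0:
                idx.add(c.variant_index)
        return sorted(idx)

    def active_exposures(self) -> list:
        names = {c.exposure_name for c in self.causal if c.or_ge != 1.0}
        names |= {e.name for e in self.exposures if e.or_main != 1.0}
        order = [e.name for e in self.exposures]
        return [n for n in order if n in names]

    def active_covariates(self) -> list:
        return [c for c in self.covariates if c.effect_or != 1.0]


@dataclass
class SimOutput:
    """A sampled dataset plus the generative truth that produced it."""

    genotype: GenotypeMatrix
    cohort: CohortTable
    scenario: SimScenario
    intercept: float
    sampler: str


# ------------------------------------------------------------------ intercept

def _cells(scenario: SimScenario, gh_points: int = 41):
    """Joint cells (weight, linear-predictor offset, assignment) of all
    risk-bearing predictors; normal covariates with effects enter through
    Gauss-Hermite nodes."""
    av = scenario.active_variants()
    ae = scenario.active_exposures()
    ac = scenario.active_covariates()

    axes = []  # list of (kind, key, [(value, prob, lp_contrib_partial)...])
    for vi in av:
        p = scenario.variants[vi].maf
        hw = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        axes.append(("variant", vi, [(g, hw[g]) for g in range(3)]))
    for name in ae:
        prev = next(e for e in scenario.exposures if e.name == name).prevalence
        axes.append(("exposure", name, [(0, 1 - prev), (1, prev)]))
    for cov in ac:
        if cov.kind == "binary":
            axes.append(("covariate", cov.name, [(0, 1 - cov.probs[0]), (1, cov.probs[0])]))
        elif cov.kind == "categorical":
            axes.append(("covariate", cov.name, [(i, p) for i, p in enumerate(cov.probs)]))
        else:  # normal: Gauss-Hermite (probabilists')
            nodes, weights = np.polynomial.hermite_e.hermegauss(gh_points)
            weights = weights / weights.sum()
            axes.append(("covariate", cov.name, list(zip(nodes, weights))))

    beta_e = {e.name: np.log(e.or_main) for e in scenario.exposures}
    beta_c = {c.name: np.log(c.effect_or) for c in scenario.covariates}
    causal_by_variant: dict = {}
    for c in scenario.causal:
        causal_by_variant.setdefault(c.variant_index, []).append(c)

    cells = []
    for combo in product(*[ax[2] for ax in axes]) if axes else [()]:
        weight = 1.0
        assign = {}
        for (kind, key, _), (value, prob) in zip(axes, combo):
            weight *= prob
            assign[(kind, key)] = value
        lp = 0.0
        for name in ae:
            lp += beta_e[name] * assign[("exposure", name)]
        for cov in ac:
            lp += beta_c[cov.name] * assign[("covariate", cov.name)]
        for vi in av:
            g = assign[("variant", vi)]
            for c in causal_by_variant.get(vi, []):
                lp += np.log(c.or_g) * g
                if c.or_ge != 1.0:
                    e_val = assign.get(("exposure", c.exposure_name), 0)
                    lp += np.log(c.or_ge) * g * e_val
        cells.append((weight, lp, assign))
    return cells


def solve_intercept(scenario: SimScenario) -> float:
    """Intercept b0 with population disease probability == prevalence.

    The expectation of ``expit(b0 + lp)`` over the joint distribution of
    risk-bearing predictors is computed by exact enumeration (quadrature
    for normal effects) and the monotone root found by Brent's method.
    """
    cells = _cells(scenario)
    w = np.array([c[0] for c in cells])
    lp = np.array([c[1] for c in cells])
    target = scenario.prevalence

    def f(b0):
        return float(w @ special.expit(b0 + lp)) - target

    lo, hi = -60.0, 60.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError(
            f"intercept root not bracketed: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    b0 = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(b0)


# ------------------------------------------------------------------ population draws

def _sample_genotypes(rng, n: int, variants: Sequence[VariantSpec], ld_rho: float):
    """Genotypes as the sum of two independent haplotypes; within a block,
    adjacent variants' allele indicators come from a thresholded latent
    AR(1) Gaussian with correlation ``ld_rho`` (a Gaussian copula), so HWE
    holds marginally at every variant."""
    M = len(variants)
    dosage = np.empty((n, M))
    thresholds = stats.norm.ppf([v.maf for v in variants])
    if ld_rho == 0.0:  # every variant independent: one vectorised draw per haplotype
        dosage = (rng.standard_normal((n, M)) < thresholds).astype(float)
        dosage += rng.standard_normal((n, M)) < thresholds
        return dosage
    # group columns by block, preserving order
    blocks: dict = {}
    for j, v in enumerate(variants):
        blocks.setdefault(v.block_id, []).append(j)
    for cols in blocks.values():
        L = len(cols)
        g = np.zeros((n, L))
        for _hap in range(2):
            z = np.empty((n, L))
            z[:, 0] = rng.standard_normal(n)
            if L > 1:
                noise = rng.standard_normal((n, L - 1))
                c = np.sqrt(1.0 - ld_rho**2)
                for l in range(1, L):
                    z[:, l] = ld_rho * z[:, l - 1] + c * noise[:, l - 1]
            g += z < thresholds[cols]
        dosage[:, cols] = g
    return dosage


def _linear_predictor(scenario, dosage, exposures, covariates):
    lp = np.zeros(dosage.shape[0])
    for e in scenario.exposures:
        if e.or_main != 1.0:
            lp += np.log(e.or_main) * exposures[e.name]
    for c in scenario.causal:
        g = dosage[:, c.variant_index]
        if c.or_g != 1.0:
            lp += np.log(c.or_g) * g
        if c.or_ge != 1.0:
            lp += np.log(c.or_ge) * g * exposures[c.exposure_name]
    for cov in scenario.covariates:
        if cov.effect_or != 1.0:
            lp += np.log(cov.effect_or) * covariates[cov.name]
    return lp


def _sample_covariate(rng, cov: CovariateSpec, n: int):
    if cov.kind == "binary":
        return (rng.random(n) < cov.probs[0]).astype(float)
    if cov.kind == "categorical":
        return rng.choice(len(cov.probs), size=n, p=np.asarray(cov.probs))
    return rng.standard_normal(n)


def simulate_population(scenario: SimScenario, rng, n: int, intercept: float | None = None):
    """Draw ``n`` population individuals: (dosage, exposures, covariates, disease)."""
    if intercept is None:
        intercept = solve_intercept(scenario)
    dosage = _sample_genotypes(rng, n, scenario.variants, scenario.ld_rho)
    exposures = {e.name: (rng.random(n) < e.prevalence).astype(float) for e in scenario.exposures}
    covariates = {c.name: _sample_covariate(rng, c, n) for c in scenario.covariates}
    lp = intercept + _linear_predictor(scenario, dosage, exposures, covariates)
    disease = (rng.random(n) < special.expit(lp)).astype(bool)
    return dosage, exposures, covariates, disease


# ------------------------------------------------------------------ case-control sampling

def _exact_eligible(scenario: SimScenario) -> bool:
    if any(c.kind == "normal" for c in scenario.active_covariates()):
        return False
    if scenario.ld_rho > 0:
        blocks: dict = {}
        for j, v in enumerate(scenario.variants):
            blocks.setdefault(v.block_id, []).append(j)
        for vi in scenario.active_variants():
            if len(blocks[scenario.variants[vi].block_id]) > 1:
                return False  # causal variant LD-linked to neighbours
    n_cells = 3 ** len(scenario.active_variants())
    n_cells *= 2 ** len(scenario.active_exposures())
    for c in scenario.active_covariates():
        n_cells *= max(len(c.probs), 2)
    return n_cells <= 100_000


def _sample_exact(scenario, rng, intercept):
    cells = _cells(scenario)
    w = np.array([c[0] for c in cells])
    lp = np.array([c[1] for c in cells])
    risk = special.expit(intercept + lp)
    p_case = w * risk
    p_ctrl = w * (1.0 - risk)
    case_counts = rng.multinomial(scenario.n_cases, p_case / p_case.sum())
    ctrl_counts = rng.multinomial(scenario.n_controls, p_ctrl / p_ctrl.sum())

    n = scenario.n_cases + scenario.n_controls
    disease = np.zeros(n, dtype=bool)
    disease[: scenario.n_cases] = True
    cell_of = np.concatenate(
        [np.repeat(np.arange(len(cells)), case_counts), np.repeat(np.arange(len(cells)), ctrl_counts)]
    )

    dosage = _sample_genotypes(rng, n, scenario.variants, scenario.ld_rho)
    exposures = {e.name: (rng.random(n) < e.prevalence).astype(float) for e in scenario.exposures}
    covariates = {c.name: _sample_covariate(rng, c, n) for c in scenario.covariates}
    # overwrite the risk-bearing predictors with their cell assignments
    assigns = [c[2] for c in cells]
    for (kind, key) in assigns[0].keys() if assigns and assigns[0] else []:
        vals = np.array([a[(kind, key)] for a in assigns], dtype=float)
        if kind == "variant":
            dosage[:, key] = vals[cell_of]
        elif kind == "exposure":
            exposures[key] = vals[cell_of]
        else:
            covariates[key] = vals[cell_of]
    # shuffle rows so case/control order carries no structure
    perm = rng.permutation(n)
    dosage = dosage[perm]
    disease = disease[perm]
    exposures = {k: v[perm] for k, v in exposures.items()}
    covariates = {k: np.asarray(v)[perm] for k, v in covariates.items()}
    return dosage, exposures, covariates, disease


def _sample_rejection(scenario, rng, intercept):
    need_cases, need_controls = scenario.n_cases, scenario.n_controls
    expected_rate = scenario.prevalence
    batch = int(min(max(50_000, 4 * need_cases / max(expected_rate, 1e-9)), 2_000_000))
    got_c: list = []
    got_t: list = []
    drawn = 0
    while (
        sum(x[3].sum() for x in got_c) < need_cases
        or sum((~x[3]).sum() for x in got_t) < need_controls
    ):
        this_batch = min(batch, scenario.max_population_draws - drawn)
        if this_batch <= 0:
            raise RuntimeError(
                f"exceeded max_population_draws={scenario.max_population_draws} "
                f"({drawn} drawn); raise the cap or the prevalence"
            )
        d, e, c, y = simulate_population(scenario, rng, this_batch, intercept)
        drawn += this_batch
        if y.any():
            idx = np.flatnonzero(y)
            got_c.append((d[idx], {k: v[idx] for k, v in e.items()}, {k: np.asarray(v)[idx] for k, v in c.items()}, y[idx]))
        if (~y).any():
            # keep only as many controls as still needed to bound memory
            still = need_controls - sum((~x[3]).sum() for x in got_t)
            if still > 0:
                idx = np.flatnonzero(~y)[:still]
                got_t.append((d[idx], {k: v[idx] for k, v in e.items()}, {k: np.asarray(v)[idx] for k, v in c.items()}, y[idx]))

    def stack(parts, limit):
        d = np.concatenate([p[0] for p in parts])[:limit]
        e = {k: np.concatenate([p[1][k] for p in parts])[:limit] for k in parts[0][1]}
        c = {k: np.concatenate([p[2][k] for p in parts])[:limit] for k in parts[0][2]}
        return d, e, c

    dc, ec, cc = stack(got_c, need_cases)
    dt, et, ct = stack(got_t, need_controls)
    dosage = np.concatenate([dc, dt])
    exposures = {k: np.concatenate([ec[k], et[k]]) for k in ec}
    covariates = {k: np.concatenate([cc[k], ct[k]]) for k in cc}
    disease = np.zeros(len(dosage), dtype=bool)
    disease[: need_cases] = True
    perm = rng.permutation(len(dosage))
    return (
        dosage[perm],
        {k: v[perm] for k, v in exposures.items()},
        {k: v[perm] for k, v in covariates.items()},
        disease[perm],
    )


def sample_case_control(
    scenario: SimScenario, rng=None, method: str = "auto"
) -> SimOutput:
    """Draw a retrospective case-control dataset meeting the quotas exactly.

    ``method`` is ``auto`` (exact conditional sampler when the scenario
    permits, else rejection), ``exact`` or ``rejection``.  Fully
    reproducible from ``scenario.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    intercept = solve_intercept(scenario)
    if method == "auto":
        method = "exact" if _exact_eligible(scenario) else "rejection"
    if method == "exact":
        if not _exact_eligible(scenario):
            raise ValueError("scenario not eligible for the exact conditional sampler")
        dosage, exposures, covariates, disease = _sample_exact(scenario, rng, intercept)
    elif method == "rejection":
        dosage, exposures, covariates, disease = _sample_rejection(scenario, rng, intercept)
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    # exposure missingness, completely at random
    n = len(disease)
    exposure_cols = {}
    for e in scenario.exposures:
        vals = np.where(exposures[e.name] == 1.0, EXPOSED, UNEXPOSED).astype(object)
        if e.missing_rate > 0:
            vals[rng.random(n) < e.missing_rate] = np.nan
        exposure_cols[e.name] = vals

    samples = [f"S{i:05d}" for i in range(n)]
    variants = [
        VariantRecord(f"snv{j:05d}", "1", 10_000 * (j + 1), "A", "G")
        for j in range(len(scenario.variants))
    ]
    gm = GenotypeMatrix(dosage, samples, variants)

    import pandas as pd

    data = {"sample_id": samples, "status": np.where(disease, "case", "control")}
    data.update(exposure_cols)
    for cov in scenario.covariates:
        v = covariates[cov.name]
        if cov.kind in {"binary", "categorical"} and cov.levels:
            data[cov.name] = [cov.levels[int(i)] for i in v]
        else:
            data[cov.name] = v
    cohort = CohortTable(pd.DataFrame(data), [e.name for e in scenario.exposures])
    return SimOutput(gm, cohort, scenario, intercept, method)


# ------------------------------------------------------------------ presets

def power_scenario(
    or_ge: float = 3.0,
    or_exposure: float = 1.5,
    or_g: float = 1.0,
    maf: float = 0.05,
    exposure_prevalence: float = 0.20,
    prevalence: float = 1.0 / 1500.0,
    n_cases: int = 381,
    n_controls: int = 598,
    seed: int = 0,
) -> SimScenario:
    """Single-variant interaction power scenario: a rare-ish log-additive
    variant (MAF 0.05), a 20%-prevalent exposure with main-effect OR 1.5,
    disease prevalence 1/1500 and the study's 381/598 quotas.  No
    covariates (none enter the power model)."""
    return SimScenario(
        n_cases=n_cases,
        n_controls=n_controls,
        prevalence=prevalence,
        variants=(VariantSpec(maf, 0),),
        exposures=(ExposureSpec("exposure", exposure_prevalence, or_main=or_exposure),),
        causal=(CausalSpec(0, "exposure", or_g=or_g, or_ge=or_ge),),
        covariates=(),
        seed=seed,
    )


def power_scenario_marginal(
    or_snv: float = 3.0, or_exposure: float = 1.5, **kw
) -> SimScenario:
    """Alternative reading of the power scenario: the OR attaches to the
    SNV's marginal effect and the interaction is tested at that scale."""
    sc = power_scenario(or_ge=1.0, or_exposure=or_exposure, or_g=or_snv, **kw)
    return sc


def genome_scenario(
    n_null: int = 500,
    causal_maf: float = 0.30,
    null_maf_range: tuple = (0.05, 0.5),
    exposure_prevalence: float = 0.30,
    or_exposure: float = 1.5,
    or_ge: float = 3.0,
    or_g: float = 1.0,
    prevalence: float = 1.0 / 1500.0,
    n_cases: int = 381,
    n_controls: int = 598,
    ld_rho: float = 0.0,
    block_size: int = 1,
    seed: int = 0,
) -> SimScenario:
    """A causal GxE variant (its own LD block) plus ``n_null`` null variants
    with MAFs uniform on ``null_maf_range``, grouped in LD blocks of
    ``block_size``."""
    rng = np.random.default_rng(seed + 101)
    mafs = rng.uniform(*null_maf_range, size=n_null)
    variants = [VariantSpec(causal_maf, 0)]
    variants += [VariantSpec(float(m), 1 + j // block_size) for j, m in enumerate(mafs)]
    return SimScenario(
        n_cases=n_cases,
        n_controls=n_controls,
        prevalence=prevalence,
        variants=tuple(variants),
        ld_rho=ld_rho,
        exposures=(ExposureSpec("exposure", exposure_prevalence, or_main=or_exposure),),
        causal=(CausalSpec(0, "exposure", or_g=or_g, or_ge=or_ge),),
        covariates=(),
        seed=seed,
    )
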