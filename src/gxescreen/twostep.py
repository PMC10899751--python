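"""Two-step gene-environment interaction analysis (Murcray-style design).

Step one screens every variant for association with the *exposure* in the
combined case-control sample (logistic regression of exposure status on
allele dosage, no covariates).  Hits with p <= 1e-5 are pruned to an
LD-independent set (pairwise r^2 <= 0.6, greedy by ascending p), and the
step-two significance threshold is 0.05 divided by the number of variants
retained.  Step two fits, per retained variant, a case-control logistic
model with exposure, dosage and their product, plus covariate main effects
and covariate-by-exposure / covariate-by-gene interactions, and Wald-tests
the exposure-by-dosage coefficient.  Variants below the screening-derived
threshold are *significant*; any with interaction p < .05 are flagged
*suggestive*.

Because step one conditions on exposure (not disease), the two stages use
nearly independent information and the multiplicity correction only pays
for the screened subset - the source of the design's power advantage when
exposure or risk allele are rare.

The module exposes both the operation-level functions and a
statsmodels-style :class:`GxEInteractionModel` / :class:`GxEInteractionResults`
pair wrapping the whole analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CohortTable, ExposureDefinition, GenotypeMatrix, VariantRecord, align
from .logistic import batch_logistic_slope, fit_logistic

__all__ = [
    "ScreenHit",
    "InteractionResult",
    "step_one_screen",
    "genotype_r2",
    "clump_independent",
    "bonferroni_threshold",
    "round_sig",
    "step_two_test",
    "run_two_step",
    "GxEInteractionModel",
    "GxEInteractionResults",
]

MIN_GROUP = 10  # minimum exposed / unexposed complete cases for the screen


@dataclass(frozen=True)
class ScreenHit:
    """Step-one association between one variant and the exposure."""

    variant: VariantRecord
    exposure_name: str
    beta_ge_screen: float
    p_screen: float
    n_used: int

    def to_row(self) -> dict:
        return {
            "variant_id": self.variant.id,
            "chrom": self.variant.chrom,
            "pos": self.variant.pos,
            "exposure": self.exposure_name,
            "beta_screen": self.beta_ge_screen,
            "p_screen": self.p_screen,
            "n_used": self.n_used,
        }


@dataclass(frozen=True)
class InteractionResult:
    """Step-two interaction test for one variant/exposure pair."""

    variant: VariantRecord
    exposure_name: str
    or_ge: float
    ci_low: float
    ci_high: float
    p_ge: float
    threshold: float
    significant: bool
    suggestive: bool
    n_used: int
    method: str = "ml"
    na_reason: str = ""

    def to_row(self) -> dict:
        return {
            "variant_id": self.variant.id,
            "chrom": self.variant.chrom,
            "pos": self.variant.pos,
            "ref": self.variant.ref,
            "alt": self.variant.alt,
            "exposure": self.exposure_name,
            "or_ge": self.or_ge,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_ge": self.p_ge,
            "threshold": self.threshold,
            "significant": self.significant,
            "suggestive": self.suggestive,
            "n_used": self.n_used,
            "method": self.method,
            "na_reason": self.na_reason,
        }


# ------------------------------------------------------------------ step one

def step_one_screen(
    gm: GenotypeMatrix, cohort: CohortTable, exposure: ExposureDefinition | str
) -> list:
    """Screen every variant for exposure association in the combined sample.

    Per variant: logistic regression of exposure status (1 = exposed) on
    additive allele dosage, unadjusted, on complete cases (excluded and
    missing exposure levels dropped).  Variants monomorphic among the
    complete cases are skipped.  Raises when fewer than 10 exposed or 10
    unexposed complete cases remain.
    """
    name = exposure.name if isinstance(exposure, ExposureDefinition) else exposure
    gm, cohort = align(gm, cohort)
    e = cohort.exposure_indicator(name)
    usable = np.isfinite(e)
    n_exp = int((e[usable] == 1).sum())
    n_unexp = int((e[usable] == 0).sum())
    if n_exp < MIN_GROUP or n_unexp < MIN_GROUP:
        raise ValueError(
            f"screen not estimable for exposure {name!r}: "
            f"{n_exp} exposed / {n_unexp} unexposed complete cases (need >= {MIN_GROUP})"
        )
    G = gm.dosage[usable]
    res = batch_logistic_slope(G, e[usable])
    hits = []
    for j in range(gm.n_variants):
        if not res["ok"][j]:
            continue  # monomorphic or inestimable in the complete cases
        hits.append(
            ScreenHit(
                variant=gm.variants[j],
                exposure_name=name,
                beta_ge_screen=float(res["beta"][j]),
                p_screen=float(res["p"][j]),
                n_used=int(res["n_used"][j]),
            )
        )
    return hits


# ------------------------------------------------------------------ pruning

def genotype_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete samples.  Returns NaN when fewer than two
    complete pairs remain or either vector is constant; callers must treat
    NaN conservatively (the pair cannot be shown independent).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump_independent(
    hits: Sequence[ScreenHit],
    gm: GenotypeMatrix,
    p_max: float = 1e-5,
    r2_max: float = 0.6,
) -> list:
    """Prune screen hits to an independent set.

    Keeps hits with ``p_screen <= p_max``; then greedily, in ascending
    p-value order (ties broken by genomic position), accepts a hit iff its
    dosage r^2 with *every* previously accepted hit is <= ``r2_max``.
    Undefined r^2 (NaN) counts as dependent.
    """
    qualifying = [h for h in hits if h.p_screen <= p_max]
    qualifying.sort(key=lambda h: (h.p_screen, h.variant.sort_key))
    accepted: list = []
    accepted_dosage: list = []
    for h in qualifying:
        d = gm.dosage_of(h.variant.id)
        ok = True
        for other in accepted_dosage:
            r2 = genotype_r2(d, other)
            if not (r2 <= r2_max):  # NaN -> not shown independent
                ok = False
                break
        if ok:
            accepted.append(h)
            accepted_dosage.append(d)
    return accepted


def bonferroni_threshold(m: int) -> float:
    """Step-two significance threshold 0.05 / m (full precision)."""
    if m < 1:
        raise ValueError("no SNVs selected in step one; threshold undefined")
    return 0.05 / m


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


# ------------------------------------------------------------------ step two

def _expand_covariates(cohort: CohortTable, covariate_names: Sequence[str]) -> pd.DataFrame:
    """Numeric covariates pass through; categorical ones become indicator
    contrasts (first level as reference), shared by main and interaction
    terms."""
    cols = {}
    for name in covariate_names:
        if name not in cohort.df.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        col = cohort.df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.dropna().unique())
            base = np.where(col.isna(), np.nan, 0.0)
            for lev in levels[1:]:
                ind = np.where(col.isna(), np.nan, (col == lev).astype(float))
                cols[f"{name}[{lev}]"] = ind + base * 0.0
    return pd.DataFrame(cols)


def step_two_test(
    gm: GenotypeMatrix,
    cohort: CohortTable,
    exposure: ExposureDefinition | str,
    selected_hits: Sequence[ScreenHit],
    covariate_names: Sequence[str] = (),
    threshold: float | None = None,
    alpha_suggestive: float = 0.05,
) -> list:
    """Interaction test for each selected variant.

    Model per variant: ``status ~ E + G + E:G + sum(C) + sum(C:E) + sum(C:G)``
    on complete cases; the Wald test is on the E:G coefficient.  Significance
    compares p against the full-precision ``threshold``; suggestive loci have
    p < ``alpha_suggestive``.  Inestimable fits (rank deficiency, e.g. no
    variant carriers among the exposed) yield a result row with NaN
    estimates and a reason, never a silent omission.
    """
    name = exposure.name if isinstance(exposure, ExposureDefinition) else exposure
    if threshold is None:
        threshold = bonferroni_threshold(len(selected_hits))
    gm, cohort = align(gm, cohort)
    e = cohort.exposure_indicator(name)
    y = cohort.is_case().astype(float)
    cov_df = _expand_covariates(cohort, covariate_names)
    results = []
    for hit in selected_hits:
        g = gm.dosage_of(hit.variant.id)
        base = {"const": np.ones_like(e), "E": e, "G": g, "GxE": e * g}
        for cname in cov_df.columns:
            c = cov_df[cname].to_numpy()
            base[cname] = c
            base[f"{cname}:E"] = c * e
            base[f"{cname}:G"] = c * g
        X = np.column_stack(list(base.values()))
        names = list(base.keys())
        try:
            fit = fit_logistic(X, y, names=names)
        except ValueError as exc:
            results.append(
                InteractionResult(
                    variant=hit.variant,
                    exposure_name=name,
                    or_ge=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    p_ge=float("nan"),
                    threshold=threshold,
                    significant=False,
                    suggestive=False,
                    n_used=int(np.isfinite(X).all(axis=1).sum()),
                    method="none",
                    na_reason=str(exc),
                )
            )
            continue
        term = fit["GxE"]
        ci = np.exp(term["beta"] + np.array([-1.0, 1.0]) * 1.959963984540054 * term["se"])
        p = float(term["p"])
        results.append(
            InteractionResult(
                variant=hit.variant,
                exposure_name=name,
                or_ge=float(np.exp(term["beta"])),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p_ge=p,
                threshold=threshold,
                significant=bool(p < threshold),
                suggestive=bool(p < alpha_suggestive),
                n_used=fit.n_used,
                method=fit.method,
            )
        )
    return results


# ------------------------------------------------------------------ model objects

@dataclass
class ExposureAnalysis:
    """Everything the two-step produced for one exposure."""

    exposure_name: str
    screen_hits: list
    selected: list
    threshold: float | None
    interactions: list
    error: str = ""

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def lowest_p_screen(self) -> float:
        return min((h.p_screen for h in self.screen_hits), default=float("nan"))


class GxEInteractionResults(Mapping):
    """Results of :meth:`GxEInteractionModel.fit`; mapping exposure -> analysis."""

    def __init__(self, analyses: dict, model: "GxEInteractionModel"):
        self._analyses = analyses
        self.model = model

    def __getitem__(self, key):
        return self._analyses[key]

    def __iter__(self):
        return iter(self._analyses)

    def __len__(self):
        return len(self._analyses)

    def summary_frame(self) -> pd.DataFrame:
        """One row per exposure: selected count, lowest screen p, threshold."""
        rows = []
        for name, a in self._analyses.items():
            rows.append(
                {
                    "exposure": name,
                    "n_selected": a.n_selected,
                    "lowest_p_step_one": a.lowest_p_screen,
                    "threshold_step_two": a.threshold,
                    "threshold_display": round_sig(a.threshold, 2) if a.threshold else np.nan,
                    "n_significant": sum(r.significant for r in a.interactions),
                    "n_suggestive": sum(r.suggestive for r in a.interactions),
                    "error": a.error,
                }
            )
        return pd.DataFrame(rows)

    def interaction_frame(self) -> pd.DataFrame:
        rows = [r.to_row() for a in self._analyses.values() for r in a.interactions]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        lines = ["Two-step GxE interaction analysis", "=" * 48]
        lines.append(df.to_string(index=False))
        sig = [
            r
            for a in self._analyses.values()
            for r in a.interactions
            if r.significant
        ]
        lines.append(f"significant interactions: {len(sig)}")
        for r in sig:
            lines.append(
                f"  {r.variant.id} x {r.exposure_name}: OR {r.or_ge:.1f} "
                f"({r.ci_low:.1f}-{r.ci_high:.1f}), p {r.p_ge:.2g} < {r.threshold:.2g}"
            )
        return "\n".join(lines)


class GxEInteractionModel:
    """Two-step genome-wide gene-environment interaction model.

    Parameters
    ----------
    gm, cohort : aligned-by-sample genotype and phenotype data (QC'd).
    exposures : exposure definitions or names of canonical exposure columns.
    covariates : cohort columns entering step two with C, C:E and C:G terms.
    p_max, r2_max : step-one selection threshold and LD-independence bound.
    alpha : family-wise level; the per-exposure step-two threshold is
        ``alpha / n_selected``.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        cohort: CohortTable,
        exposures: Sequence,
        covariates: Sequence[str] = (),
        p_max: float = 1e-5,
        r2_max: float = 0.6,
        alpha: float = 0.05,
    ):
        self.gm, self.cohort = align(gm, cohort)
        self.exposures = list(exposures)
        self.covariates = list(covariates)
        self.p_max = p_max
        self.r2_max = r2_max
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, dosage_df: pd.DataFrame, cohort_df: pd.DataFrame, **kw):
        """Build from a samples x variants dosage frame and a cohort frame."""
        variants = [
            VariantRecord(str(c), "0", j + 1, "A", "B") for j, c in enumerate(dosage_df.columns)
        ]
        gm = GenotypeMatrix(dosage_df.to_numpy(dtype=float), list(dosage_df.index), variants)
        exposures = kw.pop("exposures")
        cohort = CohortTable(cohort_df, [e.name if isinstance(e, ExposureDefinition) else e for e in exposures])
        return cls(gm, cohort, exposures, **kw)

    def fit(self, on_error: str = "record") -> GxEInteractionResults:
        """Run screen -> clump -> threshold -> interaction tests per exposure.

        ``on_error='record'`` stores per-exposure failures (e.g. too few
        exposed samples) in the results; ``'raise'`` propagates them with
        the exposure named.
        """
        analyses = {}
        for exp in self.exposures:
            name = exp.name if isinstance(exp, ExposureDefinition) else exp
            try:
                hits = step_one_screen(self.gm, self.cohort, exp)
                selected = clump_independent(hits, self.gm, self.p_max, self.r2_max)
                if selected:
                    threshold = self.alpha / len(selected)
                    interactions = step_two_test(
                        self.gm, self.cohort, exp, selected, self.covariates, threshold
                    )
                else:
                    threshold, interactions = None, []
                analyses[name] = ExposureAnalysis(name, hits, selected, threshold, interactions)
            except ValueError as exc:
                if on_error == "raise":
                    raise ValueError(f"exposure {name!r}: {exc}") from exc
                analyses[name] = ExposureAnalysis(name, [], [], None, [], error=str(exc))
        return GxEInteractionResults(analyses, self)


def run_two_step(
    gm: GenotypeMatrix,
    cohort: CohortTable,
    exposure_defs: Sequence,
    covariates: Sequence[str] = (),
    p_max: float = 1e-5,
    r2_max: float = 0.6,
    alpha: float = 0.05,
) -> GxEInteractionResults:
    """Functional entry point; see :class:`GxEInteractionModel`."""
    model = GxEInteractionModel(gm, cohort, exposure_defs, covariates, p_max, r2_max, alpha)
    return model.fit()
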