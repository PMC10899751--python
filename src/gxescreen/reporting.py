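"""Genotype-stratified odds ratios and cohort characteristics tables.

The stratified view re-expresses an interaction clinically: the exposure's
2x2 odds ratio for disease is computed separately within each genotype
stratum (0, 1 or 2 alternative alleles).  Strata that are too small to
support an estimate (fewer than 10 samples, or any empty 2x2 cell) are
reported as n/a with their counts still shown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CASE, CohortTable, ExposureDefinition, VariantRecord

__all__ = ["StratumOR", "StratifiedOR", "crude_or", "stratified_or", "characteristics_table"]

Z975 = 1.959963984540054
MIN_STRATUM = 10


@dataclass(frozen=True)
class StratumOR:
    """One genotype stratum's 2x2 exposure-disease table and OR."""

    genotype: int
    n_cases: int
    n_controls: int
    #: counts (exposed cases, unexposed cases, exposed controls, unexposed controls)
    table: tuple
    or_: float
    ci_low: float
    ci_high: float
    na_reason: str = ""

    @property
    def available(self) -> bool:
        return self.na_reason == ""


@dataclass(frozen=True)
class StratifiedOR:
    """Per-genotype exposure odds ratios for one variant/exposure pair."""

    variant: VariantRecord
    exposure_name: str
    strata: tuple  # three StratumOR, genotypes 0/1/2

    def to_row(self) -> dict:
        row = {"variant_id": self.variant.id, "exposure": self.exposure_name}
        for s in self.strata:
            g = s.genotype
            row[f"g{g}_n_cases"] = s.n_cases
            row[f"g{g}_n_controls"] = s.n_controls
            row[f"g{g}_or"] = s.or_
            row[f"g{g}_ci_low"] = s.ci_low
            row[f"g{g}_ci_high"] = s.ci_high
            row[f"g{g}_na_reason"] = s.na_reason
        return row


def crude_or(a: int, b: int, c: int, d: int) -> tuple:
    """Crude 2x2 odds ratio ``ad/bc`` with a Woolf (log-normal) 95% CI.

    Cell layout: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls.  Any zero cell makes the estimate
    undefined: returns ``(nan, (nan, nan), "zero cell")``.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        return float("nan"), (float("nan"), float("nan")), "zero cell"
    or_ = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.0, 1.0]) * Z975 * se)
    return float(or_), (float(lo), float(hi)), ""


def stratified_or(
    cohort: CohortTable,
    exposure: ExposureDefinition | str,
    dosage,
    variant: VariantRecord | None = None,
    min_stratum: int = MIN_STRATUM,
) -> StratifiedOR:
    """Exposure-disease odds ratio within each genotype stratum.

    Complete cases on exposure and genotype only.  A stratum is n/a when
    its total size is below ``min_stratum`` or its 2x2 table has an empty
    cell; counts are reported either way.
    """
    name = exposure.name if isinstance(exposure, ExposureDefinition) else exposure
    e = cohort.exposure_indicator(name)
    g = np.asarray(dosage, dtype=float)
    y = cohort.is_case()
    keep = np.isfinite(e) & np.isfinite(g)
    e, g, y = e[keep], g[keep], y[keep]
    strata = []
    for gt in (0, 1, 2):
        m = g == gt
        a = int(((e == 1) & y & m).sum())
        b = int(((e == 0) & y & m).sum())
        c = int(((e == 1) & ~y & m).sum())
        d = int(((e == 0) & ~y & m).sum())
        n_cases, n_controls = a + b, c + d
        total = n_cases + n_controls
        if total < min_stratum:
            or_, ci, reason = float("nan"), (float("nan"), float("nan")), "stratum too small"
        else:
            or_, ci, reason = crude_or(a, b, c, d)
        strata.append(
            StratumOR(gt, n_cases, n_controls, (a, b, c, d), or_, ci[0], ci[1], reason)
        )
    if variant is None:
        variant = VariantRecord("variant", "0", 1, "A", "B")
    return StratifiedOR(variant, name, tuple(strata))


def characteristics_table(
    cohort: CohortTable, exposure_defs: Sequence = (), covariates: Sequence[str] = ()
) -> pd.DataFrame:
    """Cohort characteristics: per level, ``n (%)`` among cases and controls.

    Percentages are of the column totals, rounded to integers; missing
    values get their own row.  Numeric covariates are summarised as
    ``mean (SD)`` instead.
    """
    is_case = cohort.is_case()
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())

    def fmt(n, total):
        pct = round(100.0 * n / total) if total else 0
        return f"{n} ({pct})"

    rows = []
    exp_names = [d.name if isinstance(d, ExposureDefinition) else d for d in exposure_defs]
    for name in list(exp_names) + list(covariates):
        col = cohort.df[name]
        if pd.api.types.is_numeric_dtype(col):
            rows.append(
                {
                    "characteristic": name,
                    "level": "mean (SD)",
                    "cases": f"{col[is_case].mean():.2f} ({col[is_case].std():.2f})",
                    "controls": f"{col[~is_case].mean():.2f} ({col[~is_case].std():.2f})",
                }
            )
            continue
        levels = list(pd.unique(col.dropna()))
        for lev in levels + ["missing"]:
            if lev == "missing":
                mask = col.isna().to_numpy()
            else:
                mask = (col == lev).to_numpy()
            rows.append(
                {
                    "characteristic": name,
                    "level": str(lev),
                    "cases": fmt(int((mask & is_case).sum()), n_case),
                    "controls": fmt(int((mask & ~is_case).sum()), n_ctrl),
                }
            )
    return pd.DataFrame(rows)
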