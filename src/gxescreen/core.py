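"""Shared domain containers: variants, genotype matrices, cohort tables, exposures.

Conventions used throughout the package:

* genotypes are stored as *allele dosages* (count of alternative alleles,
  0/1/2) in a ``samples x variants`` float array; missing genotypes are
  ``NaN`` and are never silently imputed by readers;
* coordinates are 1-based (VCF convention);
* exposure status lives in a four-level domain ``exposed / unexposed /
  excluded / missing`` so that contrasts that drop a category (e.g. the
  subfertile-without-ART group in an ART contrast) are expressed as data,
  not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXPOSED",
    "UNEXPOSED",
    "EXCLUDED",
    "VariantRecord",
    "ExposureDefinition",
    "GenotypeMatrix",
    "CohortTable",
    "align",
]

#: canonical exposure levels; missing is represented by NaN / None
EXPOSED = "exposed"
UNEXPOSED = "unexposed"
EXCLUDED = "excluded"
_EXPOSURE_LEVELS = {EXPOSED, UNEXPOSED, EXCLUDED}

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic single-nucleotide variant.

    ``id`` is the rsID when known, otherwise ``chrom:pos:ref:alt``.
    Positions are 1-based.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")

    @property
    def sort_key(self) -> tuple:
        """Genomic ordering key (numeric chromosomes before lexical ones)."""
        try:
            return (0, int(self.chrom.lstrip("chr")), self.pos)
        except ValueError:
            return (1, self.chrom, self.pos)


@dataclass(frozen=True)
class ExposureDefinition:
    """Maps raw labels of one exposure column onto the four-level domain.

    ``excluded_labels`` name categories dropped from that exposure's
    analyses entirely (neither exposed nor reference), e.g. parents who
    report subfertility but no ART use in an ART contrast.
    """

    name: str
    exposed_label: str
    reference_label: str
    excluded_labels: tuple = ()

    def __post_init__(self) -> None:
        if self.exposed_label == self.reference_label:
            raise ValueError(f"exposure {self.name}: exposed and reference labels coincide")
        overlap = set(self.excluded_labels) & {self.exposed_label, self.reference_label}
        if overlap:
            raise ValueError(f"exposure {self.name}: excluded labels overlap contrast: {overlap}")

    def map_label(self, raw) -> object:
        """Map one raw cell value to exposed/unexposed/excluded/NaN."""
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return np.nan
        raw = str(raw).strip()
        if raw == "" or raw.lower() in {"na", "nan", "missing"}:
            return np.nan
        if raw == self.exposed_label:
            return EXPOSED
        if raw == self.reference_label:
            return UNEXPOSED
        if raw in self.excluded_labels:
            return EXCLUDED
        if raw in _EXPOSURE_LEVELS:  # already canonical
            return raw
        raise ValueError(f"exposure {self.name}: unknown label {raw!r}")


class GenotypeMatrix:
    """Samples x variants allele-dosage matrix with missingness.

    Parameters
    ----------
    dosage : array of shape (n_samples, n_variants)
        Values in {0, 1, 2} or NaN for missing.
    samples : sequence of unique sample identifiers.
    variants : sequence of :class:`VariantRecord` with unique ids.
    """

    def __init__(self, dosage, samples: Sequence[str], variants: Sequence[VariantRecord]):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        if dosage.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        finite = dosage[np.isfinite(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be in {{0,1,2}} or NaN; found {bad[:5]}")
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate variant id(s): {list(dup[dup > 1].index[:5])}")
        self.dosage = dosage
        self.samples = samples
        self.variants = list(variants)

    # -- basic shape -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [v.id for v in self.variants]

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_variants} variants>"

    # -- summaries ---------------------------------------------------
    def variant_call_rate(self) -> np.ndarray:
        return np.isfinite(self.dosage).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return np.isfinite(self.dosage).mean(axis=1)

    def alt_allele_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, on non-missing dosages."""
        p = self.alt_allele_frequency()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self, mask=None) -> np.ndarray:
        """(n_variants, 3) counts of dosages 0/1/2, over ``mask`` rows if given."""
        d = self.dosage if mask is None else self.dosage[np.asarray(mask)]
        out = np.empty((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(d == g, axis=0)
        return out

    # -- subsetting --------------------------------------------------
    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        """Subset by boolean masks or integer indices along either axis."""
        sidx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        if sidx.dtype == bool:
            sidx = np.flatnonzero(sidx)
        vidx = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if vidx.dtype == bool:
            vidx = np.flatnonzero(vidx)
        return GenotypeMatrix(
            self.dosage[np.ix_(sidx, vidx)],
            [self.samples[i] for i in sidx],
            [self.variants[i] for i in vidx],
        )

    def reorder_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None
        return self.subset(samples=np.asarray(idx, dtype=int))

    def dosage_of(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix") from None
        return self.dosage[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.samples, columns=self.variant_ids)


class CohortTable:
    """Per-sample phenotype table: case/control status, exposures, covariates.

    Backed by a :class:`pandas.DataFrame` with a unique ``sample_id`` column,
    a ``status`` column in {case, control}, one column per named exposure in
    the four-level domain, and arbitrary covariate columns.
    """

    def __init__(self, df: pd.DataFrame, exposure_names: Sequence[str] = ()):
        df = df.copy()
        if "sample_id" not in df.columns:
            raise ValueError("cohort table needs a 'sample_id' column")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if "status" not in df.columns:
            raise ValueError("cohort table needs a 'status' column")
        bad = set(df["status"].dropna().unique()) - {CASE, CONTROL}
        if bad or df["status"].isna().any():
            raise ValueError(f"status must be 'case' or 'control'; found {bad or 'missing values'}")
        for name in exposure_names:
            if name not in df.columns:
                raise ValueError(f"exposure column {name!r} missing from cohort table")
            vals = set(df[name].dropna().unique()) - _EXPOSURE_LEVELS
            if vals:
                raise ValueError(f"exposure {name}: values outside the 4-level domain: {vals}")
        df["sample_id"] = df["sample_id"].astype(str)
        self.df = df.reset_index(drop=True)
        self.exposure_names = list(exposure_names)

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def is_case(self) -> np.ndarray:
        return (self.df["status"] == CASE).to_numpy()

    def exposure_indicator(self, name: str) -> np.ndarray:
        """1.0 for exposed, 0.0 for unexposed, NaN for excluded/missing."""
        if name not in self.df.columns:
            raise KeyError(f"exposure {name!r} not in cohort table")
        col = self.df[name]
        out = np.full(len(col), np.nan)
        out[(col == EXPOSED).to_numpy()] = 1.0
        out[(col == UNEXPOSED).to_numpy()] = 0.0
        return out

    def reorder(self, sample_ids: Iterable[str]) -> "CohortTable":
        indexed = self.df.set_index("sample_id")
        try:
            sub = indexed.loc[list(sample_ids)].reset_index()
        except KeyError as exc:
            raise KeyError(f"sample(s) missing from cohort table: {exc.args[0]}") from None
        return CohortTable(sub, self.exposure_names)

    def __repr__(self) -> str:
        n_case = int(self.is_case().sum())
        return (
            f"<CohortTable {self.n_samples} samples ({n_case} cases), "
            f"exposures={self.exposure_names}>"
        )


def align(gm: GenotypeMatrix, cohort: CohortTable) -> tuple:
    """Intersect and co-order a genotype matrix and cohort table by sample_id.

    The result is independent of the input row orders: the intersection is
    taken in sorted sample_id order.
    """
    common = set(gm.samples) & set(cohort.sample_ids)
    if not common:
        raise ValueError("no samples shared between genotype matrix and cohort table")
    keep = sorted(common)
    return gm.reorder_samples(keep), cohort.reorder(keep)
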