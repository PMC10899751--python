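"""Readers and writers for the formats the pipeline touches.

VCF 4.x (GT field only, biallelic records) is the canonical genotype
interchange format; a plain dosage TSV (variants x samples) is accepted as a
frictionless alternative.  Cohort tables and all results are TSV with
header.  Exposure definitions and pipeline parameters travel as YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import CohortTable, ExposureDefinition, GenotypeMatrix, VariantRecord

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_cohort_table",
    "write_results_tsv",
    "read_results_tsv",
    "read_exposure_definitions",
]


# ---------------------------------------------------------------- VCF

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with GT genotypes into a :class:`GenotypeMatrix`.

    Multiallelic records and files without a GT FORMAT field raise a
    descriptive error.  ``./.`` and ``.`` genotypes become NaN.  Sample
    order is preserved from the header.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen = set()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"multiallelic not supported: {rec.chrom}:{rec.pos} has alts {rec.alts}"
            )
        if "GT" not in rec.format:
            raise ValueError(f"record {rec.chrom}:{rec.pos} lacks a GT FORMAT field")
        vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
        if vid in seen:
            raise ValueError(f"duplicate variant id {vid!r}")
        seen.add(vid)
        variants.append(VariantRecord(vid, str(rec.chrom), rec.pos, rec.ref, rec.alts[0]))
        row = np.empty(len(samples))
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                row[i] = np.nan
            else:
                row[i] = float(sum(1 for a in gt if a == 1))
        rows.append(row)
    vf.close()
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosage, samples, variants)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased GT-only VCF 4.2 text file."""
    chroms = []
    for v in gm.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gxescreen\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        order = sorted(range(gm.n_variants), key=lambda j: gm.variants[j].sort_key)
        for j in order:
            v = gm.variants[j]
            gts = [gt_map.get(d, "./.") if np.isfinite(d) else "./." for d in gm.dosage[:, j]]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------- dosage TSV

def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Variants x samples dosage table with variant metadata columns."""
    meta = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "ref": [v.ref for v in gm.variants],
            "alt": [v.alt for v in gm.variants],
        }
    )
    dos = pd.DataFrame(gm.dosage.T, columns=gm.samples)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV lacks column(s) {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    variants = [
        VariantRecord(str(r.variant_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    dosage = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosage, samples, variants)


# ---------------------------------------------------------------- cohort

def read_cohort_table(path, exposure_defs: Sequence[ExposureDefinition]) -> CohortTable:
    """Read a TSV cohort table, mapping raw exposure labels via definitions.

    The file needs ``sample_id`` and ``status`` columns plus one column per
    exposure definition (named after the definition).  Unknown exposure
    labels raise; empty cells become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA", ""])
    for ed in exposure_defs:
        if ed.name not in df.columns:
            raise ValueError(f"cohort table lacks exposure column {ed.name!r}")
        df[ed.name] = df[ed.name].map(ed.map_label)
    return CohortTable(df, [ed.name for ed in exposure_defs])


def read_exposure_definitions(path) -> list:
    """Exposure definitions from a YAML/JSON list of mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(
            ExposureDefinition(
                name=item["name"],
                exposed_label=item["exposed_label"],
                reference_label=item["reference_label"],
                excluded_labels=tuple(item.get("excluded_labels", ())),
            )
        )
    return defs


# ---------------------------------------------------------------- results

_DISPLAY_RULES = {
    "or_ge": "or",
    "or": "or",
    "ci_low": "or",
    "ci_high": "or",
    "p_ge": "p",
    "p_screen": "p",
    "p": "p",
    "threshold": "p",
}


def _display(value: float, kind: str) -> str:
    """Study-style display rounding: ORs/CIs to 1 decimal, p to 2 sig. figures."""
    if value is None or not np.isfinite(value):
        return "n/a"
    if kind == "or":
        return f"{value:.1f}"
    if value == 0:
        return "0"
    from .twostep import round_sig  # local import to avoid cycle

    return f"{round_sig(value, 2):.2g}"


def write_results_tsv(records: Sequence, path, record_type=None) -> None:
    """Serialize result dataclasses to TSV.

    Column order is the dataclass field order; floats carry full precision
    and columns with reporting conventions get an extra ``*_display``
    column rounded per those rules.  An empty record list produces a
    header-only file (pass ``record_type`` to name the columns).
    """
    records = list(records)
    if not records:
        names = []
        if record_type is not None:
            probe = record_type
            if hasattr(probe, "row_fields"):
                names = list(probe.row_fields())
            elif dataclasses.is_dataclass(probe):
                names = [f.name for f in dataclasses.fields(probe)]
        with open(path, "w") as fh:
            fh.write("\t".join(names) + "\n")
        return
    rows = [r.to_row() if hasattr(r, "to_row") else dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    for col, kind in _DISPLAY_RULES.items():
        if col in df.columns and pd.api.types.is_float_dtype(df[col]):
            df[col + "_display"] = [_display(v, kind) for v in df[col]]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")


# ---------------------------------------------------------------- config

def read_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)
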