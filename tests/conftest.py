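import numpy as np
import pytest

from gxescreen.core import CohortTable, GenotypeMatrix, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_gm(dosage, sample_prefix="S", chrom="1"):
    """GenotypeMatrix from a raw (n, M) dosage array with synthetic metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    variants = [
        VariantRecord(f"v{j:04d}", chrom, 1000 * (j + 1), "A", "G") for j in range(m)
    ]
    return GenotypeMatrix(dosage, samples, variants)


def make_cohort(status, exposure=None, sample_prefix="S", **covariates):
    """CohortTable from arrays; ``exposure`` is 1/0/NaN mapped to the 4-level domain."""
    import pandas as pd

    n = len(status)
    data = {
        "sample_id": [f"{sample_prefix}{i:04d}" for i in range(n)],
        "status": ["case" if s else "control" for s in np.asarray(status, dtype=bool)],
    }
    exposure_names = []
    if exposure is not None:
        e = np.asarray(exposure, dtype=float)
        col = np.where(e == 1.0, "exposed", np.where(e == 0.0, "unexposed", None))
        data["exposure"] = col
        exposure_names = ["exposure"]
    data.update(covariates)
    return CohortTable(pd.DataFrame(data), exposure_names)


@pytest.fixture
def small_vcf(tmp_path):
    """A hand-written 2-variant, 3-sample VCF."""
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1\n"
    )
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path
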