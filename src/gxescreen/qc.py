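"""Variant- and sample-level genotype quality control.

Filters mirror standard array-GWAS practice: variant call rate >= 98%,
minor allele frequency >= 1%, and an exact Hardy-Weinberg equilibrium test
applied separately within cases (p >= 1e-10) and controls (p >= 1e-6);
samples need call rate >= 98% and pairwise KING-robust kinship below the
third-degree boundary (0.0442).  Principal components for ancestry
adjustment come from the standardised dosage matrix.

Filter order is fixed (call rate -> MAF -> HWE for variants; call rate ->
kinship for samples) and every removal is recorded in a :class:`QCReport`
so order effects stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .core import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "variant_qc",
    "sample_qc",
    "king_kinship",
    "compute_pcs",
]


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control cutoffs; defaults follow common array-GWAS practice."""

    variant_call_rate_min: float = 0.98
    sample_call_rate_min: float = 0.98
    hwe_p_min_cases: float = 1e-10
    hwe_p_min_controls: float = 1e-6
    maf_min: float = 0.01
    #: conventional 3rd-degree kinship boundary, 2**(-4.5)
    kinship_3rd_degree: float = 0.0442

    def __post_init__(self):
        for name in (
            "variant_call_rate_min",
            "sample_call_rate_min",
            "hwe_p_min_cases",
            "hwe_p_min_controls",
            "maf_min",
            "kinship_3rd_degree",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.hwe_p_min_cases > self.hwe_p_min_controls:
            raise ValueError("case HWE threshold must be <= control threshold")


@dataclass
class QCReport:
    """Per-variant / per-sample QC metrics, pass flags and removal tallies."""

    variant_table: pd.DataFrame | None = None
    sample_table: pd.DataFrame | None = None
    removals: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["QC report"]
        for rule, n in self.removals.items():
            lines.append(f"  removed by {rule}: {n}")
        return "\n".join(lines)


# ------------------------------------------------------------------ HWE

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose probability does not
    exceed that of the observed table.  Uses the standard recurrence on
    adjacent heterozygote counts, so no factorials are evaluated.
    Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare allele count
    # attainable het counts share the parity of n_rare and are <= min(n_rare, 2n - n_rare)
    het_max = min(n_rare, 2 * n - n_rare)
    if het_max == 0:
        return 1.0
    parity = n_rare % 2
    # log-scale recurrence (avoids under/overflow on large tables):
    #   P(h+2)/P(h) = 4 * n_hom_rare(h) * n_hom_common(h) / ((h+2)(h+1))
    hets = np.arange(parity, het_max + 1, 2)
    logw = np.empty(len(hets))
    logw[0] = 0.0
    for i in range(1, len(hets)):
        h = int(hets[i - 1])
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logw[i] = logw[i - 1] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2.0) * (h + 1.0))
    logp = logw - special.logsumexp(logw)
    obs = logp[int(np.searchsorted(hets, n_het))]
    p = float(np.exp(special.logsumexp(logp[logp <= obs + 1e-12])))
    return min(p, 1.0)


# ------------------------------------------------------------------ variant QC

def variant_qc(
    gm: GenotypeMatrix, status, thresholds: QCThresholds = QCThresholds()
) -> tuple:
    """Remove variants failing call rate, MAF, or within-stratum HWE.

    ``status`` is a boolean case indicator aligned with ``gm.samples``.
    Filters apply in the fixed order call rate -> MAF -> HWE; metrics are
    computed on the input matrix and each variant's first failing rule is
    recorded.  HWE is tested on cases and controls separately with their
    respective thresholds.
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    status = np.asarray(status, dtype=bool)
    if status.shape[0] != gm.n_samples:
        raise ValueError("status vector not aligned with genotype samples")

    call_rate = gm.variant_call_rate()
    maf = gm.maf()
    cc = gm.genotype_counts(mask=status)
    ct = gm.genotype_counts(mask=~status)
    hwe_cases = np.array([hwe_exact_test(*row) if row.sum() else 1.0 for row in cc])
    hwe_controls = np.array([hwe_exact_test(*row) if row.sum() else 1.0 for row in ct])

    pass_cr = call_rate >= thresholds.variant_call_rate_min
    pass_maf = maf >= thresholds.maf_min
    pass_hwe = (hwe_cases >= thresholds.hwe_p_min_cases) & (
        hwe_controls >= thresholds.hwe_p_min_controls
    )
    reason = np.array([""] * gm.n_variants, dtype=object)
    reason[~pass_hwe] = "hwe"
    reason[~pass_maf] = "maf"
    reason[~pass_cr] = "call_rate"  # first rule wins
    keep = pass_cr & pass_maf & pass_hwe

    table = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p_cases": hwe_cases,
            "hwe_p_controls": hwe_controls,
            "pass_call_rate": pass_cr,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "pass": keep,
            "removal_reason": reason,
        }
    )
    removals = {
        "call_rate": int((~pass_cr).sum()),
        "maf": int((pass_cr & ~pass_maf).sum()),
        "hwe": int((pass_cr & pass_maf & ~pass_hwe).sum()),
    }
    report = QCReport(variant_table=table, removals=removals)
    return gm.subset(variants=keep), report


# ------------------------------------------------------------------ kinship

def king_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise KING-robust kinship coefficients.

    For samples i, j over loci non-missing in both:
    ``phi = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))``.
    Duplicates/MZ twins give ~0.5, parent-offspring ~0.25, unrelated ~0.
    The diagonal is set to 0.5.
    """
    d = gm.dosage
    valid = np.isfinite(d)
    het = (d == 1.0) & valid
    hom0 = (d == 0.0) & valid
    hom2 = (d == 2.0) & valid
    # float32 matmuls: exact for integer counts << 2**24
    hetf = het.astype(np.float32)
    validf = valid.astype(np.float32)
    n_hethet = hetf @ hetf.T
    m02 = hom0.astype(np.float32) @ hom2.astype(np.float32).T
    n_opp = m02 + m02.T
    # het count of i restricted to loci valid in j (and vice versa)
    het_i = hetf @ validf.T
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi = np.asarray(phi, dtype=float)
    phi[~np.isfinite(phi)] = 0.0
    np.fill_diagonal(phi, 0.5)
    return phi


def sample_qc(gm: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()) -> tuple:
    """Remove low-call-rate samples, then break related pairs.

    Relatedness: one member of each pair with KING-robust kinship above the
    3rd-degree cutoff is dropped, greedily removing the sample involved in
    the most flagged pairs (ties broken by lower call rate, then by later
    sample order) until no flagged pair remains.
    """
    if gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    call_rate = gm.sample_call_rate()
    pass_cr = call_rate >= thresholds.sample_call_rate_min
    gm_cr = gm.subset(samples=pass_cr)
    cr_kept = call_rate[pass_cr]

    phi = king_kinship(gm_cr)
    flagged = phi > thresholds.kinship_3rd_degree
    np.fill_diagonal(flagged, False)
    removed_kinship: list = []
    active = np.ones(gm_cr.n_samples, dtype=bool)
    while True:
        counts = (flagged & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        cand = np.flatnonzero(counts == worst)
        # ties: lower call rate first, then later index
        cand = sorted(cand, key=lambda i: (cr_kept[i], -i))
        drop = cand[0]
        active[drop] = False
        removed_kinship.append(gm_cr.samples[drop])

    table = pd.DataFrame(
        {
            "sample_id": gm.samples,
            "call_rate": call_rate,
            "pass_call_rate": pass_cr,
        }
    )
    table["removed_kinship"] = table["sample_id"].isin(removed_kinship)
    table["pass"] = table["pass_call_rate"] & ~table["removed_kinship"]
    removals = {
        "sample_call_rate": int((~pass_cr).sum()),
        "kinship": len(removed_kinship),
    }
    report = QCReport(sample_table=table, removals=removals)
    return gm_cr.subset(samples=active), report


# ------------------------------------------------------------------ PCA

def compute_pcs(gm: GenotypeMatrix, k: int = 4, outlier_sd: float | None = None):
    """Top-``k`` principal component scores of the standardised dosages.

    Dosages are mean-imputed per variant and scaled by ``sqrt(2 p (1-p))``
    (the binomial standard deviation under Hardy-Weinberg), monomorphic
    variants dropped.  Scores are ``U * S`` from the SVD of the centred
    matrix, so columns are mutually orthogonal with zero means; each
    component's sign is fixed by making its largest-magnitude variant
    loading positive.

    If ``outlier_sd`` is given, also returns a boolean flag for samples
    farther than that many SDs from the mean on any PC (a crude ancestry
    outlier screen, off by default).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        scores = np.empty((gm.n_samples, 0))
        return (scores, np.zeros(gm.n_samples, dtype=bool)) if outlier_sd else scores
    d = gm.dosage.copy()
    p = gm.alt_allele_frequency()
    keep = (p > 0) & (p < 1) & np.isfinite(p)
    d = d[:, keep]
    p = p[keep]
    col_mean = 2.0 * p
    nan = ~np.isfinite(d)
    d[nan] = np.take(col_mean, np.nonzero(nan)[1])
    x = (d - d.mean(axis=0)) / np.sqrt(2.0 * p * (1.0 - p))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * max(x.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the standardised dosage matrix")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    if outlier_sd:
        sd = scores.std(axis=0, ddof=1)
        zz = np.abs(scores - scores.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        return scores, (zz > outlier_sd).any(axis=1)
    return scores
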