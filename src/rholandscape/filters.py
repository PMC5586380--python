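"""Site-level variant filtering for LD-based map inference.

The filter set mirrors the selection applied before phasing and rate
estimation: biallelic SNPs only, a variant-quality floor (QUAL), a
per-genotype quality floor (GQ) applied with any-individual semantics (one
failing individual removes the site), optional per-individual depth bounds,
and an exact Hardy-Weinberg equilibrium test with exclusion below a
configurable p-value.  The HWE test is the exact conditional test: given the
minor-allele count, heterozygote counts are enumerated and the p-value sums
the probabilities of all configurations no more probable than the observed
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FilterConfig",
    "SiteRecord",
    "FilterReport",
    "hwe_exact_test",
    "filter_sites",
    "read_vcf_sites",
]


@dataclass
class FilterConfig:
    """Thresholds for site filtering.

    min_qual: variant QUAL floor (default 30).
    min_gq: per-genotype GQ floor, any-individual semantics (default 15).
    dp_bounds: optional (low, high) per-individual depth range, inclusive.
    hwe_alpha: sites with exact-HWE p below this are excluded (default 0.002).
    """

    min_qual: float = 30.0
    min_gq: float = 15.0
    dp_bounds: tuple[float, float] | None = None
    hwe_alpha: float = 0.002

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_gq < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0, 1)")


@dataclass
class SiteRecord:
    """Minimal per-site record for filtering.

    ``genotypes`` holds per-individual allele-index pairs (0 = ref,
    1.. = alt, -1 = missing).  ``gq``/``dp`` are per-individual arrays
    aligned with genotypes; either may be None when the annotation is
    absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def is_biallelic_snp(self) -> bool:
        alleles = (self.ref, *self.alts)
        return len(self.alts) == 1 and all(
            len(a) == 1 and a in "ACGT" for a in alleles
        )

    def genotype_counts(self) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts over called genotypes."""
        gt = np.asarray(self.genotypes)
        called = gt[(gt >= 0).all(axis=1)]
        n_alt = (called == 1).sum(axis=1)
        return int((n_alt == 0).sum()), int((n_alt == 1).sum()), int((n_alt == 2).sum())


@dataclass
class FilterReport:
    """Counts of sites removed per rule, in application order."""

    n_input: int = 0
    removed: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed minor-allele count; the p-value is the summed
    probability of all heterozygote configurations whose probability does
    not exceed that of the observed one.  The enumeration uses exact integer
    configuration counts (``n! / (nAA! nAa! naa!) * 2^nAa``), so comparisons
    are free of rounding.  Monomorphic sites return 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    minor = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    if minor == 0:
        return 1.0

    def weight(h: int) -> int:
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_minor < 0 or hom_major < 0:
            return 0
        # multinomial count of genotype assignments x 2^h allele orderings
        return (
            comb(n, h) * comb(n - h, hom_minor) * (2**h)
        )

    support = range(minor % 2, minor + 1, 2)
    weights = {h: weight(h) for h in support}
    total = sum(weights.values())
    observed = weights[n_het]
    p_num = sum(w for w in weights.values() if w <= observed)
    return p_num / total


def _first_failure(record: SiteRecord, config: FilterConfig) -> str | None:
    if not record.is_biallelic_snp():
        return "not_biallelic_snp"
    if record.qual is not None and record.qual < config.min_qual:
        return "low_qual"
    if record.gq is not None and np.any(np.asarray(record.gq) < config.min_gq):
        return "low_gq"
    if config.dp_bounds is not None and record.dp is not None:
        lo, hi = config.dp_bounds
        dp = np.asarray(record.dp)
        if np.any((dp < lo) | (dp > hi)):
            return "depth_out_of_bounds"
    n_rr, n_ra, n_aa = record.genotype_counts()
    if n_rr + n_ra + n_aa > 0:
        if hwe_exact_test(n_rr, n_ra, n_aa) < config.hwe_alpha:
            return "hwe_fail"
    return None


def filter_sites(
    records: Iterable[SiteRecord], config: FilterConfig | None = None
) -> tuple[list[SiteRecord], FilterReport]:
    """Apply the filter cascade; returns kept records and a per-rule report.

    Each removed site is attributed to the first rule it fails, in the
    order: biallelic-SNP, QUAL, GQ, depth, HWE.  Filtering is idempotent.
    """
    config = config or FilterConfig()
    kept: list[SiteRecord] = []
    report = FilterReport()
    for record in records:
        report.n_input += 1
        reason = _first_failure(record, config)
        if reason is None:
            kept.append(record)
        else:
            report.removed[reason] = report.removed.get(reason, 0) + 1
    return kept, report


def read_vcf_sites(path: str) -> list[SiteRecord]:
    """Load :class:`SiteRecord` objects from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(path)
    try:
        for variant in vcf:
            genotypes = np.array(
                [[g[0], g[1]] for g in variant.genotypes], dtype=np.int64
            )
            gq = variant.gt_quals
            gq = None if gq is None or np.all(gq < 0) else np.asarray(gq, dtype=float)
            dp = variant.gt_depths
            dp = None if dp is None or np.all(dp < 0) else np.asarray(dp, dtype=float)
            records.append(
                SiteRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alts=tuple(variant.ALT),
                    qual=variant.QUAL,
                    genotypes=genotypes,
                    gq=gq,
                    dp=dp,
                )
            )
    finally:
        vcf.close()
    return records
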