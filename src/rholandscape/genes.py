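"""Per-gene diversity, divergence, and recombination correlates.

Fourfold degenerate synonymous sites (third codon positions whose codon
family encodes the same amino acid for any base) serve as the putatively
neutral site class.  A site is used only when it is fourfold in the focal
species AND both outgroups.  Per gene the module computes pairwise
nucleotide diversity pi from sample allele counts, divergence from the rat
outgroup (mismatch fraction), the mutation-rate-corrected ratio pi/d_rat,
and GC content; associations with the gene's weighted-mean recombination
rate use tie-corrected Kendall rank correlations (tau-b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ancestral import classify_cpg_prone

__all__ = [
    "FourfoldSite",
    "GeneRecord",
    "FOURFOLD_PREFIXES",
    "annotate_fourfold_sites",
    "site_pi",
    "gene_diversity_divergence",
    "kendall_tau",
]

# codon prefixes (first two bases) whose third position is fourfold
# degenerate under the standard genetic code
FOURFOLD_PREFIXES = frozenset(
    ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]
)

_COMPLEMENT = str.maketrans("ACGTacgt-Nn", "TGCAtgca-Nn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FourfoldSite:
    """One fourfold degenerate site in genomic coordinates (0-based)."""

    position: int
    focal_base: str
    rat_base: str | None
    cpg_prone: bool


@dataclass
class GeneRecord:
    """Per-gene summary statistics at fourfold degenerate sites."""

    gene_id: str
    rho_bar: float | None = None
    pi: float | None = None
    d_rat: float | None = None
    pi_over_d: float | None = None
    gc: float | None = None
    n_fourfold: int = 0
    flags: list = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


def annotate_fourfold_sites(
    exons: Sequence[tuple[int, int]],
    strand: str,
    focal: str,
    outgroup1: str,
    outgroup2: str,
) -> list[FourfoldSite]:
    """Locate fourfold sites shared by the focal species and both outgroups.

    ``exons`` are 0-based half-open CDS exon intervals on the chromosome;
    the three sequences are equal-length chromosome (or region) alignments
    with gaps as '-'.  Minus-strand genes are evaluated on the reverse
    complement of the concatenated CDS.  A third codon position qualifies
    when the codon's first two bases form a fourfold family in all three
    species.  Each site is tagged CpG-prone using one base of genomic
    context per species.  Raises if the concatenated CDS length is not a
    multiple of 3 (caller flags and skips the gene).
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if not (len(focal) == len(outgroup1) == len(outgroup2)):
        raise ValueError("aligned sequences must have equal length")
    exons = sorted(exons)
    coords: list[int] = []
    for start, end in exons:
        coords.extend(range(start, end))
    if len(coords) % 3 != 0:
        raise ValueError(f"CDS length {len(coords)} is not a multiple of 3")
    if strand == "-":
        coords = coords[::-1]

    def base_at(seq: str, genomic: int) -> str:
        b = seq[genomic]
        return b.translate(_COMPLEMENT) if strand == "-" else b

    sites: list[FourfoldSite] = []
    for codon_start in range(0, len(coords), 3):
        c0, c1, c2 = coords[codon_start : codon_start + 3]
        prefixes = []
        for seq in (focal, outgroup1, outgroup2):
            prefix = (base_at(seq, c0) + base_at(seq, c1)).upper()
            prefixes.append(prefix)
        if not all(p in FOURFOLD_PREFIXES for p in prefixes):
            continue
        contexts = []
        for seq in (focal, outgroup1, outgroup2):
            if strand == "+":
                left = seq[c2 - 1] if c2 - 1 >= 0 else None
                right = seq[c2 + 1] if c2 + 1 < len(seq) else None
            else:
                # reading-direction context on the minus strand: the genomic
                # neighbors, complemented and swapped
                left = seq[c2 + 1].translate(_COMPLEMENT) if c2 + 1 < len(seq) else None
                right = seq[c2 - 1].translate(_COMPLEMENT) if c2 - 1 >= 0 else None
            left = left.upper() if left and left.upper() in "ACGT" else None
            right = right.upper() if right and right.upper() in "ACGT" else None
            contexts.append((left, right))
        rat = base_at(outgroup2, c2).upper()
        sites.append(
            FourfoldSite(
                position=c2,
                focal_base=base_at(focal, c2).upper(),
                rat_base=rat if rat in "ACGT" else None,
                cpg_prone=classify_cpg_prone(contexts),
            )
        )
    return sites


def site_pi(allele_counts: dict[str, int]) -> float | None:
    """Pairwise nucleotide diversity at one site from sample allele counts.

    pi = (number of pairwise differences) / C(n, 2) where n is the number of
    sampled chromosomes with a called base at the site; None when n < 2.
    """
    counts = np.array([c for c in allele_counts.values() if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        return None
    diffs = (n * n - np.sum(counts**2)) / 2.0
    return float(diffs / (n * (n - 1) / 2.0))


def gene_diversity_divergence(
    gene_id: str,
    sites: Sequence[FourfoldSite],
    allele_counts: Sequence[dict[str, int] | None],
    rho_bar: float | None = None,
    gc: float | None = None,
    site_class: str = "all",
    missing_threshold: float = 0.8,
) -> GeneRecord:
    """Per-gene pi, d_rat and pi/d_rat over fourfold sites.

    ``allele_counts[i]`` gives the focal sample's base counts at
    ``sites[i]`` (None when uncalled).  ``site_class`` selects "all" or
    "non_cpg" fourfold sites, the two columns of the standard presentation.
    QC: a gene with more than ``missing_threshold`` of its fourfold sites
    missing (no rat base or no focal counts) is flagged ``high_missing``;
    a gene whose comparable non-CpG fourfold sites ALL mismatch the rat
    (and at least one exists) is flagged ``all_rat_mismatch`` — both
    indicate alignment problems.  Zero usable sites yields an excluded
    record, never NaN propagation.
    """
    if len(sites) != len(allele_counts):
        raise ValueError("sites and allele_counts length mismatch")
    record = GeneRecord(gene_id=gene_id, rho_bar=rho_bar, gc=gc)

    comparable = [
        (s, c)
        for s, c in zip(sites, allele_counts)
        if s.rat_base is not None and c is not None
    ]
    if sites and len(comparable) < (1.0 - missing_threshold) * len(sites):
        record.flags.append("high_missing")
    non_cpg = [(s, c) for s, c in comparable if not s.cpg_prone]
    if non_cpg and all(s.focal_base != s.rat_base for s, _ in non_cpg):
        record.flags.append("all_rat_mismatch")

    if site_class == "all":
        used = comparable
    elif site_class == "non_cpg":
        used = non_cpg
    else:
        raise ValueError("site_class must be 'all' or 'non_cpg'")
    pis = [p for p in (site_pi(c) for _, c in used) if p is not None]
    if not pis:
        record.flags.append("no_usable_sites")
        return record
    record.n_fourfold = len(used)
    record.pi = float(np.mean(pis))
    record.d_rat = float(
        np.mean([s.focal_base != s.rat_base for s, _ in used])
    )
    if record.d_rat > 0:
        record.pi_over_d = record.pi / record.d_rat
    return record


def kendall_tau(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for an all-tied vector")
    result = stats.kendalltau(x, y)
    return float(result.statistic), float(result.pvalue)


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence, ignoring gaps and Ns."""
    seq = sequence.upper()
    usable = [b for b in seq if b in "ACGT"]
    if not usable:
        raise ValueError("no callable bases")
    return sum(b in "GC" for b in usable) / len(usable)
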