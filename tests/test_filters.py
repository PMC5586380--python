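"""Exact Hardy-Weinberg test and the site-filter cascade."""

import itertools
from math import comb, lgamma, exp

import numpy as np
import pytest

from rholandscape import FilterConfig, SiteRecord, filter_sites, hwe_exact_test


def hwe_slot_enumeration(n_AA, n_Aa, n_aa):
    """Independent oracle: exhaustively place minor alleles into 2n slots.

    Every assignment of the minor alleles to distinct allele slots is
    equally likely under the conditional null; genotype i owns slots
    (2i, 2i+1).  Feasible for small n only.
    """
    n = n_AA + n_Aa + n_aa
    minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if minor == 0:
        return 1.0
    het_counts = {}
    for placement in itertools.combinations(range(2 * n), minor):
        chosen = set(placement)
        h = sum((2 * i in chosen) != (2 * i + 1 in chosen) for i in range(n))
        het_counts[h] = het_counts.get(h, 0) + 1
    total = sum(het_counts.values())
    observed = het_counts.get(n_Aa, 0)
    return sum(c for c in het_counts.values() if c <= observed) / total


def hwe_lgamma(n_AA, n_Aa, n_aa):
    """Independent oracle via log-gamma arithmetic on the same distribution."""
    n = n_AA + n_Aa + n_aa
    minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if minor == 0:
        return 1.0

    def log_prob(h):
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_minor < 0 or hom_major < 0:
            return None
        return (
            lgamma(n + 1) - lgamma(h + 1) - lgamma(hom_minor + 1)
            - lgamma(hom_major + 1) + h * np.log(2)
        )

    logs = {h: lp for h in range(minor % 2, minor + 1, 2)
            if (lp := log_prob(h)) is not None}
    norm = max(logs.values())
    probs = {h: exp(lp - norm) for h, lp in logs.items()}
    total = sum(probs.values())
    observed = probs[n_Aa]
    return sum(p for p in probs.values() if p <= observed * (1 + 1e-9)) / total


class TestHweExactTest:
    def test_monomorphic_site(self):
        assert hwe_exact_test(5, 0, 0) == 1.0

    def test_two_two_split_full_enumeration(self):
        # support h in {0, 2, 4} with weights 6, 48, 16 out of C(8, 4) = 70
        assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70)
        assert hwe_exact_test(1, 2, 1) == pytest.approx(1.0)  # 48+16+6 = 70
        assert hwe_exact_test(0, 4, 0) == pytest.approx((16 + 6) / 70)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_slot_level_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            counts = rng.multinomial(int(rng.integers(1, 7)), [1 / 3] * 3)
            assert hwe_exact_test(*counts) == pytest.approx(
                hwe_slot_enumeration(*counts), abs=1e-12
            )

    def test_support_probabilities_sum_to_one(self):
        # every configuration weight / total over the support sums to 1:
        # equivalent check — the most extreme observation has p <= 1 and the
        # modal observation has p == 1 when all weights are equal-or-smaller
        for n_a, n_ab, n_b in [(3, 4, 3), (10, 0, 10), (0, 20, 0), (7, 1, 0)]:
            p = hwe_exact_test(n_a, n_ab, n_b)
            assert 0.0 < p <= 1.0


def make_record(ref="A", alts=("T",), qual=100.0, genotypes=None, gq=None, dp=None):
    genotypes = genotypes if genotypes is not None else [[0, 1]] * 4
    return SiteRecord(
        chrom="chr1",
        pos=100,
        ref=ref,
        alts=alts,
        qual=qual,
        genotypes=np.array(genotypes),
        gq=None if gq is None else np.asarray(gq, float),
        dp=None if dp is None else np.asarray(dp, float),
    )


class TestFilterSites:
    def test_triallelic_removed(self):
        kept, report = filter_sites([make_record(alts=("T", "G"))])
        assert not kept
        assert report.removed == {"not_biallelic_snp": 1}

    def test_indel_removed(self):
        kept, _ = filter_sites([make_record(alts=("TTA",))])
        assert not kept

    def test_single_failing_individual_removes_site(self):
        record = make_record(gq=[99, 99, 14, 99])
        kept, report = filter_sites([record], FilterConfig(min_gq=15))
        assert not kept
        assert report.removed == {"low_gq": 1}

    def test_hwe_outlier_removed(self):
        # all heterozygous with many samples: strong HWE violation
        record = make_record(genotypes=[[0, 1]] * 20)
        assert hwe_exact_test(0, 20, 0) < 0.002
        kept, report = filter_sites([record])
        assert report.removed == {"hwe_fail": 1}

    def test_depth_bounds_applied_when_set(self):
        record = make_record(dp=[10, 10, 200, 10], genotypes=[[0, 0]] * 3 + [[0, 1]])
        kept, _ = filter_sites([record], FilterConfig(dp_bounds=(5, 100)))
        assert not kept
        kept, _ = filter_sites([record], FilterConfig())  # disabled by default
        assert len(kept) == 1

    def test_constructed_panel_report(self):
        balanced = [[0, 0]] * 1 + [[0, 1]] * 2 + [[1, 1]] * 1
        records = [make_record(genotypes=balanced) for _ in range(7)]
        records.append(make_record(qual=10.0))
        records.append(make_record(alts=("T", "G")))
        records.append(make_record(gq=[99, 14, 99, 99]))
        kept, report = filter_sites(records)
        assert len(kept) == 7
        assert report.n_input == 10
        assert report.removed == {
            "low_qual": 1,
            "not_biallelic_snp": 1,
            "low_gq": 1,
        }
        assert report.fraction_removed == pytest.approx(0.3)

    def test_idempotent(self):
        records = [make_record(), make_record(qual=1.0),
                   make_record(genotypes=[[0, 1]] * 20)]
        kept, _ = filter_sites(records)
        kept_again, report = filter_sites(kept)
        assert len(kept_again) == len(kept)
        assert report.n_removed == 0


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t80\t.\t.\tGT:GQ:DP\t0/1:99:30\t0/0:99:25
chr1\t200\t.\tC\tG\t10\t.\t.\tGT:GQ:DP\t0/1:99:30\t1/1:99:28
chr1\t300\t.\tG\tA\t90\t.\t.\tGT:GQ:DP\t0/1:12:30\t0/1:99:31
"""


class TestVcfAdapter:
    def test_read_and_filter_small_vcf(self, tmp_path):
        from rholandscape.filters import read_vcf_sites

        path = tmp_path / "sites.vcf"
        path.write_text(VCF_TEXT)
        records = read_vcf_sites(str(path))
        assert [r.pos for r in records] == [100, 200, 300]
        kept, report = filter_sites(records)
        assert [r.pos for r in kept] == [100]
        assert report.removed == {"low_qual": 1, "low_gq": 1}
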