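"""Fourfold-site annotation, per-gene diversity/divergence, Kendall tau."""

import itertools

import numpy as np
import pytest

from rholandscape import (
    annotate_fourfold_sites,
    gene_diversity_divergence,
    kendall_tau,
)
from rholandscape.genes import FourfoldSite, site_pi, gc_content


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestAnnotateFourfoldSites:
    def test_alanine_codon_in_all_species(self):
        # GCx is fourfold (Ala); third positions qualify in all three species
        sites = annotate_fourfold_sites([(0, 6)], "+", "GCAGCC", "GCCGCG", "GCGGCT")
        assert [s.position for s in sites] == [2, 5]

    def test_non_fourfold_in_any_species_excluded(self):
        # rat codon AAA (Lys) is not fourfold: site dropped despite focal GCA
        sites = annotate_fourfold_sites([(0, 3)], "+", "GCA", "GCA", "AAA")
        assert sites == []
        # rat TCA (Ser, fourfold family TC*) keeps the site
        sites = annotate_fourfold_sites([(0, 3)], "+", "GCA", "GCA", "TCA")
        assert len(sites) == 1

    def test_minus_strand_matches_pre_reverse_complemented_gene(self):
        focal_fwd, out1_fwd, out2_fwd = "GCAGTT", "GCCGTC", "GCGGTA"
        plus = annotate_fourfold_sites([(0, 6)], "+", focal_fwd, out1_fwd, out2_fwd)
        minus = annotate_fourfold_sites(
            [(0, 6)], "-", _revcomp(focal_fwd), _revcomp(out1_fwd), _revcomp(out2_fwd)
        )
        assert len(plus) == len(minus) == 2
        assert [s.focal_base for s in plus] == [s.focal_base for s in minus]
        # genomic positions mirror: pos p on + maps to 5 - p on the revcomp
        assert sorted(5 - s.position for s in minus) == [s.position for s in plus]

    def test_cds_not_divisible_by_three_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            annotate_fourfold_sites([(0, 4)], "+", "GCAG", "GCAG", "GCAG")

    def test_cpg_prone_tagging_uses_any_species_context(self):
        # focal context clean; outgroup2 has G after the third position
        sites = annotate_fourfold_sites([(0, 3)], "+", "GCAA", "GCAA", "GCAG")
        # need equal lengths: pad focal/outgroup1 to 4 as well
        assert len(sites) == 1
        assert sites[0].cpg_prone  # preceded by C in all species (GC_A)


class TestSitePi:
    def test_balanced_biallelic_counts(self):
        # (10 A, 10 T) in n = 20: 100 pairwise diffs / C(20,2) = 190
        assert site_pi({"A": 10, "T": 10}) == pytest.approx(100 / 190)

    def test_monomorphic(self):
        assert site_pi({"G": 20}) == 0.0

    def test_unbiased_estimator_identity(self):
        # biallelic: pi == 2p(1-p) * n/(n-1)
        for n_a in range(1, 20):
            n = 20
            p = n_a / n
            assert site_pi({"A": n_a, "C": n - n_a}) == pytest.approx(
                2 * p * (1 - p) * n / (n - 1)
            )

    def test_fewer_than_two_alleles_is_none(self):
        assert site_pi({"A": 1}) is None


def make_sites(n, mismatch_mask=None, cpg_mask=None):
    mismatch_mask = mismatch_mask or [False] * n
    cpg_mask = cpg_mask or [False] * n
    return [
        FourfoldSite(
            position=i,
            focal_base="A",
            rat_base="G" if mismatch_mask[i] else "A",
            cpg_prone=cpg_mask[i],
        )
        for i in range(n)
    ]


class TestGeneDiversityDivergence:
    def test_monomorphic_gene_matching_rat(self):
        sites = make_sites(10)
        counts = [{"A": 20}] * 10
        record = gene_diversity_divergence("g1", sites, counts)
        assert record.pi == 0.0
        assert record.d_rat == 0.0
        assert record.pi_over_d is None
        assert not record.excluded

    def test_pi_and_divergence_arithmetic(self):
        sites = make_sites(4, mismatch_mask=[True, False, False, False])
        counts = [{"A": 10, "T": 10}, {"A": 20}, {"A": 20}, {"A": 20}]
        record = gene_diversity_divergence("g1", sites, counts)
        assert record.pi == pytest.approx((100 / 190) / 4)
        assert record.d_rat == pytest.approx(0.25)
        assert record.pi_over_d == pytest.approx(record.pi / 0.25)

    def test_high_missingness_excluded(self):
        sites = make_sites(20)
        counts = [{"A": 20}] * 3 + [None] * 17  # 85% missing
        record = gene_diversity_divergence("g1", sites, counts)
        assert "high_missing" in record.flags

    def test_all_rat_mismatch_at_non_cpg_sites_excluded(self):
        sites = make_sites(4, mismatch_mask=[True, True, True, False],
                           cpg_mask=[False, False, False, True])
        counts = [{"A": 20}] * 4
        record = gene_diversity_divergence("g1", sites, counts)
        assert "all_rat_mismatch" in record.flags

    def test_non_cpg_site_class_restricts_sites(self):
        sites = make_sites(4, mismatch_mask=[True, False, False, False],
                           cpg_mask=[True, False, False, False])
        counts = [{"A": 20}] * 4
        record = gene_diversity_divergence("g1", sites, counts, site_class="non_cpg")
        assert record.n_fourfold == 3
        assert record.d_rat == 0.0

    def test_zero_usable_sites_flagged_not_nan(self):
        record = gene_diversity_divergence("g1", [], [])
        assert record.excluded
        assert record.pi is None


class TestKendallTau:
    def test_single_discordant_pair(self):
        tau, _ = kendall_tau([1, 2, 3], [1, 3, 2])
        assert tau == pytest.approx(1 / 3)

    def test_identity(self):
        tau, _ = kendall_tau([3, 1, 2, 5], [3, 1, 2, 5])
        assert tau == pytest.approx(1.0)

    def test_all_tied_vector_rejected(self):
        with pytest.raises(ValueError, match="all-tied"):
            kendall_tau([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_concordance_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, 12).astype(float)
        y = rng.integers(0, 8, 12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        concordant = discordant = ties_x = ties_y = 0
        for (i, j) in itertools.combinations(range(12), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
        denom = np.sqrt(
            (concordant + discordant + ties_x) * (concordant + discordant + ties_y)
        )
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx((concordant - discordant) / denom)


def test_gc_content_ignores_gaps():
    assert gc_content("GCGC--NNAT") == pytest.approx(4 / 6)
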