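import itertools

import numpy as np
import pytest

from chcadd.cne import (
    AnnotationLayers,
    GeneModel,
    HIERARCHY,
    annotate_elements,
    assign_class,
    define_promoters,
    density_correlation,
    filter_elements,
    merge_intervals,
    snp_density,
)
from chcadd.io_formats import GenomeInterval


def iv(start, end, chrom="chr1"):
    return GenomeInterval(chrom, start, end)


class TestFilterElements:
    def test_short_element_removed(self):
        assert filter_elements([iv(0, 3)]) == []

    def test_boundary_length_retained(self):
        assert len(filter_elements([iv(0, 4)])) == 1

    def test_one_bp_gap_overlap_removes(self):
        gaps = [iv(9, 20)]
        assert filter_elements([iv(0, 10)], gaps) == []
        assert len(filter_elements([iv(0, 9)], gaps)) == 1


class TestDefinePromoters:
    def test_plus_strand_two_kb_upstream(self):
        g = GeneModel("chr1", 10_000, 12_000, "+", utr5_length=20)
        (p,) = define_promoters([g])
        assert (p.start, p.end) == (8_000, 10_000)

    def test_short_utr5_emits_no_promoter(self):
        g = GeneModel("chr1", 10_000, 12_000, "+", utr5_length=10)
        assert define_promoters([g]) == []

    def test_utr5_boundary_inclusive(self):
        g = GeneModel("chr1", 10_000, 12_000, "+", utr5_length=15)
        assert len(define_promoters([g])) == 1

    def test_minus_strand_mirror(self):
        # minus-strand gene ending at 501 has its TSS at 500
        g = GeneModel("chr1", 100, 501, "-", utr5_length=20)
        (p,) = define_promoters([g])
        assert (p.start, p.end) == (500, 2_500)

    def test_truncated_at_chromosome_start(self):
        g = GeneModel("chr1", 500, 2_000, "+", utr5_length=20)
        (p,) = define_promoters([g])
        assert (p.start, p.end) == (0, 500)

    def test_missing_strand_errors(self):
        g = GeneModel("chr1", 100, 500, ".", utr5_length=20)
        with pytest.raises(ValueError):
            define_promoters([g])


@pytest.fixture
def layers():
    return AnnotationLayers({
        "CDS": [iv(100, 200)],
        "5UTR": [iv(80, 100)],
        "promoter": [iv(0, 80)],
        "lncRNA": [iv(300, 400)],
        "intronic": [iv(200, 300)],
    }, known_chroms=["chr1"])


class TestAssignClass:
    def test_cds_beats_intron(self, layers):
        ae = assign_class(iv(190, 210), layers)
        assert (ae.assigned_class, ae.is_cne) == ("CDS", False)

    def test_promoter_beats_lncrna(self):
        layers = AnnotationLayers({"promoter": [iv(0, 100)],
                                   "lncRNA": [iv(50, 200)]})
        ae = assign_class(iv(60, 120), layers)
        assert (ae.assigned_class, ae.is_cne) == ("promoter", False)

    def test_no_overlap_is_intergenic_cne(self, layers):
        ae = assign_class(iv(900, 950), layers)
        assert (ae.assigned_class, ae.is_cne) == ("intergenic", True)

    def test_lncrna_is_cne(self, layers):
        ae = assign_class(iv(350, 360), layers)
        assert (ae.assigned_class, ae.is_cne) == ("lncRNA", True)

    def test_unknown_chromosome_errors(self, layers):
        with pytest.raises(KeyError):
            assign_class(iv(0, 10, chrom="chrZ"), layers)

    def test_assignment_total_and_counts_sum(self, layers):
        elements = [iv(s, s + 20) for s in range(0, 500, 30)]
        annotated = annotate_elements(elements, layers)
        assert len(annotated) == len(elements)
        n_cne = sum(a.is_cne for a in annotated)
        n_cc = sum(not a.is_cne for a in annotated)
        assert n_cne + n_cc == len(elements)

    def test_priority_permutation_only_moves_multi_overlap(self):
        """Reversing layer priority changes assignments only for elements
        overlapping two or more layers."""
        base = {"CDS": [iv(100, 200)], "lncRNA": [iv(150, 300)]}
        layers_fwd = AnnotationLayers(base)
        elements = [iv(110, 120), iv(190, 210), iv(250, 260), iv(500, 510)]
        fwd = annotate_elements(elements, layers_fwd)
        for el, a in zip(elements, fwd):
            n_hit = sum(el.overlaps(layer_iv)
                        for ivs in base.values() for layer_iv in ivs)
            if n_hit <= 1:
                # single-overlap class is priority-independent
                expected = ("CDS" if el.overlaps(base["CDS"][0]) else
                            "lncRNA" if el.overlaps(base["lncRNA"][0])
                            else "intergenic")
                assert a.assigned_class == expected


class TestSnpDensity:
    def test_basic_arithmetic(self):
        assert snp_density([iv(0, 100)],
                           [("chr1", 10), ("chr1", 50)]) == pytest.approx(0.02)

    def test_no_snps_zero(self):
        assert snp_density([iv(0, 100)], []) == 0.0

    def test_union_semantics(self):
        # duplicated interval counts its bases once
        d = snp_density([iv(0, 50), iv(0, 50)], [("chr1", 10)])
        assert d == pytest.approx(0.02)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            snp_density([], [("chr1", 1)])

    def test_snps_outside_union_ignored(self):
        assert snp_density([iv(10, 20)], [("chr1", 5), ("chr1", 15),
                                          ("chr2", 15)]) == pytest.approx(0.1)

    def test_constrained_elements_have_lower_density(self, default_world):
        """Conserved (constrained) regions show suppressed polymorphism."""
        snps = [(r.chrom, r.pos) for r in default_world.population]
        d_cons = snp_density(default_world.constrained_regions, snps)
        d_neut = snp_density(default_world.neutral_regions, snps)
        assert d_cons < d_neut


class TestDensityCorrelation:
    CHROMS = {"chr1": 600_000}

    def _track(self, counts, offset=0):
        out = []
        for w, c in enumerate(counts):
            for k in range(c):
                s = w * 100_000 + 10 * k + offset
                out.append(iv(s, s + 5))
        return out

    def test_identical_tracks_r_one(self):
        a = self._track([1, 2, 3, 4, 5, 6])
        r, _ = density_correlation(a, a, self.CHROMS)
        assert r == pytest.approx(1.0)

    def test_reversed_counts_r_minus_one(self):
        a = self._track([1, 2, 3, 4, 5, 6])
        b = self._track([6, 5, 4, 3, 2, 1], offset=1)
        r, _ = density_correlation(a, b, self.CHROMS)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        counts_a = [2, 1, 4, 3, 5]
        counts_b = [1, 3, 2, 5, 4]
        a = self._track(counts_a)
        b = self._track(counts_b, offset=1)
        r, _ = density_correlation(a, b, {"chr1": 500_000})
        xa, xb = np.array(counts_a, float), np.array(counts_b, float)
        expected = (np.mean((xa - xa.mean()) * (xb - xb.mean()))
                    / (xa.std() * xb.std()))
        assert r == pytest.approx(expected)

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError):
            density_correlation(self._track([1]), self._track([1]),
                                {"chr1": 100_000})

    def test_scaled_mode_runs_with_coding_subtraction(self):
        a = self._track([1, 2, 3, 4, 5, 6])
        b = self._track([6, 5, 4, 3, 2, 1], offset=1)
        coding = [iv(0, 50_000)]
        r, p = density_correlation(a, b, self.CHROMS, mode="scaled",
                                   coding_intervals=coding)
        assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0


def test_merge_intervals_disjoint_sorted():
    merged = merge_intervals([iv(5, 10), iv(8, 20), iv(30, 40)])
    assert merged["chr1"] == [(5, 20), (30, 40)]
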