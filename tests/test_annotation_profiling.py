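"""Feature classification, TSS profiling, overlap, density, enrichment, export."""

import itertools
import math

import numpy as np
import pytest

from stressmark.annotation_profiling import (
    FEATURE_LABELS,
    chromosome_density,
    classify_feature,
    classify_features,
    hypergeom_enrichment,
    mapman_export,
    nearest_tss_distance,
    overlap_with_genes,
    summarize_features,
    tss_metaprofile,
)
from stressmark.core_io import Gene, GeneAnnotation, GenomicInterval, LibraryLabel
from stressmark.stress_classifier import ResponsiveRegion, ResponsiveSet
from conftest import make_fragments


def simple_gene(gene_id="g1", chrom="chr1", strand="+", start=10_000,
                length=2000):
    """5'UTR 200 / CDS 600 / intron 400 / CDS 600 / 3'UTR 200 gene model."""
    end = start + length
    if strand == "+":
        segs = [(start, start + 200), (start + 200, start + 800),
                (start + 800, start + 1200), (start + 1200, start + 1800),
                (start + 1800, end)]
        utr5, cds1, intron, cds2, utr3 = [GenomicInterval(chrom, a, b)
                                          for a, b in segs]
    else:
        segs = [(end - 200, end), (end - 800, end - 200),
                (end - 1200, end - 800), (end - 1800, end - 1200),
                (start, end - 1800)]
        utr5, cds1, intron, cds2, utr3 = [GenomicInterval(chrom, a, b)
                                          for a, b in segs]
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand,
                interval=GenomicInterval(chrom, start, end),
                tss=start if strand == "+" else end - 1,
                tes=end - 1 if strand == "+" else start,
                five_prime_utr=(utr5,), cds=tuple(sorted((cds1, cds2))),
                introns=(intron,), three_prime_utr=(utr3,))


@pytest.fixture()
def annotation():
    return GeneAnnotation(
        genes=[simple_gene()],
        repeats=[GenomicInterval("chr1", 10_300, 10_500),  # inside CDS1
                 GenomicInterval("chr1", 40_000, 41_000)])


class TestClassifyFeature:
    def test_genic_feature_beats_repeat(self, annotation):
        # midpoint 10,400 lies in both CDS and a repeat
        assert classify_feature(GenomicInterval("chr1", 10_300, 10_500),
                                annotation) == "CDS"

    def test_upstream_within_flank_of_tss(self, annotation):
        # midpoint at 8,500 = 1,500 bp 5' of the + strand TSS at 10,000
        assert classify_feature(GenomicInterval("chr1", 8_400, 8_600),
                                annotation) == "upstream"

    def test_beyond_flank_is_intergenic(self, annotation):
        assert classify_feature(GenomicInterval("chr1", 5_000, 5_200),
                                annotation) == "intergenic"

    def test_repeat_when_no_genic_overlap(self, annotation):
        assert classify_feature(GenomicInterval("chr1", 40_400, 40_600),
                                annotation) == "repeat"

    @pytest.mark.parametrize("midpoint,label", [
        (10_100, "five_prime_UTR"), (10_500, "CDS"), (11_000, "intron"),
        (11_500, "CDS"), (11_900, "three_prime_UTR"), (12_500, "downstream"),
    ])
    def test_sub_feature_partition(self, annotation, midpoint, label):
        peak = GenomicInterval("chr1", midpoint - 10, midpoint + 10)
        assert classify_feature(peak, annotation) == label

    def test_strand_aware_flanks_on_minus_gene(self):
        ann = GeneAnnotation(genes=[simple_gene(strand="-")])
        # 1,500 bp 5' of the − strand TSS at 11,999 is genomic 13,499
        assert classify_feature(GenomicInterval("chr1", 13_400, 13_600),
                                ann) == "upstream"
        assert classify_feature(GenomicInterval("chr1", 8_900, 9_100),
                                ann) == "downstream"

    def test_every_peak_gets_exactly_one_label(self, annotation):
        rng = np.random.default_rng(0)
        peaks = [GenomicInterval("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 49_000, 300)]
        labels = classify_features(peaks, annotation)
        assert len(labels) == 300
        assert set(labels) <= set(FEATURE_LABELS)

    def test_unknown_chromosome_rejected(self, annotation):
        with pytest.raises(ValueError, match="chr9"):
            classify_feature(GenomicInterval("chr9", 0, 100), annotation)


# Feature distribution of differential peaks between treatments and control
# (counts of the published H3K4me3 study; used as an arithmetic fixture).
TABLE2 = {
    ("DT", "C"): {"five_prime_UTR": 327, "CDS": 720, "upstream": 465,
                  "intron": 435, "three_prime_UTR": 45, "downstream": 384,
                  "repeat": 4028, "intergenic": 938},
    ("DTHT", "C"): {"five_prime_UTR": 326, "CDS": 947, "upstream": 345,
                    "intron": 352, "three_prime_UTR": 27, "downstream": 309,
                    "repeat": 3446, "intergenic": 758},
    ("DTHT", "DT"): {"five_prime_UTR": 485, "CDS": 995, "upstream": 590,
                     "intron": 437, "three_prime_UTR": 56, "downstream": 452,
                     "repeat": 4312, "intergenic": 1209},
}


class TestSummarizeFeatures:
    def test_published_distribution_arithmetic(self):
        labels = list(itertools.chain.from_iterable(
            [k] * v for k, v in TABLE2[("DT", "C")].items()))
        s = summarize_features(labels)
        assert s.total == 7342
        assert s.percentages["CDS"] == 9.81
        assert s.percentages["repeat"] == 54.86
        assert s.percentages["upstream"] == 6.33

    def test_second_contrast_percentage(self):
        labels = list(itertools.chain.from_iterable(
            [k] * v for k, v in TABLE2[("DTHT", "DT")].items()))
        s = summarize_features(labels)
        assert s.total == 8536
        assert s.percentages["CDS"] == 11.66

    def test_single_label_is_hundred_percent(self):
        s = summarize_features(["CDS"])
        assert s.percentages["CDS"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_features([])

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = list(rng.choice(FEATURE_LABELS,
                                     size=int(rng.integers(1, 500))))
            s = summarize_features(labels)
            assert sum(s.counts.values()) == s.total
            assert sum(s.percentages.values()) == pytest.approx(100.0, abs=0.05)


class TestNearestTss:
    def test_midpoint_at_tss_is_zero(self, annotation):
        gid, d = nearest_tss_distance(GenomicInterval("chr1", 9_900, 10_100),
                                      annotation)
        assert (gid, d) == ("g1", 0)

    def test_downstream_positive_on_plus_strand(self, annotation):
        _, d = nearest_tss_distance(GenomicInterval("chr1", 10_400, 10_600),
                                    annotation)
        assert d == 500

    def test_upstream_negative_flips_on_minus_strand(self):
        ann = GeneAnnotation(genes=[simple_gene(strand="-", start=8_001)])
        # TSS at 10,000; midpoint 10,500 is genomically right of it,
        # i.e. 500 bp upstream in transcription orientation
        _, d = nearest_tss_distance(GenomicInterval("chr1", 10_400, 10_600), ann)
        assert d == -500

    def test_tie_breaks_on_lexicographic_gene_id(self):
        ann = GeneAnnotation(genes=[
            simple_gene("gB", start=10_000), simple_gene("gA", start=11_000)])
        gid, _ = nearest_tss_distance(GenomicInterval("chr1", 10_400, 10_600), ann)
        assert gid == "gA"  # both TSSs 500 bp away


class TestTssMetaprofile:
    def test_no_fragments_all_zero(self, annotation):
        frags = make_fragments([], {"chr1": 50_000})
        frags.by_chrom = {}
        prof = tss_metaprofile(frags, annotation, 2000, 100)
        assert prof.rpm.sum() == 0.0
        assert len(prof.rpm) == 40

    def test_downstream_only_enrichment(self, annotation):
        # fragments strictly within [TSS, TSS+2000)
        starts = np.arange(10_000, 11_700, 100)
        frags = make_fragments(starts, {"chr1": 50_000}, fragment_size=300)
        prof = tss_metaprofile(frags, annotation, 2000, 100)
        upstream = prof.rpm[prof.offsets < -300]  # clear of fragment bleed
        downstream = prof.rpm[prof.offsets >= 0]
        assert upstream.sum() == 0.0
        assert downstream.sum() > 0

    def test_single_fragment_bin_arithmetic(self, annotation):
        # one fragment [10050, 10350) around the + strand TSS at 10,000
        frags = make_fragments([10_050], {"chr1": 50_000}, fragment_size=300)
        prof = tss_metaprofile(frags, annotation, 1000, 100)
        # overlaps offset bins [0,100),[100,200),[200,300),[300,400)
        expected = np.zeros(20)
        expected[10:14] = 1e6  # one fragment, one gene, per-million of N=1
        assert np.allclose(prof.rpm, expected)

    def test_minus_strand_orientation_flip(self):
        ann = GeneAnnotation(genes=[simple_gene(strand="-")])
        tss = 11_999
        # fragment immediately 3' of the TSS in transcription direction
        frags = make_fragments([tss - 400], {"chr1": 50_000}, fragment_size=300)
        prof = tss_metaprofile(frags, ann, 1000, 100)
        assert prof.rpm[prof.offsets >= 0].sum() > 0
        assert prof.rpm[prof.offsets < 0].sum() == 0


class TestOverlapWithGenes:
    def _regions(self, *intervals):
        return ResponsiveSet("DT", [
            ResponsiveRegion(iv, (96,), 1, 1e-4) for iv in intervals])

    def test_flank_inclusion(self, annotation):
        # gene ends at 12,000; region 500 bp past it links with 2-kb flank
        res = overlap_with_genes(self._regions(
            GenomicInterval("chr1", 12_500, 12_700)), annotation, 2000)
        assert res.n_regions == 1 and res.n_genes == 1

    def test_beyond_flank_not_linked(self, annotation):
        res = overlap_with_genes(self._regions(
            GenomicInterval("chr1", 14_500, 14_700)), annotation, 2000)
        assert res.links == []

    def test_region_gene_count_asymmetry(self, annotation):
        res = overlap_with_genes(self._regions(
            GenomicInterval("chr1", 10_100, 10_300),
            GenomicInterval("chr1", 11_500, 11_700)), annotation, 2000)
        assert len(res.links) == 2
        assert res.n_regions == 2 and res.n_genes == 1


class TestChromosomeDensity:
    def test_no_peaks_zero_density(self):
        df = chromosome_density([], {"chr1": 1_000_000})
        assert (df["density_per_mb"] == 0).all()

    def test_split_ratios(self):
        genome = {"chr1": 1_000_000, "chr2": 1_000_000}
        peaks = ([GenomicInterval("chr1", i * 100, i * 100 + 50)
                  for i in range(8)]
                 + [GenomicInterval("chr2", i * 100, i * 100 + 50)
                    for i in range(2)])
        df = chromosome_density(peaks, genome).set_index("chrom")
        assert df.loc["chr1", "ratio_to_genome"] == pytest.approx(1.6)
        assert df.loc["chr2", "ratio_to_genome"] == pytest.approx(0.4)


def hypergeom_oracle(k, M, K, n):
    """Upper-tail P(X >= k) by combinatorial enumeration."""
    return sum(math.comb(K, j) * math.comb(M - K, n - j)
               for j in range(k, min(K, n) + 1)) / math.comb(M, n)


class TestEnrichment:
    def test_whole_population_term_is_null(self):
        pop = [f"g{i}" for i in range(20)]
        rows = hypergeom_enrichment(pop[:5], pop, {"all": pop})
        assert rows[0].fold_enrichment == pytest.approx(1.0)
        assert rows[0].p_value == pytest.approx(1.0)
        assert not rows[0].significant

    def test_perfect_term_exact_p(self):
        pop = [f"g{i}" for i in range(20)]
        rows = hypergeom_enrichment(pop[:5], pop, {"t": pop[:5]})
        assert rows[0].p_value == pytest.approx(1 / 15504, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        pop = [f"g{i}" for i in range(25)]
        for _ in range(20):
            study = list(rng.choice(pop, size=8, replace=False))
            term = list(rng.choice(pop, size=int(rng.integers(1, 15)),
                                   replace=False))
            (row,) = hypergeom_enrichment(study, pop, {"t": term})
            assert row.p_value == pytest.approx(
                hypergeom_oracle(row.study_hits, 25, len(term), 8), rel=1e-9)

    def test_significance_needs_both_conditions(self):
        pop = [f"g{i}" for i in range(20)]
        # high fold but weak evidence: 1 of 2 study genes in a 2-gene term
        # (p = P(X>=1) = 1 - C(18,2)/C(20,2) ~ 0.195)
        rows = hypergeom_enrichment(pop[:2], pop, {"t": [pop[0], pop[10]]})
        assert rows[0].fold_enrichment > 1.3 and not rows[0].significant
        assert rows[0].adjusted_p > 0.05

    def test_study_must_be_subset(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], ["a", "b"], {})


class TestMapmanExport:
    def _links(self, entries):
        from stressmark.annotation_profiling import GeneLink, OverlapResult
        links = [GeneLink(i, GenomicInterval("chr1", 1 + i, 100 + i), g, d, p)
                 for i, (g, d, p) in enumerate(entries)]
        return OverlapResult(links, len(entries), len({e[0] for e in entries}))

    def test_three_valued_encoding(self):
        result = self._links([("gUp", 1, 1e-5), ("gDown", -1, 1e-4)])
        df = mapman_export({"DT": result}, ["gUp", "gDown", "gNone"])
        assert df.loc["gUp", "DT"] == 1
        assert df.loc["gDown", "DT"] == -1
        assert df.loc["gNone", "DT"] == 0

    def test_conflict_resolved_by_smaller_p(self):
        result = self._links([("g", -1, 1e-3), ("g", 1, 1e-6)])
        df = mapman_export({"DT": result}, ["g"])
        assert df.loc["g", "DT"] == 1
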