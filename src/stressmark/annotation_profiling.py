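"""Genomic-feature annotation, TSS profiling, overlap, enrichment, export.

Peaks are assigned a single genomic-feature label by testing the peak
midpoint against features in a fixed precedence order (genic sub-features
first, then strand-aware 2-kb flanks, then repeats, then intergenic), so the
per-feature percentages of a peak set always sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import FragmentCollection, Gene, GeneAnnotation, GenomicInterval
from .stress_classifier import ResponsiveSet

__all__ = [
    "FEATURE_LABELS", "FeatureSummary", "TssProfile", "EnrichmentRow",
    "GeneLink", "OverlapResult", "FeatureIndex",
    "classify_feature", "classify_features", "summarize_features",
    "nearest_tss_distance", "tss_metaprofile", "overlap_with_genes",
    "chromosome_density", "hypergeom_enrichment", "mapman_export",
]

#: Feature classes in precedence order (first match wins).
FEATURE_LABELS = ("five_prime_UTR", "CDS", "three_prime_UTR", "intron",
                  "upstream", "downstream", "repeat", "intergenic")


# ---------------------------------------------------------------------------
# Feature classification
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval trees over annotation features, built once per annotation."""

    def __init__(self, ann: GeneAnnotation, flank_bp: int = 2000):
        self.flank_bp = flank_bp
        self.trees: dict[str, dict[str, IntervalTree]] = {
            lab: {} for lab in FEATURE_LABELS[:-1]
        }
        for g in ann.genes:
            for lab, ivs in (("five_prime_UTR", g.five_prime_utr),
                             ("CDS", g.cds),
                             ("three_prime_UTR", g.three_prime_utr),
                             ("intron", g.introns)):
                for iv in ivs:
                    self._add(lab, iv.chrom, iv.start, iv.end)
            if g.strand == "+":
                up = (max(g.tss - flank_bp, 0), g.tss)
                down = (g.tes + 1, g.tes + 1 + flank_bp)
            else:
                up = (g.tss + 1, g.tss + 1 + flank_bp)
                down = (max(g.tes - flank_bp, 0), g.tes)
            self._add("upstream", g.chrom, *up)
            self._add("downstream", g.chrom, *down)
        for iv in ann.repeats:
            self._add("repeat", iv.chrom, iv.start, iv.end)

    def _add(self, label: str, chrom: str, start: int, end: int) -> None:
        if end <= start:
            return
        self.trees[label].setdefault(chrom, IntervalTree()).addi(start, end)

    def label_of(self, chrom: str, pos: int) -> str:
        for lab in FEATURE_LABELS[:-1]:
            tree = self.trees[lab].get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                return lab
        return "intergenic"


def classify_feature(peak: GenomicInterval, ann: GeneAnnotation,
                     flank_bp: int = 2000,
                     index: Optional[FeatureIndex] = None) -> str:
    """Assign the single feature label of a peak (midpoint, precedence order).

    Precedence: five_prime_UTR > CDS > three_prime_UTR > intron > upstream
    (within ``flank_bp`` 5' of the TSS, strand-aware) > downstream (within
    ``flank_bp`` 3' of the TES) > repeat > intergenic.
    """
    if index is None:
        index = FeatureIndex(ann, flank_bp)
    chroms = {g.chrom for g in ann.genes} | {r.chrom for r in ann.repeats}
    if chroms and peak.chrom not in chroms:
        raise ValueError(f"peak chromosome {peak.chrom!r} unknown to the annotation")
    return index.label_of(peak.chrom, peak.midpoint)


def classify_features(peaks: Sequence[GenomicInterval], ann: GeneAnnotation,
                      flank_bp: int = 2000) -> list[str]:
    """Vector version of :func:`classify_feature` with a shared index."""
    index = FeatureIndex(ann, flank_bp)
    return [classify_feature(p, ann, flank_bp, index=index) for p in peaks]


@dataclass
class FeatureSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": list(FEATURE_LABELS),
            "n_peaks": [self.counts[k] for k in FEATURE_LABELS],
            "pct_of_total": [self.percentages[k] for k in FEATURE_LABELS],
        })


def summarize_features(labels: Sequence[str]) -> FeatureSummary:
    """Per-feature counts and 2-decimal percentages of a peak label list."""
    if not labels:
        raise ValueError("empty label list")
    unknown = set(labels) - set(FEATURE_LABELS)
    if unknown:
        raise ValueError(f"unknown feature labels: {sorted(unknown)}")
    total = len(labels)
    counts = {lab: 0 for lab in FEATURE_LABELS}
    for lab in labels:
        counts[lab] += 1
    pct = {lab: round(100.0 * c / total, 2) for lab, c in counts.items()}
    return FeatureSummary(counts=counts, percentages=pct, total=total)


# ---------------------------------------------------------------------------
# TSS distance and metaprofile
# ---------------------------------------------------------------------------

def nearest_tss_distance(peak: GenomicInterval, ann: GeneAnnotation
                         ) -> tuple[Optional[str], Optional[int]]:
    """Signed distance from the peak midpoint to the nearest TSS.

    The sign follows transcription orientation: positive downstream of the
    TSS (into the gene body), negative upstream.  Equidistant TSSs tie-break
    on the lexicographically smaller gene id.  Only genes on the peak's
    chromosome are considered; (None, None) when there are none.
    """
    if not ann.genes:
        raise ValueError("empty annotation")
    mid = peak.midpoint
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
    for g in ann.genes:
        if g.chrom != peak.chrom:
            continue
        signed = mid - g.tss if g.strand == "+" else g.tss - mid
        key = (abs(signed), g.gene_id, signed)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return None, None
    return best[1], best[2]


@dataclass
class TssProfile:
    """Mean fragment coverage in orientation-aligned bins around the TSS."""

    offsets: np.ndarray       # signed bin left edges (bp from TSS)
    rpm: np.ndarray           # mean fragments per bin per gene, per million
    flank_bp: int
    bin_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.offsets, "rpm": self.rpm})


def tss_metaprofile(frags: FragmentCollection, ann: GeneAnnotation,
                    flank_bp: int = 2000, bin_bp: int = 100) -> TssProfile:
    """Average fragment occupancy around TSSs, scaled to per-million.

    Bin b covers transcription-direction offsets
    [−flank + b·bin, −flank + (b+1)·bin) from the TSS.  A fragment counts in
    every bin it overlaps by >= 1 bp; bin values are averaged over genes and
    scaled by 1e6 / library size.
    """
    if not ann.genes:
        raise ValueError("annotation must contain at least one gene")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank must be a multiple of the bin width")
    n_bins = 2 * flank_bp // bin_bp
    sums = np.zeros(n_bins)
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for chrom, arr in frags.by_chrom.items():
        starts_by_chrom[chrom] = np.sort(arr[:, 0])
        ends_by_chrom[chrom] = np.sort(arr[:, 1])
    for g in ann.genes:
        starts = starts_by_chrom.get(g.chrom)
        if starts is None:
            continue
        ends = ends_by_chrom[g.chrom]
        for b in range(n_bins):
            off0 = -flank_bp + b * bin_bp
            off1 = off0 + bin_bp
            if g.strand == "+":
                g0, g1 = g.tss + off0, g.tss + off1
            else:
                # genomic position p has offset tss - p on the − strand
                g0, g1 = g.tss - off1 + 1, g.tss - off0 + 1
            # fragments overlapping [g0, g1): start < g1 and end > g0
            n = np.searchsorted(starts, g1, side="left") \
                - np.searchsorted(ends, g0, side="right")
            sums[b] += max(n, 0)
    n = max(frags.n_fragments, 1)
    rpm = sums / len(ann.genes) * 1e6 / n
    offsets = np.arange(n_bins) * bin_bp - flank_bp
    return TssProfile(offsets=offsets, rpm=rpm, flank_bp=flank_bp, bin_bp=bin_bp)


# ---------------------------------------------------------------------------
# Peak <-> gene overlap, density, enrichment, export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLink:
    region_index: int
    region: GenomicInterval
    gene_id: str
    direction: int
    p_value: float


@dataclass
class OverlapResult:
    links: list[GeneLink]
    n_regions: int   # distinct regions with >= 1 link
    n_genes: int     # distinct genes with >= 1 link


def overlap_with_genes(regions: "ResponsiveSet | Sequence[GenomicInterval]",
                       genes: Sequence[Gene] | GeneAnnotation,
                       flank_bp: int = 2000) -> OverlapResult:
    """Link regions to genes whose flank-extended interval they overlap.

    Gene intervals are extended by ``flank_bp`` on both sides; any >= 1 bp
    overlap makes a link.  Many-to-many links are allowed, so the distinct
    region and gene counts are generally unequal.
    """
    if isinstance(genes, GeneAnnotation):
        genes = genes.genes
    if isinstance(regions, ResponsiveSet):
        items = [(r.interval, r.direction, r.p_value) for r in regions.regions]
    else:
        items = [(iv, 0, 1.0) for iv in regions]
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        start = max(g.interval.start - flank_bp, 0)
        end = g.interval.end + flank_bp
        trees.setdefault(g.chrom, IntervalTree()).addi(start, end, g.gene_id)
    links: list[GeneLink] = []
    for i, (iv, direction, p) in enumerate(items):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end), key=lambda h: h.data):
            links.append(GeneLink(region_index=i, region=iv, gene_id=hit.data,
                                  direction=direction, p_value=p))
    return OverlapResult(
        links=links,
        n_regions=len({l.region_index for l in links}),
        n_genes=len({l.gene_id for l in links}),
    )


def chromosome_density(peaks: Sequence[GenomicInterval],
                       genome: Mapping[str, int]) -> pd.DataFrame:
    """Peaks per Mb per chromosome and the ratio to the genome-wide density."""
    rows = []
    total_mb = sum(genome.values()) / 1e6
    genome_density = len(peaks) / total_mb if total_mb else 0.0
    counts = {c: 0 for c in genome}
    for p in peaks:
        if p.chrom in counts:
            counts[p.chrom] += 1
    for chrom in sorted(genome):
        mb = genome[chrom] / 1e6
        dens = counts[chrom] / mb if mb else 0.0
        ratio = dens / genome_density if genome_density else 0.0
        rows.append((chrom, counts[chrom], mb, dens, ratio))
    return pd.DataFrame(rows, columns=["chrom", "n_peaks", "length_mb",
                                       "density_per_mb", "ratio_to_genome"])


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    study_hits: int
    study_size: int
    population_hits: int
    population_size: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float = 1.0
    significant: bool = False


def hypergeom_enrichment(study: Iterable[str], population: Iterable[str],
                         term_map: Mapping[str, Iterable[str]],
                         alpha: float = 0.05,
                         min_fold: float = 1.3) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each term in the study set.

    p is the upper-tail probability of >= the observed study hits;
    Benjamini–Hochberg adjustment runs across terms; a row is significant iff
    adjusted p < ``alpha`` AND fold enrichment > ``min_fold`` (both required).
    """
    study_set, pop_set = set(study), set(population)
    if not study_set <= pop_set:
        raise ValueError("study genes must be a subset of the population")
    M, n = len(pop_set), len(study_set)
    rows: list[EnrichmentRow] = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & pop_set
        K = len(term_genes)
        k = len(term_genes & study_set)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        fold = (k / n) / (K / M) if (K and n) else 0.0
        rows.append(EnrichmentRow(term=term, study_hits=k, study_size=n,
                                  population_hits=K, population_size=M,
                                  fold_enrichment=fold, p_value=min(p, 1.0)))
    if rows:
        _, padj, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        rows = [
            EnrichmentRow(**{**r.__dict__, "adjusted_p": float(q),
                             "significant": bool(q < alpha
                                                 and r.fold_enrichment > min_fold)})
            for r, q in zip(rows, padj)
        ]
    return rows


def mapman_export(links_by_class: Mapping[str, OverlapResult],
                  gene_ids: Sequence[str]) -> pd.DataFrame:
    """Gene x stress-class matrix with entries in {0, 1, −1}.

    1: the gene is linked to >= 1 responsive region gaining the mark in that
    class; −1: linked only to losing regions; 0: unlinked.  A gene linked to
    regions of both directions takes the direction of the smallest-p region.
    """
    data = {}
    for cls, result in links_by_class.items():
        col = {g: 0 for g in gene_ids}
        best_p: dict[str, float] = {}
        for link in result.links:
            if link.gene_id not in col or link.direction == 0:
                continue
            if link.gene_id not in best_p or link.p_value < best_p[link.gene_id]:
                best_p[link.gene_id] = link.p_value
                col[link.gene_id] = link.direction
        data[cls] = [col[g] for g in gene_ids]
    return pd.DataFrame(data, index=list(gene_ids))


def write_mapman(df: pd.DataFrame, stress_class: str, path) -> None:
    """Two-column MapMan experiment file (gene id, value) for one class."""
    with open(path, "w") as fh:
        fh.write("IDENTIFIER\tVALUE\n")
        for gene, value in df[stress_class].items():
            fh.write(f"{gene}\t{value}\n")
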