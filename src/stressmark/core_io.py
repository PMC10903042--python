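"""Data model, coordinate conventions, and readers/writers for the pipeline.

All coordinates are 0-based half-open (BED convention) internally; GFF3 input
(1-based closed) is converted on read.  A sequencing *read* is reduced to its
strand-aware 5' position; a *fragment* is that read extended to the sonication
fragment size.  Libraries are keyed by (condition, timepoint, replicate, role),
where ``role`` distinguishes ChIP libraries from the per-condition input
(sonicated chromatin, no immunoprecipitation) controls.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ChIP conditions: unstressed control, drought, drought-then-heat.
CONDITIONS = ("C", "DT", "DTHT")
#: Sampling grid in hours of drought (heat is imposed at 72 h in DTHT).
TIMEPOINTS_H = (0, 72, 96, 120, 144, 168)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class LibraryLabel:
    """Identity of one sequencing library.

    Input-control libraries carry ``timepoint_h=None`` (one control per
    condition, shared across time points).
    """

    condition: str
    timepoint_h: Optional[int]
    replicate: int
    role: str = "chip"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.role not in ("chip", "input"):
            raise ValueError(f"role must be 'chip' or 'input', got {self.role!r}")
        if self.role == "chip" and self.timepoint_h not in TIMEPOINTS_H:
            raise ValueError(
                f"chip library timepoint must be one of {TIMEPOINTS_H}, "
                f"got {self.timepoint_h!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    def __str__(self) -> str:
        tp = "NA" if self.timepoint_h is None else f"{self.timepoint_h}h"
        return f"{self.condition}_{tp}_rep{self.replicate}_{self.role}"


@dataclass
class ReadCollection:
    """Strand-aware 5' read positions of one library."""

    label: LibraryLabel
    reads: list[tuple[str, int, str]]  # (chrom, 5' position, strand)
    genome: dict[str, int]

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class FragmentCollection:
    """Fragment-extended reads of one library.

    Fragments are stored per chromosome as an (n, 2) integer array of
    [start, end) rows for vectorised window counting; ``fragments`` yields
    them as :class:`GenomicInterval` objects.
    """

    label: LibraryLabel
    by_chrom: dict[str, np.ndarray]
    genome: dict[str, int]

    @property
    def n_fragments(self) -> int:
        return sum(len(a) for a in self.by_chrom.values())

    @property
    def fragments(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.by_chrom):
            for s, e in self.by_chrom[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def count_overlapping(self, interval: GenomicInterval) -> int:
        """Number of fragments overlapping ``interval`` by >= 1 bp."""
        arr = self.by_chrom.get(interval.chrom)
        if arr is None or len(arr) == 0:
            return 0
        return int(np.count_nonzero((arr[:, 0] < interval.end) & (arr[:, 1] > interval.start)))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    interval: GenomicInterval
    tss: int
    tes: int
    five_prime_utr: tuple[GenomicInterval, ...] = ()
    cds: tuple[GenomicInterval, ...] = ()
    introns: tuple[GenomicInterval, ...] = ()
    three_prime_utr: tuple[GenomicInterval, ...] = ()


@dataclass
class GeneAnnotation:
    """Gene models plus a repeat track.

    TSS is the gene start on the + strand and ``end - 1`` on the − strand;
    TES is the opposite extremity.  Introns are the gaps between exons of the
    representative (longest) mRNA.
    """

    genes: list[Gene]
    repeats: list[GenomicInterval] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with the study's defaults.

    Island calling: 200-bp windows, 200-bp gap, redundancy threshold 1,
    effective genome fraction 0.7, island FDR 0.05.  Differential calling:
    200-bp windows stepped every 100 bp, gap 0, fragment size 300,
    raw p-value cutoff 0.01.  ``eligible_window_p`` is the per-window Poisson
    tail probability below which a window may seed an island (SICER default).
    ``min_diff_peak_windows`` is the minimum number of significant member
    windows a merged differential peak must have to be reported by the
    pipeline-level caller (isolated sub-fragment-scale single windows are
    discarded as noise), and ``min_diff_fold`` the minimum between-group
    RPM ratio of a reported differential peak — a raw p cutoff alone admits
    small-amplitude sampling fluctuations inside strong constitutive domains,
    where counts are large enough to make a ~1.1-fold wobble nominally
    significant.
    """

    window_bp: int = 200
    gap_bp: int = 200
    redundancy_threshold: int = 1
    effective_genome_fraction: float = 0.7
    island_fdr: float = 0.05
    diff_window_bp: int = 200
    diff_step_bp: int = 100
    diff_gap_bp: int = 0
    fragment_size_bp: int = 300
    diff_p_cutoff: float = 0.01
    flank_bp: int = 2000
    eligible_window_p: float = 0.2
    min_diff_peak_windows: int = 2
    min_diff_fold: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_bp", "redundancy_threshold", "diff_window_bp",
                     "diff_step_bp", "fragment_size_bp", "flank_bp",
                     "min_diff_peak_windows"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.gap_bp < 0 or self.diff_gap_bp < 0:
            raise ValueError("gap sizes must be non-negative")
        if self.min_diff_fold < 1:
            raise ValueError("min_diff_fold must be >= 1")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")
        for name in ("island_fdr", "diff_p_cutoff", "eligible_window_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genome_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into a genome map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#", dtype={"chrom": str})
    return {str(r.chrom): int(r.length) for r in df.itertuples()}


def read_bed_reads(path: str | Path, genome: Mapping[str, int],
                   label: LibraryLabel) -> ReadCollection:
    """Read aligned reads from a >= 6-column BED file.

    Each record becomes one read at its strand-aware 5' end: ``start`` for
    + records and ``end - 1`` for − records.
    """
    reads: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: reads require 6-column BED "
                    "(chrom, start, end, name, score, strand)"
                )
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            strand = parts[5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if chrom not in genome:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} absent from genome map"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
            if not 0 <= start < end <= genome[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} outside "
                    f"chromosome bounds [0, {genome[chrom]}) — genome/annotation mismatch?"
                )
            pos = start if strand == "+" else end - 1
            reads.append((chrom, pos, strand))
    return ReadCollection(label=label, reads=reads, genome=dict(genome))


def write_bed_reads(rc: ReadCollection, path: str | Path,
                    read_length: int = 1) -> None:
    """Write reads as BED6 records of ``read_length`` bp anchored at the 5' end."""
    with open(path, "w") as fh:
        for i, (chrom, pos, strand) in enumerate(rc.reads):
            if strand == "+":
                s, e = pos, min(pos + read_length, rc.genome[chrom])
            else:
                s, e = max(pos - read_length + 1, 0), pos + 1
            fh.write(f"{chrom}\t{s}\t{e}\tr{i}\t0\t{strand}\n")


def read_bam_reads(path: str | Path, genome: Mapping[str, int],
                   label: LibraryLabel) -> ReadCollection:
    """Optional BAM adapter: mapped records to strand-aware 5' positions."""
    import pysam  # local import: BAM support is optional

    reads: list[tuple[str, int, str]] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            chrom = aln.reference_name
            if chrom not in genome:
                raise ValueError(f"{path}: chromosome {chrom!r} absent from genome map")
            if aln.is_reverse:
                reads.append((chrom, aln.reference_end - 1, "-"))
            else:
                reads.append((chrom, aln.reference_start, "+"))
    return ReadCollection(label=label, reads=reads, genome=dict(genome))


def read_repeats_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3(+) repeat track."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED3 requires 3 columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def read_gff3_genes(path: str | Path, repeats_bed: str | Path | None = None
                    ) -> GeneAnnotation:
    """Parse gene models from GFF3 into the internal 0-based representation.

    When a gene carries several mRNAs the longest one is taken as the
    representative model.  Introns are derived as the gaps between its exons.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    gene_ids = {f.id for f in db.features_of_type("gene")}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if parents and not set(parents) & gene_ids:
            logger.warning("mRNA %s has no resolvable gene parent; skipped", mrna.id)

    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise ValueError(f"gene {g.id}: end < start in GFF3")
        interval = GenomicInterval(g.seqid, g.start - 1, g.end)
        strand = g.strand
        tss = interval.start if strand == "+" else interval.end - 1
        tes = interval.end - 1 if strand == "+" else interval.start

        mrnas = list(db.children(g, featuretype="mRNA"))
        rep = max(mrnas, key=lambda m: m.end - m.start) if mrnas else None

        def _sub(ftype: str) -> tuple[GenomicInterval, ...]:
            if rep is None:
                return ()
            ivs = []
            for f in db.children(rep, featuretype=ftype):
                if f.end < f.start:
                    raise ValueError(f"{ftype} of {g.id}: end < start in GFF3")
                ivs.append(GenomicInterval(f.seqid, f.start - 1, f.end))
            return tuple(sorted(ivs))

        exons = _sub("exon")
        introns = tuple(
            GenomicInterval(g.seqid, a.end, b.start)
            for a, b in zip(exons, exons[1:])
            if b.start > a.end
        )
        genes.append(Gene(
            gene_id=g.id, chrom=g.seqid, strand=strand, interval=interval,
            tss=tss, tes=tes,
            five_prime_utr=_sub("five_prime_UTR"),
            cds=_sub("CDS"),
            introns=introns,
            three_prime_utr=_sub("three_prime_UTR"),
        ))
    genes.sort(key=lambda x: (x.chrom, x.interval.start, x.gene_id))
    repeats = read_repeats_bed(repeats_bed) if repeats_bed else []
    return GeneAnnotation(genes=genes, repeats=repeats)


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path,
                        extra_columns: Optional[Sequence[Sequence]] = None,
                        names: Optional[Sequence[str]] = None) -> None:
    """Write intervals as BED6(+extra) with '.' strand."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            row = [iv.chrom, str(iv.start), str(iv.end), name, "0", "."]
            if extra_columns:
                row += [str(x) for x in extra_columns[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Read-level transforms
# ---------------------------------------------------------------------------

def deduplicate(rc: ReadCollection, redundancy_threshold: int = 1) -> ReadCollection:
    """Keep at most ``redundancy_threshold`` reads per (chrom, position, strand).

    Order-independent: the retained multiset depends only on per-site counts.
    """
    if redundancy_threshold < 1:
        raise ValueError("redundancy_threshold must be >= 1")
    counts: Counter = Counter()
    kept: list[tuple[str, int, str]] = []
    for read in sorted(rc.reads):
        counts[read] += 1
        if counts[read] <= redundancy_threshold:
            kept.append(read)
    return ReadCollection(label=rc.label, reads=kept, genome=rc.genome)


def extend_reads(rc: ReadCollection, fragment_size_bp: int) -> FragmentCollection:
    """Extend each 5' read position to a fragment of ``fragment_size_bp``.

    + strand read at p → [p, p+size); − strand read at p → [p−size+1, p+1);
    intervals are clipped to chromosome bounds. No read is dropped.
    """
    if fragment_size_bp < 1:
        raise ValueError("fragment_size_bp must be >= 1")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    n_clipped = 0
    for chrom, pos, strand in rc.reads:
        length = rc.genome[chrom]
        if strand == "+":
            s, e = pos, pos + fragment_size_bp
        else:
            s, e = pos - fragment_size_bp + 1, pos + 1
        cs, ce = max(s, 0), min(e, length)
        if (cs, ce) != (s, e):
            n_clipped += 1
        per_chrom.setdefault(chrom, []).append((cs, ce))
    if n_clipped:
        logger.debug("clipped %d fragments at chromosome edges", n_clipped)
    by_chrom = {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in per_chrom.items()
    }
    return FragmentCollection(label=rc.label, by_chrom=by_chrom, genome=rc.genome)


def pool_fragments(collections: Sequence[FragmentCollection],
                   label: Optional[LibraryLabel] = None) -> FragmentCollection:
    """Pool fragment collections (e.g. replicates of one group) into one."""
    if not collections:
        raise ValueError("nothing to pool")
    genome = collections[0].genome
    by_chrom: dict[str, list[np.ndarray]] = {}
    for fc in collections:
        for c, arr in fc.by_chrom.items():
            by_chrom.setdefault(c, []).append(arr)
    merged = {
        c: np.array(sorted(map(tuple, np.concatenate(v))), dtype=np.int64).reshape(-1, 2)
        for c, v in by_chrom.items()
    }
    return FragmentCollection(label=label or collections[0].label,
                              by_chrom=merged, genome=genome)


# ---------------------------------------------------------------------------
# Experiment manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[tuple[Path, LibraryLabel]]:
    """Read the driving manifest TSV: path, condition, timepoint_h, replicate, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"path", "condition", "timepoint_h", "replicate", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    out = []
    for r in df.itertuples():
        tp = None if r.timepoint_h in ("NA", "", None) or pd.isna(r.timepoint_h) \
            else int(r.timepoint_h)
        label = LibraryLabel(condition=r.condition, timepoint_h=tp,
                             replicate=int(r.replicate), role=r.role)
        p = Path(r.path)
        out.append((p if p.is_absolute() else base / p, label))
    labels = [lab for _, lab in out]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (condition, timepoint, replicate, role) in manifest")
    return out


def load_experiment(manifest_path: str | Path, genome: Mapping[str, int],
                    cfg: PipelineConfig) -> dict[LibraryLabel, FragmentCollection]:
    """Read, deduplicate, and fragment-extend every library in a manifest."""
    frags: dict[LibraryLabel, FragmentCollection] = {}
    for path, label in read_manifest(manifest_path):
        rc = read_bed_reads(path, genome, label)
        rc = deduplicate(rc, cfg.redundancy_threshold)
        frags[label] = extend_reads(rc, cfg.fragment_size_bp)
    return frags
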