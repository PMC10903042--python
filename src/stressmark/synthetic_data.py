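"""Synthetic multi-condition ChIP experiment generator with ground truth.

Emulates the study design — 3 conditions (C, DT, DTHT) × 6 time points
(0–168 h of drought, heat imposed at 72 h in DTHT) × 3 replicates plus one
input control per condition — on a toy genome.  Fragments (not short reads)
are simulated: uniform Poisson background everywhere, multiplied by an
effect size inside implanted enrichment islands whose activity depends on
the island's stress class, the library's condition, and the time point:

* ``constitutive`` islands are active in every ChIP library;
* ``DT`` islands activate in DT **and** DTHT from their onset time point
  (drought is present in both treatments);
* ``DTHT`` islands (combined-stress effects) activate only in DTHT from onset;
* ``HT`` islands activate only in DTHT from an onset >= 96 h, since heat
  begins only after 72 h of drought.

Input libraries are background-only.  Islands are implanted immediately
downstream of gene TSSs (where this activating mark concentrates), one gene
per island.  The manifest records, per island, both its generative class and
the *expected rule classes* — the classes the factorial rules analytically
imply for its activity pattern (the rules overlap by construction: e.g. a DT
island is also DTHT-responsive because drought effects persist in the
combined treatment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_io import (
    CONDITIONS,
    TIMEPOINTS_H,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    LibraryLabel,
)
from .stress_classifier import CLASS_RULES, Membership, ResponsiveSet, evaluate_rule

__all__ = [
    "TruthSpec", "IslandTruth", "GroundTruthManifest",
    "simulate_annotation", "simulate_experiment", "expected_rule_classes",
    "evaluate_against_truth",
]

ISLAND_CLASSES = ("DT", "DTHT", "HT", "constitutive")

#: Allowed onset time points per island class.  Heat starts at 72 h of
#: drought, so heat-only effects cannot precede the 96 h sample.
ONSET_CHOICES = {"DT": (72, 96, 120), "DTHT": (72, 96), "HT": (96, 120)}


@dataclass(frozen=True)
class IslandTruth:
    interval: GenomicInterval
    stress_class: str
    onset_h: Optional[int]       # None for constitutive islands
    multiplier: float
    gene_id: str
    expected_classes: tuple[str, ...] = ()


@dataclass
class TruthSpec:
    """Study conditions of the synthetic experiment.

    Defaults give a 2 × 500 kb genome with 100 genes, 30 background
    fragments/kb per library (≈ 30 fragments per 1-kb island per library),
    300-bp fragments, and 12 implanted 1-kb islands per class at effect
    multiplier 4.
    """

    genome: tuple[tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 500_000))
    n_genes: int = 100
    gene_length_bp: int = 2000
    repeat_fraction: float = 0.15
    fragments_per_kb: float = 30.0
    fragment_size_bp: int = 300
    island_width_bp: int = 1000
    multiplier: float = 4.0
    n_islands_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"DT": 12, "DTHT": 12, "HT": 12,
                                 "constitutive": 12})
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.fragments_per_kb <= 0:
            raise ValueError("zero-depth libraries requested")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        unknown = set(self.n_islands_per_class) - set(ISLAND_CLASSES)
        if unknown:
            raise ValueError(f"unknown island classes {sorted(unknown)}")

    @property
    def genome_map(self) -> dict[str, int]:
        return dict(self.genome)


@dataclass
class GroundTruthManifest:
    islands: list[IslandTruth]
    libraries: list[dict]  # label fields, n_fragments, path

    def to_json(self, path: str | Path) -> None:
        payload = {
            "islands": [
                {
                    "chrom": i.interval.chrom, "start": i.interval.start,
                    "end": i.interval.end, "stress_class": i.stress_class,
                    "onset_h": i.onset_h, "multiplier": i.multiplier,
                    "gene_id": i.gene_id,
                    "expected_classes": list(i.expected_classes),
                }
                for i in self.islands
            ],
            "libraries": self.libraries,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        islands = [
            IslandTruth(
                interval=GenomicInterval(d["chrom"], d["start"], d["end"]),
                stress_class=d["stress_class"], onset_h=d["onset_h"],
                multiplier=d["multiplier"], gene_id=d["gene_id"],
                expected_classes=tuple(d["expected_classes"]),
            )
            for d in payload["islands"]
        ]
        return cls(islands=islands, libraries=payload["libraries"])


# ---------------------------------------------------------------------------
# Island activity and expected classification
# ---------------------------------------------------------------------------

def island_active(stress_class: str, onset_h: Optional[int],
                  condition: str, timepoint_h: int) -> bool:
    """Whether an island is enriched in a ChIP library of this condition/time."""
    if stress_class == "constitutive":
        return True
    assert onset_h is not None
    if stress_class == "DT":
        return condition in ("DT", "DTHT") and timepoint_h >= onset_h
    if stress_class in ("DTHT", "HT"):
        return condition == "DTHT" and timepoint_h >= onset_h
    raise ValueError(f"unknown island class {stress_class!r}")


def expected_rule_classes(stress_class: str, onset_h: Optional[int]
                          ) -> tuple[str, ...]:
    """Classes the factorial rules imply for an island's activity pattern.

    Built by evaluating each class rule on the analytic differential pattern:
    a comparison (A vs B, t) is differential iff the island's activity
    differs between conditions A and B at time t.
    """
    pattern = {}
    for (a, b), tp in {k for r in CLASS_RULES.values()
                       for k in r.baseline + r.support}:
        diff = (island_active(stress_class, onset_h, a, tp)
                != island_active(stress_class, onset_h, b, tp))
        pattern[((a, b), tp)] = Membership(diff, 1 if diff else 0, 0.0)
    out = []
    for cls, rule in CLASS_RULES.items():
        ok, _ = evaluate_rule(rule, pattern)
        if ok:
            out.append(cls)
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def _place_genes(spec: TruthSpec, rng: np.random.Generator) -> list[Gene]:
    """Place non-overlapping genes on fixed slots with random jitter."""
    glen = spec.gene_length_bp
    slot = glen + 3000  # inter-gene spacing keeps flanks and islands disjoint
    slots: list[tuple[str, int]] = []
    for chrom, length in spec.genome:
        for s in range(0, length - slot, slot):
            slots.append((chrom, s))
    if len(slots) < spec.n_genes:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes of {glen} bp into the genome; "
            "use a larger genome or fewer genes")
    chosen = rng.choice(len(slots), size=spec.n_genes, replace=False)
    genes: list[Gene] = []
    for i, slot_idx in enumerate(sorted(chosen)):
        chrom, s0 = slots[slot_idx]
        jitter = int(rng.integers(0, slot - glen - 1000))
        start = s0 + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_build_gene(f"gene{i:04d}", chrom, strand, start, glen))
    return genes


def _build_gene(gene_id: str, chrom: str, strand: str, start: int,
                length: int) -> Gene:
    """Two-exon gene: 5'UTR 10%, CDS 30%, intron 20%, CDS 30%, 3'UTR 10%."""
    end = start + length
    u5, cds, intr = length // 10, 3 * length // 10, length // 5
    # transcription-order segment widths
    widths = [u5, cds, intr, cds, length - u5 - 2 * cds - intr]
    if strand == "+":
        edges = np.cumsum([start] + widths)
        seg = [GenomicInterval(chrom, int(a), int(b))
               for a, b in zip(edges[:-1], edges[1:])]
        utr5, cds1, intron, cds2, utr3 = seg
    else:
        edges = np.cumsum([start] + widths[::-1])
        seg = [GenomicInterval(chrom, int(a), int(b))
               for a, b in zip(edges[:-1], edges[1:])]
        utr3, cds2, intron, cds1, utr5 = seg
    iv = GenomicInterval(chrom, start, end)
    tss = start if strand == "+" else end - 1
    tes = end - 1 if strand == "+" else start
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand, interval=iv,
                tss=tss, tes=tes,
                five_prime_utr=(utr5,), cds=tuple(sorted((cds1, cds2))),
                introns=(intron,), three_prime_utr=(utr3,))


def _gff3_text(genes: Sequence[Gene]) -> str:
    """Serialise gene models to GFF3 (1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    for g in genes:
        iv = g.interval
        attrs = f"ID={g.gene_id}"
        lines.append("\t".join(map(str, [
            g.chrom, "sim", "gene", iv.start + 1, iv.end, ".", g.strand, ".",
            attrs])))
        mid = f"{g.gene_id}.1"
        lines.append("\t".join(map(str, [
            g.chrom, "sim", "mRNA", iv.start + 1, iv.end, ".", g.strand, ".",
            f"ID={mid};Parent={g.gene_id}"])))
        exons = _exons_of(g)
        for kind, ivs in (("exon", exons), ("CDS", g.cds),
                          ("five_prime_UTR", g.five_prime_utr),
                          ("three_prime_UTR", g.three_prime_utr)):
            for k, sub in enumerate(sorted(ivs)):
                lines.append("\t".join(map(str, [
                    g.chrom, "sim", kind, sub.start + 1, sub.end, ".",
                    g.strand, ".", f"ID={mid}.{kind}{k};Parent={mid}"])))
    return "\n".join(lines) + "\n"


def _exons_of(g: Gene) -> list[GenomicInterval]:
    """Exons = gene interval minus introns."""
    exons = []
    pos = g.interval.start
    for intron in sorted(g.introns):
        if intron.start > pos:
            exons.append(GenomicInterval(g.chrom, pos, intron.start))
        pos = intron.end
    if pos < g.interval.end:
        exons.append(GenomicInterval(g.chrom, pos, g.interval.end))
    return exons


def _place_repeats(spec: TruthSpec, genes: Sequence[Gene],
                   rng: np.random.Generator) -> list[GenomicInterval]:
    """Fill intergenic space with 500-bp repeats up to the requested fraction."""
    target_bp = spec.repeat_fraction * sum(spec.genome_map.values())
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.genome_map}
    for g in genes:
        occupied[g.chrom].append((g.interval.start, g.interval.end))
    repeats: list[GenomicInterval] = []
    placed = 0
    rep_len = 500
    attempts = 0
    max_attempts = int(20 * target_bp / rep_len) + 100
    chroms = sorted(spec.genome_map)
    lengths = np.array([spec.genome_map[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    while placed < target_bp and attempts < max_attempts:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, spec.genome_map[chrom] - rep_len))
        end = start + rep_len
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        repeats.append(GenomicInterval(chrom, start, end))
        placed += rep_len
    repeats.sort()
    return repeats


def simulate_annotation(spec: TruthSpec,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[GeneAnnotation, str]:
    """Simulate gene models and repeats; returns (annotation, GFF3 text).

    Deterministic for a given spec (the RNG defaults to one seeded from
    ``spec.seed``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = _place_genes(spec, rng) if spec.n_genes else []
    repeats = _place_repeats(spec, genes, rng)
    return GeneAnnotation(genes=genes, repeats=repeats), _gff3_text(genes)


# ---------------------------------------------------------------------------
# Island placement and fragment simulation
# ---------------------------------------------------------------------------

def _place_islands(spec: TruthSpec, genes: Sequence[Gene],
                   rng: np.random.Generator) -> list[IslandTruth]:
    """One island per randomly chosen gene, at [TSS, TSS + width) in
    transcription orientation."""
    n_total = sum(spec.n_islands_per_class.values())
    if n_total > len(genes):
        raise ValueError("more islands requested than genes available")
    chosen = rng.choice(len(genes), size=n_total, replace=False)
    islands: list[IslandTruth] = []
    k = 0
    for cls in ISLAND_CLASSES:
        for _ in range(spec.n_islands_per_class.get(cls, 0)):
            g = genes[int(chosen[k])]
            k += 1
            w = min(spec.island_width_bp, g.interval.width)
            if g.strand == "+":
                iv = GenomicInterval(g.chrom, g.tss, g.tss + w)
            else:
                iv = GenomicInterval(g.chrom, g.tss - w + 1, g.tss + 1)
            onset = (None if cls == "constitutive"
                     else int(rng.choice(ONSET_CHOICES[cls])))
            islands.append(IslandTruth(
                interval=iv, stress_class=cls, onset_h=onset,
                multiplier=spec.multiplier, gene_id=g.gene_id,
                expected_classes=expected_rule_classes(cls, onset)))
    islands.sort(key=lambda i: i.interval)
    return islands


def _simulate_library(spec: TruthSpec, label: LibraryLabel,
                      islands: Sequence[IslandTruth],
                      rng: np.random.Generator) -> list[tuple[str, int, int, str]]:
    """Fragments of one library as (chrom, start, end, strand) records."""
    F = spec.fragment_size_bp
    records: list[tuple[str, int, int, str]] = []
    for chrom, length in spec.genome:
        n_bg = int(rng.poisson(spec.fragments_per_kb * length / 1000))
        starts = rng.integers(0, length - F, size=n_bg)
        strands = rng.choice(np.array(["+", "-"]), size=n_bg)
        records += [(chrom, int(s), int(s) + F, str(st))
                    for s, st in zip(starts, strands)]
    if label.role == "chip":
        for isl in islands:
            if not island_active(isl.stress_class, isl.onset_h,
                                 label.condition, label.timepoint_h):
                continue
            iv = isl.interval
            extra_rate = (isl.multiplier - 1) * spec.fragments_per_kb \
                * iv.width / 1000
            n_extra = int(rng.poisson(extra_rate))
            hi = max(iv.end - F, iv.start + 1)
            starts = rng.integers(iv.start, hi, size=n_extra)
            strands = rng.choice(np.array(["+", "-"]), size=n_extra)
            records += [(iv.chrom, int(s), int(s) + F, str(st))
                        for s, st in zip(starts, strands)]
    return records


def simulate_experiment(spec: TruthSpec, outdir: str | Path
                        ) -> GroundTruthManifest:
    """Emit the full synthetic experiment to ``outdir``.

    Writes per-library BED6 files (57 by default: 3 × 6 × 3 ChIP plus one
    input per condition), ``manifest.tsv``, ``genome.tsv``,
    ``annotation.gff3``, ``repeats.bed`` and ``truth.json``.  Byte-identical
    output for identical specs.
    """
    outdir = Path(outdir)
    (outdir / "libs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ann, gff3 = simulate_annotation(spec, rng)
    islands = _place_islands(spec, ann.genes, rng)

    (outdir / "annotation.gff3").write_text(gff3)
    with open(outdir / "repeats.bed", "w") as fh:
        for iv in ann.repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(outdir / "genome.tsv", "w") as fh:
        for chrom, length in spec.genome:
            fh.write(f"{chrom}\t{length}\n")

    labels: list[LibraryLabel] = []
    for cond in CONDITIONS:
        for tp in TIMEPOINTS_H:
            for rep in range(1, spec.replicates + 1):
                labels.append(LibraryLabel(cond, tp, rep, "chip"))
    for cond in CONDITIONS:
        labels.append(LibraryLabel(cond, None, 1, "input"))

    lib_rows = []
    manifest_lines = ["path\tcondition\ttimepoint_h\treplicate\trole"]
    for label in labels:
        records = _simulate_library(spec, label, islands, rng)
        rel = f"libs/{label}.bed"
        with open(outdir / rel, "w") as fh:
            for i, (chrom, s, e, st) in enumerate(records):
                fh.write(f"{chrom}\t{s}\t{e}\tf{i}\t0\t{st}\n")
        tp = "NA" if label.timepoint_h is None else str(label.timepoint_h)
        manifest_lines.append(
            f"{rel}\t{label.condition}\t{tp}\t{label.replicate}\t{label.role}")
        lib_rows.append({
            "condition": label.condition, "timepoint_h": label.timepoint_h,
            "replicate": label.replicate, "role": label.role,
            "n_fragments": len(records), "path": rel,
        })
    (outdir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")

    truth = GroundTruthManifest(islands=islands, libraries=lib_rows)
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(responsive: Mapping[str, ResponsiveSet],
                           truth: GroundTruthManifest) -> dict[str, dict[str, float]]:
    """Per-class precision and recall of classified regions vs the manifest.

    A truth island counts as recovered for class X when any called region of
    class X overlaps it by >= 1 bp; a called region counts as a true positive
    when it overlaps any island whose expected rule classes include X.
    """
    out: dict[str, dict[str, float]] = {}
    for cls, rs in responsive.items():
        expected = [i for i in truth.islands if cls in i.expected_classes]
        called = [r.interval for r in rs.regions]
        recovered = sum(
            1 for i in expected if any(i.interval.overlaps(c) for c in called))
        tp = sum(
            1 for c in called
            if any(c.overlaps(i.interval) for i in expected))
        recall = recovered / len(expected) if expected else float("nan")
        precision = tp / len(called) if called else float("nan")
        out[cls] = {"precision": precision, "recall": recall,
                    "n_called": len(called), "n_truth": len(expected)}
    return out
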