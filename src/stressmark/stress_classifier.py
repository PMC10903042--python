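"""Factorial time-course rules classifying drought/heat-responsive regions.

Differential peaks from every contrast and time point are merged
(single-linkage, >= 1 bp overlap) into one region universe so that "a region"
has a persistent coordinate identity across comparisons.  A region is then:

* **DT-responsive** — not differential in DT-vs-C at 0 h, and differential in
  DT-vs-C at >= 1 of {72, 96, 120, 144, 168} h;
* **DTHT-responsive** — same template on the DTHT-vs-C contrast;
* **HT-responsive** — not differential in DTHT-vs-DT at 0 h nor 72 h, and
  differential in DTHT-vs-C at >= 1 of {96, 120, 144, 168} h.  Heat is imposed
  after 72 h of drought, so heat effects can only be read off the combined
  treatment from 96 h on, against both the drought-only and control baselines.

The classes deliberately overlap (no exclusivity is imposed): e.g. any region
meeting the HT rule also meets the DTHT rule unless it is differential in
DTHT-vs-C at 0 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import GenomicInterval
from .differential import DifferentialPeakSet

__all__ = [
    "STRESS_CLASSES", "CLASS_RULES", "ClassRule", "RegionUniverse",
    "ResponsiveRegion", "ResponsiveSet", "build_region_universe",
    "classify_responsive", "evaluate_rule",
]

STRESS_CLASSES = ("DT", "DTHT", "HT")

#: membership key: ((condition A, condition B), timepoint_h)
MembershipKey = tuple[tuple[str, str], int]


@dataclass(frozen=True)
class ClassRule:
    """A factorial rule: every baseline key non-differential, and at least one
    support key differential."""

    baseline: tuple[MembershipKey, ...]
    support: tuple[MembershipKey, ...]


CLASS_RULES: dict[str, ClassRule] = {
    "DT": ClassRule(
        baseline=((("DT", "C"), 0),),
        support=tuple((("DT", "C"), t) for t in (72, 96, 120, 144, 168)),
    ),
    "DTHT": ClassRule(
        baseline=((("DTHT", "C"), 0),),
        support=tuple((("DTHT", "C"), t) for t in (72, 96, 120, 144, 168)),
    ),
    "HT": ClassRule(
        baseline=((("DTHT", "DT"), 0), (("DTHT", "DT"), 72)),
        support=tuple((("DTHT", "C"), t) for t in (96, 120, 144, 168)),
    ),
}

#: Every (contrast, timepoint) differential comparison any rule consumes.
REQUIRED_COMPARISONS: tuple[MembershipKey, ...] = tuple(
    sorted({k for r in CLASS_RULES.values() for k in r.baseline + r.support})
)


@dataclass(frozen=True)
class Membership:
    is_differential: bool
    direction: int = 0
    p_value: float = 1.0


@dataclass
class RegionUniverse:
    """Merged regions plus their differential membership per comparison."""

    regions: list[GenomicInterval]
    membership: list[dict[MembershipKey, Membership]]
    covered_keys: frozenset[MembershipKey] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ResponsiveRegion:
    interval: GenomicInterval
    supporting_timepoints: tuple[int, ...]
    direction: int     # at the earliest qualifying time point
    p_value: float     # at the earliest qualifying time point


@dataclass
class ResponsiveSet:
    stress_class: str
    regions: list[ResponsiveRegion]


def build_region_universe(peaksets: Sequence[DifferentialPeakSet]
                          ) -> RegionUniverse:
    """Single-linkage merge of all differential peaks into one region universe.

    Peaks from every contrast/time point are merged wherever they overlap by
    >= 1 bp (transitively); each region's membership records, for every
    (contrast, timepoint), whether any peak of that comparison overlaps it,
    with the direction and p-value of the smallest-p such peak.
    """
    tagged = []  # (interval, key, direction, p)
    covered: set[MembershipKey] = set()
    for ps in peaksets:
        key: MembershipKey = (ps.contrast, ps.timepoint_h)
        covered.add(key)
        for pk in ps.peaks:
            tagged.append((pk.interval, key, pk.direction, pk.p_value))
    tagged.sort(key=lambda x: (x[0].chrom, x[0].start, x[0].end))

    regions: list[GenomicInterval] = []
    members: list[list[tuple[MembershipKey, int, float]]] = []
    cur: list[tuple[MembershipKey, int, float]] = []
    cur_iv: GenomicInterval | None = None
    for iv, key, direction, p in tagged:
        if cur_iv is not None and iv.chrom == cur_iv.chrom and iv.start < cur_iv.end:
            cur_iv = GenomicInterval(cur_iv.chrom, cur_iv.start,
                                     max(cur_iv.end, iv.end))
            cur.append((key, direction, p))
        else:
            if cur_iv is not None:
                regions.append(cur_iv)
                members.append(cur)
            cur_iv, cur = iv, [(key, direction, p)]
    if cur_iv is not None:
        regions.append(cur_iv)
        members.append(cur)

    membership: list[dict[MembershipKey, Membership]] = []
    for entries in members:
        best: dict[MembershipKey, Membership] = {}
        for key, direction, p in entries:
            prev = best.get(key)
            if prev is None or p < prev.p_value:
                best[key] = Membership(True, direction, p)
        membership.append(best)
    return RegionUniverse(regions=regions, membership=membership,
                          covered_keys=frozenset(covered))


def evaluate_rule(rule: ClassRule,
                  pattern: Mapping[MembershipKey, Membership]
                  ) -> tuple[bool, tuple[int, ...]]:
    """Apply one class rule to a membership pattern.

    Returns (qualifies, supporting timepoints in ascending order).  Keys
    absent from the pattern count as not differential.
    """
    for key in rule.baseline:
        m = pattern.get(key)
        if m is not None and m.is_differential:
            return False, ()
    supporting = tuple(sorted(
        tp for (contrast, tp) in rule.support
        if (m := pattern.get((contrast, tp))) is not None and m.is_differential
    ))
    return bool(supporting), supporting


def classify_responsive(universe: RegionUniverse, stress_class: str
                        ) -> ResponsiveSet:
    """Return the regions whose membership pattern satisfies the class rule.

    The region's direction (gain +1 / loss −1 of the mark) is taken at the
    earliest qualifying time point.
    """
    if stress_class not in CLASS_RULES:
        raise ValueError(f"unknown stress class {stress_class!r}; "
                         f"expected one of {STRESS_CLASSES}")
    rule = CLASS_RULES[stress_class]
    missing = [k for k in rule.baseline + rule.support
               if k not in universe.covered_keys]
    if missing:
        raise ValueError(
            f"universe lacks required comparisons for {stress_class}: "
            + ", ".join(f"{a}-vs-{b}@{tp}h" for (a, b), tp in missing))
    contrast_by_tp = {tp: contrast for contrast, tp in rule.support}
    out: list[ResponsiveRegion] = []
    for iv, pattern in zip(universe.regions, universe.membership):
        ok, supporting = evaluate_rule(rule, pattern)
        if not ok:
            continue
        first = supporting[0]
        m = pattern[(contrast_by_tp[first], first)]
        out.append(ResponsiveRegion(interval=iv,
                                    supporting_timepoints=supporting,
                                    direction=m.direction,
                                    p_value=m.p_value))
    return ResponsiveSet(stress_class=stress_class, regions=out)


def write_responsive_bed(rs: ResponsiveSet, path) -> None:
    """BED6+ with supporting time points (comma-separated hours) in column 7."""
    with open(path, "w") as fh:
        for i, r in enumerate(rs.regions):
            iv = r.interval
            fh.write("\t".join(map(str, [
                iv.chrom, iv.start, iv.end, f"{rs.stress_class}_{i}",
                f"{r.p_value:.3e}", "+" if r.direction > 0 else "-",
                ",".join(str(t) for t in r.supporting_timepoints),
            ])) + "\n")
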