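"""End-to-end orchestration: manifest → differential peak sets → responsive sets."""

from __future__ import annotations

from typing import Mapping

from .core_io import FragmentCollection, LibraryLabel, PipelineConfig
from .differential import DifferentialPeakSet, call_differential
from .stress_classifier import (
    REQUIRED_COMPARISONS,
    RegionUniverse,
    ResponsiveSet,
    STRESS_CLASSES,
    build_region_universe,
    classify_responsive,
)

__all__ = ["run_differential_comparisons", "run_stress_classification"]


def run_differential_comparisons(
        frags: Mapping[LibraryLabel, FragmentCollection],
        genome: Mapping[str, int], cfg: PipelineConfig
) -> list[DifferentialPeakSet]:
    """Run every (contrast, timepoint) comparison the class rules consume."""
    peaksets = []
    for (cond_a, cond_b), tp in REQUIRED_COMPARISONS:
        group_a = [fc for lab, fc in frags.items()
                   if lab.role == "chip" and lab.condition == cond_a
                   and lab.timepoint_h == tp]
        group_b = [fc for lab, fc in frags.items()
                   if lab.role == "chip" and lab.condition == cond_b
                   and lab.timepoint_h == tp]
        if not group_a or not group_b:
            raise ValueError(
                f"no libraries for {cond_a}-vs-{cond_b} at {tp} h")
        peaksets.append(call_differential(
            group_a, group_b, genome, cfg,
            contrast=(cond_a, cond_b), timepoint_h=tp))
    return peaksets


def run_stress_classification(
        frags: Mapping[LibraryLabel, FragmentCollection],
        genome: Mapping[str, int], cfg: PipelineConfig
) -> tuple[list[DifferentialPeakSet], RegionUniverse, dict[str, ResponsiveSet]]:
    """Full classification: differential calling, region universe, class rules."""
    peaksets = run_differential_comparisons(frags, genome, cfg)
    universe = build_region_universe(peaksets)
    responsive = {cls: classify_responsive(universe, cls)
                  for cls in STRESS_CLASSES}
    return peaksets, universe, responsive
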