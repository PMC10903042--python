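"""Relative expression from qPCR CT values via the 2^−ΔΔCT method.

ΔCT normalises the target gene's cycle threshold to a constitutive reference
gene (``cons7`` by default) within each sample; ΔΔCT subtracts the
calibrator sample's ΔCT; the fold change is 2^−ΔΔCT.  Replicates are paired
by replicate index and the result is reported as the mean ± standard error of
the per-replicate fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["CtTable", "QpcrResult", "relative_expression"]

DEFAULT_REFERENCE_GENE = "cons7"


@dataclass
class CtTable:
    """Long-format CT measurements: one row per (gene, sample, replicate)."""

    data: pd.DataFrame  # columns: gene, sample, replicate, ct
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CT table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("CT values must be positive")
        for sample in self.data["sample"].unique():
            genes = set(self.data.loc[self.data["sample"] == sample, "gene"])
            if self.reference_gene not in genes:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing for "
                    f"sample {sample!r}")

    @classmethod
    def from_csv(cls, path: str | Path,
                 reference_gene: str = DEFAULT_REFERENCE_GENE) -> "CtTable":
        return cls(pd.read_csv(path), reference_gene=reference_gene)

    def _delta_ct(self, gene: str, sample: str) -> pd.Series:
        """Per-replicate ΔCT = CT_gene − CT_reference for one sample."""
        d = self.data[self.data["sample"] == sample]
        g = d[d["gene"] == gene].set_index("replicate")["ct"]
        r = d[d["gene"] == self.reference_gene].set_index("replicate")["ct"]
        if g.empty:
            raise ValueError(f"gene {gene!r} not measured in sample {sample!r}")
        common = g.index.intersection(r.index)
        if len(common) != len(g) or len(common) != len(r):
            raise ValueError(
                f"cannot pair replicates of {gene!r} and "
                f"{self.reference_gene!r} in sample {sample!r}")
        return (g.loc[common] - r.loc[common]).sort_index()


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    sample: str
    calibrator: str
    fold_changes: tuple[float, ...]  # per replicate pair
    mean: float
    se: float                        # sd/sqrt(n) of per-replicate folds; nan if n == 1


def relative_expression(ct: CtTable, gene: str, sample: str,
                        calibrator: str) -> QpcrResult:
    """Fold change of ``gene`` in ``sample`` relative to ``calibrator``.

    ΔΔCT is computed per replicate pair (sample and calibrator replicates
    paired by index); fold = 2^−ΔΔCT; mean and standard error are taken over
    the per-replicate fold changes.
    """
    d_sample = ct._delta_ct(gene, sample)
    d_cal = ct._delta_ct(gene, calibrator)
    if len(d_sample) != len(d_cal):
        raise ValueError(
            f"replicate counts differ between {sample!r} ({len(d_sample)}) "
            f"and {calibrator!r} ({len(d_cal)}): cannot pair")
    folds = tuple(
        2.0 ** -(float(ds) - float(dc))
        for ds, dc in zip(d_sample.to_numpy(), d_cal.to_numpy())
    )
    n = len(folds)
    mean = sum(folds) / n
    if n > 1:
        var = sum((f - mean) ** 2 for f in folds) / (n - 1)
        se = math.sqrt(var) / math.sqrt(n)
    else:
        se = float("nan")
    return QpcrResult(gene=gene, sample=sample, calibrator=calibrator,
                      fold_changes=folds, mean=mean, se=se)


def expression_table(ct: CtTable, calibrator: str,
                     genes: Optional[list[str]] = None) -> pd.DataFrame:
    """Fold-change table for every (gene, sample) against one calibrator."""
    genes = genes or [g for g in ct.data["gene"].unique()
                      if g != ct.reference_gene]
    rows = []
    for gene in genes:
        for sample in ct.data["sample"].unique():
            r = relative_expression(ct, gene, sample, calibrator)
            rows.append((gene, sample, r.mean, r.se))
    return pd.DataFrame(rows, columns=["gene", "sample", "fold_mean", "fold_se"])
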