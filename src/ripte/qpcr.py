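"""Relative quantification from qPCR Ct tables.

Implements the 2^-ddCt method with multi-reference-gene normalisation
(arithmetic mean of reference Ct values, i.e. geometric mean of reference
quantities), the RIP fold-enrichment statistic

    Fe = (IP_specific - IP_control) / Input,

input-abundance quantification anchored at a chosen gene, and Spearman
concordance between two per-gene enrichment estimates.

Amplification efficiency is fixed at 2 (one cycle per doubling); no
standard-curve correction is applied. Technical replicates are averaged on
the Ct scale before any differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidAnchorError,
    InvalidParameterError,
    MissingReferenceError,
)

__all__ = [
    "CtTable",
    "FeRecord",
    "delta_delta_ct",
    "input_abundance",
    "fold_enrichment",
    "fold_enrichment_table",
    "concordance",
]

#: canonical column order of the tidy Ct layout
CT_COLUMNS = ("gene", "sample", "replicate", "ct")


@dataclass(frozen=True)
class CtTable:
    """Tidy table of Ct values with designated reference genes.

    Parameters
    ----------
    data
        DataFrame with columns ``gene, sample, replicate, ct``; one row per
        well. ``(gene, sample, replicate)`` must be unique.
    ref_genes
        Genes used for normalisation; must be measured in every sample.
    """

    data: pd.DataFrame
    ref_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        missing_cols = set(CT_COLUMNS) - set(self.data.columns)
        if missing_cols:
            raise InvalidParameterError(f"Ct table lacks columns {sorted(missing_cols)}")
        object.__setattr__(self, "ref_genes", tuple(self.ref_genes))
        if self.data.duplicated(subset=["gene", "sample", "replicate"]).any():
            raise InvalidParameterError("duplicate (gene, sample, replicate) rows in Ct table")
        if not np.isfinite(self.data["ct"].to_numpy(dtype=float)).all():
            raise InvalidParameterError("non-finite Ct values")
        for sample, grp in self.data.groupby("sample"):
            absent = set(self.ref_genes) - set(grp["gene"])
            if absent:
                raise MissingReferenceError(
                    f"reference gene(s) {sorted(absent)} absent from sample {sample!r}"
                )

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def mean_ct(self, sample: str) -> pd.Series:
        """Per-gene Ct averaged over replicates within ``sample``."""
        sub = self.data[self.data["sample"] == sample]
        if sub.empty:
            raise InvalidParameterError(f"sample {sample!r} not in Ct table")
        return sub.groupby("gene")["ct"].mean()

    def subset(self, samples: Iterable[str]) -> "CtTable":
        keep = self.data[self.data["sample"].isin(list(samples))].reset_index(drop=True)
        return CtTable(keep, self.ref_genes)

    def to_csv(self, path: str | Path) -> None:
        self.data.loc[:, list(CT_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, ref_genes: Iterable[str] = ()) -> "CtTable":
        return cls(pd.read_csv(path), tuple(ref_genes))


@dataclass(frozen=True)
class FeRecord:
    """Per-gene RIP fold enrichment and the relative amounts behind it."""

    gene: str
    ip_brca1: float
    ip_nr: float
    input_amount: float
    fe: float


def _delta_ct(table: CtTable, sample: str) -> pd.Series:
    """Per-gene dCt = Ct(gene) - mean Ct(reference genes), replicate-averaged."""
    if not table.ref_genes:
        raise MissingReferenceError("Ct table has no designated reference genes")
    mean = table.mean_ct(sample)
    absent = set(table.ref_genes) - set(mean.index)
    if absent:
        raise MissingReferenceError(
            f"reference gene(s) {sorted(absent)} absent from sample {sample!r}"
        )
    ref_mean = mean.loc[list(table.ref_genes)].mean()
    return mean - ref_mean


def delta_delta_ct(
    table: CtTable, target_sample: str, calibrator_sample: str
) -> pd.Series:
    """Relative expression of each gene in ``target_sample`` vs ``calibrator_sample``.

    Returns ``2^-(dCt_target - dCt_calibrator)`` per gene shared by both
    samples, where dCt normalises against the arithmetic mean Ct of the
    table's reference genes within each sample.
    """
    d_target = _delta_ct(table, target_sample)
    d_cal = _delta_ct(table, calibrator_sample)
    shared = d_target.index.intersection(d_cal.index)
    ddct = d_target.loc[shared] - d_cal.loc[shared]
    return np.exp2(-ddct).rename("relative_expression")


def input_abundance(
    table: CtTable, anchor_gene: str = "TRMT10B", sample: str | None = None
) -> pd.Series:
    """Relative per-gene abundance in one sample, rescaled so the anchor is 1.

    Amounts are ``2^-dCt`` against the reference genes; the anchor gene
    (TRMT10B in the source assay) is set to exactly 1.0 by construction.
    """
    if sample is None:
        samples = table.samples
        if len(samples) != 1:
            raise InvalidParameterError(
                "sample must be given explicitly when the table holds several samples"
            )
        sample = samples[0]
    dct = _delta_ct(table, sample)
    if anchor_gene not in dct.index:
        raise InvalidAnchorError(f"anchor gene {anchor_gene!r} absent from sample {sample!r}")
    amounts = np.exp2(-(dct - dct.loc[anchor_gene]))
    return amounts.rename("relative_amount")


def fold_enrichment(ip_brca1: float, ip_nr: float, input_amount: float) -> float:
    """Fe = (IP_specific - IP_control) / Input. May be negative; input must be > 0."""
    if input_amount <= 0:
        raise DomainError(f"input_amount must be > 0, got {input_amount}")
    return (ip_brca1 - ip_nr) / input_amount


def fold_enrichment_table(
    table: CtTable,
    ip_sample: str,
    nr_sample: str,
    input_sample: str,
) -> pd.DataFrame:
    """Per-gene Fe from a Ct table holding the two IPs and the input.

    Relative amounts are ``2^-dCt`` within each sample (reference-gene
    normalised), which puts the three samples on a common scale; Fe is then
    computed gene-wise.
    """
    amounts = {
        role: np.exp2(-_delta_ct(table, sample))
        for role, sample in (
            ("ip_brca1", ip_sample),
            ("ip_nr", nr_sample),
            ("input_amount", input_sample),
        )
    }
    df = pd.DataFrame(amounts).dropna()
    df = df.drop(index=[g for g in table.ref_genes if g in df.index])
    df["fe"] = [
        fold_enrichment(row.ip_brca1, row.ip_nr, row.input_amount)
        for row in df.itertuples()
    ]
    df.index.name = "gene"
    return df


def concordance(
    fc: Mapping[str, float], fe: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rank correlation between two per-gene enrichment estimates.

    Returns ``(rho, p)`` over the genes present in both mappings (two-sided
    test); requires at least 4 shared genes.
    """
    shared = sorted(set(fc) & set(fe))
    if len(shared) < 4:
        raise InsufficientDataError(
            f"need >= 4 shared genes for concordance, got {len(shared)}"
        )
    x = np.array([fc[g] for g in shared], dtype=float)
    y = np.array([fe[g] for g in shared], dtype=float)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
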