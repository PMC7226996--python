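"""Translational efficiency from polysome profiling under knockdown vs control.

For each gene, expression changes between si-BRCA1 (knockdown) and si-Ctrl
are measured separately in total cytoplasmic RNA and in pooled polysomal
RNA (heavy gradient fractions, the actively translated pool):

    totRNA  = expr(kd, total)    / expr(ctrl, total)
    polyRNA = expr(kd, polysome) / expr(ctrl, polysome)
    Te      = polyRNA / totRNA

Te isolates the change in polysome association from any change in total
cytoplasmic abundance. Ratios below 1 are reported in the signed-fold
convention (r -> -1/r) so that symmetric cutoffs (default +-1.4) apply; a
gene is called up (down) only if its signed Te exceeds the cutoff in every
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidParameterError, MissingReferenceError
from .qpcr import CtTable

__all__ = [
    "condition_ratio",
    "translational_efficiency",
    "signed_fold",
    "select_candidates",
    "TranslationalEfficiency",
    "TeResults",
    "POOLS",
    "CONDITIONS",
    "sample_name",
]

POOLS = ("total", "polysome")
CONDITIONS = ("kd", "ctrl")


def sample_name(pool: str, condition: str) -> str:
    """Canonical sample label for one (RNA pool, condition) cell, e.g. ``total:kd``."""
    if pool not in POOLS or condition not in CONDITIONS:
        raise InvalidParameterError(f"unknown pool/condition {(pool, condition)!r}")
    return f"{pool}:{condition}"


def condition_ratio(expr_kd: float, expr_ctrl: float) -> float:
    """Knockdown/control expression ratio within one RNA pool."""
    if expr_kd <= 0 or expr_ctrl <= 0:
        raise DomainError(f"expression values must be > 0, got {(expr_kd, expr_ctrl)}")
    return expr_kd / expr_ctrl


def translational_efficiency(poly_ratio: float, tot_ratio: float) -> float:
    """Te = polyRNA / totRNA (both si-BRCA1/si-Ctrl ratios); raw, unsigned."""
    if poly_ratio <= 0 or tot_ratio <= 0:
        raise DomainError(f"ratios must be > 0, got {(poly_ratio, tot_ratio)}")
    return poly_ratio / tot_ratio


def signed_fold(te_raw: float) -> float:
    """Signed-fold encoding of a positive ratio: r if r >= 1 else -1/r."""
    if te_raw <= 0:
        raise DomainError(f"te_raw must be > 0, got {te_raw}")
    return te_raw if te_raw >= 1 else -1.0 / te_raw


def select_candidates(
    records: pd.DataFrame, cutoff: float = 1.4, require_all: bool = True
) -> pd.DataFrame:
    """Direction calls from per-replicate signed Te values.

    ``records`` needs columns ``gene, replicate, te_signed``. A gene is
    called ``up`` iff te_signed > cutoff in all replicates, ``down`` iff
    te_signed < -cutoff in all replicates, else ``unchanged`` (strict
    inequalities). With ``require_all=False`` a strict-majority rule is
    applied instead.
    """
    if cutoff <= 1:
        raise InvalidParameterError(f"cutoff must exceed 1, got {cutoff}")
    counts = records.groupby("gene")["replicate"].count()
    if counts.nunique() > 1:
        raise InvalidParameterError(
            f"inconsistent replicate counts per gene: {sorted(counts.unique())}"
        )
    rows = []
    for gene, grp in records.groupby("gene"):
        te = grp.sort_values("replicate")["te_signed"].to_numpy()
        n_up, n_down = int((te > cutoff).sum()), int((te < -cutoff).sum())
        need = len(te) if require_all else len(te) // 2 + 1
        if n_up >= need:
            direction = "up"
        elif n_down >= need:
            direction = "down"
        else:
            direction = "unchanged"
        rows.append({"gene": gene, "direction": direction, "te_signed": tuple(te)})
    return pd.DataFrame(rows).set_index("gene")


def _pool_ratio(table: CtTable, pool: str, replicate: int, use_refs: bool) -> pd.Series:
    """Per-gene kd/ctrl expression ratio within one pool for one replicate."""
    sub = table.data[table.data["replicate"] == replicate]
    kd = sub[sub["sample"] == sample_name(pool, "kd")].set_index("gene")["ct"]
    ctrl = sub[sub["sample"] == sample_name(pool, "ctrl")].set_index("gene")["ct"]
    shared = kd.index.intersection(ctrl.index)
    kd, ctrl = kd.loc[shared], ctrl.loc[shared]
    if use_refs:
        refs = list(table.ref_genes)
        absent = set(refs) - set(shared)
        if absent:
            raise MissingReferenceError(
                f"reference gene(s) {sorted(absent)} absent from pool {pool!r} "
                f"replicate {replicate}"
            )
        kd = kd - kd.loc[refs].mean()
        ctrl = ctrl - ctrl.loc[refs].mean()
    return np.exp2(-(kd - ctrl))


class TranslationalEfficiency:
    """Per-gene translational-efficiency model over replicated measurements.

    Built either from per-replicate expression ratios (``records`` with
    columns ``gene, replicate, tot_ratio, poly_ratio``) or from a tidy Ct
    table via :meth:`from_ct_table`. :meth:`fit` applies the signed-fold
    cutoff rule and returns a :class:`TeResults`.
    """

    def __init__(self, records: pd.DataFrame, *, metadata: Mapping | None = None):
        needed = {"gene", "replicate", "tot_ratio", "poly_ratio"}
        if not needed <= set(records.columns):
            raise InvalidParameterError(f"records need columns {sorted(needed)}")
        rec = records.copy()
        if (rec["tot_ratio"] <= 0).any() or (rec["poly_ratio"] <= 0).any():
            raise DomainError("condition ratios must be > 0")
        rec["te_raw"] = rec["poly_ratio"] / rec["tot_ratio"]
        rec["te_signed"] = [signed_fold(x) for x in rec["te_raw"]]
        self.records = rec
        self.metadata = dict(metadata or {})

    @classmethod
    def from_ct_table(
        cls, table: CtTable, *, normalize: str = "refs"
    ) -> "TranslationalEfficiency":
        """Build from Ct values of the four (pool, condition) sample classes.

        Samples must be named ``total:kd``, ``total:ctrl``, ``polysome:kd``,
        ``polysome:ctrl``. ``normalize='refs'`` normalises each pool against
        the table's reference genes before the kd/ctrl ratio (references
        chosen per pool are the same set); ``normalize='equal-input'`` takes
        raw Ct differences, assuming equal RNA input per reaction.
        """
        if normalize not in ("refs", "equal-input"):
            raise InvalidParameterError(f"unknown normalize mode {normalize!r}")
        use_refs = normalize == "refs"
        if use_refs and not table.ref_genes:
            raise MissingReferenceError(
                "normalize='refs' requires designated reference genes"
            )
        rows = []
        replicates = sorted(table.data["replicate"].unique())
        for rep in replicates:
            tot = _pool_ratio(table, "total", rep, use_refs)
            poly = _pool_ratio(table, "polysome", rep, use_refs)
            for gene in tot.index.intersection(poly.index):
                if gene in table.ref_genes:
                    continue
                rows.append(
                    {
                        "gene": gene,
                        "replicate": rep,
                        "tot_ratio": float(tot.loc[gene]),
                        "poly_ratio": float(poly.loc[gene]),
                    }
                )
        return cls(
            pd.DataFrame(rows),
            metadata={"normalize": normalize, "ref_genes": list(table.ref_genes)},
        )

    def fit(self, cutoff: float = 1.4, require_all: bool = True) -> "TeResults":
        calls = select_candidates(self.records, cutoff=cutoff, require_all=require_all)
        return TeResults(
            records=self.records.copy(),
            calls=calls,
            cutoff=cutoff,
            require_all=require_all,
            metadata=dict(self.metadata),
        )


@dataclass
class TeResults:
    """Fitted translational-efficiency calls with their per-replicate evidence."""

    records: pd.DataFrame
    calls: pd.DataFrame
    cutoff: float
    require_all: bool
    metadata: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = self.calls["direction"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("up", "down", "unchanged")}

    def summary(self) -> str:
        counts = self.counts
        lines = [
            "Translational efficiency (Te = polyRNA/totRNA, signed-fold convention)",
            f"cutoff: +-{self.cutoff}  rule: "
            + ("all replicates" if self.require_all else "majority of replicates"),
            f"genes: {len(self.calls)}  up: {counts['up']}  "
            f"down: {counts['down']}  unchanged: {counts['unchanged']}",
            "",
            f"{'gene':<12} {'direction':<10} per-replicate signed Te",
        ]
        for gene, row in self.calls.iterrows():
            te = ", ".join(f"{v:+.2f}" for v in row["te_signed"])
            lines.append(f"{gene:<12} {row['direction']:<10} {te}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Dot plot of per-replicate signed Te per gene with cutoff lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.5 * len(self.calls)), 4))
        for i, (gene, row) in enumerate(self.calls.iterrows()):
            te = row["te_signed"]
            ax.scatter([i] * len(te), te, s=18, color="k", zorder=3)
        for y in (self.cutoff, -self.cutoff):
            ax.axhline(y, ls="--", lw=1, color="tab:red")
        ax.axhline(0, lw=0.5, color="gray")
        ax.set_xticks(range(len(self.calls)))
        ax.set_xticklabels(self.calls.index, rotation=90)
        ax.set_ylabel("signed Te")
        return ax
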