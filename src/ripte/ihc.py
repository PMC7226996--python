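"""Immunohistochemistry staining scores and cohort comparison.

Each tumor core is graded by a pathologist for staining intensity (0-3) and
percent of positively stained cells; the percent is mapped to a proportion
grade (0-3) and the staining score is their product (0-9). Tumors with
replicate TMA cores are reduced to one record (maximum score across cores
by default). Scores are dichotomised into low/high and two cohorts are
compared with a Pearson chi-square test (df=1, no continuity correction) on
the resulting 2x2 table.

The published proportion bins (<=10% -> 0; 20-40 -> 1; 50-80 -> 2; >80 -> 3)
leave the intervals (10, 20) and (40, 50) unassigned; they are closed here
by extending the lower grade upward, i.e. boundaries at 10, 50, 80, which
keeps the printed 50-80 bin intact. The low/high threshold is unpublished;
the default calls a score >= 4 high and a sensitivity sweep over thresholds
is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, DomainError, InvalidParameterError

__all__ = [
    "proportion_grade",
    "score",
    "score_records",
    "dichotomize",
    "cohort_chisq",
    "CohortComparison",
    "IhcCohorts",
    "threshold_sensitivity",
]


def proportion_grade(percent_positive: float) -> int:
    """Grade of the percent of positive cells: <=10 -> 0, <50 -> 1, <=80 -> 2, >80 -> 3."""
    if not 0 <= percent_positive <= 100:
        raise DomainError(f"percent_positive must be in [0, 100], got {percent_positive}")
    if percent_positive <= 10:
        return 0
    if percent_positive < 50:
        return 1
    if percent_positive <= 80:
        return 2
    return 3


def score(intensity: int, prop_grade: int) -> int:
    """Staining score = intensity x proportion grade, both on 0-3, product 0-9."""
    if not (0 <= intensity <= 3 and 0 <= prop_grade <= 3):
        raise DomainError(
            f"intensity and proportion grade must be in 0..3, got {(intensity, prop_grade)}"
        )
    return int(intensity) * int(prop_grade)


def score_records(records: pd.DataFrame, collapse: str = "max") -> pd.DataFrame:
    """Score each core and reduce replicate cores to one record per tumor.

    ``records`` needs columns ``sample_id, cohort, marker, intensity,
    percent_positive`` (``core_id`` optional). ``collapse`` is ``'max'``
    (default) or ``'median'`` over a tumor's cores; the median is rounded
    half-up to stay on the integer score scale.
    """
    if collapse not in ("max", "median"):
        raise InvalidParameterError(f"collapse must be 'max' or 'median', got {collapse!r}")
    df = records.copy()
    df["proportion_grade"] = [proportion_grade(p) for p in df["percent_positive"]]
    df["score"] = [score(i, g) for i, g in zip(df["intensity"], df["proportion_grade"])]
    grouped = df.groupby(["sample_id", "cohort", "marker"], as_index=False)["score"]
    if collapse == "max":
        out = grouped.max()
    else:
        out = grouped.median()
        out["score"] = np.floor(out["score"] + 0.5).astype(int)
    return out


def dichotomize(records: pd.DataFrame, threshold: int = 4) -> pd.DataFrame:
    """Set ``klass`` to ``'high'`` where score >= threshold, else ``'low'``."""
    out = records.copy()
    out["klass"] = np.where(out["score"] >= threshold, "high", "low")
    return out


@dataclass(frozen=True)
class CohortComparison:
    """2x2 low/high contingency table between two cohorts with its chi-square test."""

    cohorts: tuple[str, str]
    contingency: np.ndarray  # rows: cohorts, columns: (low, high)
    chi2: float
    df: int
    p: float

    def summary(self) -> str:
        (a, b), t = self.cohorts, self.contingency
        return (
            f"{a}: low {t[0, 0]}, high {t[0, 1]}  |  {b}: low {t[1, 0]}, high {t[1, 1]}\n"
            f"chi-square = {self.chi2:.4f} (df={self.df}), p = {self.p:.4g}"
        )


def _contingency(records_a: pd.DataFrame, records_b: pd.DataFrame) -> np.ndarray:
    table = np.zeros((2, 2), dtype=int)
    for i, rec in enumerate((records_a, records_b)):
        counts = rec["klass"].value_counts()
        table[i, 0] = int(counts.get("low", 0))
        table[i, 1] = int(counts.get("high", 0))
    return table


def cohort_chisq(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    cohorts: tuple[str, str] = ("A", "B"),
    correction: bool = False,
) -> CohortComparison:
    """Pearson chi-square comparison of the low/high split between two cohorts.

    No continuity correction by default. Both cohorts must be non-empty and
    both classes must appear somewhere in the pooled table.
    """
    if records_a.empty or records_b.empty:
        raise DegenerateTableError("both cohorts must be non-empty")
    table = _contingency(records_a, records_b)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"contingency table has an all-zero margin:\n{table}")
    res = stats.chi2_contingency(table, correction=correction)
    return CohortComparison(
        cohorts=cohorts,
        contingency=table,
        chi2=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
    )


class IhcCohorts:
    """Cohort-comparison model over a table of graded IHC cores.

    ``fit`` scores and collapses cores, dichotomises, and runs the
    chi-square comparison for every requested cohort pair and marker.
    """

    def __init__(self, records: pd.DataFrame, collapse: str = "max"):
        needed = {"sample_id", "cohort", "marker", "intensity", "percent_positive"}
        if not needed <= set(records.columns):
            raise InvalidParameterError(f"records need columns {sorted(needed)}")
        self.records = records
        self.collapse = collapse

    def fit(
        self,
        threshold: int = 4,
        pairs: Sequence[tuple[str, str]] | None = None,
        correction: bool = False,
    ) -> "IhcResults":
        scored = dichotomize(score_records(self.records, self.collapse), threshold)
        cohorts = sorted(scored["cohort"].unique())
        if pairs is None:
            pairs = [(cohorts[0], c) for c in cohorts[1:]]
        comparisons = {}
        for marker in sorted(scored["marker"].unique()):
            sub = scored[scored["marker"] == marker]
            for a, b in pairs:
                rec_a = sub[sub["cohort"] == a]
                rec_b = sub[sub["cohort"] == b]
                if rec_a.empty or rec_b.empty:
                    continue
                comparisons[(marker, a, b)] = cohort_chisq(
                    rec_a, rec_b, cohorts=(a, b), correction=correction
                )
        return IhcResults(scored=scored, comparisons=comparisons, threshold=threshold)


@dataclass
class IhcResults:
    """Scored, dichotomised records and per-marker cohort comparisons."""

    scored: pd.DataFrame
    comparisons: dict[tuple[str, str, str], CohortComparison]
    threshold: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"IHC scores (intensity x proportion grade), high <=> score >= {self.threshold}",
            f"tumors: {len(self.scored)}",
        ]
        for (marker, a, b), cmp in self.comparisons.items():
            lines.append(f"\n{marker}: {a} vs {b}")
            lines.append(cmp.summary())
        return "\n".join(lines)

    def plot(self, marker: str, ax=None):
        """Stacked low/high fraction bars per cohort for one marker."""
        import matplotlib.pyplot as plt

        sub = self.scored[self.scored["marker"] == marker]
        frac = (
            sub.groupby("cohort")["klass"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=["low", "high"], fill_value=0.0)
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        x = np.arange(len(frac))
        ax.bar(x, frac["low"] * 100, color="white", edgecolor="k", label="low")
        ax.bar(x, frac["high"] * 100, bottom=frac["low"] * 100, color="k", label="high")
        ax.set_xticks(x)
        ax.set_xticklabels(frac.index)
        ax.set_ylabel("% of tumors")
        ax.set_title(marker)
        ax.legend()
        return ax


def threshold_sensitivity(
    records: pd.DataFrame,
    cohort_a: str,
    cohort_b: str,
    marker: str,
    thresholds: Iterable[int] = range(2, 7),
    collapse: str = "max",
) -> pd.DataFrame:
    """Chi-square p for one cohort pair across candidate low/high thresholds."""
    scored = score_records(records[records["marker"] == marker], collapse)
    rows = []
    for thr in thresholds:
        cut = dichotomize(scored, thr)
        try:
            cmp = cohort_chisq(
                cut[cut["cohort"] == cohort_a],
                cut[cut["cohort"] == cohort_b],
                cohorts=(cohort_a, cohort_b),
            )
            rows.append({"threshold": thr, "chi2": cmp.chi2, "p": cmp.p})
        except DegenerateTableError:
            rows.append({"threshold": thr, "chi2": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("threshold")
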