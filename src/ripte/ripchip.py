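"""RIP-chip enrichment: identify transcripts bound by an immunoprecipitated protein.

Input is a replicated, RMA-normalised (log2-scale) probe-intensity matrix
with paired columns for the specific antibody (BRCA1) and the non-relevant
control antibody (NR). Per replicate the control is subtracted on the log2
scale — equivalently, the IP/control ratio Fc is formed — replicates are
averaged, a one-sample location test of the per-replicate differences
against 0 yields a p-value, and transcripts with Fc > 1.5 and p < 0.05
(both strict) are retained. Retained transcripts are binned by Fc into the
volcano-plot colour classes gray [1.5, 2), orange [2, 3), blue [3, inf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, MissingDataError

__all__ = [
    "subtract_control",
    "summarize_enrichment",
    "filter_enriched",
    "classify_fc_bin",
    "read_probe_matrix",
    "RipEnrichment",
    "RipEnrichmentResults",
    "FC_BINS",
]

#: Fc bin edges as printed on the volcano plot; the top edge is the observed
#: maximum, not a cap, so fc beyond it still falls in the top bin.
FC_BINS = (("gray", 1.5, 2.0), ("orange", 2.0, 3.0), ("blue", 3.0, np.inf))


def read_probe_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV probe matrix (first column transcript_id, columns <antibody>_rep<k>)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def _replicate_columns(
    matrix: pd.DataFrame, ip: str, control: str
) -> list[tuple[int, str, str]]:
    """Pair <ip>_rep<k> with <control>_rep<k>; error on an unpaired replicate."""
    reps: dict[int, dict[str, str]] = {}
    for col in matrix.columns:
        name, _, rep = col.rpartition("_rep")
        if not rep.isdigit() or name not in (ip, control):
            continue
        reps.setdefault(int(rep), {})[name] = col
    if not reps:
        raise InvalidParameterError(
            f"no '<antibody>_rep<k>' columns for antibodies {ip!r}/{control!r}"
        )
    pairs = []
    for r in sorted(reps):
        if set(reps[r]) != {ip, control}:
            missing = ({ip, control} - set(reps[r])).pop()
            raise MissingDataError(f"replicate {r}: missing {missing!r} column")
        pairs.append((r, reps[r][ip], reps[r][control]))
    if len(pairs) < 2:
        raise InvalidParameterError(f"need >= 2 replicates, got {len(pairs)}")
    return pairs


def subtract_control(
    matrix: pd.DataFrame, ip: str = "BRCA1", control: str = "NR"
) -> pd.DataFrame:
    """Per-replicate log2 differences d_r = log2 IP - log2 control.

    Returns a DataFrame (transcripts x replicates, columns ``rep<k>`` in
    replicate order). A missing value raises, naming transcript and
    replicate.
    """
    pairs = _replicate_columns(matrix, ip, control)
    diffs = {}
    for r, ip_col, nr_col in pairs:
        d = matrix[ip_col] - matrix[nr_col]
        if d.isna().any():
            t = d.index[d.isna()][0]
            raise MissingDataError(f"transcript {t!r}: missing value in replicate {r}")
        diffs[f"rep{r}"] = d
    out = pd.DataFrame(diffs)
    out.index.name = "transcript_id"
    return out


def _one_sample_p(diffs: np.ndarray, test: str) -> tuple[float, bool]:
    """Two-sided p for location 0; returns (p, degenerate_flag)."""
    n = len(diffs)
    if np.ptp(diffs) == 0.0:
        mean = diffs[0]
        if mean == 0.0:
            return 1.0, True
        # zero variance: t statistic infinite for n >= 3; undefined for n < 3
        return (0.0, True) if n >= 3 else (1.0, True)
    if test == "t":
        return float(stats.ttest_1samp(diffs, 0.0).pvalue), False
    if test == "wilcoxon":
        return float(stats.wilcoxon(diffs, alternative="two-sided").pvalue), False
    raise InvalidParameterError(f"unknown test {test!r} (choose 't' or 'wilcoxon')")


def summarize_enrichment(diffs: pd.DataFrame, test: str = "t") -> pd.DataFrame:
    """Average replicate log2 differences and test each transcript against 0.

    Returns a DataFrame indexed by transcript with columns ``mean_log2fc``,
    ``fc`` (2^mean, the geometric-mean IP/control ratio), ``p_value``,
    ``degenerate`` (True where the variance was zero and the p-value is a
    convention rather than a test), and ``fc_bin``.
    """
    if diffs.shape[1] < 2:
        raise InvalidParameterError("need >= 2 replicates to summarise")
    arr = diffs.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    pvals = np.empty(len(arr))
    degen = np.zeros(len(arr), dtype=bool)
    # vectorised t over non-degenerate rows; row-wise fallback otherwise
    spread = np.ptp(arr, axis=1)
    ok = spread > 0
    if test == "t" and ok.any():
        res = stats.ttest_1samp(arr[ok], 0.0, axis=1)
        pvals[ok] = res.pvalue
    else:
        for i in np.flatnonzero(ok):
            pvals[i], _ = _one_sample_p(arr[i], test)
    for i in np.flatnonzero(~ok):
        pvals[i], degen[i] = _one_sample_p(arr[i], test)
    out = pd.DataFrame(
        {
            "mean_log2fc": mean,
            "fc": np.exp2(mean),
            "p_value": pvals,
            "degenerate": degen,
        },
        index=diffs.index,
    )
    out["fc_bin"] = [classify_fc_bin(v) for v in out["fc"]]
    return out


def filter_enriched(
    records: pd.DataFrame, fc_min: float = 1.5, p_max: float = 0.05
) -> pd.DataFrame:
    """Retain transcripts with fc > fc_min and p < p_max (both strict).

    Sets/overwrites the ``retained`` column on ``records`` in place and
    returns the retained subset sorted by descending fc (ties broken by
    transcript id).
    """
    records["retained"] = (records["fc"] > fc_min) & (records["p_value"] < p_max)
    subset = records[records["retained"]]
    # descending fc, exact ties broken by transcript id for deterministic output
    order = sorted(subset.index, key=lambda t: (-subset.at[t, "fc"], str(t)))
    return subset.loc[order].copy()


def classify_fc_bin(fc: float) -> str:
    """Volcano colour bin: none below 1.5, else gray/orange/blue by Fc interval."""
    for name, lo, hi in FC_BINS:
        if lo <= fc < hi:
            return name
    return "none"


class RipEnrichment:
    """Enrichment model over a replicated RIP-chip probe matrix.

    Parameters
    ----------
    matrix
        log2 intensities, transcripts x ``<antibody>_rep<k>`` columns.
    ip, control
        Antibody labels of the specific and non-relevant IP columns.
    test
        One-sample location test for the replicate differences: ``'t'``
        (default, two-sided one-sample t) or ``'wilcoxon'`` (signed-rank,
        for the sensitivity check on the unstated-test assumption).
    collapse_probe_sets
        If True and the index has duplicates (several probe sets per
        transcript), log2 values are averaged per antibody column first.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        ip: str = "BRCA1",
        control: str = "NR",
        test: str = "t",
        collapse_probe_sets: bool = True,
    ):
        if collapse_probe_sets and matrix.index.has_duplicates:
            matrix = matrix.groupby(level=0).mean()
        self.matrix = matrix
        self.ip = ip
        self.control = control
        self.test = test

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "RipEnrichment":
        return cls(read_probe_matrix(path), **kwargs)

    def fit(self, fc_min: float = 1.5, p_max: float = 0.05) -> "RipEnrichmentResults":
        diffs = subtract_control(self.matrix, self.ip, self.control)
        records = summarize_enrichment(diffs, test=self.test)
        retained = filter_enriched(records, fc_min=fc_min, p_max=p_max)
        return RipEnrichmentResults(
            records=records,
            retained=retained,
            diffs=diffs,
            params={
                "fc_min": fc_min,
                "p_max": p_max,
                "test": self.test,
                "ip": self.ip,
                "control": self.control,
                "n_replicates": diffs.shape[1],
            },
        )


@dataclass
class RipEnrichmentResults:
    """Fitted enrichment records, the retained subset, and run metadata."""

    records: pd.DataFrame
    retained: pd.DataFrame
    diffs: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        """Row count of the input matrix (transcripts measured on chip)."""
        return len(self.records)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def bin_counts(self) -> dict[str, int]:
        c = self.retained["fc_bin"].value_counts().to_dict()
        return {name: int(c.get(name, 0)) for name, _, _ in FC_BINS}

    def run_summary(self) -> dict:
        """JSON-ready run metadata: thresholds, test choice, per-bin counts."""
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "bin_counts": self.bin_counts,
            **self.params,
        }

    def summary(self) -> str:
        p = self.params
        bins = self.bin_counts
        lines = [
            "RIP-chip enrichment (log2 control subtraction, replicate average)",
            f"transcripts on chip: {self.n_input}   replicates: {p.get('n_replicates')}",
            f"filter: Fc > {p.get('fc_min')} and p < {p.get('p_max')} "
            f"(one-sample {p.get('test')} test)",
            f"retained: {self.n_retained} "
            f"({100.0 * self.n_retained / max(self.n_input, 1):.1f}%)",
            f"Fc bins among retained: gray {bins['gray']}, orange {bins['orange']}, "
            f"blue {bins['blue']}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """-log10 p against mean log2 Fc, coloured by Fc bin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        rec = self.records
        colors = rec["fc_bin"].map(
            {"none": "lightgray", "gray": "dimgray", "orange": "orange", "blue": "tab:blue"}
        )
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(rec["p_value"].clip(lower=1e-300))
        ax.scatter(rec["mean_log2fc"], neglogp, s=8, c=colors)
        ax.axhline(-np.log10(self.params.get("p_max", 0.05)), ls="--", lw=1, color="k")
        for x in (np.log2(self.params.get("fc_min", 1.5)), -np.log2(self.params.get("fc_min", 1.5))):
            ax.axvline(x, ls="--", lw=1, color="k")
        ax.set_xlabel("mean log2 Fc (IP / control)")
        ax.set_ylabel("-log10 p")
        return ax

    def to_tsv(self, prefix: str | Path) -> None:
        """Write ``<prefix>.records.tsv``, ``<prefix>.retained.tsv``, ``<prefix>.json``."""
        import json

        prefix = str(prefix)
        self.records.to_csv(prefix + ".records.tsv", sep="\t")
        self.retained.to_csv(prefix + ".retained.tsv", sep="\t")
        Path(prefix + ".json").write_text(json.dumps(self.run_summary(), indent=2))


def recovery_metrics(
    retained_ids: set[str] | frozenset[str] | Mapping,
    truth_ids: set[str] | frozenset[str],
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of a retained set vs planted truth."""
    retained = set(retained_ids)
    truth = set(truth_ids)
    tp = len(retained & truth)
    sens = tp / len(truth) if truth else float("nan")
    fdp = (len(retained) - tp) / len(retained) if retained else 0.0
    return {"sensitivity": sens, "false_discovery_proportion": fdp}
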