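"""Synthetic-data generators with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a single integer
seed (no hidden global state): the same call yields byte-identical output.
The planted truth is returned alongside the data as a :class:`SimTruth` so
downstream estimators can be scored against it.

What is emulated, per stage:

* RIP-chip: RMA-style log2 probe intensities for paired BRCA1/NR
  immunoprecipitations over replicates, Gaussian noise on the log2 scale,
  a planted enriched subset with a fixed IP-minus-control log2 fold change.
* qPCR: Ct values with efficiency-2 amplification (one cycle per two-fold
  abundance), per-gene baselines, reference genes at constant expression.
* Polysome profiling: Ct values for the four (total/polysome x kd/ctrl)
  sample classes such that the expected polyRNA/totRNA ratio equals the
  planted Te per gene; pooled heavy fractions are represented by the single
  polysome pool (the fraction range is provenance metadata, not signal).
* tRNA amplicon reads: full-length ungapped copies of each reference, the
  wobble A read as G with the planted editing probability (inosine is read
  as G), uniform substitution errors elsewhere at the given rate.
* IHC cohorts: per-tumor (intensity, percent-positive) pairs drawn from a
  cohort-specific categorical distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .editing import TrnaReference
from .errors import InvalidParameterError, InvalidReferenceError
from .polysome import CONDITIONS, POOLS, sample_name
from .qpcr import CtTable

__all__ = [
    "SimTruth",
    "simulate_rip_chip",
    "simulate_qpcr",
    "simulate_polysome",
    "simulate_trna_reads",
    "simulate_ihc_cohort",
    "write_probe_matrix",
    "write_fastq",
    "write_fasta",
]

DEFAULT_REF_GENES = ("POP4", "ACTB")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth of one generator call.

    Only the fields relevant to the generating stage are populated; the
    others stay empty. ``seed`` fully determines the paired dataset.
    """

    seed: int
    enriched_ids: frozenset[str] = frozenset()
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    planted_te: dict[str, float] = field(default_factory=dict)
    planted_editing: dict[str, float] = field(default_factory=dict)
    planted_ihc_shift: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "seed": self.seed,
            "enriched_ids": sorted(self.enriched_ids),
            "planted_log2fc": self.planted_log2fc,
            "planted_te": self.planted_te,
            "planted_editing": self.planted_editing,
            "planted_ihc_shift": self.planted_ihc_shift,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {value}")


def simulate_rip_chip(
    n_transcripts: int,
    n_enriched: int,
    log2fc: float = 1.0,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicated log2 probe-intensity matrix with a planted enriched subset.

    Returns a DataFrame indexed by transcript_id with columns
    ``BRCA1_rep<k>`` and ``NR_rep<k>``; enriched transcripts have expected
    per-replicate IP-minus-NR log2 difference ``log2fc``, all others 0.
    ``noise_sd`` parameterises the dispersion of that per-replicate
    difference: each intensity column receives independent Gaussian noise
    with sd ``noise_sd / sqrt(2)``, so d_r = IP - NR has sd exactly
    ``noise_sd``.
    """
    _check_positive(n_transcripts=n_transcripts, n_replicates=n_replicates)
    if n_enriched < 0 or n_enriched > n_transcripts:
        raise InvalidParameterError(
            f"n_enriched must lie in [0, n_transcripts], got {n_enriched}"
        )
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_replicates < 2:
        raise InvalidParameterError(f"need n_replicates >= 2, got {n_replicates}")
    rng = np.random.default_rng(seed)
    ids = np.array([f"T{i:05d}" for i in range(1, n_transcripts + 1)])
    baseline = rng.normal(8.0, 1.5, size=n_transcripts)  # log2 abundance on chip
    enriched_idx = rng.choice(n_transcripts, size=n_enriched, replace=False)
    effect = np.zeros(n_transcripts)
    effect[enriched_idx] = log2fc
    col_sd = noise_sd / np.sqrt(2.0)  # so the per-replicate difference has sd noise_sd
    cols: dict[str, np.ndarray] = {}
    for r in range(1, n_replicates + 1):
        cols[f"BRCA1_rep{r}"] = baseline + effect + rng.normal(0, col_sd, n_transcripts)
        cols[f"NR_rep{r}"] = baseline + rng.normal(0, col_sd, n_transcripts)
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="transcript_id"))
    truth = SimTruth(
        seed=seed,
        enriched_ids=frozenset(ids[enriched_idx]),
        planted_log2fc={t: (log2fc if i in set(enriched_idx) else 0.0) for i, t in enumerate(ids)},
    )
    return matrix, truth


def _ct_rows(
    rng: np.random.Generator,
    baselines: Mapping[str, float],
    expression: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float,
    n_replicates: int,
) -> pd.DataFrame:
    """Ct = baseline(gene) - log2(expression) + N(0, sd); efficiency 2."""
    rows = []
    for gene, per_sample in expression.items():
        for sample, expr in per_sample.items():
            if expr <= 0:
                raise InvalidParameterError(
                    f"expression must be > 0, got {expr} for {gene!r}/{sample!r}"
                )
            mu = baselines[gene] - np.log2(expr)
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                rows.append({"gene": gene, "sample": sample, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def simulate_qpcr(
    genes: Sequence[str],
    ref_genes: Sequence[str],
    expression: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[CtTable, SimTruth]:
    """Ct table for target genes with planted expression and constant references.

    ``expression`` maps each target gene to ``{sample: relative expression}``
    (values > 0). Reference genes are generated at constant expression 1 in
    every sample appearing in ``expression``. One cycle corresponds to a
    two-fold abundance change (efficiency 2).
    """
    if ct_noise_sd < 0:
        raise InvalidParameterError(f"ct_noise_sd must be >= 0, got {ct_noise_sd}")
    _check_positive(n_replicates=n_replicates)
    overlap = set(genes) & set(ref_genes)
    if overlap:
        raise InvalidParameterError(f"ref_genes overlap target genes: {sorted(overlap)}")
    missing = set(genes) - set(expression)
    if missing:
        raise InvalidParameterError(f"no expression given for genes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    samples = sorted({s for per in expression.values() for s in per})
    all_genes = list(genes) + list(ref_genes)
    baselines = {g: rng.uniform(20.0, 28.0) for g in all_genes}
    full_expr: dict[str, dict[str, float]] = {g: dict(expression[g]) for g in genes}
    for ref in ref_genes:
        full_expr[ref] = {s: 1.0 for s in samples}
    data = _ct_rows(rng, baselines, full_expr, ct_noise_sd, n_replicates)
    table = CtTable(data, tuple(ref_genes))
    return table, SimTruth(seed=seed)


def simulate_polysome(
    genes: Sequence[str],
    planted_te: Mapping[str, float],
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    planted_tot: Mapping[str, float] | None = None,
    ref_genes: Sequence[str] = DEFAULT_REF_GENES,
) -> tuple[CtTable, SimTruth]:
    """Ct table over the four (pool, condition) sample classes with planted Te.

    Expression is 1 for controls; the knockdown total pool carries
    ``planted_tot`` (default 1, i.e. no transcriptional change) and the
    knockdown polysome pool ``planted_te * planted_tot``, so the expected
    polyRNA/totRNA ratio equals ``planted_te`` per gene. Each replicate is
    an independent noisy measurement of all four classes.
    """
    if ct_noise_sd < 0:
        raise InvalidParameterError(f"ct_noise_sd must be >= 0, got {ct_noise_sd}")
    _check_positive(n_replicates=n_replicates)
    missing = set(genes) - set(planted_te)
    if missing:
        raise InvalidParameterError(f"no planted Te for genes {sorted(missing)}")
    for g in genes:
        if planted_te[g] <= 0:
            raise InvalidParameterError(f"planted Te must be > 0, got {planted_te[g]} for {g!r}")
    tot = {g: (planted_tot or {}).get(g, 1.0) for g in genes}
    if any(v <= 0 for v in tot.values()):
        raise InvalidParameterError("planted_tot values must be > 0")
    rng = np.random.default_rng(seed)
    all_genes = list(genes) + list(ref_genes)
    baselines = {g: rng.uniform(20.0, 28.0) for g in all_genes}
    expr: dict[str, dict[str, float]] = {}
    for g in genes:
        expr[g] = {
            sample_name("total", "ctrl"): 1.0,
            sample_name("total", "kd"): tot[g],
            sample_name("polysome", "ctrl"): 1.0,
            sample_name("polysome", "kd"): planted_te[g] * tot[g],
        }
    for ref in ref_genes:
        expr[ref] = {sample_name(p, c): 1.0 for p in POOLS for c in CONDITIONS}
    data = _ct_rows(rng, baselines, expr, ct_noise_sd, n_replicates)
    table = CtTable(data, tuple(ref_genes))
    truth = SimTruth(seed=seed, planted_te={g: float(planted_te[g]) for g in genes})
    return table, truth


def simulate_trna_reads(
    refs: Sequence[TrnaReference],
    editing_fraction: Mapping[str, float],
    n_reads: int = 1000,
    error_rate: float = 0.001,
    seed: int = 0,
    base_quality: int = 40,
) -> tuple[list, SimTruth]:
    """Full-length amplicon reads per reference with planted wobble editing.

    Each read copies its reference; the wobble base is G with the planted
    probability (inosine is reverse-transcribed as G), A otherwise; every
    position is then independently substituted to a uniformly chosen
    different base with probability ``error_rate``. Read ids encode the
    source reference as ``<ref name>|<index>``. Returns Biopython
    SeqRecords with constant Phred quality.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    _check_positive(n_reads=n_reads)
    if not 0 <= error_rate < 1:
        raise InvalidParameterError(f"error_rate must be in [0, 1), got {error_rate}")
    for ref in refs:
        if ref.name not in editing_fraction:
            raise InvalidParameterError(f"no editing fraction for reference {ref.name!r}")
        f = editing_fraction[ref.name]
        if not 0 <= f <= 1:
            raise InvalidParameterError(f"editing fraction must be in [0, 1], got {f}")
        if ref.sequence[ref.wobble_offset - 1] != "A":
            raise InvalidReferenceError(f"{ref.name}: no A at wobble offset")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for ref in refs:
        f = editing_fraction[ref.name]
        template = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        length = len(template)
        reads = np.tile(template, (n_reads, 1))
        edited = rng.random(n_reads) < f
        reads[edited, ref.wobble_offset - 1] = ord("G")
        if error_rate > 0:
            err = rng.random((n_reads, length)) < error_rate
            # uniform over the three non-current bases: shift by 1..3 in base order
            shifts = rng.integers(1, 4, size=(n_reads, length))
            idx = np.searchsorted(bases, reads)
            reads = np.where(err, bases[(idx + shifts) % 4], reads)
        for i in range(n_reads):
            seq = reads[i].tobytes().decode()
            rec = SeqRecord(Seq(seq), id=f"{ref.name}|{i}", description="")
            rec.letter_annotations["phred_quality"] = [base_quality] * length
            records.append(rec)
    truth = SimTruth(
        seed=seed,
        planted_editing={r.name: float(editing_fraction[r.name]) for r in refs},
    )
    return records, truth


def simulate_ihc_cohort(
    n_per_group: Mapping[str, int],
    score_dist: Mapping[str, Mapping[tuple[int, float], float]],
    seed: int = 0,
    marker: str = "ADAT2",
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-tumor IHC records sampled from cohort-specific score distributions.

    ``score_dist`` maps each cohort to a categorical distribution over
    ``(intensity, percent_positive)`` pairs (probabilities summing to 1).
    One record (single core) per tumor is emitted with columns
    ``sample_id, cohort, marker, core_id, intensity, percent_positive``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cohort in sorted(n_per_group):
        n = n_per_group[cohort]
        _check_positive(**{f"n_per_group[{cohort}]": n})
        if cohort not in score_dist:
            raise InvalidParameterError(f"no score distribution for cohort {cohort!r}")
        pairs = list(score_dist[cohort].items())
        probs = np.array([p for _, p in pairs], dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"score distribution for cohort {cohort!r} is not a probability vector"
            )
        for (intensity, percent), _ in pairs:
            if not (0 <= intensity <= 3 and 0 <= percent <= 100):
                raise InvalidParameterError(
                    f"invalid (intensity, percent) pair {(intensity, percent)!r}"
                )
        draws = rng.choice(len(pairs), size=n, p=probs)
        for i, k in enumerate(draws, start=1):
            (intensity, percent), _ = pairs[k]
            rows.append(
                {
                    "sample_id": f"{cohort}-{i:03d}",
                    "cohort": cohort,
                    "marker": marker,
                    "core_id": 1,
                    "intensity": int(intensity),
                    "percent_positive": float(percent),
                }
            )
    truth = SimTruth(
        seed=seed,
        planted_ihc_shift={
            cohort: {f"{i}|{p}": float(q) for (i, p), q in dist.items()}
            for cohort, dist in score_dist.items()
        },
    )
    return pd.DataFrame(rows), truth


def write_probe_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """TSV with transcript_id as first column, one column per (antibody, replicate)."""
    matrix.to_csv(path, sep="\t", index=True)


def write_fastq(records: Sequence, path: str | Path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fastq")


def write_fasta(refs: Sequence[TrnaReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n{ref.sequence}\n")
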