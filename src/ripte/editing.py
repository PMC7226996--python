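"""Quantification of tRNA A34-to-I34 (wobble inosine) editing from reads.

ADAT2/ADAT3 deaminates adenosine at position 34 (the anticodon wobble base)
of substrate tRNAs to inosine, which reverse transcription reads as G. The
editing level of a reference is therefore estimated from a read pileup at
the annotated wobble position as

    i34_fraction = G / (A + G),

excluding C/T calls (sequencing error) from the denominator. Two conditions
are compared with a two-sided Fisher exact test on the (G, A) counts.

A minimal ungapped mapper is included as plumbing for synthetic amplicon
reads; pre-aligned reads may be supplied as SAM instead (parsed with pysam).
Mature tRNAs are short (~76 nt) and the statistic is positional, so ungapped
full-overlap placement is adequate for the synthetic data this consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientCoverageError,
    InvalidParameterError,
    InvalidReferenceError,
)

__all__ = [
    "TrnaReference",
    "AlignedRead",
    "TrnaPileup",
    "EditingResult",
    "align_reads",
    "pileup",
    "editing_fraction",
    "compare_editing",
    "quantify_editing",
    "references_from_fasta",
    "read_sam",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TrnaReference:
    """A mature tRNA sequence with its annotated wobble position.

    ``wobble_offset`` is a 1-based index on the mature sequence (Sprinzl
    numbering is not used); the genomic template must carry A there.
    """

    name: str
    sequence: str
    wobble_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 1 <= self.wobble_offset <= len(self.sequence):
            raise InvalidReferenceError(
                f"{self.name}: wobble offset {self.wobble_offset} outside sequence "
                f"of length {len(self.sequence)}"
            )
        if self.sequence[self.wobble_offset - 1] != "A":
            raise InvalidReferenceError(
                f"{self.name}: expected A at wobble offset {self.wobble_offset}, "
                f"found {self.sequence[self.wobble_offset - 1]!r}"
            )


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped read placement on a reference (0-based start, forward ref coords)."""

    name: str
    sequence: str  # oriented to the reference strand
    qualities: tuple[int, ...]
    reference: str
    ref_start: int
    mismatches: int
    reverse: bool = False


@dataclass(frozen=True)
class TrnaPileup:
    """Base counts at one reference position (1-based)."""

    reference: str
    position: int
    counts: Mapping[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EditingResult:
    """I34 editing estimate at the wobble position of one reference."""

    reference: str
    a_count: int
    g_count: int
    other_count: int
    min_depth: int

    @property
    def informative_depth(self) -> int:
        return self.a_count + self.g_count

    @property
    def passed_coverage(self) -> bool:
        return self.informative_depth >= self.min_depth

    @property
    def i34_fraction(self) -> float:
        """G/(A+G); NaN when no informative (A or G) calls cover the site."""
        if self.informative_depth == 0:
            return float("nan")
        return self.g_count / self.informative_depth

    def summary(self) -> str:
        frac = self.i34_fraction
        flag = "" if self.passed_coverage else "  [LOW COVERAGE]"
        return (
            f"{self.reference}: I34 fraction {frac:.4f} "
            f"(G={self.g_count}, A={self.a_count}, other={self.other_count}){flag}"
        )


def _as_read_tuples(
    reads: Iterable,
) -> list[tuple[str, str, tuple[int, ...]]]:
    """Accept Biopython SeqRecords or (name, seq[, quals]) tuples."""
    out = []
    for r in reads:
        if hasattr(r, "seq"):  # SeqRecord
            quals = tuple(r.letter_annotations.get("phred_quality", ()))
            if not quals:
                quals = (40,) * len(r.seq)
            out.append((r.id, str(r.seq).upper(), quals))
        else:
            name, seq = r[0], str(r[1]).upper()
            quals = tuple(r[2]) if len(r) > 2 else (40,) * len(seq)
            out.append((name, seq, quals))
    return out


def align_reads(
    reads: Iterable,
    refs: Sequence[TrnaReference],
    max_mismatches: int = 3,
) -> dict[str, list[AlignedRead]]:
    """Assign each read to the reference/offset/strand minimising mismatches.

    Placements require the read to lie fully within the reference (ungapped
    full overlap); the reverse complement is also scored. Reads whose best
    placement exceeds ``max_mismatches``, or whose best score is tied between
    two placements, are discarded (ambiguous).
    """
    if not refs:
        raise InvalidParameterError("empty reference set")
    ref_arrays = {
        ref.name: np.frombuffer(ref.sequence.encode(), dtype=np.uint8) for ref in refs
    }
    out: dict[str, list[AlignedRead]] = {ref.name: [] for ref in refs}
    for name, seq, quals in _as_read_tuples(reads):
        placements: list[tuple[int, str, int, bool, str]] = []
        for oriented, reverse in ((seq, False), (_revcomp(seq), True)):
            arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for ref_name, ref_arr in ref_arrays.items():
                span = len(ref_arr) - len(arr)
                if span < 0:
                    continue
                for start in range(span + 1):
                    mm = int((arr != ref_arr[start : start + len(arr)]).sum())
                    placements.append((mm, ref_name, start, reverse, oriented))
        if not placements:
            continue
        placements.sort(key=lambda p: p[0])
        best = placements[0]
        if best[0] > max_mismatches:
            continue
        if len(placements) > 1 and placements[1][0] == best[0]:
            continue  # ambiguous
        mm, ref_name, start, reverse, oriented = best
        q = tuple(reversed(quals)) if reverse else quals
        out[ref_name].append(
            AlignedRead(name, oriented, q, ref_name, start, mm, reverse)
        )
    return out


def pileup(
    aligned: Iterable[AlignedRead],
    reference: str,
    position: int,
    *,
    ref_length: int | None = None,
    min_base_quality: int = 20,
) -> TrnaPileup:
    """Count A/C/G/T among reads covering ``position`` (1-based) on ``reference``.

    Base calls below ``min_base_quality`` are ignored.
    """
    if position < 1 or (ref_length is not None and position > ref_length):
        raise DomainError(f"position {position} outside reference {reference!r}")
    counts = {b: 0 for b in "ACGT"}
    for read in aligned:
        if read.reference != reference:
            continue
        idx = position - 1 - read.ref_start
        if not 0 <= idx < len(read.sequence):
            continue
        if idx < len(read.qualities) and read.qualities[idx] < min_base_quality:
            continue
        base = read.sequence[idx]
        if base in counts:
            counts[base] += 1
    return TrnaPileup(reference, position, counts)


def editing_fraction(site: TrnaPileup, min_depth: int = 50) -> EditingResult:
    """I34 estimate from a wobble-position pileup: G/(A+G), C/T reported apart."""
    return EditingResult(
        reference=site.reference,
        a_count=site.counts.get("A", 0),
        g_count=site.counts.get("G", 0),
        other_count=site.counts.get("C", 0) + site.counts.get("T", 0),
        min_depth=min_depth,
    )


def compare_editing(
    result_a: EditingResult, result_b: EditingResult
) -> tuple[float, float]:
    """Difference in I34 fraction between two conditions with a Fisher exact p.

    Returns ``(delta, p)`` where ``delta = fraction_a - fraction_b`` and p is
    the two-sided Fisher exact test on the 2x2 table of (G, A) counts.
    """
    for r in (result_a, result_b):
        if not r.passed_coverage:
            raise InsufficientCoverageError(
                f"{r.reference}: informative depth {r.informative_depth} "
                f"below min_depth {r.min_depth}"
            )
    table = [
        [result_a.g_count, result_a.a_count],
        [result_b.g_count, result_b.a_count],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    delta = result_a.i34_fraction - result_b.i34_fraction
    return float(delta), float(p)


def quantify_editing(
    reads: Iterable,
    refs: Sequence[TrnaReference],
    *,
    max_mismatches: int = 3,
    min_base_quality: int = 20,
    min_depth: int = 50,
) -> list[EditingResult]:
    """Align reads, pile up each reference's wobble position, estimate editing."""
    aligned = align_reads(reads, refs, max_mismatches=max_mismatches)
    results = []
    for ref in refs:
        site = pileup(
            aligned[ref.name],
            ref.name,
            ref.wobble_offset,
            ref_length=len(ref.sequence),
            min_base_quality=min_base_quality,
        )
        results.append(editing_fraction(site, min_depth=min_depth))
    return results


def references_from_fasta(
    fasta_path: str | Path, wobble_tsv: str | Path
) -> list[TrnaReference]:
    """Load references from FASTA plus a two-column TSV (name, 1-based offset)."""
    from Bio import SeqIO

    offsets = pd.read_csv(
        wobble_tsv, sep="\t", header=None, names=["name", "offset"], comment="#"
    ).set_index("name")["offset"]
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in offsets.index:
            raise InvalidParameterError(f"no wobble offset annotated for {rec.id!r}")
        refs.append(TrnaReference(rec.id, str(rec.seq), int(offsets.loc[rec.id])))
    return refs


def read_sam(path: str | Path) -> dict[str, list[AlignedRead]]:
    """Load ungapped alignments from a SAM file into per-reference read sets."""
    import pysam

    out: dict[str, list[AlignedRead]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name is None:
                continue
            quals = tuple(rec.query_qualities) if rec.query_qualities is not None else ()
            out.setdefault(rec.reference_name, []).append(
                AlignedRead(
                    name=rec.query_name,
                    sequence=(rec.query_sequence or "").upper(),
                    qualities=quals or (40,) * len(rec.query_sequence or ""),
                    reference=rec.reference_name,
                    ref_start=rec.reference_start,
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    reverse=rec.is_reverse,
                )
            )
    return out
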