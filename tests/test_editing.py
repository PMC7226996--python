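"""Wobble-inosine editing: alignment, pileup, estimator, exact-test comparison."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import hypergeom

from ripte.editing import (
    AlignedRead,
    EditingResult,
    TrnaPileup,
    TrnaReference,
    align_reads,
    compare_editing,
    editing_fraction,
    pileup,
    quantify_editing,
    read_sam,
    references_from_fasta,
)
from ripte.errors import (
    DomainError,
    InsufficientCoverageError,
    InvalidParameterError,
    InvalidReferenceError,
)
from ripte.simulate import simulate_trna_reads, write_fasta, write_fastq

from conftest import SEED, make_trna_reference


def _result(g, a, other=0, min_depth=1, ref="tRNA"):
    return EditingResult(ref, a_count=a, g_count=g, other_count=other, min_depth=min_depth)


def fisher_two_sided_by_enumeration(g_a: int, a_a: int, g_b: int, a_b: int) -> float:
    """Independent oracle: sum hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed one.

    Probability ties are resolved with the conventional 1e-7 relative slack
    of the two-sided Fisher definition, so float noise between pmf routes
    cannot flip a genuinely tied table in or out of the sum.
    """
    row_a, row_b = g_a + a_a, g_b + a_b
    n_total = row_a + row_b
    col_g = g_a + g_b
    rv = hypergeom(n_total, col_g, row_a)
    support = np.arange(max(0, col_g - row_b), min(col_g, row_a) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(g_a)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestReferences:
    def test_wobble_must_be_adenosine(self):
        with pytest.raises(InvalidReferenceError):
            TrnaReference("bad", "ACGTACGT", 2)  # C at offset 2

    def test_offset_bounds(self):
        with pytest.raises(InvalidReferenceError):
            TrnaReference("bad", "ACGT", 9)

    def test_fasta_round_trip(self, tmp_path, trna_refs):
        fasta = tmp_path / "refs.fa"
        wobble = tmp_path / "wobble.tsv"
        write_fasta(trna_refs, fasta)
        wobble.write_text("".join(f"{r.name}\t{r.wobble_offset}\n" for r in trna_refs))
        back = references_from_fasta(fasta, wobble)
        assert back == list(trna_refs)


class TestAlignReads:
    def test_exact_match_assigned(self, trna_refs):
        ref = trna_refs[0]
        out = align_reads([("r1", ref.sequence)], trna_refs)
        assert len(out[ref.name]) == 1
        assert out[ref.name][0].mismatches == 0
        assert out[ref.name][0].ref_start == 0

    def test_reverse_complement_detected(self, trna_refs):
        ref = trna_refs[0]
        rc = ref.sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        out = align_reads([("r1", rc)], trna_refs)
        assert len(out[ref.name]) == 1
        assert out[ref.name][0].reverse

    def test_equidistant_read_discarded(self):
        a = TrnaReference("refA", "AAAACCCCGGGGTTTT", 1)
        b = TrnaReference("refB", "AAAACCCCGGGGTTTA", 1)
        # read differs from each reference at exactly one position
        read = "AAAACCCCGGGGTTTC"
        out = align_reads([("r1", read)], [a, b])
        assert not out["refA"] and not out["refB"]

    def test_exceeding_max_mismatches_discarded(self, trna_refs):
        ref = trna_refs[0]
        seq = list(ref.sequence)
        for i in (2, 10, 20, 30):  # 4 > default max_mismatches=3
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        out = align_reads([("r1", "".join(seq))], trna_refs)
        assert all(not reads for reads in out.values())

    def test_empty_reference_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            align_reads([("r1", "ACGT")], [])

    def test_simulated_provenance_recovered(self, trna_refs):
        """>= 99% of low-error reads map back to their true source reference."""
        reads, _ = simulate_trna_reads(
            trna_refs, {r.name: 0.5 for r in trna_refs}, n_reads=500,
            error_rate=0.001, seed=SEED,
        )
        out = align_reads(reads, trna_refs)
        total = sum(len(v) for v in out.values())
        correct = sum(
            ar.name.rsplit("|", 1)[0] == ref_name
            for ref_name, lst in out.items()
            for ar in lst
        )
        assert total >= 0.99 * len(reads)
        assert correct == total


class TestPileup:
    def test_empty_pileup(self):
        site = pileup([], "ref", 5, ref_length=10)
        assert site.depth == 0

    def test_uniform_g(self):
        reads = [AlignedRead(f"r{i}", "GGGG", (40,) * 4, "ref", 0, 0) for i in range(7)]
        site = pileup(reads, "ref", 2, ref_length=4)
        assert site.counts["G"] == 7 and site.depth == 7

    def test_position_out_of_range(self):
        with pytest.raises(DomainError):
            pileup([], "ref", 11, ref_length=10)

    def test_low_quality_bases_masked(self):
        reads = [
            AlignedRead("hi", "GGGG", (40,) * 4, "ref", 0, 0),
            AlignedRead("lo", "GGGG", (40, 5, 40, 40), "ref", 0, 0),
        ]
        site = pileup(reads, "ref", 2, ref_length=4, min_base_quality=20)
        assert site.counts["G"] == 1

    def test_offset_reads_counted_at_right_position(self):
        reads = [AlignedRead("r", "AC", (40, 40), "ref", 3, 0)]
        assert pileup(reads, "ref", 4, ref_length=10).counts["A"] == 1
        assert pileup(reads, "ref", 5, ref_length=10).counts["C"] == 1
        assert pileup(reads, "ref", 6, ref_length=10).depth == 0

    def test_mixed_synthetic_pileup_matches_direct_tally(self, trna_refs):
        ref = trna_refs[0]
        reads, _ = simulate_trna_reads([ref], {ref.name: 0.4}, n_reads=300,
                                       error_rate=0.01, seed=SEED)
        aligned = align_reads(reads, [ref], max_mismatches=5)
        site = pileup(aligned[ref.name], ref.name, ref.wobble_offset,
                      ref_length=len(ref.sequence))
        # oracle: direct tally over the reads the aligner kept
        tally = {b: 0 for b in "ACGT"}
        kept = {ar.name for ar in aligned[ref.name]}
        for rec in reads:
            if rec.id in kept:
                tally[str(rec.seq)[ref.wobble_offset - 1]] += 1
        assert dict(site.counts) == tally


class TestEditingFraction:
    def test_unedited(self):
        assert editing_fraction(TrnaPileup("r", 34, {"A": 100, "C": 0, "G": 0, "T": 0})).i34_fraction == 0.0

    def test_fully_edited(self):
        assert editing_fraction(TrnaPileup("r", 34, {"A": 0, "C": 0, "G": 100, "T": 0})).i34_fraction == 1.0

    def test_ct_counts_do_not_move_fraction(self):
        a = editing_fraction(TrnaPileup("r", 34, {"A": 60, "C": 0, "G": 40, "T": 0}))
        b = editing_fraction(TrnaPileup("r", 34, {"A": 60, "C": 9, "G": 40, "T": 13}))
        assert a.i34_fraction == b.i34_fraction
        assert b.other_count == 22

    def test_coverage_flag(self):
        low = editing_fraction(TrnaPileup("r", 34, {"A": 10, "C": 0, "G": 10, "T": 0}), min_depth=50)
        assert not low.passed_coverage
        ok = editing_fraction(TrnaPileup("r", 34, {"A": 30, "C": 0, "G": 30, "T": 0}), min_depth=50)
        assert ok.passed_coverage

    def test_zero_informative_depth_flagged_nan(self):
        res = editing_fraction(TrnaPileup("r", 34, {"A": 0, "C": 5, "G": 0, "T": 5}))
        assert np.isnan(res.i34_fraction)

    def test_simulated_fraction_recovered(self, trna_refs):
        """Planted fraction 0.8, 1000 reads, error 0.001: estimate within 0.03."""
        frac = {r.name: 0.8 for r in trna_refs}
        reads, _ = simulate_trna_reads(trna_refs, frac, n_reads=1000, error_rate=0.001, seed=SEED)
        results = quantify_editing(reads, trna_refs)
        for res in results:
            assert res.passed_coverage
            assert res.i34_fraction == pytest.approx(0.8, abs=0.03)


class TestCompareEditing:
    def test_identical_tables(self):
        delta, p = compare_editing(_result(40, 60), _result(40, 60))
        assert delta == 0.0 and p == 1.0

    def test_extreme_separation(self):
        _, p = compare_editing(_result(90, 10), _result(10, 90))
        assert p < 0.05

    def test_symmetry(self):
        d1, p1 = compare_editing(_result(80, 20), _result(55, 45))
        d2, p2 = compare_editing(_result(55, 45), _result(80, 20))
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_failed_coverage_rejected(self):
        with pytest.raises(InsufficientCoverageError):
            compare_editing(_result(4, 4, min_depth=50), _result(40, 60, min_depth=50))

    def test_matches_hypergeometric_enumeration_small_margins(self):
        """p equals the exhaustive hypergeometric oracle on small random tables."""
        rng = np.random.default_rng(SEED)
        for _ in range(200):
            g_a, a_a, g_b, a_b = (int(x) for x in rng.integers(0, 13, 4))
            if g_a + a_a == 0 or g_b + a_b == 0:
                continue
            _, p = compare_editing(
                _result(g_a, a_a, min_depth=0), _result(g_b, a_b, min_depth=0)
            )
            oracle = fisher_two_sided_by_enumeration(g_a, a_a, g_b, a_b)
            assert p == pytest.approx(oracle, abs=1e-10)


class TestSamInput:
    def test_sam_path_matches_internal_aligner(self, tmp_path, trna_refs):
        ref = trna_refs[0]
        reads, _ = simulate_trna_reads([ref], {ref.name: 0.6}, n_reads=100,
                                       error_rate=0.0, seed=SEED)
        # write a minimal SAM of the known (trivial) placements
        sam = tmp_path / "aln.sam"
        lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{ref.name}\tLN:{len(ref.sequence)}"]
        for rec in reads:
            seq = str(rec.seq)
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            lines.append(
                f"{rec.id}\t0\t{ref.name}\t1\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}"
            )
        sam.write_text("\n".join(lines) + "\n")
        aligned = read_sam(sam)
        site = pileup(aligned[ref.name], ref.name, ref.wobble_offset,
                      ref_length=len(ref.sequence))
        direct = quantify_editing(reads, [ref])[0]
        res = editing_fraction(site)
        assert (res.g_count, res.a_count) == (direct.g_count, direct.a_count)
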