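# Methods

`ripte` implements the computational arm of a study design in which an
RNA-binding protein (BRCA1) is immunoprecipitated together with its bound
mRNAs, candidate transcripts are validated by qPCR, their translational
behaviour is measured by polysome profiling under knockdown, a downstream
enzymatic consequence (tRNA wobble inosine editing by ADAT2) is quantified
from sequencing reads, and protein-level correlates are scored by
immunohistochemistry in patient cohorts. Every stage consumes a standard
tabular or sequence format and can be exercised on synthetic data with
planted ground truth.

## RIP-chip enrichment (`ripte.ripchip`)

**Model.** Input is an RMA-style normalised probe-intensity matrix on the
log2 scale, transcripts × paired columns `BRCA1_rep<k>` / `NR_rep<k>`
(specific vs non-relevant antibody, R ≥ 2 replicates). Per replicate the
control is subtracted on the log2 scale, d_r = log2 IP − log2 NR, which is
the log of the IP/control ratio Fc; the replicate differences are averaged
(a geometric-mean ratio) and Fc = 2^mean. Averaging on the log scale, not
of linear ratios, is the consistent choice for log-scale input.

**Test.** The location test behind the per-transcript p-value is a
two-sided one-sample t-test of the d_r against 0 (df = R−1). The test
choice is an assumption recorded in the run metadata and configurable
(`test="wilcoxon"` gives a signed-rank alternative for sensitivity
analysis; with R = 3 its minimum two-sided p is 0.25, so it is only
informative at larger R). Degenerate rows (zero variance) cannot be
t-tested: with mean 0 the p is 1; with non-zero mean and R ≥ 3 the t
statistic diverges and p is reported as 0; with R < 3 it is reported as 1.
All three cases carry a `degenerate` flag.

**Filter and bins.** Retention requires Fc > 1.5 and p < 0.05, both strict.
Retained transcripts are binned gray [1.5, 2), orange [2, 3), blue [3, ∞);
the top bin is open because the printed upper edge of such plots is the
observed maximum, not a cap. Ties in the descending-Fc output ordering are
broken lexicographically by transcript id. Multiple probe sets mapping to
one transcript are collapsed by arithmetic mean of log2 values per column
before subtraction (simplest symmetric rule; configurable off).

## qPCR quantification (`ripte.qpcr`)

Relative expression uses 2^−ΔΔCt with amplification efficiency fixed at 2
(one cycle per doubling); no standard-curve correction is modelled.
Technical replicates are averaged on the Ct scale before differencing.
Normalisation against multiple reference genes (POP4 and beta-actin in the
motivating assay) takes the arithmetic mean of the reference Ct values,
i.e. the geometric mean of reference quantities — the standard
multi-reference rule. Input abundances are 2^−ΔCt within the input sample
rescaled so an anchor gene (TRMT10B by default) is exactly 1.

RIP validation uses the fold-enrichment statistic

    Fe = (IP_specific − IP_control) / Input,

with all three amounts as reference-normalised 2^−ΔCt on a common scale.
Fe is computed from replicate-averaged amounts (per-replicate Fe is a
documented alternative the data layout supports); negative values are
reported, not clipped. Concordance between the array Fc and qPCR Fe is
Spearman rank correlation (two-sided) over shared genes, requiring ≥ 4.

## Translational efficiency (`ripte.polysome`)

For each gene and replicate, knockdown/control expression ratios are formed
separately within total cytoplasmic RNA and pooled polysomal RNA
(`totRNA`, `polyRNA`), and Te = polyRNA/totRNA. Te isolates the change in
polysome association from transcriptional/stability effects: scaling both
pools equally cancels. Ratios are reported in the signed-fold convention,
r < 1 → −1/r, so that the symmetric cutoff ±1.4 is meaningful (a plain
positive ratio can never be below −1.4; the signed encoding is the only
reading under which such cutoffs apply). A gene is called up (down) only if
its signed Te exceeds +cutoff (is below −cutoff) in **every** replicate,
strict inequalities; a majority rule is available off by default.

Two normalisation modes for Ct input: `refs` (default) normalises each
pool/condition against the designated reference genes before the kd/ctrl
ratio; `equal-input` takes raw Ct differences, assuming equal RNA input per
reaction. The choice is recorded in the result metadata because gradient
experiments do not always carry stable references in the polysomal pool.
Pooled heavy-gradient fractions (e.g. fractions 7–14) are represented by a
single polysome pool; continuous gradient traces are out of scope.

## Wobble-inosine editing (`ripte.editing`)

ADAT2/ADAT3 deaminates A34 (the anticodon wobble base) to inosine, which
reverse transcription reads as G. The editing level is estimated from a
pileup at the annotated wobble offset as G/(A+G); C/T calls are counted
separately as sequencing error and excluded from the denominator, so the
estimator is invariant to them. Conditions are compared by a two-sided
Fisher exact test on the (G, A) counts; Δ is the difference of fractions.

The built-in aligner is deliberate plumbing for short amplicon reads:
ungapped full-overlap placement minimising Hamming mismatches over all
references, offsets and both strands, discarding reads above
`max_mismatches` (default 3) or with tied best placements (ambiguous).
Mature tRNAs are ~76 nt and the statistic is positional, so indel handling
would add nothing for the synthetic data this consumes; real alignments can
be supplied as SAM instead (parsed with pysam). Defaults — base quality
≥ 20, informative depth ≥ 50 — are conventional amplicon thresholds; the
wobble position is a 1-based offset on the mature sequence (Sprinzl
numbering is not implemented).

## IHC scoring (`ripte.ihc`)

Score = staining intensity (0–3) × proportion grade (0–3), range 0–9. The
published proportion bins (≤10% → 0; 20–40 → 1; 50–80 → 2; >80 → 3) leave
(10, 20) and (40, 50) unassigned; the implementation closes the gaps with
boundaries at 10, 50, 80, extending the lower grade upward, which keeps the
50–80 bin intact. Replicate TMA cores per tumor are reduced by maximum
score (configurable to median) — the reduction rule is not fixed by the
source grading description. Scores are dichotomised at score ≥ 4 by default
(at least moderate intensity on a majority of cells); since the low/high
split is a free choice, `threshold_sensitivity` reports the comparison
across thresholds 2–6. Cohorts are compared with a Pearson chi-square on
the 2×2 low/high table, df = 1, two-sided, without continuity correction by
default (Yates correction available as an option).

## Synthetic data (`ripte.simulate`)

Every generator is a pure function of its parameters and one integer seed
(numpy `default_rng`; no global state), returning the dataset together with
a `SimTruth` carrying the planted values.

* **RIP-chip**: per-transcript baseline ~ N(8, 1.5²) log2 units; enriched
  transcripts get a fixed log2 offset in the IP columns. `noise_sd`
  parameterises the dispersion of the per-replicate IP−NR difference: each
  intensity column receives independent Gaussian noise with sd
  `noise_sd/√2`, so d_r has sd exactly `noise_sd`. This makes the
  generator's noise parameter directly the noise of the downstream
  statistic.
* **qPCR**: Ct = baseline(gene) − log2(expression) + N(0, sd); baselines
  uniform on [20, 28] cycles; reference genes at constant expression 1 in
  every sample. Efficiency calibration and pre-amplification chemistry are
  not modelled.
* **Polysome**: expression 1 in control pools; knockdown total carries an
  optional transcriptional fold (default 1) and knockdown polysome carries
  Te × that fold, so the expected polyRNA/totRNA ratio equals the planted
  Te.
* **Reads**: full-length ungapped copies of each reference; wobble base G
  with the planted probability, then uniform substitution errors at the
  given rate over all positions; ids encode the source reference. Indels,
  truncation, coverage bias and quality-score variation are not simulated.
* **IHC**: per-tumor (intensity, percent) pairs drawn from a cohort-specific
  categorical distribution; one core per tumor (multi-core reduction is
  exercised with hand-built tables).

These generators emulate the *statistical* structure the estimators rely on
— planted effect sizes, replicate structure, efficiency-2 amplification,
binomial editing — not the physics of arrays, amplification chemistry or
staining. Passing tests therefore demonstrate correct recovery of planted
parameters under idealised noise, not robustness to array batch effects,
probe cross-hybridisation, PCR inhibitors, alignment artefacts on full
genomes, or inter-pathologist grading variability.

## Problem sizes and numerical choices

Study-condition checks run at the scale of the motivating design: 200
transcripts with 20 enriched (log2fc 1, noise sd 0.2, 3 replicates) for
recovery; 10,000 null transcripts for the retention-rate control; a 16-gene
panel with 1 up / 6 down planted for Te selection; 1000 reads per reference
at error 0.001 for the editing estimator; depth 500 and 1000 simulated
trials for the exact test's error rates; cohorts of 26 (WT) and 19 (MT)
tumors for IHC. The documented seed for fixed-seed checks is 20200410.
Oracle-equivalence checks enumerate all 2×2 tables with row margins ≤ 30
(tests) or ≤ 20 (acceptance script) against an explicit hypergeometric
enumeration, with probability ties resolved by the conventional 1e-7
relative slack of the two-sided Fisher definition.

Noiseless-generator checks assert exact recovery (≤ 1e-9); oracle
equivalences assert ≤ 1e-10; stochastic recoveries assert the bounds stated
in the tests (e.g. editing estimate within ±0.03 of 0.8 at n = 1000, which
is ≈ 2.4 binomial standard deviations).

## Known limitations

* The enrichment p-value test is an assumption (the upstream assay's exact
  test is not fixed); results carry the choice in metadata.
* The aligner is not a general-purpose mapper; use SAM input for anything
  beyond short amplicons.
* No multiple-testing correction is applied to the enrichment filter — the
  retention rule is the published-style joint Fc/p gate, and the null
  retention rate is controlled empirically instead.
* IHC analysis starts from pathologist-graded inputs; no image analysis.
* Config files are JSON; YAML is not parsed.
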