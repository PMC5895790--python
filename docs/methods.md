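# Methods

## Scope and model

satkit quantifies satellite repeat families from single-end sequencing
reads under a simple sampling model: reads are drawn uniformly from the
genome (shotgun / ChIP input) or, in an immunoprecipitated pool, with
per-family multiplicative re-weighting. The package's own contribution is
the pipeline logic — planted-truth simulation, QC, best-hit assignment,
abundance/enrichment tables, composition statistics, and tandem-validation
tools; standard primitives (pairwise alignment, FASTA/FASTQ parsing, OLS)
are delegated to Biopython, pandas and statsmodels.

## Synthetic data generator

`synthetic_data` plants each family as one uninterrupted tandem array of
independently mutated monomer copies (substitutions only; no indels in
v1 — this keeps alignment-score oracles exact while reproducing the
92–99 % copy-to-consensus identity seen in cloned satellite amplicons).
Defaults emulate the published regime: AT-rich monomers (AT fraction
0.5–0.8) of tens of bp to ~2 kb, per-copy divergence 0.05, genomic
fractions from ~10⁻⁴ to a few 10⁻², 101-nt reads with 1 % substitution
error at constant Q30 (an optional low-quality 3′-tail mode exercises the
QC filter). Array length is the target fraction rounded to whole monomers,
so the reported truth fractions are exact by construction. Coordinates are
0-based half-open; a read belongs to the family containing its *start*
position — one consistent rule for boundary-crossing reads.

ChIP pools sample family labels from weights f·e renormalized to sum to
one (the physical constraint of sequencing a fixed number of molecules),
then a uniform start within the family's arrays. What the generator does
*not* model: indels and structural mutation, higher-order repeat
evolution, GC/fragment-length bias, paired ends, and any sequence-specific
pull-down bias of a real ChIP library (uniform sampling is assumed, not
claimed). Passing tests therefore demonstrate correctness of the
estimators under this idealized model, not robustness to those real-data
effects.

## Read QC

Reads are trimmed by dropping `drop_leading` = 1 base and truncating to
`trim_to` = 100 nt, then kept iff ≥ 95 positions (`min_bases_at_q`) have
Phred ≥ 10 (`min_q`, Phred+33). "Exceeds the cutoff" is read as ≥ (the
conventional meaning of a cutoff); a `strict` flag switches to > for the
boundary reads, since only those are affected. Reads shorter than the trim
target are discarded — uniform length keeps proportion arithmetic exact.

## Alignment and assignment

Scoring follows the classic BLASTn parameterization: match +2, mismatch
−3, affine gap of length k costs 5 + 2k, word size 9, and *no*
low-complexity filtering (satellites are low-complexity; masking would
destroy the analysis). The E-value cutoff of a database search is replaced
by a raw-score threshold (`min_score` = 100, ≈ 50 matched bases), because
E-value calibration depends on database size and desk-scale runs should be
deterministic.

Two routes share these semantics. `local_align_score` is exact maximal
local alignment via Bio.Align.PairwiseAligner (biopython charges open for
the first gap base, so open = −7, extend = −2 reproduces the 5 + 2k
convention). `SeededPoolAligner` scores whole pools: exact 9-mer seeding
proposes candidate (reference, strand, diagonal) triples; each read's
best-supported diagonal per orientation (ties prefer a diagonal where the
read fits entirely inside the reference — tandem phases tie on seed
support and the rightmost phase would truncate the alignment) is then
scored by a banded affine Smith–Waterman (half-width 16) vectorized across
all candidates. Banding and seeding are accelerators: on
substitution-dominated data they reproduce the exact score, which the test
suite asserts against the exact route, and both are checked against an
independent brute-force dynamic program. Monomer references are
tandem-extended to ⌈(m + L − 1)/m⌉ copies so a read sampled at any array
phase aligns over its full length — the analog of mapping against contigs
longer than the repeat unit.

Assignment is best-hit-only: the family with the strictly highest score ≥
threshold; ties resolve to the lexicographically smallest name and are
counted. Tables are sorted by read id, making output byte-identical
regardless of input order.

## Abundance and enrichment

Abundance uses all reads as denominator (read fraction estimates genome
fraction); Mbp/1C = pct/100 × 13 410, rounded half-away-from-zero to one
decimal, which reproduces the majority of the printed catalogue values.
The audit threshold for printed-vs-recomputed Mbp is 0.05 (half a rounding
unit): eight catalogue rows differ by exactly one rounding unit because
the printed Mbp column was computed from unrounded percentages; they are
reported, never corrected.

The enrichment ratio's proportion denominator is genuinely
underdetermined; both options are implemented. The API default is
"assigned" (total assigned reads per pool — robust to differing
unassignable fractions when the reference panel covers most of the
repeatome, as in the original 500-cluster setting). The recovery
experiments in `benchmarks` use "total" (all pool reads): their reference
panel covers only the planted satellites, and with a satellite-only panel
assigned-total normalization can only measure ratios *relative* to other
satellites, making absolute factor recovery impossible by arithmetic. The
call rule is strict: ratio > 10 *and* genomic proportion ≥ 0.002 %
(input-derived; chip-derived fallback for families absent from the input,
which otherwise carry an infinity sentinel). Only the `evaluate_top_n` =
500 families by input count are evaluated.

Renormalization of the ChIP pool deflates every measured ratio by
W = 1 + Σᵢ fᵢ(eᵢ − 1); under the default recovery design (1 Mbp genome;
191-bp/1 %/1×, 58-bp/0.1 %/10×, 47-bp/0.1 %/100× families; 5 % divergence;
100k reads per pool) W ≈ 1.11, so recovered ratios sit ~10 % below the
planted factors even with unlimited reads — a property of ChIP proportions
themselves, not an estimator defect. Observed median relative error across
10 replicate seeds is ~12–13 %.

## Composition statistics

k-mer counts are circular (rotation-invariant, appropriate for monomers
that are arbitrary rotations of a repeat unit) and, for ρ\*/γ\*,
strand-symmetrized (sequence + reverse complement) in the Karlin-school
convention — read pools mix strands, and the separate asymmetry indices
carry the strand signal instead. The trinucleotide statistic is

  γ\*(XYZ) = f\*(XYZ) f\*(X) f\*(Y) f\*(Z) / (f\*(XY) f\*(YZ) f\*(X·Z)),

with f\*(X·Z) the one-gapped dinucleotide frequency; it normalizes to 1 on
iid input and is guarded by a literal dict-arithmetic reimplementation in
the tests. Values for k-mers absent from the data are 0. N bases are
dropped from all counts. Pool profiles orient each read to the reference
strand (better-scoring strand; ties keep forward) before counting, and
count each read circularly, so a pool of exact monomer copies reproduces
the monomer profile to machine precision. Asymmetry indices are reported
as max(x/y, y/x) ≥ 1, with ∞ when one member is absent and 1 when both
are.

## Tandem validation

Period estimation uses shifted self-identity (transparent and
oracle-checkable, unlike k-mer spectra): the smallest lag whose match
fraction exceeds 0.8 and is a local maximum, so the fundamental period is
reported rather than its multiples; at 5 % per-copy divergence the match
fraction at the true lag is ≈ (1 − d)² + d²/3 ≈ 0.90. Subrepeat detection
reports off-diagonal exact-identity runs ≥ `min_len` (default 20 bp; at
that length chance runs are vanishingly rare in random sequence). The
original dot-plot window/identity settings are unknown, so these are
exposed parameters, not claimed to match.

Outward primer design prefers the outermost windows (forward rightmost,
reverse leftmost, lengths 18–25) with GC 40–60 %, relaxed to ≥ 30 % with a
warning on AT-rich monomers; melting temperature is the Wallace rule
2(A+T) + 4(G+C), reported informationally only. In-silico PCR is
exact-match by design — the assay is a logical check of tandem
arrangement, not thermodynamics — and scans both strands; a product runs
from a rightward-priming site to the *next* leftward-priming site of the
other primer, so the junction product length is (m − forward.start) +
reverse.end. Clone-vs-consensus identity is global alignment with free end
gaps under the same score set, identities / alignment columns × 100.

## Replication-timing regression

Timing classes are encoded ordinally mid = 0, late = 1, latest = 2
(preserving S-phase order); each feature is regressed singly by OLS with a
two-sided t test on the slope, no multiple-testing correction by default
(Benjamini–Hochberg behind a flag, matching the single-feature screen
described for the original analysis, which found no significant
association). Constant features yield NA with a warning. Calibration is
verified by permutation: on 26 families with permuted labels the rejection
rate at α = 0.05 stays at the nominal level (observed ≈ 4–5 % over 1,000
permutations), and null p-values are approximately uniform.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen to make binomial/Monte-Carlo
tolerances meaningful: 1 Mbp genomes, 100k reads per pool and 10 seeds for
enrichment recovery; 50k reads for read-start binomial checks; 1,000
random pairs (length ≤ 30) for oracle equivalence; 1,000 permutations for
regression calibration. Integer DP arithmetic is int32 with a −10⁶
sentinel; proportions normalize to 1 within 10⁻¹²; all generators are
numpy `default_rng` seeded explicitly, and identical seeds give
byte-identical FASTA/FASTQ output.

## Known limitations

Substitution-only mutation and error models; single uninterrupted array
per family; exact-match primer sites; no E-value statistics; enrichment
recovery inherits the W-deflation above; composition of real degenerate
consensus sequences (with ambiguity positions collapsed) will not
reproduce published asymmetry indices computed on the full consensus
population, and the packaged catalogue's asymmetry columns are therefore
treated as transcription, not as a recomputation target.
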