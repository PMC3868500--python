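# Methods

## Setting and model

The package targets the classic pooled two-library design for small-RNA
sequencing: all case samples (MN, membranous nephropathy in the motivating
application) are sequenced as one library and all controls (NC) as
another, so there is exactly one count per miRNA per group and no
replicate-level variance estimate.  Inference on counts therefore uses the
Audic–Claverie statistic, which conditions on the count x observed in one
library and asks how surprising the count y in the other is, given the
library totals N₁ and N₂:

    P(y|x) = (N₂/N₁)ʸ (x+y)! / ( x! y! (1 + N₂/N₁)^(x+y+1) ).

As a function of y at fixed x this is the negative-binomial pmf with
r = x+1 and success probability N₁/(N₁+N₂); the identity is used for
closed-form tail sums and as an independent cross-check in the tests.
Replicate-aware models (negative binomial with dispersion, e.g. DESeq-type)
are deliberately out of scope: they answer a different design.

## Pipeline stages and parameter defaults

**Cleaning.** Reads are kept when mean Phred ≥ 20 and the N fraction is
≤ 10% (both configurable; conventional small-RNA QC values, stated
explicitly because any such rule must be reproducible).  The 3′ adaptor is
located by the leftmost exact match of its first 8 nt; the insert before
it is kept when its length is within 18–30 nt (the typical mature-miRNA
window around the 18–24-nt reference range), otherwise the read is
discarded as `too-short`/`too-long`/`no-adaptor`, each reason tallied so
that reads in = clean + removed always holds.  Tags beginning with the 5′
adaptor seed are removed as ligation artifacts.  Matching is exact — at
desk scale determinism is worth more than marginal recall, and it keeps
every oracle trivial.  Sequences are normalized to DNA (U→T) internally
and rendered with U in miRNA-facing reports.

**Mapping.** Exact matching only (max_mismatch is fixed at 0; the
parameter name is reserved in the config for forward compatibility).  A
multi-mapping tag counts once toward the mapped fraction but contributes
its read count at every locus in the per-chromosome sense/antisense
table — the two tables answer different questions (how much of the library
maps vs where the tags sit).  Coordinates are 0-based half-open
internally, 1-based inclusive in TSV output.  Report percentages are
100·mapped/total at full precision, rounded half-up to 1 decimal only at
rendering; published tables of this kind are only self-consistent at
1-decimal precision.

**Profiling.** A tag is assigned to a mature miRNA only by exact
full-length identity.  No isomiR shifts: tolerance is undefined in the
pooled design and exactness keeps the unannotated pool — the input of the
edit stage — well defined.  The base-composition matrix is computed
count-weighted over miRNA-assigned tags for positions 1–24 (an option
runs it over all tags); position p is normalized over tags of length ≥ p,
so each covered row sums to 100 by construction.  Dominant-base ties break
in the fixed order A < U < C < G and carry a tie flag.

**Differential expression.** Normalized expression is count/N × 10⁶,
floored at 0.01 so that log₂ fold change is always defined; the floor
value follows the convention of printing 0.01 for miRNAs absent from one
library.  The default p-value is the point probability P(y|x) — the
formula as printed is the defensible default when a study's exact tail
convention cannot be reconstructed (see Limitations).  Tail mode is the
exact min-likelihood p: the sum of P(y′|x) over all y′ whose point
probability does not exceed the observed one.  The pmf is unimodal, so the
summation region is [0,a] ∪ [b,∞); a and b are found by binary search on
the log-pmf and each piece is a regularized incomplete beta value
(`scipy.special.betainc`).  A one-sided sum whose direction is picked from
the observed discrepancy was rejected: direction selection doubles the
null rejection rate (measured ≈0.096 at nominal 0.05), whereas the
min-likelihood p controls it (measured ≈0.051).  All point-probability
arithmetic is in log space via `gammaln`; an exact `fractions.Fraction`
path exists for modest counts and is the test oracle (agreement to
~1e-12 relative).  Calls: up if FC ≥ 1 and p ≤ 0.01, down if FC ≤ −1 and
p ≤ 0.01, else unchanged; the FC threshold of 1.0 is inferred from the
smallest significant |FC| ≈ 1.03 seen in practice for this rule and is
configurable (0 restores a pure p-rule).  No multiple-testing correction
enters the calls; a Benjamini–Hochberg column is emitted as supplementary
output only.

**Seed edits.** Mature positions 2–8 (1-based) are the seed.  A candidate
edit is an unannotated tag at Hamming distance exactly 1 from an
equal-length mature sequence, with the mismatch inside the seed.  No
indels or shifted alignments — the phenomenon modelled is substitution
editing.  Exactness trumps edit: a tag equal to some mature sequence never
counts as an edit of another.  Multi-parent tags are tallied for every
parent and flagged.  Percentages are 100·edited/(edited+exact) in read
counts (a flag switches to distinct tags); the MN/NC ratio is rounded
half-up to 2 decimals *before* classification, so a pair like
100.00/99.55 lands in the "=1" class — matching how such tables are
printed.  miRNAs absent from either group, or with zero NC percentage,
are excluded from the three-class partition (logged), so the partition
always sums to the number of classified miRNAs.

**qPCR.** ΔCt = Ct_target − Ct_ref per group, ΔΔCt = ΔCt_MN − ΔCt_NC,
ratio = 2^(−ΔΔCt), log₂ ratio = −ΔΔCt.  The reference row is any name the
table provides (reference-RNA naming is notoriously inconsistent);
replicate Cts are averaged (configurable to median) before ΔCt.  Direction
concordance is sign agreement between −ΔΔCt and the sequencing log₂ FC.

**Clustering.** The pair matrix holds one log₂ fold-change column per
sample pair; a cell is missing when the miRNA was floored (effectively
absent) in at least one member of the pair.  Distances (euclidean or
correlation) are computed pairwise-complete over shared non-missing cells
— a column pair with no shared cells is an error naming the columns, so no
NaN can leak into the linkage.  Merging is scipy's average or complete
linkage; both keep merge heights non-decreasing.  The heat-map TSV encodes
the tri-state semantics (positive / negative / NA) so graphics are
reproducible without the package.

## The synthetic-data generator

The generator emulates the study conditions: two libraries of raw 50-nt
reads whose inserts are planted mature miRNAs (18–24 nt) read off a toy
genome on either strand, padded with a 13-nt 3′ adaptor and random filler.
Per-miRNA counts are multinomial over fixed uniform base weights, scaled
by 2^effect in MN, so the expected MN/NC ratio of a planted effect is
analytic up to the weight renormalization log₂(Σw_MN/Σw_NC) (≈0.016 for 2
perturbed miRNAs among 200 — well inside the ±0.3 recovery tolerance used
in the tests).  Uniform base weights are chosen so that, at the reference
depth of 10⁵ reads over 200 miRNAs, every miRNA has ≈500 expected reads
and the binomial standard error of a recovered log₂ effect (~0.09) leaves
~3σ headroom inside ±0.3.  Seed edits are planted per read with one
uniform substitution at positions 2–8.  Contaminants (default split
equally) are low-quality reads (Phred 2–10, 20% N), adaptor dimers, and
adaptor-free random reads — one per removal rule of the cleaner.  Emitted
reads per library equal the configured depth exactly; all randomness flows
from one seeded `numpy` generator, and identical configs give
byte-identical outputs.

What the generator does **not** emulate: position-dependent sequencing
error, quality-score correlation along the read, isomiR length
heterogeneity, precursor/hairpin structure, rRNA/tRNA/sno/snRNA
contamination classes, and realistic (power-law) abundance distributions.
Passing tests therefore demonstrate correctness of the algorithms under
clean, known-truth conditions — not robustness to every artifact of real
sequencing data.

## Problem sizes used in tests and the acceptance script

Unit tests run at 10³–10⁴ reads.  The acceptance checks run a full
read-level study at 10⁵ reads per library with 200 miRNAs, a
type-I-rate simulation of 200 (script) or 500 (tests) replicate library
pairs at the counts level (the statistic consumes counts; read-level
simulation adds nothing to that check), 200 random instances against the
exact-arithmetic oracle, and a byte-level determinism rerun.  These sizes
were chosen as the smallest at which the statistical tolerances above are
meaningful.

## Known limitations

- Published tables of this design are reproducible from their printed
  inputs only to limited precision: mapping percentages at 1 decimal, and
  fold changes for floored (absent-in-one-library) entries only to ~6
  decimals, because the printed per-million inputs are themselves rounded.
  Two reference fold-change assertions in the acceptance tests fail at the
  8-decimal level for exactly this reason; the computed values are the
  correct log₂ of the printed inputs.
- Tail p-values of the pooled design cannot be matched to any single
  published convention; the point formula is the default and the
  min-likelihood tail is the validated alternative.
- The exact-match mapper is quadratic in genome size at index build time
  per tag length; it is intended for desk-scale genomes (≤ a few Mb), not
  the human genome.
- With 0-mismatch mapping, every seed-edited tag is unmappable; unique-tag
  mapping percentages on edit-rich synthetic data are therefore low by
  construction.
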