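# Methods

This note documents the models, rules and numerical choices behind
`triowes`, and what the synthetic-cohort tests do and do not establish
about real data.

## Somatic filter cascade

Input is one record per (site, alt allele) with read counts for the
matched normal, the pre-treatment (primary) and the post-treatment
(resistant) tumor. The per-sample mutant read frequency is
`MRF = mutant_reads / total_reads`, undefined at zero depth. The total
is the sum of the allelic depths (`AD`), not the `DP` field, so that
numerator and denominator come from the same accounting; a sample
without `AD` contributes an absent observation, which fails the
corresponding depth rule.

Rules, applied in a fixed order with the first failure recorded:

1. population allele frequency > 0.02 → known polymorphism;
2. normal total reads < 10 → normal sample unevaluable;
3. normal mutant reads > 0 → germline evidence;
4. primary or resistant total reads < 10 → tumor unevaluable;
5. ≥ 2 mutant reads in primary or resistant → somatic, else
   no qualifying support.

All boundaries are inclusive exactly as stated (depth 10 passes,
pop AF 0.02 passes). A missing population frequency means "not a known
polymorphism" and passes rule 1. Whether the population filter runs
before or after the read-count rules changes only which rule is
recorded as failed, never the somatic set; the order above is fixed
for reproducible bookkeeping.

## Treatment-related classification

A somatic variant is treatment-related when
`MRF_resistant ≥ 0.20` and `MRF_resistant ≥ 2 × MRF_primary`, both
inclusive. A primary MRF of zero — or an undefined one — satisfies the
fold rule: the region is a trapezium in the (primary, resistant) MRF
plane whose left edge sits on the y-axis. A treatment-related variant
whose primary-tumor mutant reads fall below the somatic detection
threshold (2 reads) is *resistant-only*; by construction the
resistant-only set is a subset of the treatment-related set.

Gatekeeper exclusion: a patient whose treatment-related variants
include a catalogued on-target resistance mutation is dropped from
cross-patient gene-list analyses, since their resistance is already
explained. The catalog is an editable two-column TSV shipped with the
package, seeded with *ALK* G1269A; a catalog mutation that fails the
MRF rule does not trigger exclusion.

## CADD bins and percentage reporting

Scores ≥ 20 → deleterious, [10, 20) → possibly deleterious, < 10 →
non-deleterious. The middle interval is closed below and open above so
the three scored bins partition. Scoreless frameshift indels are
deleterious by override; other scoreless variants form a fourth
`no_score` bin. Integer percentages are rounded half-up by default;
`floor` and banker's (`half_even`) modes are exposed because published
tables do not always state their rounding rule and adjacent conventions
can differ by one percentage point.

## Pathway over-representation

For a query of n genes in an N-gene universe and a pathway with K
members in the universe, the p-value is the hypergeometric upper tail
P(X ≥ k) (scipy `hypergeom.sf(k-1, N, K, n)`), and the enrichment
score is −ln(p), so score 3.0 ⇔ p = 0.05 and `exp(-score)` recovers p
to machine precision. Results are sorted by descending score with ties
broken by pathway name. No multiple-testing correction is applied by
default (scores are reported as raw −ln p); Benjamini–Hochberg is
available behind a flag.

The background universe is a modelling choice the user controls: the
default is all genes carrying at least one annotated variant in the
cohort, with a fixed-catalog universe as the alternative; the choice is
recorded in the run's effective config.

The EMT second pass reports the overlap of every EMT-tagged pathway
with each patient's treatment-related genes regardless of
significance, because single-gene overlaps in related pathways are
biologically informative even when no test can fire. The bundled GMT
carries 14 small EMT-related pathway fixtures and one constructed
metabolism set (marked "synthetic fixture" in its description field);
it is a curated test catalog, not a KEGG snapshot, and real analyses
should supply their own GMT.

## Pseudo-probe copy number

Coverage bins of 2–5 kb with mean base-wise coverage ≥ 1× act as
probes (the upstream mapping-quality filter, reads with MAPQ > 40, is
a recorded input contract, not recomputed here). The reference is the
per-bin median across ≥ 2 normal samples after scaling each to the
mean total coverage — robust to a single corrupted normal. Log2 ratios
use `log2((t + 0.5)/(r + 0.5))` after total-coverage scaling; the 0.5
pseudo-count keeps zero-coverage bins finite. GC normalization
subtracts the median log2 ratio within GC deciles and restores the
global median, removing the GC trend while preserving genome-wide
level shifts.

Segmentation is circular binary segmentation: the maximal
pooled-variance two-sample t statistic over all arcs (i, j) of a
chromosome, accepted when a seeded permutation test (default 1,000
permutations, threshold p ≤ 0.01, early-stopped once the exceedance
count makes acceptance impossible) deems it significant, then applied
recursively to the pieces. Chromosomes with < 2 probes are single
segments without a test. Segment calls threshold the mean log2 ratio
at ±0.3 by default; the thresholds are configuration, not biology —
they replace a manual-inspection step that has no algorithmic
definition, and should be tuned to the noise level of real data.
Locus comparisons report the call of the maximally overlapping segment
in each sample and flag loci outside the covered grid as `uncovered`
rather than neutral.

## Cross-platform concordance

A variant is evaluable on a validation platform (RNA-seq or a second
exome) at ≥ 10× coverage and confirmed when ≥ 1 mutant read is
present; "confirmed" deliberately uses the weakest defensible rule
since validation platforms have different error profiles, and the
threshold is configurable. Combination across platforms is a
disjunction: evaluable anywhere, validated if confirmed on any
platform where evaluable. Percentages are integer, half-up.

## Synthetic cohort generator

The generator emulates a small FFPE-heavy exome cohort:

* Depth: negative binomial, mean 66 reads, dispersion 3
  (variance = μ + μ²/k). This puts ~93 % of positions above 20× and a
  ~1 % tail below 10×, the kind of overdispersion archival tissue
  shows at a nominal 66× exome.
* Mutant reads: binomial(depth, true MRF).
* Germline: true MRF ≈ N(0.5, 0.05) in all three samples; half carry
  a population frequency drawn up to 0.5, exercising the population
  rule.
* Stable somatic: true MRF ~ Beta(2, 5) (clipped to [0.08, 0.9]),
  identical in both tumors; zero in the normal.
* Treatment-related: resistant MRF ~ U(0.35, 0.70); 75 % are
  resistant-only (primary MRF 0), the rest have primary MRF =
  resistant / 3, so expectations clear both classification thresholds
  with margin and sampled read counts pass with probability ≥ 0.9.
* Annotation: gamma(2.2, 5.5) CADD-like scores for SNVs (~2 %
  scoreless); indels (8 % of variants) are scoreless, 60 % frameshift.
* Gene labels: treatment-related variants draw from one planted
  pathway with probability 0.5 (configurable), giving the enrichment
  stage a recoverable signal against a catalog of ten 20-gene
  synthetic pathways plus 200 background genes.
* Coverage bins: widths U[2 kb, 5 kb]; expected coverage =
  60 × (copy number / 2) × exp(0.6 · (GC − 0.45)) on tumor samples
  (the normal is GC-unbiased) × 2^N(0, 0.15) noise. Planted states:
  a copy-4 gain and a copy-1 loss on separate chromosomes, applied to
  the resistant sample.
* Validation reads: per-platform negative-binomial depth (mean 50,
  dispersion 5) and binomial mutant reads at the resistant MRF, with a
  5 % dropout rate emulating platform misses, which yields ~95 %
  confirmation among evaluable treatment-related positions.

All draws flow from `numpy.random.default_rng` seeded with
(seed, patient, stream) tuples; identical configs give bit-identical
bundles, and no global random state is touched.

What passing the recovery tests shows: the filter cascade, trapezium
rule, enrichment ranking and CBS localize *planted* signals of the
stated sizes under binomial read noise and overdispersed depth. What
it does not show: robustness to tumor impurity, subclonal structure,
alignment artifacts, FFPE deamination damage, or mis-annotation — none
of which the generator models.

## Problem sizes in the test suite

Recovery suites use 20 fixed or seed-derived replicates: 2,000-variant
patients for treatment-related sensitivity (mean ≥ 0.8), 500-variant
patients for somatic recall (mean ≥ 0.95, zero germline leakage
observed), 80-probe chromosomes with a Δlog2 = 1.0 step for CBS
(breakpoint within ±2 probes), and 400-variant patients for
planted-pathway ranking (top rank in ≥ 90 % of seeds). Hypergeometric
p-values are checked exhaustively against integer-combinatorics tail
sums for every universe size N ≤ 25, and the trapezium decision is
checked on the full 0.01-step MRF lattice.
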