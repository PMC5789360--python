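# triowes

Analysis pipeline for paired pre-/post-treatment tumor exomes with a
matched normal: find somatic variants whose mutant-allele support rises
under a targeted therapy, and characterize them by predicted impact,
pathway membership and copy-number context.

The intended user is a cancer-genomics analyst with per-patient
normal/primary/resistant variant calls (VCF with per-sample `DP`/`AD`),
a variant annotation table, gene-set catalogs (GMT) and per-bin exome
coverage tables — the typical output of a GATK-style calling pipeline
on a small cohort of patients who progressed on a tyrosine-kinase
inhibitor.

## What it computes

For each sample the **mutant read frequency** at a variant position is

    MRF = mutant reads / total reads

with total reads taken as the sum of the allelic depths.

**Somatic filter cascade** (all thresholds configurable, defaults shown):
a variant is excluded when its population allele frequency exceeds
0.02; when the normal sample has fewer than 10 total reads; when the
normal sample has any mutant read (germline evidence); or when either
tumor sample has fewer than 10 total reads. The remaining variants
with ≥ 2 mutant reads in the primary or the resistant tumor are
somatic.

**Treatment-related classification**: a somatic variant is
treatment-related when

    MRF_resistant ≥ 0.20   and   MRF_resistant ≥ 2 × MRF_primary

(both boundaries inclusive; a zero or undefined primary MRF satisfies
the fold rule). A treatment-related variant with fewer than 2 mutant
reads in the primary tumor is additionally *resistant-only*. Patients
whose resistance is already explained by a catalogued on-target
gatekeeper mutation (shipped catalog: *ALK* G1269A) are excluded from
the downstream gene lists.

**CADD bins**: scores ≥ 20 are deleterious, [10, 20) possibly
deleterious, < 10 non-deleterious; frameshift indels without a score
are deleterious by override.

**Pathway over-representation**: hypergeometric upper tail
p = P(X ≥ k) for k query genes hitting a K-member pathway in an
N-gene universe, reported with the enrichment score −ln(p)
(score 3.0 ⇔ p = 0.05). Includes a second pass over EMT-tagged
pathways regardless of significance and cross-patient intersection of
enriched pathways.

**Pseudo-probe copy number**: 2–5 kb coverage bins with ≥ 1× mean
coverage become probes; tumor/reference log2 ratios (pooled-median
normal reference, GC-decile normalization) are segmented with circular
binary segmentation (seeded permutation test) and compared between
primary and resistant samples at named loci.

**Cross-platform concordance**: a variant is evaluable on a validation
platform at ≥ 10× coverage and confirmed with ≥ 1 mutant read;
platforms combine by any-platform disjunction.

A synthetic cohort generator (`triowes.simulate`) produces
trio VCFs, annotation tables, GMT catalogs, coverage tables and
validation read sets with known ground truth, so every stage is
testable without patient data.

## Worked example

```
$ triowes simulate --outdir bundle --seed 5 --patients 2 --variants 50 > /dev/null
$ triowes run-all --bundle bundle --outdir out --seed 5 --no-cna > /dev/null
$ triowes report --manifest out/manifest.json
{
 "classify/P00": {
  "resistant_only": 8,
  "somatic": 25,
  "treatment_related": 9,
  ...
 },
 "filter/P00": {
  "excluded_germline_evidence": 12,
  "excluded_low_normal_depth": 0,
  "excluded_low_tumor_depth": 0,
  "excluded_population": 13,
  "not_somatic": 0,
  "somatic": 25
 },
 ...
}
```

Of patient P00's 50 simulated variants, 25 are excluded by the cascade
(12 with germline evidence in the normal sample, 13 known
polymorphisms), 25 are somatic, and 9 of those fall in the
treatment-related region of the MRF plane — 8 of them with no
qualifying mutant reads in the primary tumor. Each stage also writes
its full per-variant table (`P00.filter_outcomes.tsv`,
`P00.mrf_scatter.tsv`, `P00.enrichment.tsv`, …) under `out/`.

The same stages are importable as functions:

```python
from triowes import (CohortConfig, generate_patient_trio, filter_cohort,
                     classify_treatment_related)
records, truth = generate_patient_trio(CohortConfig(seed=5), 0)
somatic, outcomes = filter_cohort(records)
flags = [classify_treatment_related(r) for r in somatic
         if r.mrf_resistant is not None]
```

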