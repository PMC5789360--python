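"""Synthetic paired-trio cohort generator with known ground truth.

Generates, per patient, a normal/primary/resistant variant table, the
matching annotation, coverage-bin tables with planted copy-number
states, and cross-platform validation read sets — everything the
downstream stages consume, with truth labels for recovery testing.

Generative model
----------------
* Depth per sample per variant: negative binomial with mean
  ``depth_mean`` (default 66 reads, a typical deep FFPE exome) and
  dispersion ``depth_dispersion`` (default 3; smaller = heavier
  low-coverage tail, matching the overdispersion of archival material).
* Mutant reads: binomial(depth, true MRF).
* Germline variants: true MRF near 0.5 in all three samples (diploid
  heterozygous), often with a population allele frequency.
* Stable somatic variants: zero normal MRF, one true MRF shared by the
  primary and resistant samples, drawn from a beta law.
* Treatment-related variants: true resistant MRF uniform on
  [0.35, 0.70]; a ``frac_resistant_only`` share has zero primary MRF,
  the rest have primary MRF = resistant / ``resistant_mrf_boost``
  (default 3), so by construction the expected resistant MRF clears
  both the 0.20 floor and the two-fold rule with margin.
* Gene labels: treatment-related variants draw their gene from a
  planted pathway with probability ``planted_enrichment``, giving the
  enrichment stage a recoverable signal.
* Coverage bins: widths uniform on [2 kb, 5 kb]; expected coverage =
  baseline x (copy_number / 2) x exp(gc_bias_slope x (gc - 0.5)) x
  multiplicative log-normal noise.  The planted copy-number states
  apply to the resistant sample; normal and primary are neutral.
  GC bias is applied to tumor samples only (the pooled normal
  reference is unbiased, as for frozen-vs-FFPE comparisons).

All randomness flows from ``numpy.random.default_rng`` seeded from
(config.seed, patient_index, stream) tuples; identical config and seed
give bit-identical output bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as tio
from .model import (
    CoverageBin,
    GeneSet,
    SimTruth,
    SampleObservation,
    ValidationObservation,
    VariantRecord,
)

_CONSEQUENCES_SNV = ("missense_variant", "synonymous_variant", "stop_gained")
_CONSEQUENCES_SNV_P = (0.70, 0.20, 0.10)
_BASES = ("A", "C", "G", "T")

DEFAULT_GENOME: dict[str, int] = {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
# resistant-sample truth: a gain on chr2 and a loss on chr3
DEFAULT_CNA_STATES: tuple[tuple[str, int, int, int], ...] = (
    ("chr2", 300_000, 600_000, 4),
    ("chr3", 200_000, 500_000, 1),
)


def default_pathway_catalog(
    n_pathways: int = 10, genes_per_pathway: int = 20
) -> list[GeneSet]:
    """Deterministic synthetic catalog: PW01..PWnn with disjoint members."""
    catalog = []
    for p in range(1, n_pathways + 1):
        genes = [f"PW{p:02d}G{g:02d}" for g in range(1, genes_per_pathway + 1)]
        catalog.append(GeneSet.from_iterable(f"PW{p:02d}", genes, tag="synthetic"))
    return catalog


def background_genes(n: int = 200) -> list[str]:
    return [f"BG{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort (see module docstring)."""

    n_patients: int = 4
    n_variants_per_patient: int = 150
    frac_germline: float = 0.50
    frac_treatment_related: float = 0.15
    frac_resistant_only: float = 0.75  # share of treatment-related without primary MRF
    depth_mean: float = 66.0
    depth_dispersion: float = 3.0
    primary_mrf_beta: tuple[float, float] = (2.0, 5.0)
    resistant_mrf_range: tuple[float, float] = (0.35, 0.70)
    resistant_mrf_boost: float = 3.0
    cadd_gamma: tuple[float, float] = (2.2, 5.5)  # shape, scale; mean ~12
    frac_indel: float = 0.08
    planted_enrichment: float = 0.5
    planted_pathway_index: int = 0
    pathway_catalog: tuple[GeneSet, ...] = field(
        default_factory=lambda: tuple(default_pathway_catalog())
    )
    n_background_genes: int = 200
    genome: tuple[tuple[str, int], ...] = tuple(DEFAULT_GENOME.items())
    cna_states: tuple[tuple[str, int, int, int], ...] = DEFAULT_CNA_STATES
    gc_bias_slope: float = 0.6
    cna_baseline_coverage: float = 60.0
    cna_noise_sd: float = 0.15  # sd of log2 multiplicative noise
    gatekeeper_patients: tuple[int, ...] = ()
    validation_depth_mean: float = 50.0
    validation_depth_dispersion: float = 5.0
    validation_miss_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_germline",
            "frac_treatment_related",
            "frac_resistant_only",
            "frac_indel",
            "planted_enrichment",
            "validation_miss_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_germline + self.frac_treatment_related > 1.0 + 1e-12:
            raise ValueError("frac_germline + frac_treatment_related must be <= 1")
        if self.resistant_mrf_boost < 1.0:
            raise ValueError("resistant_mrf_boost must be >= 1")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth law parameters must be positive")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _cn in self.cna_states:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping cna_states on {chrom}")

    @property
    def all_genes(self) -> list[str]:
        genes: list[str] = []
        for gs in self.pathway_catalog:
            genes.extend(sorted(gs.members))
        genes.extend(background_genes(self.n_background_genes))
        return genes

    @property
    def planted_pathway(self) -> GeneSet:
        return self.pathway_catalog[self.planted_pathway_index]


def _nb_depths(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``k`` (var = m + m^2/k)."""
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def _draw_observation(
    rng: np.random.Generator, depth_mean: float, k: float, true_mrf: float
) -> SampleObservation:
    depth = int(_nb_depths(rng, depth_mean, k, 1)[0])
    mutant = int(rng.binomial(depth, true_mrf)) if depth > 0 else 0
    return SampleObservation(total_reads=depth, mutant_reads=mutant)


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _random_indel(rng: np.random.Generator) -> tuple[str, str, bool]:
    """(ref, alt, frameshift) for a small insertion or deletion."""
    frameshift = bool(rng.random() < 0.6)
    length = int(rng.integers(1, 4))
    if frameshift and length % 3 == 0:
        length += 1
    if not frameshift:
        length = 3
    tail = "".join(_BASES[rng.integers(4)] for _ in range(length))
    anchor = _BASES[rng.integers(4)]
    if rng.random() < 0.5:
        return anchor + tail, anchor, frameshift  # deletion
    return anchor, anchor + tail, frameshift  # insertion


def generate_patient_trio(
    config: CohortConfig, patient_index: int
) -> tuple[list[VariantRecord], SimTruth]:
    """Generate one patient's trio variant table and its ground truth."""
    if not (0 <= patient_index < config.n_patients):
        raise ValueError("patient_index out of range")
    rng = np.random.default_rng((config.seed, patient_index, 1))
    patient = f"P{patient_index:02d}"
    n = config.n_variants_per_patient
    n_germ = int(round(config.frac_germline * n))
    n_tr = int(round(config.frac_treatment_related * n))
    n_tr = min(n_tr, n - n_germ)
    n_stable = n - n_germ - n_tr
    labels = (
        ["germline"] * n_germ
        + ["somatic_treatment_related"] * n_tr
        + ["somatic_stable"] * n_stable
    )
    rng.shuffle(labels)

    catalog_membership: dict[str, set[str]] = {}
    for gs in config.pathway_catalog:
        for g in gs.members:
            catalog_membership.setdefault(g, set()).add(gs.name)
    gene_pool = config.all_genes
    planted = sorted(config.planted_pathway.members)

    genome = dict(config.genome)
    chroms = list(genome)
    records: list[VariantRecord] = []
    truth = SimTruth(patient=patient, patient_index=patient_index)
    truth.cna_truth = [tuple(t) for t in config.cna_states]
    gatekeeper_pending = patient_index in config.gatekeeper_patients

    for i, label in enumerate(labels):
        vid = f"{patient}_v{i:05d}"
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, genome[chrom]))
        is_indel = bool(rng.random() < config.frac_indel)
        if is_indel:
            ref, alt, frameshift = _random_indel(rng)
            consequence = "frameshift_variant" if frameshift else "inframe_indel"
            cadd: Optional[float] = None
        else:
            ref, alt = _random_snv(rng)
            consequence = str(
                rng.choice(_CONSEQUENCES_SNV, p=_CONSEQUENCES_SNV_P)
            )
            shape, scale = config.cadd_gamma
            cadd = float(rng.gamma(shape, scale)) if rng.random() >= 0.02 else None

        if label == "germline":
            true_mrf = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
            mrf_n, mrf_p, mrf_r = true_mrf, true_mrf, true_mrf
            pop_af = float(rng.uniform(0.0, 0.5)) if rng.random() < 0.5 else None
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
        elif label == "somatic_stable":
            a, b = config.primary_mrf_beta
            true_mrf = float(np.clip(rng.beta(a, b), 0.08, 0.90))
            mrf_n, mrf_p, mrf_r = 0.0, true_mrf, true_mrf
            pop_af = float(rng.uniform(0.0, 0.01)) if rng.random() < 0.05 else None
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
        else:  # somatic_treatment_related
            lo, hi = config.resistant_mrf_range
            mrf_r = float(rng.uniform(lo, hi))
            if rng.random() < config.frac_resistant_only:
                mrf_p = 0.0
            else:
                mrf_p = mrf_r / config.resistant_mrf_boost
            mrf_n = 0.0
            pop_af = None
            if rng.random() < config.planted_enrichment:
                gene = planted[int(rng.integers(len(planted)))]
            else:
                gene = gene_pool[int(rng.integers(len(gene_pool)))]

        protein_change: Optional[str] = None
        if label == "somatic_treatment_related" and gatekeeper_pending:
            gene, protein_change = "ALK", "G1269A"
            ref, alt = _random_snv(rng)
            consequence, cadd, is_indel = "missense_variant", 28.0, False
            gatekeeper_pending = False

        k = config.depth_dispersion
        rec = VariantRecord(
            variant_id=vid,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            consequence=consequence,
            cadd=cadd,
            pop_af=pop_af,
            protein_change=protein_change,
            normal=_draw_observation(rng, config.depth_mean, k, mrf_n),
            primary=_draw_observation(rng, config.depth_mean, k, mrf_p),
            resistant=_draw_observation(rng, config.depth_mean, k, mrf_r),
        )
        records.append(rec)
        truth.true_class[vid] = label
        truth.true_gene[vid] = gene
        truth.true_pathways[vid] = frozenset(catalog_membership.get(gene, set()))
        truth.true_mrf_resistant[vid] = mrf_r

    return records, truth


def _copy_number_at(
    states: Sequence[tuple[str, int, int, int]], chrom: str, start: int, end: int
) -> int:
    for s_chrom, s_start, s_end, cn in states:
        if s_chrom == chrom and start < s_end and end > s_start:
            return cn
    return 2


def _bin_grid(config: CohortConfig, rng: np.random.Generator) -> list[tuple[str, int, int, float]]:
    grid = []
    for chrom, length in config.genome:
        pos = 0
        while pos < length:
            width = int(rng.integers(2_000, 5_001))
            end = min(pos + width, length)
            if end - pos >= 2_000:
                gc = float(np.clip(rng.normal(0.45, 0.08), 0.2, 0.8))
                grid.append((chrom, pos, end, gc))
            pos = end
    return grid


def generate_coverage_bins(
    config: CohortConfig, patient_index: int = 0
) -> dict[str, list[CoverageBin]]:
    """Coverage-bin tables for the trio, on a shared bin grid.

    The planted copy-number states shape the resistant sample; the
    normal and primary samples are copy-neutral.  GC bias applies to
    the two tumor samples.
    """
    rng = np.random.default_rng((config.seed, patient_index, 2))
    grid = _bin_grid(config, rng)
    out: dict[str, list[CoverageBin]] = {}
    for sample in ("normal", "primary", "resistant"):
        slope = config.gc_bias_slope if sample != "normal" else 0.0
        bins = []
        for chrom, start, end, gc in grid:
            cn = (
                _copy_number_at(config.cna_states, chrom, start, end)
                if sample == "resistant"
                else 2
            )
            expected = (
                config.cna_baseline_coverage
                * (cn / 2.0)
                * float(np.exp(slope * (gc - 0.45)))
            )
            noise = float(2.0 ** rng.normal(0.0, config.cna_noise_sd))
            bins.append(
                CoverageBin(
                    chrom=chrom,
                    start=start,
                    end=end,
                    gc=gc,
                    mean_coverage=expected * noise,
                )
            )
        out[sample] = bins
    return out


def generate_normal_pool(
    config: CohortConfig, n_samples: int = 4
) -> list[list[CoverageBin]]:
    """Independent copy-neutral normal samples on the patient-0 bin grid."""
    rng = np.random.default_rng((config.seed, 0, 2))
    grid = _bin_grid(config, rng)
    pool_rng = np.random.default_rng((config.seed, 0, 3))
    tables = []
    for _ in range(n_samples):
        bins = [
            CoverageBin(
                chrom=chrom,
                start=start,
                end=end,
                gc=gc,
                mean_coverage=config.cna_baseline_coverage
                * float(2.0 ** pool_rng.normal(0.0, config.cna_noise_sd)),
            )
            for chrom, start, end, gc in grid
        ]
        tables.append(bins)
    return tables


def generate_validation_reads(
    truth: SimTruth,
    config: CohortConfig,
    platforms: Sequence[str] = ("rnaseq", "wes2"),
) -> list[ValidationObservation]:
    """Independent platform read counts at every somatic truth position.

    Depth is negative-binomial per platform; mutant reads are binomial
    in the resistant-sample true MRF.  With probability
    ``validation_miss_rate`` a variant is missed entirely (zero mutant
    reads) regardless of depth, emulating platform dropout.  Positions
    below the 10x evaluability floor arise naturally from the depth law.
    """
    rng = np.random.default_rng((config.seed, truth.patient_index, 4))
    mrf_map = truth.true_mrf_resistant
    out: list[ValidationObservation] = []
    somatic = [
        vid
        for vid, label in truth.true_class.items()
        if label in ("somatic_stable", "somatic_treatment_related")
    ]
    for platform in platforms:
        for vid in somatic:
            depth = int(
                _nb_depths(
                    rng,
                    config.validation_depth_mean,
                    config.validation_depth_dispersion,
                    1,
                )[0]
            )
            mrf = float(mrf_map.get(vid, 0.0))
            missed = rng.random() < config.validation_miss_rate
            mutant = 0 if (missed or depth == 0) else int(rng.binomial(depth, mrf))
            out.append(
                ValidationObservation(
                    variant_id=vid,
                    platform=platform,
                    total_reads=depth,
                    mutant_reads=mutant,
                )
            )
    return out


def generate_cohort(
    config: CohortConfig,
) -> dict[str, tuple[list[VariantRecord], SimTruth]]:
    return {
        f"P{i:02d}": generate_patient_trio(config, i)
        for i in range(config.n_patients)
    }


def write_bundle(config: CohortConfig, outdir: str | Path) -> dict[str, list[str]]:
    """Write the full synthetic bundle (VCFs, annotation, GMT, coverage,
    validation, truth) to ``outdir``; returns the manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {
        "vcf": [], "annotation": [], "coverage": [], "validation": [], "truth": [],
        "gene_sets": [],
    }
    gmt_path = outdir / "pathways.gmt"
    tio.write_gene_sets(list(config.pathway_catalog), gmt_path)
    manifest["gene_sets"].append(str(gmt_path))
    for i in range(config.n_patients):
        patient = f"P{i:02d}"
        records, truth = generate_patient_trio(config, i)
        vcf = outdir / f"{patient}.trio.vcf"
        ann = outdir / f"{patient}.annotation.tsv"
        tru = outdir / f"{patient}.truth.json"
        val = outdir / f"{patient}.validation.tsv"
        tio.write_vcf_trio(records, vcf)
        tio.write_annotation_table(records, ann)
        tio.write_truth(truth, tru)
        tio.write_validation_table(generate_validation_reads(truth, config), val)
        manifest["vcf"].append(str(vcf))
        manifest["annotation"].append(str(ann))
        manifest["truth"].append(str(tru))
        manifest["validation"].append(str(val))
        coverage = generate_coverage_bins(config, i)
        for sample, bins in coverage.items():
            cov = outdir / f"{patient}.{sample}.coverage.tsv"
            tio.write_coverage_table(bins, cov)
            manifest["coverage"].append(str(cov))
    return manifest


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
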