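"""End-to-end pipeline: filter -> classify -> enrich -> CNA -> concordance.

Operates on a bundle directory laid out the way
:func:`triowes.simulate.write_bundle` writes it (and the way external
inputs should be arranged):

    <bundle>/pathways.gmt
    <bundle>/<patient>.trio.vcf
    <bundle>/<patient>.annotation.tsv
    <bundle>/<patient>.validation.tsv          (optional)
    <bundle>/<patient>.{normal,primary,resistant}.coverage.tsv  (optional)

Every stage writes its table into the output directory; the run
manifest records outputs, row counts and SHA-256 checksums, and the
effective configuration is serialized next to the outputs so a run is
reproducible from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as tio
from .cna import (
    SegmentationParams,
    compare_calls,
    compute_log2_ratios,
    gc_normalize_probes,
    retain_bins,
    segment,
)
from .concordance import ConcordanceConfig, combine_platforms, evaluate_platform
from .enrichment import enrich_all, shared_pathways
from .filtering import FilterConfig, filter_cohort, summarize_verdicts
from .model import VariantRecord
from .resistance import (
    ResistanceConfig,
    classify_resistant_only,
    classify_treatment_related,
    exclude_gatekeeper_patients,
    summarize_cadd_distribution,
)

log = logging.getLogger("triowes")


@dataclass
class PipelineConfig:
    bundle_dir: str
    output_dir: str
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    resistance_config: ResistanceConfig = field(default_factory=ResistanceConfig)
    concordance_config: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05
    universe_mode: str = "cohort"  # cohort | catalog
    seed: int = 0
    run_cna: bool = True
    run_concordance: bool = True

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_mrf_scatter(
    records: Sequence[VariantRecord],
    config: ResistanceConfig | None = None,
) -> pd.DataFrame:
    """Scatter-plot table of primary vs resistant MRFs for somatic variants.

    One row per variant: both MRFs plus whether the variant falls inside
    the treatment-related region (resistant MRF >= floor and >= fold x
    primary MRF).
    """
    cfg = config or ResistanceConfig()
    rows = []
    for rec in records:
        mrf_r = rec.mrf_resistant
        flagged = (
            classify_treatment_related(rec, cfg) if mrf_r is not None else False
        )
        rows.append(
            {
                "variant_id": rec.variant_id,
                "mrf_primary": rec.mrf_primary,
                "mrf_resistant": mrf_r,
                "treatment_related": flagged,
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "mrf_primary", "mrf_resistant", "treatment_related"]
    )


def _load_patients(bundle: Path) -> dict[str, list[VariantRecord]]:
    patients: dict[str, list[VariantRecord]] = {}
    for vcf in sorted(bundle.glob("*.trio.vcf")):
        patient = vcf.name.replace(".trio.vcf", "")
        records = tio.read_vcf_trio(vcf)
        ann_path = bundle / f"{patient}.annotation.tsv"
        if ann_path.exists():
            records = tio.annotate_records(records, tio.read_annotation_table(ann_path))
        patients[patient] = records
    if not patients:
        raise FileNotFoundError(f"no *.trio.vcf found in {bundle}")
    return patients


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    bundle = Path(config.bundle_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "counts": {}, "checksums": {}}

    (outdir / "effective_config.json").write_text(config.to_json())

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        manifest["checksums"][name] = _sha256(path)

    # stage: load + filter -------------------------------------------------
    t0 = time.perf_counter()
    try:
        patients = _load_patients(bundle)
    except Exception as exc:  # contract: stage-named error context
        raise RuntimeError(f"stage load: {exc}") from exc
    somatic_by_patient: dict[str, list[VariantRecord]] = {}
    for patient, records in patients.items():
        somatic, outcomes = filter_cohort(records, config.filter_config)
        somatic_by_patient[patient] = somatic
        path = outdir / f"{patient}.filter_outcomes.tsv"
        tio.write_filter_outcomes(outcomes, path)
        emit(f"filter/{patient}", path)
        manifest["counts"][f"filter/{patient}"] = summarize_verdicts(outcomes)
        log.info(
            "filter %s: %d variants -> %d somatic", patient, len(records), len(somatic)
        )
    manifest["stages"]["filter"] = time.perf_counter() - t0

    # stage: classify ------------------------------------------------------
    t0 = time.perf_counter()
    treatment_by_patient: dict[str, list[VariantRecord]] = {}
    for patient, somatic in somatic_by_patient.items():
        treatment = [
            rec
            for rec in somatic
            if rec.mrf_resistant is not None
            and classify_treatment_related(rec, config.resistance_config)
        ]
        treatment_by_patient[patient] = treatment
        resistant_only = [
            rec.variant_id
            for rec in treatment
            if classify_resistant_only(
                rec, config.filter_config, config.resistance_config
            )
        ]
        scatter = export_mrf_scatter(somatic, config.resistance_config)
        path = outdir / f"{patient}.mrf_scatter.tsv"
        scatter.to_csv(path, sep="\t", index=False)
        emit(f"scatter/{patient}", path)
        counts, percents = summarize_cadd_distribution(treatment)
        manifest["counts"][f"classify/{patient}"] = {
            "somatic": len(somatic),
            "treatment_related": len(treatment),
            "resistant_only": len(resistant_only),
            "cadd_counts": counts,
            "cadd_percent": percents,
        }
    retained, excluded = exclude_gatekeeper_patients(
        treatment_by_patient, config.resistance_config
    )
    manifest["counts"]["gatekeeper_excluded"] = excluded
    gene_lists = {
        patient: sorted({rec.gene for rec in records if rec.gene})
        for patient, records in retained.items()
    }
    path = outdir / "treatment_related_genes.tsv"
    pd.DataFrame(
        [(p, g) for p, genes in gene_lists.items() for g in genes],
        columns=["patient", "gene"],
    ).to_csv(path, sep="\t", index=False)
    emit("gene_lists", path)
    manifest["stages"]["classify"] = time.perf_counter() - t0

    # stage: enrich --------------------------------------------------------
    t0 = time.perf_counter()
    catalog = tio.read_gene_sets(bundle / "pathways.gmt")
    if config.universe_mode == "cohort":
        universe = {
            rec.gene
            for records in patients.values()
            for rec in records
            if rec.gene
        }
    elif config.universe_mode == "catalog":
        universe = set().union(*(gs.members for gs in catalog))
    else:
        raise RuntimeError(f"stage enrich: unknown universe_mode {config.universe_mode!r}")
    per_patient_results = {}
    for patient, genes in gene_lists.items():
        query = [g for g in genes if g in universe]
        if not query:
            continue
        results = enrich_all(query, catalog, universe, alpha=config.alpha)
        per_patient_results[patient] = results
        path = outdir / f"{patient}.enrichment.tsv"
        tio.write_enrichment_results(results, path)
        emit(f"enrich/{patient}", path)
        manifest["counts"][f"enrich/{patient}"] = {
            "tested": len(results),
            "significant": sum(r.significant for r in results),
        }
    if len(per_patient_results) >= 2:
        manifest["counts"]["shared_pathways"] = sorted(
            shared_pathways(per_patient_results, mode="overlap")
        )
    manifest["stages"]["enrich"] = time.perf_counter() - t0

    # stage: cna -----------------------------------------------------------
    if config.run_cna:
        t0 = time.perf_counter()
        for patient in patients:
            cov = {
                sample: bundle / f"{patient}.{sample}.coverage.tsv"
                for sample in ("normal", "primary", "resistant")
            }
            if not all(p.exists() for p in cov.values()):
                continue
            tables = {s: tio.read_coverage_table(p) for s, p in cov.items()}
            reference = retain_bins(tables["normal"])
            keep = {(b.chrom, b.start) for b in reference}
            for sample in ("primary", "resistant"):
                tumor = [
                    b
                    for b in retain_bins(tables[sample])
                    if (b.chrom, b.start) in keep
                ]
                ref = [
                    b
                    for b in reference
                    if (b.chrom, b.start) in {(t.chrom, t.start) for t in tumor}
                ]
                probes = gc_normalize_probes(compute_log2_ratios(tumor, ref))
                segs = segment(probes, config.segmentation)
                path = outdir / f"{patient}.{sample}.segments.tsv"
                tio.write_segments(segs, path)
                emit(f"cna/{patient}/{sample}", path)
                manifest["counts"][f"cna/{patient}/{sample}"] = len(segs)
        manifest["stages"]["cna"] = time.perf_counter() - t0

    # stage: concordance ---------------------------------------------------
    if config.run_concordance:
        t0 = time.perf_counter()
        for patient, somatic in somatic_by_patient.items():
            val_path = bundle / f"{patient}.validation.tsv"
            if not val_path.exists():
                continue
            observations = tio.read_validation_table(val_path)
            platforms = sorted({o.platform for o in observations})
            per_platform = {}
            report = {}
            for platform in platforms:
                summary = evaluate_platform(
                    somatic,
                    [o for o in observations if o.platform == platform],
                    config.concordance_config,
                )
                per_platform[platform] = summary.per_variant
                report[platform] = {
                    "evaluable": summary.evaluable,
                    "confirmed": summary.confirmed,
                    "percent": summary.percent,
                }
            if per_platform:
                ev, va, pct = combine_platforms(per_platform)
                report["combined"] = {
                    "evaluable": ev,
                    "validated": va,
                    "percent": pct,
                }
            path = outdir / f"{patient}.concordance.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
            emit(f"concordance/{patient}", path)
            manifest["counts"][f"concordance/{patient}"] = report
        manifest["stages"]["concordance"] = time.perf_counter() - t0

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def compare_patient_cna(
    primary_segments, resistant_segments, loci: Optional[Sequence] = None
):
    """Thin wrapper over :func:`triowes.cna.compare_calls` for named loci."""
    return compare_calls(primary_segments, resistant_segments, loci or [])
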