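"""Readers and writers for the formats the pipeline touches.

* VCF 4.2 trios (samples NORMAL/PRIMARY/RESISTANT with FORMAT DP and AD)
  via pysam.
* Annotation tables, coverage-bin tables, validation read-count tables
  and result tables as TSV via pandas.
* Gene-set catalogs as GMT (name, description, tab-separated members).
* Simulation ground truth as JSON.

All readers accept gzip-compressed files.  Variant positions are
1-based (VCF convention); coverage bins are 0-based half-open.

The mutant-read-frequency denominator is the sum of the AD entries of a
sample, not its DP field: the numerator (mutant reads) comes from AD,
so the denominator must too.  A sample with no AD entry yields an
absent observation — DP alone cannot supply a mutant-read count.
"""

from __future__ import annotations

import gzip
import json
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .cna import Segment
from .filtering import FilterOutcome
from .model import (
    CoverageBin,
    EnrichmentResult,
    GeneSet,
    SampleObservation,
    SimTruth,
    ValidationObservation,
    VariantRecord,
)

TRIO_ROLES = ("normal", "primary", "resistant")
DEFAULT_SAMPLE_ROLES = {
    "normal": "NORMAL",
    "primary": "PRIMARY",
    "resistant": "RESISTANT",
}

ANNOTATION_COLUMNS = [
    "variant_id",
    "gene",
    "consequence",
    "protein_change",
    "cadd",
    "pop_af",
]
COVERAGE_COLUMNS = ["chrom", "start", "end", "gc", "mean_coverage"]
VALIDATION_COLUMNS = ["variant_id", "platform", "total_reads", "mutant_reads"]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# VCF trios


def write_vcf_trio(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_roles: Mapping[str, str] | None = None,
) -> None:
    """Write trio records as a VCF 4.2 with DP and AD per sample."""
    roles = dict(sample_roles or DEFAULT_SAMPLE_ROLES)
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(rec.chrom for rec in records):
        header.contigs.add(chrom)
    header.formats.add("DP", 1, "Integer", "Read depth (sum of allelic depths)")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for role in TRIO_ROLES:
        header.add_sample(roles[role])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
                id=rec.variant_id,
            )
            for role in TRIO_ROLES:
                obs: Optional[SampleObservation] = getattr(rec, role)
                sample = vrec.samples[roles[role]]
                if obs is None:
                    continue
                ref_reads = obs.total_reads - obs.mutant_reads
                sample["AD"] = (ref_reads, obs.mutant_reads)
                sample["DP"] = obs.total_reads
            out.write(vrec)


def _observation_from_ad(ad, alt_index: int) -> Optional[SampleObservation]:
    if ad is None or any(a is None for a in ad):
        return None
    total = int(sum(ad))
    mutant = int(ad[alt_index + 1])
    return SampleObservation(total_reads=total, mutant_reads=mutant)


def read_vcf_trio(
    path: str | Path, sample_roles: Mapping[str, str] | None = None
) -> list[VariantRecord]:
    """Read a trio VCF into VariantRecords, one per (site, alt allele).

    Multi-allelic sites are decomposed; AD is apportioned per alt
    allele while the total stays the sum over all alleles.  Samples
    with missing AD yield an absent observation.
    """
    roles = dict(sample_roles or DEFAULT_SAMPLE_ROLES)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        present = set(vcf.header.samples)
        for role in TRIO_ROLES:
            if role not in roles:
                raise ValueError(f"sample role {role!r} not mapped")
            if roles[role] not in present:
                raise ValueError(
                    f"sample {roles[role]!r} (role {role}) absent from VCF"
                )
        for vrec in vcf:
            alts = vrec.alts or ()
            for a, alt in enumerate(alts):
                if vrec.id and len(alts) == 1:
                    vid = vrec.id
                else:
                    base = vrec.id or f"{vrec.chrom}_{vrec.pos}"
                    vid = f"{base}_{alt}" if len(alts) > 1 else base
                obs = {}
                for role in TRIO_ROLES:
                    sample = vrec.samples[roles[role]]
                    obs[role] = _observation_from_ad(sample.get("AD"), a)
                records.append(
                    VariantRecord(
                        variant_id=vid,
                        chrom=vrec.chrom,
                        pos=vrec.pos,
                        ref=vrec.ref,
                        alt=alt,
                        normal=obs["normal"],
                        primary=obs["primary"],
                        resistant=obs["resistant"],
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Annotation tables


def write_annotation_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "variant_id": r.variant_id,
            "gene": r.gene,
            "consequence": r.consequence,
            "protein_change": r.protein_change or "",
            "cadd": "" if r.cadd is None else f"{r.cadd:.3f}",
            "pop_af": "" if r.pop_af is None else f"{r.pop_af:.6f}",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(
    path: str | Path,
) -> dict[str, dict[str, object]]:
    """Map variant_id -> annotation fields; empty cells become None."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()[:5]
        raise ValueError(f"duplicate variant_id in annotation table: {dups}")
    out: dict[str, dict[str, object]] = {}
    for row in df.itertuples(index=False):
        out[row.variant_id] = {
            "gene": row.gene,
            "consequence": row.consequence,
            "protein_change": row.protein_change or None,
            "cadd": float(row.cadd) if row.cadd != "" else None,
            "pop_af": float(row.pop_af) if row.pop_af != "" else None,
        }
    return out


def annotate_records(
    records: Sequence[VariantRecord], annotation: Mapping[str, Mapping[str, object]]
) -> list[VariantRecord]:
    """Attach annotation fields to records by variant_id (missing ids kept bare)."""
    out = []
    for rec in records:
        ann = annotation.get(rec.variant_id)
        if ann is None:
            out.append(rec)
            continue
        out.append(
            VariantRecord(
                variant_id=rec.variant_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                gene=str(ann["gene"]),
                consequence=str(ann["consequence"]),
                protein_change=ann["protein_change"],  # type: ignore[arg-type]
                cadd=ann["cadd"],  # type: ignore[arg-type]
                pop_af=ann["pop_af"],  # type: ignore[arg-type]
                normal=rec.normal,
                primary=rec.primary,
                resistant=rec.resistant,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name TAB description TAB member TAB member ...

    Duplicate members are counted once; a set with zero members is a
    format error.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set {parts[0]!r} has no members"
                )
            name, tag = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet.from_iterable(name, members, tag=tag))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.tag, *sorted(gs.members)]) + "\n")


def load_bundled_pathways() -> list[GeneSet]:
    """The pathway catalog shipped with the package.

    Fourteen EMT-related pathway fixtures plus a constructed metabolism
    set; member lists are small curated fixtures, not a KEGG snapshot.
    """
    path = resources.files("triowes.data") / "emt_pathways.gmt"
    with resources.as_file(path) as p:
        return read_gene_sets(p)


# ---------------------------------------------------------------------------
# Coverage bins


def write_coverage_table(bins: Sequence[CoverageBin], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": b.start,
                "end": b.end,
                "gc": f"{b.gc:.4f}",
                "mean_coverage": f"{b.mean_coverage:.4f}",
            }
            for b in bins
        ],
        columns=COVERAGE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> list[CoverageBin]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    return [
        CoverageBin(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            gc=float(row.gc),
            mean_coverage=float(row.mean_coverage),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Validation read counts


def write_validation_table(
    observations: Sequence[ValidationObservation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": o.variant_id,
                "platform": o.platform,
                "total_reads": o.total_reads,
                "mutant_reads": o.mutant_reads,
            }
            for o in observations
        ],
        columns=VALIDATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_validation_table(path: str | Path) -> list[ValidationObservation]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VALIDATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"validation table missing columns: {missing}")
    return [
        ValidationObservation(
            variant_id=str(row.variant_id),
            platform=str(row.platform),
            total_reads=int(row.total_reads),
            mutant_reads=int(row.mutant_reads),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Ground truth JSON


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "patient": truth.patient,
        "patient_index": truth.patient_index,
        "true_class": truth.true_class,
        "true_gene": truth.true_gene,
        "true_pathways": {k: sorted(v) for k, v in truth.true_pathways.items()},
        "true_mrf_resistant": truth.true_mrf_resistant,
        "cna_truth": [list(t) for t in truth.cna_truth],
    }
    with _open_text(path, "wt") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> SimTruth:
    with _open_text(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        patient=payload["patient"],
        patient_index=int(payload.get("patient_index", 0)),
        true_class=dict(payload["true_class"]),
        true_gene=dict(payload["true_gene"]),
        true_pathways={
            k: frozenset(v) for k, v in payload["true_pathways"].items()
        },
        true_mrf_resistant={
            k: float(v)
            for k, v in payload.get("true_mrf_resistant", {}).items()
        },
        cna_truth=[tuple(t) for t in payload["cna_truth"]],
    )


# ---------------------------------------------------------------------------
# Result tables


def write_filter_outcomes(outcomes: Sequence[FilterOutcome], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "variant_id": o.variant_id,
                "verdict": o.verdict,
                "failed_rule": o.failed_rule or "",
                "mrf_primary": "" if o.mrf_primary is None else f"{o.mrf_primary:.6f}",
                "mrf_resistant": ""
                if o.mrf_resistant is None
                else f"{o.mrf_resistant:.6f}",
            }
            for o in outcomes
        ],
        columns=["variant_id", "verdict", "failed_rule", "mrf_primary", "mrf_resistant"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": f"{r.p_value:.6g}",
                "score": f"{r.score:.4f}",
                "significant": r.significant,
                "overlap_genes": ",".join(sorted(r.overlap_genes)),
            }
            for r in results
        ],
        columns=[
            "pathway", "k", "K", "n", "N", "p_value", "score",
            "significant", "overlap_genes",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, mean_log2, n_probes, call."""
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "mean_log2": f"{s.mean_log2:.4f}",
                "n_probes": s.n_probes,
                "call": s.call,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "mean_log2", "n_probes", "call"],
    )
    df.to_csv(path, sep="\t", index=False)
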