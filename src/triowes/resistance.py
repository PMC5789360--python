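"""Treatment-related variant classification and CADD deleteriousness bins.

A somatic variant is "treatment-related" when its mutant read frequency
(MRF) in the resistant sample is at least ``min_resistant_mrf`` (default
0.20) and at least ``min_fold_change`` (default 2.0) times the MRF in the
paired primary sample.  Both boundaries are inclusive.  A primary MRF of
zero or an undefined primary MRF satisfies the fold condition, so
variants seen only in the resistant tumor qualify whenever they clear
the 0.20 floor.

CADD bins: >= 20 deleterious, [10, 20) possibly deleterious, < 10
non-deleterious.  Frameshift INDELs without a CADD score are deleterious
by override; other scoreless variants fall in the no_score bin.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .filtering import FilterConfig, compute_mrf
from .model import VariantRecord

CADD_LABELS = ("deleterious", "possibly_deleterious", "non_deleterious", "no_score")


def _load_default_gatekeepers() -> frozenset[tuple[str, str]]:
    """Known on-target resistance mutations shipped with the package.

    The bundled catalog is an editable TSV (gene, protein_change); it is
    seeded with the ALK kinase-domain gatekeeper-region mutation G1269A
    and is meant to be extended for other targets.
    """
    path = resources.files("triowes.data") / "gatekeepers.tsv"
    entries: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.add((row["gene"], row["protein_change"]))
    return frozenset(entries)


@dataclass(frozen=True)
class ResistanceConfig:
    """Thresholds of the MRF trapezium plus the gatekeeper catalog."""

    min_resistant_mrf: float = 0.20
    min_fold_change: float = 2.0
    gatekeeper_catalog: frozenset[tuple[str, str]] = field(
        default_factory=_load_default_gatekeepers
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.min_resistant_mrf <= 1.0):
            raise ValueError("min_resistant_mrf must lie in (0, 1]")
        if self.min_fold_change < 1.0:
            raise ValueError("min_fold_change must be >= 1")


@dataclass(frozen=True)
class CaddBin:
    label: str
    basis: str

    def __post_init__(self) -> None:
        if self.label not in CADD_LABELS:
            raise ValueError(f"unknown CADD bin label {self.label!r}")


def classify_treatment_related(
    record: VariantRecord, config: ResistanceConfig | None = None
) -> bool:
    """Is the variant inside the MRF trapezium (resistant-enriched)?

    Raises ValueError when the resistant MRF is undefined — the decision
    is meaningless without resistant-sample coverage.
    """
    cfg = config or ResistanceConfig()
    mrf_r = compute_mrf(record.resistant)
    if mrf_r is None:
        raise ValueError(
            f"variant {record.variant_id}: resistant MRF undefined "
            "(no resistant-sample reads)"
        )
    mrf_p = compute_mrf(record.primary)
    if mrf_r < cfg.min_resistant_mrf:
        return False
    if mrf_p is None or mrf_p == 0.0:
        return True
    return mrf_r >= cfg.min_fold_change * mrf_p


def classify_resistant_only(
    record: VariantRecord,
    filter_config: FilterConfig | None = None,
    resistance_config: ResistanceConfig | None = None,
) -> bool:
    """Treatment-related variant with no qualifying primary-tumor evidence.

    "No qualifying evidence" means fewer mutant reads in the primary
    sample than the somatic-detection threshold, i.e. the variant would
    not have been detected in the primary tumor on its own.
    """
    fcfg = filter_config or FilterConfig()
    if not classify_treatment_related(record, resistance_config):
        return False
    mutant_primary = 0 if record.primary is None else record.primary.mutant_reads
    return mutant_primary < fcfg.min_mutant_reads_somatic


def cadd_bin(record: VariantRecord) -> CaddBin:
    """Deleteriousness bin for one variant (see module docstring)."""
    if record.cadd is None:
        if record.variant_class == "INDEL" and record.is_frameshift:
            return CaddBin("deleterious", "frameshift_override")
        return CaddBin("no_score", "absent")
    if record.cadd >= 20.0:
        return CaddBin("deleterious", "cadd_ge_20")
    if record.cadd >= 10.0:
        return CaddBin("possibly_deleterious", "cadd_10_20")
    return CaddBin("non_deleterious", "cadd_lt_10")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf.

    Exposed because percentage reporting must be reproducible and
    Python's built-in round() is banker's rounding.
    """
    return math.floor(x + 0.5)


def percentages_from_counts(
    counts: Mapping[str, int], rounding: str = "half_up"
) -> dict[str, int]:
    """Integer percentages of bin counts; empty input gives an empty dict.

    ``rounding`` selects half_up (default), half_even or floor — useful
    when reconciling percentages quoted with an unknown rounding rule.
    """
    total = sum(counts.values())
    if total == 0:
        return {}
    out: dict[str, int] = {}
    for label, count in counts.items():
        pct = 100.0 * count / total
        if rounding == "half_up":
            out[label] = round_half_up(pct)
        elif rounding == "half_even":
            out[label] = round(pct)
        elif rounding == "floor":
            out[label] = math.floor(pct)
        else:
            raise ValueError(f"unknown rounding mode {rounding!r}")
    return out


def summarize_cadd_distribution(
    records: Sequence[VariantRecord],
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts and integer (half-up) percentages per CADD bin.

    Counts always sum to the input size; percentages may not sum to 100
    because each is rounded independently.
    """
    counts = {label: 0 for label in CADD_LABELS}
    for rec in records:
        counts[cadd_bin(rec).label] += 1
    return counts, percentages_from_counts(counts)


def exclude_gatekeeper_patients(
    patients: Mapping[str, Sequence[VariantRecord]],
    config: ResistanceConfig | None = None,
) -> tuple[dict[str, list[VariantRecord]], dict[str, str]]:
    """Drop patients whose resistance is explained by an on-target mutation.

    A patient is excluded iff any of their *treatment-related* variants
    matches the gatekeeper catalog (gene, protein change).  A catalog
    mutation that fails the MRF rule does not trigger exclusion.

    Returns (retained patients, excluded patients with the reason).
    """
    cfg = config or ResistanceConfig()
    retained: dict[str, list[VariantRecord]] = {}
    excluded: dict[str, str] = {}
    for patient, records in patients.items():
        reason: Optional[str] = None
        for rec in records:
            key = (rec.gene, rec.protein_change or "")
            if key in cfg.gatekeeper_catalog and classify_treatment_related(rec, cfg):
                reason = f"gatekeeper mutation {rec.gene} {rec.protein_change}"
                break
        if reason is None:
            retained[patient] = list(records)
        else:
            excluded[patient] = reason
    return retained, excluded
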