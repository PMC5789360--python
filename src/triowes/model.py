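"""Core data model for paired tumor-normal-resistant exome analysis.

Every downstream stage (somatic filtering, treatment-related
classification, pathway enrichment, pseudo-probe copy number,
cross-platform concordance) consumes or produces these types.

Conventions
-----------
* VCF-style variant positions are 1-based; coverage bins are 0-based
  half-open intervals.
* A "mutant read frequency" (MRF) is mutant_reads / total_reads within a
  single sample; it is undefined (``None``) when total_reads == 0.
* Missing annotation values (CADD score, population allele frequency)
  are ``None``, never 0 — absence of a score is informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class SampleObservation:
    """Read counts for one sample at one variant position."""

    total_reads: int
    mutant_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.mutant_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.mutant_reads > self.total_reads:
            raise ValueError(
                f"mutant_reads ({self.mutant_reads}) exceeds total_reads "
                f"({self.total_reads})"
            )

    @property
    def mrf(self) -> Optional[float]:
        """Mutant read frequency; None when no reads cover the position."""
        if self.total_reads == 0:
            return None
        return self.mutant_reads / self.total_reads


def classify_allele_lengths(ref: str, alt: str) -> str:
    """SNV when both alleles are single bases, INDEL otherwise."""
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass
class VariantRecord:
    """One called variant with trio read counts and annotation.

    ``consequence`` uses Sequence Ontology style terms
    (e.g. ``missense_variant``, ``frameshift_variant``, ``stop_gained``);
    a variant is treated as frameshift when the term contains
    ``frameshift``.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    cadd: Optional[float] = None
    pop_af: Optional[float] = None
    protein_change: Optional[str] = None
    normal: Optional[SampleObservation] = None
    primary: Optional[SampleObservation] = None
    resistant: Optional[SampleObservation] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("CADD score must be non-negative")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError("pop_af must lie in [0, 1]")

    @property
    def variant_class(self) -> str:
        return classify_allele_lengths(self.ref, self.alt)

    @property
    def is_frameshift(self) -> bool:
        return "frameshift" in self.consequence.lower()

    @property
    def mrf_primary(self) -> Optional[float]:
        return self.primary.mrf if self.primary is not None else None

    @property
    def mrf_resistant(self) -> Optional[float]:
        return self.resistant.mrf if self.resistant is not None else None


@dataclass(frozen=True)
class GeneSet:
    """A named pathway gene set; ``tag`` is a free-text category label."""

    name: str
    members: frozenset[str]
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    @staticmethod
    def from_iterable(name: str, genes: Sequence[str], tag: str = "") -> "GeneSet":
        return GeneSet(name=name, members=frozenset(genes), tag=tag)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of a query gene list in a pathway.

    ``score`` is the Partek-style enrichment score -ln(p_value).
    """

    pathway: str
    overlap_genes: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p_value: float
    significant: bool

    @property
    def score(self) -> float:
        return -math.log(self.p_value)


@dataclass(frozen=True)
class CoverageBin:
    """A pseudo-probe: small genomic bin with mean base-wise coverage."""

    chrom: str
    start: int
    end: int
    gc: float
    mean_coverage: float
    mapq_filter_applied: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must lie in [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PseudoProbe:
    """A retained coverage bin with its GC-normalized tumor/reference log2 ratio."""

    bin: CoverageBin
    log2_ratio: float


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number interval produced by segmentation."""

    chrom: str
    start: int
    end: int
    mean_log2: float
    n_probes: int
    call: str  # loss | neutral | gain

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")
        if self.call not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class ValidationObservation:
    """Read counts at a variant position on an orthogonal platform."""

    variant_id: str
    platform: str  # rnaseq | wes2
    total_reads: int
    mutant_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_reads <= self.total_reads):
            raise ValueError("require 0 <= mutant_reads <= total_reads")


@dataclass
class SimTruth:
    """Ground-truth labels emitted by the synthetic cohort generator."""

    patient: str
    patient_index: int = 0
    true_class: dict[str, str] = field(default_factory=dict)
    true_gene: dict[str, str] = field(default_factory=dict)
    true_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    true_mrf_resistant: dict[str, float] = field(default_factory=dict)
    cna_truth: list[tuple[str, int, int, int]] = field(default_factory=list)

    def variants_of_class(self, label: str) -> list[str]:
        return [v for v, c in self.true_class.items() if c == label]


TRUE_CLASSES = ("germline", "somatic_stable", "somatic_treatment_related")
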