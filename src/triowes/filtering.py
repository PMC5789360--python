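"""Somatic variant filter cascade for tumor-normal-resistant trios.

The cascade separates germline, unevaluable and somatic variants using
read-count thresholds applied in a fixed order:

1. population:      pop_af > max_pop_af           -> excluded_population
2. normal depth:    normal total < min_normal_depth  -> excluded_low_normal_depth
3. normal evidence: normal mutant > max_normal_mutant_reads
                                                  -> excluded_germline_evidence
4. tumor depth:     primary or resistant total < min_tumor_depth
                                                  -> excluded_low_tumor_depth
5. mutant support:  >= min_mutant_reads_somatic mutant reads in primary
                    or resistant                  -> somatic, else not_somatic

All thresholds are inclusive exactly as written: a normal depth of 10
passes rule 2, a population frequency of exactly 0.02 passes rule 1.
An absent sample observation fails the corresponding depth rule.
A missing population frequency means "not a known polymorphism" and
passes rule 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import SampleObservation, VariantRecord

VERDICTS = (
    "excluded_population",
    "excluded_low_normal_depth",
    "excluded_germline_evidence",
    "excluded_low_tumor_depth",
    "not_somatic",
    "somatic",
)

# verdict -> name of the rule that failed (None when the variant survives)
_FAILED_RULE = {
    "excluded_population": "population_af",
    "excluded_low_normal_depth": "normal_depth",
    "excluded_germline_evidence": "normal_mutant_reads",
    "excluded_low_tumor_depth": "tumor_depth",
    "not_somatic": "tumor_mutant_reads",
    "somatic": None,
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter cascade."""

    min_normal_depth: int = 10
    max_normal_mutant_reads: int = 0
    min_tumor_depth: int = 10
    min_mutant_reads_somatic: int = 2
    max_pop_af: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "min_normal_depth",
            "max_normal_mutant_reads",
            "min_tumor_depth",
            "min_mutant_reads_somatic",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.max_pop_af <= 1.0):
            raise ValueError("max_pop_af must lie in [0, 1]")


@dataclass(frozen=True)
class FilterOutcome:
    """Per-variant trace of the cascade: verdict, first failing rule, MRFs."""

    variant_id: str
    verdict: str
    failed_rule: Optional[str]
    mrf_primary: Optional[float]
    mrf_resistant: Optional[float]

    @property
    def is_somatic(self) -> bool:
        return self.verdict == "somatic"


def compute_mrf(obs: Optional[SampleObservation]) -> Optional[float]:
    """Mutant read frequency of one observation; None when undefined."""
    if obs is None:
        return None
    return obs.mrf


def _total(obs: Optional[SampleObservation]) -> int:
    return 0 if obs is None else obs.total_reads


def _mutant(obs: Optional[SampleObservation]) -> int:
    return 0 if obs is None else obs.mutant_reads


def classify_somatic(
    record: VariantRecord, config: FilterConfig | None = None
) -> FilterOutcome:
    """Apply the filter cascade to one variant; every input gets a verdict."""
    cfg = config or FilterConfig()
    mrf_p = compute_mrf(record.primary)
    mrf_r = compute_mrf(record.resistant)

    if record.pop_af is not None and record.pop_af > cfg.max_pop_af:
        verdict = "excluded_population"
    elif _total(record.normal) < cfg.min_normal_depth:
        verdict = "excluded_low_normal_depth"
    elif _mutant(record.normal) > cfg.max_normal_mutant_reads:
        verdict = "excluded_germline_evidence"
    elif (
        _total(record.primary) < cfg.min_tumor_depth
        or _total(record.resistant) < cfg.min_tumor_depth
    ):
        verdict = "excluded_low_tumor_depth"
    elif (
        _mutant(record.primary) >= cfg.min_mutant_reads_somatic
        or _mutant(record.resistant) >= cfg.min_mutant_reads_somatic
    ):
        verdict = "somatic"
    else:
        verdict = "not_somatic"

    return FilterOutcome(
        variant_id=record.variant_id,
        verdict=verdict,
        failed_rule=_FAILED_RULE[verdict],
        mrf_primary=mrf_p,
        mrf_resistant=mrf_r,
    )


def filter_cohort(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], list[FilterOutcome]]:
    """Classify every record, preserving order.

    Returns the somatic subset and the full outcome trace.
    """
    cfg = config or FilterConfig()
    outcomes = [classify_somatic(rec, cfg) for rec in records]
    somatic = [rec for rec, out in zip(records, outcomes) if out.is_somatic]
    return somatic, outcomes


def summarize_verdicts(outcomes: Sequence[FilterOutcome]) -> dict[str, int]:
    counts = {v: 0 for v in VERDICTS}
    for out in outcomes:
        counts[out.verdict] += 1
    return counts
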