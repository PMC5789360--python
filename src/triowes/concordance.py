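"""Cross-platform variant validation and concordance percentages.

A variant is *evaluable* on a platform when the platform covers its
position with at least ``min_validation_depth`` reads (default 10x), and
*confirmed* when it is evaluable and carries at least
``min_confirm_mutant_reads`` mutant reads (default 1).  Per-platform
concordance is confirmed / evaluable, reported as an integer percentage
(half-up).

When combining platforms, a variant is combined-evaluable if evaluable
on at least one platform and combined-validated if confirmed on at
least one platform on which it is evaluable (any-platform disjunction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import ValidationObservation, VariantRecord
from .resistance import round_half_up


@dataclass(frozen=True)
class ConcordanceConfig:
    min_validation_depth: int = 10
    min_confirm_mutant_reads: int = 1

    def __post_init__(self) -> None:
        if self.min_validation_depth < 0 or self.min_confirm_mutant_reads < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class PlatformSummary:
    evaluable: int
    confirmed: int
    percent: Optional[int]
    per_variant: dict[str, tuple[bool, bool]]  # variant_id -> (evaluable, confirmed)


def _percent(confirmed: int, evaluable: int) -> Optional[int]:
    if evaluable == 0:
        return None
    return round_half_up(100.0 * confirmed / evaluable)


def evaluate_platform(
    variants: Sequence[VariantRecord | str],
    observations: Sequence[ValidationObservation],
    config: ConcordanceConfig | None = None,
) -> PlatformSummary:
    """Evaluability and confirmation of a variant list on one platform.

    ``variants`` may be VariantRecords or bare variant ids.  Variants
    without an observation on the platform are not evaluable.
    """
    cfg = config or ConcordanceConfig()
    ids = [v if isinstance(v, str) else v.variant_id for v in variants]
    by_id = {obs.variant_id: obs for obs in observations}
    per_variant: dict[str, tuple[bool, bool]] = {}
    evaluable = confirmed = 0
    for vid in ids:
        obs = by_id.get(vid)
        ok = obs is not None and obs.total_reads >= cfg.min_validation_depth
        hit = bool(ok) and obs.mutant_reads >= cfg.min_confirm_mutant_reads
        per_variant[vid] = (bool(ok), hit)
        evaluable += ok
        confirmed += hit
    return PlatformSummary(
        evaluable=evaluable,
        confirmed=confirmed,
        percent=_percent(confirmed, evaluable),
        per_variant=per_variant,
    )


def combine_platforms(
    per_platform: Mapping[str, Mapping[str, tuple[bool, bool]]],
) -> tuple[int, int, Optional[int]]:
    """Combined (evaluable, validated, percent) under the any-platform rule."""
    if not per_platform:
        raise ValueError("at least one platform is required")
    ids: set[str] = set()
    for table in per_platform.values():
        ids |= set(table)
    evaluable = validated = 0
    for vid in sorted(ids):
        states = [table.get(vid, (False, False)) for table in per_platform.values()]
        ev = any(e for e, _ in states)
        va = any(e and c for e, c in states)
        evaluable += ev
        validated += va
    return evaluable, validated, _percent(validated, evaluable)
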