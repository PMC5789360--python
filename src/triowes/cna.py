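"""Pseudo-probe copy-number analysis from exome coverage bins.

The pipeline turns per-bin mean coverage tables (2-5 kb bins, mean
base-wise coverage >= 1x, mapping-quality filtering applied upstream)
into GC-normalized tumor/reference log2 ratios ("pseudo-probes"),
segments them with circular binary segmentation (CBS) and compares
segment calls between the primary and resistant tumor of a patient.

Numerical choices
-----------------
* Reference pooling: each normal sample is scaled to the mean total
  coverage, then the per-bin median across samples is taken — robust to
  a single corrupted sample.
* log2 ratios use a pseudo-count of 0.5 reads on numerator and
  denominator so zero-coverage bins stay finite.
* GC normalization subtracts the median log2 ratio within GC deciles
  and restores the global median, so a genome-wide level shift is
  preserved while the GC trend is removed.
* CBS: the statistic is the two-sample pooled-variance t comparing the
  mean inside an arc (i, j) against the rest of the chromosome;
  significance by a seeded permutation test.  Calls threshold the
  segment mean (gain >= +0.3, loss <= -0.3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import CoverageBin, PseudoProbe, Segment

MIN_BIN_WIDTH = 2_000
MAX_BIN_WIDTH = 5_000
MIN_BIN_COVERAGE = 1.0
EPSILON = 0.5  # pseudo-count (reads) in log2 ratios


@dataclass(frozen=True)
class SegmentationParams:
    p_threshold: float = 0.01
    n_permutations: int = 1_000
    seed: int = 0
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    min_segment_probes: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.loss_threshold >= self.gain_threshold:
            raise ValueError("loss_threshold must be below gain_threshold")


def _check_sorted(bins: Sequence[CoverageBin]) -> None:
    for a, b in zip(bins, bins[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("bins must be sorted by (chrom, start)")


def retain_bins(bins: Sequence[CoverageBin]) -> list[CoverageBin]:
    """Keep bins meeting the width [2 kb, 5 kb] and >= 1x coverage floors."""
    _check_sorted(bins)
    return [
        b
        for b in bins
        if MIN_BIN_WIDTH <= b.width <= MAX_BIN_WIDTH
        and b.mean_coverage >= MIN_BIN_COVERAGE
    ]


def _same_grid(a: Sequence[CoverageBin], b: Sequence[CoverageBin]) -> bool:
    return len(a) == len(b) and all(
        (x.chrom, x.start, x.end) == (y.chrom, y.start, y.end) for x, y in zip(a, b)
    )


def pool_reference(
    normal_bin_tables: Sequence[Sequence[CoverageBin]],
) -> list[CoverageBin]:
    """Merge >= 2 normal coverage tables into a pooled reference.

    Samples are scaled to equal total coverage (the mean of the totals)
    before taking the per-bin median.
    """
    if len(normal_bin_tables) < 2:
        raise ValueError("pooling requires at least two normal samples")
    first = normal_bin_tables[0]
    for table in normal_bin_tables[1:]:
        if not _same_grid(first, table):
            raise ValueError("normal samples are not on the same bin grid")
    cov = np.array(
        [[b.mean_coverage for b in table] for table in normal_bin_tables], dtype=float
    )
    totals = cov.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a normal sample has zero total coverage")
    scaled = cov * (totals.mean() / totals)[:, None]
    pooled = np.median(scaled, axis=0)
    return [
        CoverageBin(
            chrom=b.chrom,
            start=b.start,
            end=b.end,
            gc=b.gc,
            mean_coverage=float(c),
            mapq_filter_applied=b.mapq_filter_applied,
        )
        for b, c in zip(first, pooled)
    ]


def compute_log2_ratios(
    tumor_bins: Sequence[CoverageBin],
    reference_bins: Sequence[CoverageBin],
    epsilon: float = EPSILON,
) -> list[PseudoProbe]:
    """log2((tumor + eps) / (reference + eps)) after total-coverage scaling."""
    if not _same_grid(tumor_bins, reference_bins):
        raise ValueError("tumor and reference are not on the same bin grid")
    t = np.array([b.mean_coverage for b in tumor_bins], dtype=float)
    r = np.array([b.mean_coverage for b in reference_bins], dtype=float)
    if t.sum() == 0 or r.sum() == 0:
        raise ValueError("zero total coverage")
    t = t * (r.sum() / t.sum())
    ratios = np.log2((t + epsilon) / (r + epsilon))
    return [
        PseudoProbe(bin=b, log2_ratio=float(x)) for b, x in zip(tumor_bins, ratios)
    ]


def gc_normalize(
    log2_ratios: Sequence[float], gc: Sequence[float], n_bins: int = 10
) -> np.ndarray:
    """Remove the GC trend from log2 ratios, preserving the overall level.

    Median-in-GC-decile correction: within each GC decile the median
    log2 ratio is subtracted, then the global median is added back.
    With fewer than 10 probes the correction is skipped with a warning.
    """
    x = np.asarray(log2_ratios, dtype=float)
    g = np.asarray(gc, dtype=float)
    if x.shape != g.shape:
        raise ValueError("log2_ratios and gc must have equal length")
    if np.any((g < 0) | (g > 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    if x.size < 10:
        warnings.warn("fewer than 10 probes: GC normalization skipped")
        return x.copy()
    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:  # essentially constant GC: nothing to correct
        return x.copy()
    idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, edges.size - 2)
    corrected = x.copy()
    for d in range(edges.size - 1):
        mask = idx == d
        if mask.any():
            corrected[mask] -= np.median(x[mask])
    return corrected + np.median(x)


def gc_normalize_probes(probes: Sequence[PseudoProbe]) -> list[PseudoProbe]:
    corrected = gc_normalize(
        [p.log2_ratio for p in probes], [p.bin.gc for p in probes]
    )
    return [
        PseudoProbe(bin=p.bin, log2_ratio=float(x)) for p, x in zip(probes, corrected)
    ]


def max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal |t| over all arcs (i, j), 0 <= i < j <= n.

    The arc statistic compares the mean of x[i:j] with the mean of the
    complement using the pooled two-sample t.  Returns (|t|, i, j);
    (0, 0, n) when no valid arc exists (n < 2 or zero variance).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0, 0, n
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    tot1, tot2 = s1[-1], s2[-1]
    # matrices over (i, j) with j > i; proper arcs leave both sides non-empty
    i_idx = np.arange(n + 1)
    m = i_idx[None, :] - i_idx[:, None]  # m[i, j] = j - i
    sum_in = s1[None, :] - s1[:, None]
    ss_in = s2[None, :] - s2[:, None]
    valid = (m >= 1) & (m <= n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_f = m.astype(float)
        m_out = n - m_f
        sum_out = tot1 - sum_in
        ss_out = tot2 - ss_in
        rss = (ss_in - sum_in**2 / m_f) + (ss_out - sum_out**2 / m_out)
        var_pooled = rss / max(n - 2, 1)
        t2 = (sum_in / m_f - sum_out / m_out) ** 2 / (
            var_pooled * (1.0 / m_f + 1.0 / m_out)
        )
    t2 = np.where(valid & np.isfinite(t2), t2, -1.0)
    flat = int(np.argmax(t2))
    i, j = divmod(flat, n + 1)
    if t2[i, j] < 0:
        return 0.0, 0, n
    return float(np.sqrt(t2[i, j])), int(i), int(j)


def _segment_array(
    x: np.ndarray, rng: np.random.Generator, params: SegmentationParams
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns probe-index intervals."""
    n = x.size
    if n < 2 * params.min_segment_probes:
        return [(0, n)]
    t_obs, i, j = max_arc_t(x)
    if t_obs == 0.0:
        return [(0, n)]
    # permutation test with early stopping: once the exceedance count
    # guarantees p > threshold the split cannot be accepted
    limit = int(np.ceil(params.p_threshold * (params.n_permutations + 1)))
    exceed = 1  # the observed statistic counts itself
    for _ in range(params.n_permutations):
        t_perm, _, _ = max_arc_t(rng.permutation(x))
        if t_perm >= t_obs:
            exceed += 1
            if exceed > limit:
                return [(0, n)]
    cuts = sorted({0, i, j, n})
    pieces = [(a, b) for a, b in zip(cuts, cuts[1:])]
    if len(pieces) == 1:
        return [(0, n)]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        out.extend((a + lo, a + hi) for lo, hi in _segment_array(x[a:b], rng, params))
    return out


def _call(mean_log2: float, params: SegmentationParams) -> str:
    if mean_log2 >= params.gain_threshold:
        return "gain"
    if mean_log2 <= params.loss_threshold:
        return "loss"
    return "neutral"


def segment(
    probes: Sequence[PseudoProbe], params: SegmentationParams | None = None
) -> list[Segment]:
    """CBS segmentation of ordered pseudo-probes, per chromosome."""
    params = params or SegmentationParams()
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    by_chrom: dict[str, list[PseudoProbe]] = {}
    for p in probes:
        by_chrom.setdefault(p.bin.chrom, []).append(p)
    for chrom, chrom_probes in by_chrom.items():
        starts = [p.bin.start for p in chrom_probes]
        if starts != sorted(starts):
            raise ValueError(f"probes on {chrom} are not position-ordered")
        x = np.array([p.log2_ratio for p in chrom_probes], dtype=float)
        for lo, hi in _segment_array(x, rng, params):
            mean = float(x[lo:hi].mean())
            segments.append(
                Segment(
                    chrom=chrom,
                    start=chrom_probes[lo].bin.start,
                    end=chrom_probes[hi - 1].bin.end,
                    mean_log2=mean,
                    n_probes=hi - lo,
                    call=_call(mean, params),
                )
            )
    return segments


def _locus_call(
    segments: Sequence[Segment], chrom: str, start: int, end: int
) -> Optional[str]:
    """Call of the segment with the largest overlap; None when uncovered."""
    best: tuple[int, str] | None = None
    for seg in segments:
        if seg.chrom != chrom:
            continue
        overlap = min(seg.end, end) - max(seg.start, start)
        if overlap > 0 and (best is None or overlap > best[0]):
            best = (overlap, seg.call)
    return best[1] if best else None


def compare_calls(
    primary_segments: Sequence[Segment],
    resistant_segments: Sequence[Segment],
    loci_of_interest: Sequence[tuple[str, str, int, int]],
) -> list[dict]:
    """Per-locus (gene, chrom, start, end) primary-vs-resistant call table.

    A locus outside both segmentations is reported as uncovered, never
    silently called neutral.
    """
    rows = []
    for gene, chrom, start, end in loci_of_interest:
        p_call = _locus_call(primary_segments, chrom, start, end)
        r_call = _locus_call(resistant_segments, chrom, start, end)
        covered = p_call is not None and r_call is not None
        rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "start": start,
                "end": end,
                "primary_call": p_call if p_call is not None else "uncovered",
                "resistant_call": r_call if r_call is not None else "uncovered",
                "covered": covered,
                "changed": covered and p_call != r_call,
            }
        )
    return rows


def changed_intervals(
    primary_segments: Sequence[Segment], resistant_segments: Sequence[Segment]
) -> list[tuple[str, int, int, str, str]]:
    """Genome-wide intervals where the primary and resistant calls differ."""
    out = []
    chroms = sorted(
        {s.chrom for s in primary_segments} & {s.chrom for s in resistant_segments}
    )
    for chrom in chroms:
        p_segs = sorted(
            (s for s in primary_segments if s.chrom == chrom), key=lambda s: s.start
        )
        r_segs = sorted(
            (s for s in resistant_segments if s.chrom == chrom), key=lambda s: s.start
        )
        edges = sorted(
            {s.start for s in p_segs}
            | {s.end for s in p_segs}
            | {s.start for s in r_segs}
            | {s.end for s in r_segs}
        )
        for a, b in zip(edges, edges[1:]):
            pc = _locus_call(p_segs, chrom, a, b)
            rc = _locus_call(r_segs, chrom, a, b)
            if pc is not None and rc is not None and pc != rc:
                out.append((chrom, a, b, pc, rc))
    return out
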