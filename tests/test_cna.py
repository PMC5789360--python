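"""Pseudo-probe copy number: retention, pooling, GC fit, CBS segmentation."""

import numpy as np
import pytest

from triowes.cna import (
    SegmentationParams,
    changed_intervals,
    compare_calls,
    compute_log2_ratios,
    gc_normalize,
    gc_normalize_probes,
    max_arc_t,
    pool_reference,
    retain_bins,
    segment,
)
from triowes.model import CoverageBin, PseudoProbe
from triowes.simulate import CohortConfig, generate_coverage_bins, generate_normal_pool


def cbin(start, width=3000, cov=30.0, gc=0.45, chrom="chr1"):
    return CoverageBin(chrom=chrom, start=start, end=start + width, gc=gc,
                       mean_coverage=cov)


def probes_from(values, chrom="chr1", spacing=3000):
    return [
        PseudoProbe(bin=cbin(i * spacing, chrom=chrom), log2_ratio=float(v))
        for i, v in enumerate(values)
    ]


# --- retention --------------------------------------------------------------

def test_retain_bins_width_and_coverage_floors():
    bins = [
        cbin(0, width=1_999),           # too narrow
        cbin(2_000, width=3_000),       # kept
        cbin(6_000, width=3_000, cov=0.5),  # under-covered
        cbin(10_000, width=5_000),      # kept (max width inclusive)
        cbin(16_000, width=5_001),      # too wide
        cbin(22_000, width=2_000, cov=1.0),  # kept (floors inclusive)
    ]
    kept = retain_bins(bins)
    assert [b.start for b in kept] == [2_000, 10_000, 22_000]
    assert retain_bins(kept) == kept  # all-valid input is identity


def test_retain_bins_requires_sorted_input():
    with pytest.raises(ValueError):
        retain_bins([cbin(5_000), cbin(0)])


# --- pooling ----------------------------------------------------------------

def test_pool_reference_median_and_idempotence():
    a = [cbin(0, cov=10.0), cbin(3_000, cov=10.0), cbin(6_000, cov=10.0)]
    assert [b.mean_coverage for b in pool_reference([a, a])] == pytest.approx(
        [10.0, 10.0, 10.0]
    )
    # equal totals: per-bin median without rescaling effects
    t1 = [cbin(0, cov=10.0), cbin(3_000, cov=110.0)]
    t2 = [cbin(0, cov=20.0), cbin(3_000, cov=100.0)]
    t3 = [cbin(0, cov=90.0), cbin(3_000, cov=30.0)]
    pooled = pool_reference([t1, t2, t3])
    assert pooled[0].mean_coverage == pytest.approx(20.0)


def test_pool_reference_contract_errors():
    a = [cbin(0), cbin(3_000)]
    with pytest.raises(ValueError):
        pool_reference([a])
    with pytest.raises(ValueError):
        pool_reference([a, [cbin(0)]])


def test_pooled_reference_robust_to_one_corrupted_sample():
    """Bin-wise |log2| < 0.2 for neutral truth even with one bad normal."""
    cfg = CohortConfig(seed=21, cna_noise_sd=0.04)
    tables = generate_normal_pool(cfg, n_samples=5)
    corrupt_idx = {i for i in range(len(tables[0])) if i % 7 == 0}
    corrupted = [
        CoverageBin(b.chrom, b.start, b.end, b.gc, b.mean_coverage * 5.0)
        if i in corrupt_idx
        else b
        for i, b in enumerate(tables[0])
    ]
    pooled = pool_reference([corrupted, *tables[1:4]])
    clean = tables[4]  # held-out copy-neutral sample on the same grid
    ratios = np.array(
        [p.log2_ratio for p in compute_log2_ratios(clean, pooled)]
    )
    assert np.max(np.abs(ratios - np.median(ratios))) < 0.2
    # mean pooling would leave a ~log2(1/2.3) dip at corrupted bins; the
    # scaled median does not single them out
    corrupt_mask = np.array([i in corrupt_idx for i in range(len(ratios))])
    assert abs(ratios[corrupt_mask].mean() - ratios[~corrupt_mask].mean()) < 0.05


# --- log2 ratios ------------------------------------------------------------

def test_log2_ratios_trivial_cases():
    ref = [cbin(0, cov=30.0), cbin(3_000, cov=30.0)]
    same = compute_log2_ratios(ref, ref)
    assert [p.log2_ratio for p in same] == pytest.approx([0.0, 0.0])
    # doubling every bin is removed by total-coverage scaling (level shift)
    double = [cbin(0, cov=60.0), cbin(3_000, cov=60.0)]
    assert [p.log2_ratio for p in compute_log2_ratios(double, ref)] == pytest.approx(
        [0.0, 0.0]
    )
    # a 2x region against a flat background shows ~log2(2) contrast
    ref4 = [cbin(i * 3_000, cov=30.0) for i in range(4)]
    tum = [cbin(0, cov=60.0)] + [cbin(i * 3_000, cov=30.0) for i in range(1, 4)]
    probes = compute_log2_ratios(tum, ref4)
    contrast = probes[0].log2_ratio - probes[1].log2_ratio
    assert contrast == pytest.approx(1.0, abs=0.05)


def test_log2_ratio_grid_mismatch_is_error():
    with pytest.raises(ValueError):
        compute_log2_ratios([cbin(0)], [cbin(3_000)])


# --- GC normalization -------------------------------------------------------

def test_gc_normalize_no_bias_is_near_identity():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.05, 200)
    gc = rng.uniform(0.3, 0.6, 200)
    out = gc_normalize(x, gc)
    assert np.max(np.abs(out - x)) < 0.05


def test_gc_normalize_removes_planted_linear_bias():
    rng = np.random.default_rng(5)
    gc = rng.uniform(0.3, 0.6, 500)
    x = 1.5 * (gc - 0.45) + rng.normal(0, 0.02, 500)
    out = gc_normalize(x, gc)
    slope = np.polyfit(gc, out, 1)[0]
    assert abs(slope) < 0.05 * 1.5  # >95% of the trend removed
    assert abs(np.polyfit(gc, x, 1)[0]) > 1.0  # the bias was really there


def test_gc_normalize_preserves_constant_shift():
    rng = np.random.default_rng(6)
    gc = rng.uniform(0.3, 0.6, 100)
    x = np.full(100, 0.8)
    out = gc_normalize(x, gc)
    assert out == pytest.approx(x)


def test_gc_normalize_skips_tiny_inputs_with_warning():
    with pytest.warns(UserWarning):
        out = gc_normalize([0.1] * 5, [0.4] * 5)
    assert list(out) == pytest.approx([0.1] * 5)


# --- CBS --------------------------------------------------------------------

def naive_max_arc_t(x):
    """Brute-force arc scan with the pooled two-sample t (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best = (0.0, 0, n)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            m = j - i
            if m == 0 or m == n:
                continue
            inside, outside = x[i:j], np.concatenate([x[:i], x[j:]])
            rss = ((inside - inside.mean()) ** 2).sum() + (
                (outside - outside.mean()) ** 2
            ).sum()
            var = rss / max(n - 2, 1)
            if var <= 0:
                continue
            t = abs(inside.mean() - outside.mean()) / np.sqrt(
                var * (1 / m + 1 / (n - m))
            )
            if t > best[0]:
                best = (t, i, j)
    return best


@pytest.mark.parametrize("seed,n", [(0, 12), (1, 25), (2, 50)])
def test_max_arc_statistic_matches_bruteforce(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    x[n // 3: 2 * n // 3] += rng.uniform(0.5, 2.0)
    t_fast, i_fast, j_fast = max_arc_t(x)
    t_slow, i_slow, j_slow = naive_max_arc_t(x)
    assert t_fast == pytest.approx(t_slow, rel=1e-9)
    assert (i_fast, j_fast) == (i_slow, j_slow)


def test_constant_signal_yields_single_segment_per_chromosome():
    probes = probes_from([0.1] * 40) + probes_from([0.0] * 30, chrom="chr2")
    segs = segment(probes, SegmentationParams(seed=1))
    assert sorted((s.chrom, s.n_probes) for s in segs) == [("chr1", 40), ("chr2", 30)]


def test_single_probe_chromosome_is_one_segment_without_test():
    segs = segment(probes_from([0.5]))
    assert len(segs) == 1 and segs[0].n_probes == 1


def test_planted_step_recovered_within_two_probes():
    """One Delta-log2 = 1.0 step over >= 30 probes -> 2 segments, +/-2 probes."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.2, 80)
        x[40:] += 1.0
        segs = segment(probes_from(x), SegmentationParams(seed=seed))
        if len(segs) == 2:
            bp = sorted(segs, key=lambda s: s.start)[1].start // 3000
            hits += abs(bp - 40) <= 2
    assert hits == 20


def test_segmentation_is_deterministic_and_scale_invariant():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 0.2, 60)
    x[30:] += 1.0
    params = SegmentationParams(seed=3)
    segs_a = segment(probes_from(x), params)
    segs_b = segment(probes_from(x), params)
    assert segs_a == segs_b
    # adding a constant (coverage scale factor in log space) moves levels only
    segs_shift = segment(probes_from(x + 0.7), params)
    assert [(s.start, s.end, s.n_probes) for s in segs_shift] == [
        (s.start, s.end, s.n_probes) for s in segs_a
    ]
    for a, b in zip(segs_a, segs_shift):
        assert b.mean_log2 == pytest.approx(a.mean_log2 + 0.7)


def test_segment_means_conserve_global_probe_mean():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 0.3, 70)
    x[20:45] += 1.2
    segs = segment(probes_from(x), SegmentationParams(seed=2))
    weighted = sum(s.mean_log2 * s.n_probes for s in segs) / sum(
        s.n_probes for s in segs
    )
    assert weighted == pytest.approx(float(np.mean(x)), rel=1e-9)


def test_calls_threshold_segment_means():
    segs = segment(probes_from([0.6] * 20), SegmentationParams(seed=0))
    assert segs[0].call == "gain"
    segs = segment(probes_from([-0.6] * 20), SegmentationParams(seed=0))
    assert segs[0].call == "loss"
    segs = segment(probes_from([0.0] * 20), SegmentationParams(seed=0))
    assert segs[0].call == "neutral"


# --- comparison -------------------------------------------------------------

def test_compare_calls_identical_planted_and_uncovered():
    rng = np.random.default_rng(10)
    base = rng.normal(0, 0.15, 60)
    gained = base.copy()
    gained[20:40] += 1.0
    params = SegmentationParams(seed=4)
    primary = segment(probes_from(base), params)
    resistant = segment(probes_from(gained), params)
    same = compare_calls(primary, primary, [("GENE", "chr1", 70_000, 75_000)])
    assert not same[0]["changed"]
    loci = [
        ("HIT", "chr1", 25 * 3000, 26 * 3000),
        ("FLAT", "chr1", 2 * 3000, 3 * 3000),
        ("GAP", "chr9", 0, 1000),
    ]
    rows = {r["gene"]: r for r in compare_calls(primary, resistant, loci)}
    assert rows["HIT"]["resistant_call"] == "gain" and rows["HIT"]["changed"]
    assert not rows["FLAT"]["changed"]
    assert rows["GAP"]["primary_call"] == "uncovered" and not rows["GAP"]["covered"]
    diffs = changed_intervals(primary, resistant)
    assert any(a <= 25 * 3000 < b for _, a, b, _, _ in diffs)


# --- generator integration --------------------------------------------------

def test_generated_neutral_genome_has_zero_expected_log2():
    cfg = CohortConfig(seed=12, cna_states=(), gc_bias_slope=0.0, cna_noise_sd=0.1)
    cov = generate_coverage_bins(cfg)
    probes = compute_log2_ratios(retain_bins(cov["resistant"]),
                                 retain_bins(cov["normal"]))
    ratios = np.array([p.log2_ratio for p in probes])
    assert abs(float(np.mean(ratios))) < 0.02


def test_generated_gain_recovered_through_full_cna_path():
    """Planted copy-4 interval segments to ~log2 ratio 1 within +/-2 bins."""
    cfg = CohortConfig(seed=13, gc_bias_slope=0.6, cna_noise_sd=0.1)
    cov = generate_coverage_bins(cfg)
    reference = retain_bins(cov["normal"])
    tumor = retain_bins(cov["resistant"])
    probes = gc_normalize_probes(compute_log2_ratios(tumor, reference))
    segs = segment(probes, SegmentationParams(seed=13))
    gains = [s for s in segs if s.chrom == "chr2" and s.call == "gain"]
    assert len(gains) == 1
    chr2 = [p.bin for p in probes if p.bin.chrom == "chr2"]
    idx = {b.start: i for i, b in enumerate(chr2)}
    truth_start_bin = min(
        (i for b, i in ((b, idx[b.start]) for b in chr2) if b.end > 300_000),
    )
    seg_start_bin = idx[gains[0].start]
    assert abs(seg_start_bin - truth_start_bin) <= 2
    assert gains[0].mean_log2 == pytest.approx(1.0, abs=0.15)
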