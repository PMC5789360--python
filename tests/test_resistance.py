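"""MRF trapezium classification, CADD binning, rounding, gatekeeper exclusion."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triowes.filtering import FilterConfig, filter_cohort
from triowes.resistance import (
    ResistanceConfig,
    cadd_bin,
    classify_resistant_only,
    classify_treatment_related,
    exclude_gatekeeper_patients,
    percentages_from_counts,
    round_half_up,
    summarize_cadd_distribution,
)
from triowes.simulate import CohortConfig, generate_patient_trio

from conftest import make_record


def rec_with_mrfs(mrf_primary, mrf_resistant, depth=100):
    return make_record(
        primary=(depth, round(mrf_primary * depth)),
        resistant=(depth, round(mrf_resistant * depth)),
    )


@pytest.mark.parametrize(
    "mrf_p,mrf_r,expected",
    [
        (0.10, 0.25, True),   # clears floor and fold
        (0.10, 0.20, True),   # both boundaries inclusive
        (0.00, 0.19, False),  # below the 0.20 floor
        (0.15, 0.25, False),  # fold change below 2
        (0.00, 0.20, True),   # resistant-only at the floor
    ],
)
def test_trapezium_worked_examples(mrf_p, mrf_r, expected):
    assert classify_treatment_related(rec_with_mrfs(mrf_p, mrf_r)) is expected


def test_absent_primary_observation_counts_as_resistant_only_side():
    rec = make_record(primary=None, resistant=(100, 30))
    assert classify_treatment_related(rec) is True
    rec = make_record(primary=(0, 0), resistant=(100, 30))
    assert classify_treatment_related(rec) is True


def test_undefined_resistant_mrf_is_an_error():
    with pytest.raises(ValueError):
        classify_treatment_related(make_record(resistant=(0, 0)))


def test_trapezium_exhaustive_lattice_oracle():
    """Decisions on a 0.01-step MRF lattice equal direct inequality evaluation."""
    cfg = ResistanceConfig()
    for pi in range(101):
        for ri in range(101):
            mrf_p, mrf_r = pi / 100.0, ri / 100.0
            rec = make_record(primary=(100, pi), resistant=(100, ri))
            expected = mrf_r >= 0.20 and (mrf_p == 0.0 or mrf_r >= 2.0 * mrf_p)
            assert classify_treatment_related(rec, cfg) is expected, (mrf_p, mrf_r)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    p=st.integers(0, 100),
    r=st.integers(0, 100),
    bump=st.integers(0, 20),
)
def test_monotone_in_resistant_mrf(p, r, bump):
    """Raising the resistant MRF never revokes treatment-related status."""
    lo = classify_treatment_related(make_record(primary=(100, p), resistant=(100, r)))
    hi = classify_treatment_related(
        make_record(primary=(100, p), resistant=(100, min(100, r + bump)))
    )
    assert lo <= hi


def test_resistant_only_requires_treatment_related_and_no_primary_evidence():
    tr_no_primary = make_record(primary=(40, 0), resistant=(40, 12))
    assert classify_resistant_only(tr_no_primary) is True
    shared = make_record(primary=(40, 5), resistant=(40, 20))
    assert classify_treatment_related(shared) is True
    assert classify_resistant_only(shared) is False
    # one mutant read in the primary is below the 2-read detection floor
    borderline = make_record(primary=(40, 1), resistant=(40, 12))
    assert classify_resistant_only(borderline) is True


def test_resistant_only_subset_of_treatment_related_over_seeds():
    fcfg, rcfg = FilterConfig(), ResistanceConfig()
    for seed in range(20):
        records, _ = generate_patient_trio(
            CohortConfig(n_variants_per_patient=300, seed=seed), 0
        )
        somatic, _ = filter_cohort(records, fcfg)
        evaluable = [r for r in somatic if r.mrf_resistant is not None]
        tr = {r.variant_id for r in evaluable if classify_treatment_related(r, rcfg)}
        ro = {
            r.variant_id
            for r in evaluable
            if classify_resistant_only(r, fcfg, rcfg)
        }
        assert ro <= tr


@pytest.mark.parametrize(
    "cadd,consequence,ref,alt,label,basis",
    [
        (20.0, "missense_variant", "A", "T", "deleterious", "cadd_ge_20"),
        (35.0, "stop_gained", "A", "T", "deleterious", "cadd_ge_20"),
        (10.0, "missense_variant", "A", "T", "possibly_deleterious", "cadd_10_20"),
        (19.99, "missense_variant", "A", "T", "possibly_deleterious", "cadd_10_20"),
        (9.99, "synonymous_variant", "A", "T", "non_deleterious", "cadd_lt_10"),
        (None, "frameshift_variant", "AT", "A", "deleterious", "frameshift_override"),
        (None, "inframe_indel", "ATTT", "A", "no_score", "absent"),
        (None, "missense_variant", "A", "T", "no_score", "absent"),
        # frameshift with a score uses the score, not the override
        (5.0, "frameshift_variant", "AT", "A", "non_deleterious", "cadd_lt_10"),
    ],
)
def test_cadd_bins(cadd, consequence, ref, alt, label, basis):
    rec = make_record(cadd=cadd, consequence=consequence, ref=ref, alt=alt)
    b = cadd_bin(rec)
    assert (b.label, b.basis) == (label, basis)


def test_cadd_bins_partition_and_permutation_invariance():
    records, _ = generate_patient_trio(
        CohortConfig(n_variants_per_patient=400, seed=2), 0
    )
    counts, percents = summarize_cadd_distribution(records)
    assert sum(counts.values()) == len(records)
    counts_rev, _ = summarize_cadd_distribution(list(reversed(records)))
    assert counts_rev == counts


def test_percentage_rounding_conventions():
    counts = {"a": 116, "b": 265, "c": 151, "d": 50}  # total 582
    half_up = percentages_from_counts(counts)
    assert half_up == {"a": 20, "b": 46, "c": 26, "d": 9}
    floor = percentages_from_counts(counts, rounding="floor")
    assert floor["b"] == 45  # 45.53 floors to the other printed convention
    assert percentages_from_counts({}) == {}
    assert summarize_cadd_distribution([]) == (
        {"deleterious": 0, "possibly_deleterious": 0,
         "non_deleterious": 0, "no_score": 0},
        {},
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 500), min_size=1, max_size=6))
def test_percentages_match_independent_arithmetic(counts):
    labelled = {f"bin{i}": c for i, c in enumerate(counts)}
    total = sum(counts)
    result = percentages_from_counts(labelled)
    if total == 0:
        assert result == {}
    else:
        for i, c in enumerate(counts):
            assert result[f"bin{i}"] == math.floor(100 * c / total + 0.5)


def test_round_half_up_ties():
    assert round_half_up(0.5) == 1
    assert round_half_up(1.5) == 2
    assert round_half_up(2.4999) == 2


def test_gatekeeper_patient_exclusion():
    gate = make_record(
        variant_id="gk", gene="ALK", protein_change="G1269A",
        primary=(40, 0), resistant=(40, 20), cadd=28.0,
    )
    benign = make_record(variant_id="x", gene="TP53", resistant=(40, 20))
    # the same catalog mutation failing the MRF rule does not exclude
    gate_low_mrf = make_record(
        variant_id="gk2", gene="ALK", protein_change="G1269A",
        primary=(40, 0), resistant=(40, 4),
    )
    retained, excluded = exclude_gatekeeper_patients(
        {"A": [gate, benign], "B": [benign], "C": [gate_low_mrf]}
    )
    assert set(excluded) == {"A"}
    assert "G1269A" in excluded["A"]
    assert set(retained) == {"B", "C"}


def test_planted_gatekeeper_recovered_from_cohort():
    cfg = CohortConfig(
        n_patients=4, n_variants_per_patient=120, gatekeeper_patients=(2,), seed=9
    )
    per_patient = {}
    for i in range(cfg.n_patients):
        records, _ = generate_patient_trio(cfg, i)
        somatic, _ = filter_cohort(records)
        per_patient[f"P{i:02d}"] = [
            r for r in somatic if r.mrf_resistant is not None
        ]
    _, excluded = exclude_gatekeeper_patients(per_patient)
    assert set(excluded) == {"P02"}
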