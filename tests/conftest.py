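import pytest

from triowes.model import SampleObservation, VariantRecord


def make_record(
    variant_id="v1",
    normal=(50, 0),
    primary=(40, 0),
    resistant=(40, 10),
    gene="GENE1",
    consequence="missense_variant",
    cadd=15.0,
    pop_af=None,
    protein_change=None,
    ref="A",
    alt="T",
):
    def obs(pair):
        return None if pair is None else SampleObservation(*pair)

    return VariantRecord(
        variant_id=variant_id,
        chrom="chr1",
        pos=100,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        cadd=cadd,
        pop_af=pop_af,
        protein_change=protein_change,
        normal=obs(normal),
        primary=obs(primary),
        resistant=obs(resistant),
    )


@pytest.fixture
def record_factory():
    return make_record
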