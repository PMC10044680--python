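import numpy as np
import pytest

from tmbcal import Consequence, Origin, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_variant(
    sample_id="S1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    consequence=Consequence.NONSYNONYMOUS,
    alt_count=30,
    depth=100,
    origin=Origin.SOMATIC,
    popmax_af=None,
    overall_af=None,
    hotspot=False,
):
    return VariantRecord(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        consequence=consequence, alt_count=alt_count, depth=depth,
        origin=origin, popmax_af=popmax_af or {}, overall_af=overall_af or {},
        hotspot=hotspot,
    )


@pytest.fixture
def variant_factory():
    return make_variant
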