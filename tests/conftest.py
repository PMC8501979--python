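import numpy as np
import pytest

from ribofork.ars import ARSRecord
from ribofork.io import RNMPLibrary, RNMPSite


def make_ars(name="ARS1", chrom="chr1", anchor=50_000, firing_time=20.0,
             efficiency=0.8, status="confirmed", half_width=100):
    return ARSRecord(
        name=name, chrom=chrom, start=anchor - half_width,
        end=anchor + half_width, anchor=anchor, firing_time=firing_time,
        efficiency=efficiency, status=status,
    )


def make_library(sites, name="lib", **kwargs):
    return RNMPLibrary(name=name, sites=[RNMPSite(*s) for s in sites],
                       **kwargs)


@pytest.fixture
def lone_ars():
    return make_ars()


@pytest.fixture
def genome_lengths():
    return {"chr1": 200_000}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
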