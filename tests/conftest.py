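import numpy as np
import pandas as pd
import pytest

from flgenomics.channels import CHANNELS
from flgenomics.signatures import kataegis_fixture_signatures, normalize_signatures


@pytest.fixture(scope="session")
def ksig():
    """Bundled K1-like / K2-like fixture pair (disjoint channel support)."""
    return kataegis_fixture_signatures()


@pytest.fixture(scope="session")
def three_signatures(ksig):
    """K1-like, K2-like, plus a C>A-concentrated third profile.

    The third signature lives on the 16 N[C>A]N channels, disjoint from both
    fixtures, so all three are mutually orthogonal.
    """
    third = pd.Series(0.0, index=list(CHANNELS), name="CA-like")
    for five in "ACGT":
        for three in "ACGT":
            third[f"{five}[C>A]{three}"] = 1.0
    sigs = pd.concat([ksig, third], axis=1)
    return normalize_signatures(sigs)


def make_mutations(positions_by_chrom, sample="S001", ref="C", alt="T", context="ACA"):
    """Mutation table from bare positions (identical channel everywhere)."""
    rows = [
        (sample, chrom, int(p), ref, alt, context)
        for chrom, positions in positions_by_chrom.items()
        for p in positions
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "context"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
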