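import numpy as np
import pandas as pd
import pytest

from spikefill.io import LibraryMeta

STAGES = (10, 15, 21, 27, 35)


@pytest.fixture
def design_meta():
    """Ten libraries: one superior and one inferior at each of five stages."""
    metas = []
    for i, s in enumerate(STAGES):
        metas.append(LibraryMeta(f"S{s}", "superior", s, 1_000_000 + i))
        metas.append(LibraryMeta(f"I{s}", "inferior", s, 1_200_000 + i))
    return metas


@pytest.fixture
def tiny_counts():
    """3 entities x 2 libraries of raw counts."""
    return pd.DataFrame(
        {"S10": [100, 0, 7], "I10": [50, 3, 0]},
        index=pd.Index(["mirA", "mirB", "mirC"], name="entity_id"),
        dtype="int64",
    )


@pytest.fixture
def tiny_meta():
    return [
        LibraryMeta("S10", "superior", 10, 10_000_000),
        LibraryMeta("I10", "inferior", 10, 5_000_000),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
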