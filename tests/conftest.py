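from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_track():
    """A 20-bin track at 500 bp with a few missing bins."""
    from dafca.types import GenomeTrack

    vals = np.arange(20, dtype=float)
    vals[[3, 4, 11]] = np.nan
    return GenomeTrack(bin_size=500, values={"chr1": vals}, chrom_lengths={"chr1": 10_000})
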