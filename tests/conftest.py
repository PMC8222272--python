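import numpy as np
import pytest

from replistress import make_genome
from replistress.synth import RTSimConfig, simulate_arrays, simulate_rt_truth


@pytest.fixture
def small_layout():
    """Two 5 Mb chromosomes at 13 kb probe spacing (384 probes each)."""
    return make_genome(2, 5_000_000, 13_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_truth(small_layout):
    cfg = RTSimConfig(shift_frac_earlier=0.0, shift_frac_later=0.0)
    return simulate_rt_truth(small_layout, cfg, seed=7), cfg
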