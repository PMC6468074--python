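import numpy as np
import pytest

from capmark import SimulationConfig, read_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20190305)


@pytest.fixture
def quartet_tree():
    return read_tree("((t1,t2),(t3,t4));")


@pytest.fixture
def small_cfg():
    """A small, fast capture configuration used across tests."""
    return SimulationConfig(
        seed=7, n_loci=8, taxa_per_group=1,
        flank_len_mean=80.0, flank_len_sd=15.0,
        exon_len_range=(90, 180),
    )
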