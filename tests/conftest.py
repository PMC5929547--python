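import numpy as np
import pytest

from pfvcat import SimConfig, simulate_panel
from pfvcat.simulate import simulate_tss


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_blocks=6, n_decoy_blocks=18, n_haplotypes=100,
                     snps_per_block=8, target_r2=0.95, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_tss(small_cfg, small_sim):
    return simulate_tss(small_cfg, small_sim.blocks)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
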