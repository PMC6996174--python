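import numpy as np
import pytest

from mhscan.fragments import filter_fragment_table
from mhscan.simulate import SimConfig, fragments_to_interval_set, simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    # 1-Mb genome keeps the unit suite fast; the acceptance tests rerun
    # the caller at full scale
    return SimConfig(
        seed=11,
        genome=(("chr1", 700_000), ("chr2", 300_000)),
        n_common_sites=50,
        n_specific_sites=50,
        n_fragments=200_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return small_cfg.chrom_sizes()


@pytest.fixture(scope="session")
def small_fragments(small_sim, small_genome):
    kept = filter_fragment_table(small_sim.fragments)
    return fragments_to_interval_set(kept, small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
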