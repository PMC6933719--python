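import numpy as np
import pytest

from numtseek.sim import (
    SimConfig,
    random_truths,
    simulate_mt_panel,
    simulate_sample,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 30x, 150 bp reads, 350 +/- 50 templates."""
    return SimConfig(
        nuclear_length=400_000,
        coverage=30,
        seed=7,
        n_modern_mt=20,
        n_neanderthal_mt=5,
        n_denisovan_mt=4,
    )


@pytest.fixture(scope="session")
def panel_sim(small_config):
    return simulate_mt_panel(small_config)


@pytest.fixture(scope="session")
def cohort_sample(small_config, panel_sim):
    """One diploid sample with five NUMTs of mixed source lineage."""
    rng = np.random.default_rng(1)
    truths = random_truths(
        small_config,
        rng,
        n_modern=2,
        n_denisovan=2,
        n_ancestral=1,
        min_length_by_lineage={"denisovan": 200},
    )
    return simulate_sample(small_config, truths, panel_sim)
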