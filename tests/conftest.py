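import numpy as np
import pytest

from ladagrs.simulate import SimulatorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Structured, related four-group cohort at reduced size."""
    cfg = SimulatorConfig(
        group_sizes={"LADA": 60, "CONTROL": 70, "T1D": 50, "T2D": 50},
        n_background_snps=300,
        fst=0.05,
        n_subpops=2,
        related_pair_fraction=0.1,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_size_cohort():
    """Study-sized groups (978/1057/2000/1960) with few background SNPs."""
    cfg = SimulatorConfig(n_background_snps=20, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
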