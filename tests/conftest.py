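import numpy as np
import pytest

from bseeker import synthetic_data as synth


@pytest.fixture(scope="session")
def default_dataset():
    """One default-fixture simulation shared by read-only tests."""
    return synth.simulate_dataset(synth.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def single_b_copy_dataset():
    """All-B-linked fixture with one B copy per gene (Alt fraction 1/3)."""
    cfg = synth.SimulationConfig(
        seed=7,
        n_genes=30,
        class_fractions={"single_copy": 10 / 30, "b_linked_UC": 20 / 30},
        b_copies=1,
        snp_rate=0.01,
    )
    return synth.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
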