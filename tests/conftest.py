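import numpy as np
import pytest

from fnwpipe import synth


@pytest.fixture(scope="session")
def small_panel():
    """500 individuals, 120 variants in AR(0.5) blocks of 6."""
    return synth.simulate_reference_panel(
        n_individuals=500, n_variants=120, block_size=6, within_block_rho=0.5, seed=11
    )


@pytest.fixture(scope="session")
def small_arch(small_panel):
    return synth.default_architecture(
        small_panel,
        n_fnw=10,
        n_bmd=8,
        n_shared_inverse=2,
        n_shared_positive=1,
        target_fnw_variance=0.076,
        seed=12,
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_arch):
    return synth.simulate_cohort(small_panel, small_arch, n=4000, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
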