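import numpy as np
import pytest

from taskdecode.synth import default_designs, simulate_cohort


@pytest.fixture(scope="session")
def designs3():
    return default_designs(3, tr=1.0, n_frames=96)


@pytest.fixture(scope="session")
def small_cohort(designs3):
    """8 subjects x 3 tasks on an 8x8x8 grid, snr 2 (shared, read-only)."""
    return simulate_cohort(
        n_subjects=8,
        designs=designs3,
        grid_dims=(8, 8, 8),
        n_networks=3,
        n_artifacts=2,
        snr=2.0,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
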