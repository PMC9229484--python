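import numpy as np
import pytest

from glucopipe import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_acq():
    """Shortened acquisition (30 s) to keep per-test signal synthesis cheap."""
    return synthetic.AcquisitionConfig(duration_s=30.0)


@pytest.fixture(scope="session")
def clean_acq():
    """Noise- and drift-free 30 s acquisition for oracle comparisons."""
    return synthetic.AcquisitionConfig(duration_s=30.0, noise_sigma=0.0,
                                       drift_amplitude=0.0)


@pytest.fixture(scope="session")
def small_cohort(short_acq):
    """Six-participant cohort with 30 s recordings, fixed seed."""
    cfg = synthetic.CohortConfig(n_participants=6, seed=11)
    return synthetic.generate_cohort(cfg, short_acq, synthetic.SweepConfig())


@pytest.fixture
def participant(rng):
    return synthetic.generate_participant(synthetic.CohortConfig(), rng, "p000")
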