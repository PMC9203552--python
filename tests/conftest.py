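import numpy as np
import pytest

from biotypeflow import motion, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """One scaled-down cohort with planted structure, shared across tests."""
    cfg = synthetic.CohortConfig(n_roi=30, n_signal_fc=20, effect_size=1.5, seed=7)
    return synthetic.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_trace():
    z = np.zeros(20)
    return motion.MotionTrace(z, z, z, z, z, z)
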