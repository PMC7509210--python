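import numpy as np
import pytest

from steerlimb.cohort import MuscleSpec, SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_specs():
    """Balanced montage for fast tests: a few coupled muscles, one lead, rest weak."""
    rows = [
        (0.6, 0.6, 0.0),
        (0.5, 0.5, 100.0),
        (0.3, 0.35, 200.0),
        (0.2, 0.2, 0.0),
        (0.15, 0.15, 0.0),
        (0.5, 0.4, 0.0),
        (0.4, 0.5, 0.0),
        (0.1, 0.1, 0.0),
        (0.1, 0.1, 0.0),
        (0.1, 0.1, 0.0),
    ]
    return tuple(MuscleSpec(g_cw=c, g_ccw=cc, d_ms=d) for c, cc, d in rows)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_subjects=3,
        duration_s=20.0,
        fs=1000.0,
        torque_period_s=5.0,
        muscle_specs=small_specs(),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """3 subjects, 20 s at 1 kHz; shared by I/O and pipeline tests."""
    return generate_cohort(small_config)
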