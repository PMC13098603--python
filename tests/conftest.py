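import numpy as np
import pytest

import fatiperc as fp


@pytest.fixture(scope="session")
def temporal_cohort():
    """Default-truth temporal cohort (30 subjects, MG4 a=0.8 b=0.5)."""
    return fp.simulate_feature_cohort(30, "temporal", seed=101)


@pytest.fixture(scope="session")
def spatial_cohort():
    return fp.simulate_feature_cohort(27, "spatial", seed=202)


@pytest.fixture(scope="session")
def small_signal_session():
    """One rendered full-signal session from a tiny cohort."""
    from fatiperc import simulate

    cohort = fp.simulate_feature_cohort(3, "temporal", seed=7)
    sess = simulate.simulate_session_signals(cohort, subject=1, group="standard", seed=11)
    return cohort, sess


def rng(seed=0):
    return np.random.default_rng(seed)
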