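import numpy as np
import pytest

from mswear.synthetic_cohort import (EffectConfig, simulate_clinic_session,
                                     simulate_subject_profile)


@pytest.fixture(scope="session")
def mid_profile():
    """A deterministic mid-disability subject profile."""
    rng = np.random.default_rng(42)
    return simulate_subject_profile("S_mid", 0.5, EffectConfig(), rng)


@pytest.fixture(scope="session")
def clinic_session(mid_profile):
    """One simulated clinic session (shortened walk test for speed)."""
    return simulate_clinic_session(mid_profile, fs=100.0, seed=7,
                                   walk_test_duration_s=30.0)
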