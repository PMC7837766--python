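import dataclasses

import numpy as np
import pytest

from dvhgru.cohort import CohortSpec, OARProfile, generate_cohort


def small_profile(noise_gy: float = 0.5, base_dose: float = 30.0) -> OARProfile:
    return OARProfile(
        base_dose=base_dose,
        beam_gammas=tuple(np.linspace(0.6, 2.0, 9)),
        beam_weights=tuple(np.linspace(0.7, 1.3, 9)),
        mix_weights=tuple(np.full(9, 1 / 9)),
        noise_gy=noise_gy,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient, single-organ cohort for fast training tests."""
    spec = CohortSpec(
        n_patients=12,
        n_train=8,
        seed=42,
        oar_profiles={"spinal_cord": small_profile()},
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless single-organ cohort: plan is an exact function of the beams."""
    spec = CohortSpec(
        n_patients=12,
        n_train=8,
        seed=7,
        oar_profiles={"spinal_cord": small_profile(noise_gy=0.0)},
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dvh(rng: np.random.Generator, scale: float = 60.0) -> np.ndarray:
    """A random valid dose-at-volume curve (non-negative, non-increasing)."""
    steps = rng.exponential(scale / 100.0, size=100)
    return np.cumsum(steps[::-1])[::-1]
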