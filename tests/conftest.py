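import numpy as np
import pytest

from cherimatch.specs import AcquisitionSpec, BeamSpec, ShiftSpec, TissueSpec
from cherimatch.simulate import simulate_condition


@pytest.fixture
def yellow():
    return TissueSpec("yellow")


@pytest.fixture
def black():
    return TissueSpec("black")


@pytest.fixture
def photon_beam():
    return BeamSpec("photon", 6.0)


@pytest.fixture
def electron_beam():
    return BeamSpec("electron", 10.0)


def noiseless_acq(beam, tissue, **overrides):
    """Acquisition settings with every noise source switched off."""
    base = dict(background_mean=0.0, background_sd=0.0, sparkle_rate=0.0, shot_noise=False)
    base.update(overrides)
    return AcquisitionSpec.default_for(beam, tissue, **base)


@pytest.fixture
def noiseless_pair(photon_beam, electron_beam, yellow):
    """Noiseless zero-shift photon and electron stacks on the default grid."""
    sp = simulate_condition(photon_beam, yellow, noiseless_acq(photon_beam, yellow), None, 0)
    se = simulate_condition(electron_beam, yellow, noiseless_acq(electron_beam, yellow), None, 1)
    return sp, se


def simulate_shifted(beam, tissue, magnitude_mm, direction="superior", seed=7, noiseless=True,
                     **acq_overrides):
    shifted_field = beam.modality
    acq = (noiseless_acq(beam, tissue, **acq_overrides) if noiseless
           else AcquisitionSpec.default_for(beam, tissue, **acq_overrides))
    return simulate_condition(
        beam, tissue, acq, ShiftSpec(magnitude_mm, direction, shifted_field), rng_seed=seed
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
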