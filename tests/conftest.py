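import numpy as np
import pytest

from tunnelfold.nmr_core import AcquisitionParams, estimate_noise, fourier_transform
from tunnelfold.synthetic_data import GroundTruthSpectrum, simulate_fid

#: ppm window containing both resonances, excluded from noise estimation
SIGNAL_WINDOW = (-61.5, -58.5)


@pytest.fixture
def acq_4k() -> AcquisitionParams:
    return AcquisitionParams(n_points=4096, dwell=0.350 / 4096)


@pytest.fixture
def acq_8k() -> AcquisitionParams:
    return AcquisitionParams(n_points=8192, dwell=0.350 / 8192)


def make_two_state_spectrum(p_f, acq, snr=20.0, seed=0, noise_sd=None,
                            zero_fill_factor=1, **kwargs):
    """Simulated two-state spectrum with its noise level estimated from the
    baseline, as it would be for measured data."""
    truth = GroundTruthSpectrum.two_state(p_f, snr=snr, noise_sd=noise_sd,
                                          seed=seed, **kwargs)
    fid = simulate_fid(truth, acq)
    spec = fourier_transform(fid, zero_fill_factor=zero_fill_factor)
    if truth.noise_sd > 0:
        spec.noise_sd = estimate_noise(spec, exclusion_windows=[SIGNAL_WINDOW])
    else:
        spec.noise_sd = 1e-8
    return truth, spec
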