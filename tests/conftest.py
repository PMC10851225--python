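import numpy as np
import pytest

from phisdm import (IonSpecies, MzCalibration, PhaseModel, TransientSpec,
                    fourier_spectrum, simulate_transient)


@pytest.fixture(scope="session")
def calib():
    return MzCalibration()


@pytest.fixture(scope="session")
def phase():
    return PhaseModel(phi0=0.5, t0=1e-5)


@pytest.fixture(scope="session")
def fs(calib):
    # band-limited sampling: 2.5x the frequency of the lowest simulated m/z
    return 2.5 * float(calib.mz_to_frequency(400.0))


def make_tone(calib, phase, fs, mz=500.0, amplitude=100.0, T=0.032,
              noise=0.0, seed=0, on_bin=False, bin_offset=0.0):
    """Single-species transient; optionally snapped to a Fourier bin (+offset)."""
    spec = TransientSpec(duration_T=T, sampling_rate=fs, noise_sigma=noise,
                         seed=seed)
    f = float(calib.mz_to_frequency(mz))
    if on_bin or bin_offset:
        binw = fs / spec.n_samples
        f = (round(f / binw) + bin_offset) * binw
        mz = float(calib.frequency_to_mz(f))
    tr = simulate_transient([IonSpecies(mz=mz, amplitude=amplitude)],
                            spec, phase, calib)
    return tr, f


@pytest.fixture(scope="session")
def tone_032(calib, phase, fs):
    """Noiseless 32 ms tone at m/z 500 with its exact frequency."""
    return make_tone(calib, phase, fs)
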