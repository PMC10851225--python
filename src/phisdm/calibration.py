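"""Instrument calibration: phase law, frequency <-> m/z conversion, spectral noise.

In Orbitrap FTMS the axial oscillation frequency of an ion scales as
``f = C / sqrt(m/z)``, and the spectral phase of every species follows a
stable, precalibrated linear law ``phi(f) = phi0 + 2*pi*f*t0`` (t0 being an
effective detection/group delay). Both functions are treated here as
precalibrated inputs to deconvolution, fitted once from calibrant tones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default frequency calibration constant (Hz * Th^0.5).
#: Chosen so that f(200 Th) ~= 5.66e5 Hz, which places the eFT resolving
#: power of a 32 ms transient at ~15,000 at m/z 200 (the conventional
#: nominal figure for that transient length).
DEFAULT_C: float = 5.66e5 * np.sqrt(200.0)


@dataclass(frozen=True)
class MzCalibration:
    """Frequency/mass calibration ``f = C / sqrt(m/z)``."""

    C: float = DEFAULT_C

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"calibration constant C must be > 0, got {self.C}")

    def mz_to_frequency(self, mz):
        mz = np.asarray(mz, dtype=float)
        if np.any(mz <= 0):
            raise ValueError("m/z values must be > 0")
        return self.C / np.sqrt(mz)

    def frequency_to_mz(self, f):
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequencies must be > 0")
        return (self.C / f) ** 2


@dataclass(frozen=True)
class PhaseModel:
    """Linear spectral phase law ``phi(f) = phi0 + 2*pi*f*t0``.

    Parameters
    ----------
    phi0 : float
        Phase intercept in radians.
    t0 : float
        Group-delay term in seconds.
    valid_band : tuple of float
        (f_min, f_max) in Hz over which the law was calibrated. ``(0, inf)``
        means unrestricted.
    """

    phi0: float = 0.0
    t0: float = 0.0
    valid_band: tuple = (0.0, np.inf)

    def __post_init__(self) -> None:
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        lo, hi = self.valid_band
        if not lo < hi:
            raise ValueError(f"invalid band {self.valid_band}")

    def __call__(self, f):
        return self.phi0 + 2.0 * np.pi * np.asarray(f, dtype=float) * self.t0

    def covers(self, f_lo: float, f_hi: float) -> bool:
        return self.valid_band[0] <= f_lo and f_hi <= self.valid_band[1]


@dataclass(frozen=True)
class NoiseModel:
    """Calibrated spectral noise level (same intensity units as the spectrum)."""

    sigma_spec: float
    method: str = "mad"

    def __post_init__(self) -> None:
        if self.sigma_spec < 0:
            raise ValueError("sigma_spec must be >= 0")


def mz_to_frequency(mz, calib: MzCalibration):
    """Convert m/z (Th) to frequency (Hz) via ``f = C / sqrt(m/z)``."""
    return calib.mz_to_frequency(mz)


def frequency_to_mz(f, calib: MzCalibration):
    """Convert frequency (Hz) to m/z (Th) via ``m/z = (C/f)**2``."""
    return calib.frequency_to_mz(f)


def fit_phase_model(spectrum, known_freqs) -> PhaseModel:
    """Fit (phi0, t0) by linear regression of unwrapped apex phases on frequency.

    For each calibrant frequency the phase of the complex spectrum at the
    nearest grid bin is taken; phases are unwrapped along ascending frequency
    and regressed against ``2*pi*f``. At least two well separated calibrants
    are required, and the calibrant spacing must satisfy
    ``spacing * |t0| < 0.5`` cycles or the unwrap is ambiguous.

    Returns a :class:`PhaseModel` whose ``valid_band`` spans the calibrants.
    """
    known_freqs = np.sort(np.asarray(known_freqs, dtype=float))
    if known_freqs.size < 2:
        raise ValueError("phase fit requires >= 2 calibrant tones")
    idx = np.searchsorted(spectrum.freqs, known_freqs)
    idx = np.clip(idx, 0, len(spectrum.freqs) - 1)
    # snap to the nearer of the two bracketing bins
    left = np.clip(idx - 1, 0, len(spectrum.freqs) - 1)
    take_left = np.abs(spectrum.freqs[left] - known_freqs) < np.abs(
        spectrum.freqs[idx] - known_freqs
    )
    idx = np.where(take_left, left, idx)
    phases = np.unwrap(np.angle(spectrum.values[idx]))
    A = np.vstack([np.ones_like(known_freqs), 2.0 * np.pi * known_freqs]).T
    (phi0, t0), *_ = np.linalg.lstsq(A, phases, rcond=None)
    # the intercept is only identifiable modulo 2*pi from a high-frequency
    # calibrant band; report it on the principal branch
    phi0 = (phi0 + np.pi) % (2.0 * np.pi) - np.pi
    spacing = np.min(np.diff(known_freqs))
    if spacing * abs(t0) > 0.5:
        raise ValueError(
            "phase unwrap ambiguous: calibrant spacing x t0 exceeds 0.5 cycles"
        )
    return PhaseModel(
        phi0=float(phi0),
        t0=float(t0),
        valid_band=(float(known_freqs[0]), float(known_freqs[-1])),
    )


def estimate_noise_level(spectrum, n_rounds: int = 3, cut: float = 5.0) -> NoiseModel:
    """Robust spectral noise level via MAD with iterative peak exclusion.

    Works on the magnitudes of a complex spectrum or the values of a real one.
    The estimator assumes the noise floor of a white-noise transient, whose
    magnitude bins are Rayleigh distributed; the returned ``sigma_spec`` is the
    per-quadrature standard deviation (Rayleigh scale), recovered from the
    median via ``sigma = median / sqrt(2 ln 2)``. Three rounds of > ``cut``
    sigma exclusion make the estimate insensitive to sparse signal peaks.
    """
    mags = np.abs(np.asarray(spectrum.values))
    if mags.size < 64:
        raise ValueError("noise estimation requires a spectrum of length >= 64")
    if not np.any(mags > 0):
        return NoiseModel(sigma_spec=0.0)
    keep = np.ones(mags.size, dtype=bool)
    rayleigh_median = np.sqrt(2.0 * np.log(2.0))
    sigma = np.median(mags) / rayleigh_median
    for _ in range(n_rounds):
        keep = mags < cut * sigma
        if not np.any(keep):
            break
        sigma = np.median(mags[keep]) / rayleigh_median
    return NoiseModel(sigma_spec=float(sigma))


def fit_mz_calibration(centroids, known_mz) -> MzCalibration:
    """Least-squares fit of C over known (frequency, m/z) pairs.

    Parameters
    ----------
    centroids :
        Sequence of observed frequencies (Hz), one per known species.
    known_mz :
        The true m/z (Th) of each species, same order.
    """
    f = np.asarray(centroids, dtype=float)
    mz = np.asarray(known_mz, dtype=float)
    if f.size == 0:
        raise ValueError("mz calibration requires >= 1 known species")
    if f.shape != mz.shape:
        raise ValueError("frequency and m/z lists must have equal length")
    # f = C / sqrt(mz)  =>  C = sum(f * x) / sum(x^2), x = 1/sqrt(mz)
    x = 1.0 / np.sqrt(mz)
    C = float(np.dot(f, x) / np.dot(x, x))
    return MzCalibration(C=C)


def calibration_residuals_ppm(calib: MzCalibration, freqs, known_mz):
    """Signed ppm residuals of the fitted calibration at each calibrant."""
    pred = calib.frequency_to_mz(np.asarray(freqs, dtype=float))
    mz = np.asarray(known_mz, dtype=float)
    return (pred - mz) / mz * 1e6
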