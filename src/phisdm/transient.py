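"""Synthetic Orbitrap-style transient generation.

The image current induced by ions oscillating in the analyzer is modeled as a
sum of exponentially damped cosines plus white Gaussian noise,

    s(t) = sum_j A_j * exp(-t / tau_j) * cos(2*pi*f_j*t + phi(f_j) + dphi_j) + n(t)

with f_j = C / sqrt(mz_j) from the mass calibration and phi the precalibrated
phase law. Every generated transient carries its ground-truth species list so
downstream transforms and the deconvolution can be tested end to end without
instrument data.

Simulation happens at a configurable (reduced) sampling rate: the mathematics
of finite-window Fourier analysis is rate invariant, so band-limited scenarios
are sampled at a few times the highest species frequency rather than at MHz
instrument rates, keeping transients at 1e3-1e5 samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import MzCalibration, PhaseModel


@dataclass(frozen=True)
class IonSpecies:
    """One simulated ion packet.

    Parameters
    ----------
    mz : float
        Mass-to-charge in Th; must be > 0.
    amplitude : float
        Signal amplitude in arbitrary intensity units; >= 0.
    decay_tau : float
        Exponential decay time constant in seconds; ``inf`` disables decay.
        Ion decay is what limits the practical maximum transient length on
        the instrument.
    phase_offset : float
        Extra phase in radians on top of the global phase law (default 0).
    """

    mz: float
    amplitude: float
    decay_tau: float = np.inf
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.decay_tau > 0:
            raise ValueError(f"decay_tau must be > 0, got {self.decay_tau}")


@dataclass(frozen=True)
class TransientSpec:
    """Acquisition parameters of a simulated transient."""

    duration_T: float
    sampling_rate: float
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_T > 0:
            raise ValueError("duration_T must be > 0")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_samples < 8:
            raise ValueError("transient must contain >= 8 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_T * self.sampling_rate))


@dataclass(frozen=True)
class Transient:
    """A sampled real-valued image-current trace with optional ground truth."""

    samples: np.ndarray
    spec: TransientSpec
    truth: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if len(self.samples) != self.spec.n_samples:
            raise ValueError(
                f"sample count {len(self.samples)} != spec N {self.spec.n_samples}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("transient contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.spec.n_samples) / self.spec.sampling_rate


def simulate_transient(
    species,
    spec: TransientSpec,
    phase: PhaseModel,
    calib: MzCalibration,
) -> Transient:
    """Simulate the image-current transient for a list of :class:`IonSpecies`.

    Deterministic for a fixed ``spec.seed``. Raises if any species frequency
    violates the Nyquist limit of ``spec.sampling_rate``.
    """
    species = list(species)
    t = np.arange(spec.n_samples) / spec.sampling_rate
    s = np.zeros(spec.n_samples)
    nyquist = spec.sampling_rate / 2.0
    for sp in species:
        f = float(calib.mz_to_frequency(sp.mz))
        if f >= nyquist:
            raise ValueError(
                f"species at m/z {sp.mz} has frequency {f:.1f} Hz >= Nyquist "
                f"{nyquist:.1f} Hz; raise sampling_rate"
            )
        envelope = np.exp(-t / sp.decay_tau) if np.isfinite(sp.decay_tau) else 1.0
        s += sp.amplitude * envelope * np.cos(
            2.0 * np.pi * f * t + phase(f) + sp.phase_offset
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        s = s + rng.normal(0.0, spec.noise_sigma, spec.n_samples)
    return Transient(samples=s, spec=spec, truth=tuple(species))


# ---------------------------------------------------------------------------
# Fixture suite


def _suite_recipes(calib: MzCalibration):
    """Named scenarios covering the regimes the analysis chain must handle."""
    T = 0.032
    mid = 500.0
    f_mid = float(calib.mz_to_frequency(mid))
    fs = 2.5 * float(calib.mz_to_frequency(400.0))

    def mz_at_offset(df):
        # m/z whose frequency sits df Hz from the m/z-500 tone
        return float(calib.frequency_to_mz(f_mid + df))

    sub_sep = 0.35 / T  # below the absorption-mode FWHM of 0.60/T
    window_lo, window_hi = 496.35, 503.65  # 7.3 m/z DIA-style isolation window
    dense = [round(x, 4) for x in np.linspace(window_lo + 0.4, window_hi - 0.4, 12)]
    return {
        "single_tone": dict(
            mzs=[mid], amps=[100.0], noise=0.0, T=T, fs=fs,
        ),
        "doublet_ongrid": dict(
            mzs=[mid, mz_at_offset(3.0 / T)], amps=[100.0, 100.0],
            noise=0.0, T=T, fs=fs,
        ),
        "doublet_subfourier": dict(
            mzs=[mid, mz_at_offset(sub_sep)], amps=[100.0, 100.0],
            noise=0.0, T=T, fs=fs,
        ),
        "dense_window": dict(
            mzs=dense, amps=list(np.linspace(20.0, 100.0, len(dense))),
            noise=0.5, T=T, fs=fs, window=(window_lo, window_hi),
        ),
        "pure_noise": dict(mzs=[], amps=[], noise=1.0, T=T, fs=fs),
    }


def make_fixture_suite(
    seed: int,
    outdir=None,
    phase: PhaseModel | None = None,
    calib: MzCalibration | None = None,
) -> dict:
    """Build the documented fixture set; optionally serialize it to ``outdir``.

    Returns a dict name -> :class:`Transient`. The set covers: a single tone,
    an on-grid doublet, a sub-Fourier doublet (separation below the
    absorption-mode FWHM), a dense multiplex emulating a 7.3 m/z DIA isolation
    window, and pure noise. When ``outdir`` is given, each transient is stored
    as a little-endian float64 ``.npy`` array with a JSON sidecar holding the
    spec, phase law, calibration and truth table; identical seeds produce
    byte-identical files.
    """
    phase = phase or PhaseModel(phi0=0.5, t0=1e-4)
    calib = calib or MzCalibration()
    ss = np.random.SeedSequence(seed)
    fixtures = {}
    metas = {}
    for name, r in sorted(_suite_recipes(calib).items()):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        spec = TransientSpec(
            duration_T=r["T"], sampling_rate=r["fs"],
            noise_sigma=r["noise"], seed=sub_seed,
        )
        species = [IonSpecies(mz=m, amplitude=a) for m, a in zip(r["mzs"], r["amps"])]
        fixtures[name] = simulate_transient(species, spec, phase, calib)
        metas[name] = {
            "spec": {
                "duration_T": spec.duration_T,
                "sampling_rate": spec.sampling_rate,
                "noise_sigma": spec.noise_sigma,
                "seed": spec.seed,
            },
            "phase": {"phi0": phase.phi0, "t0": phase.t0},
            "calibration": {"C": calib.C},
            "truth": [
                {"mz": sp.mz, "amplitude": sp.amplitude,
                 "decay_tau": None if np.isinf(sp.decay_tau) else sp.decay_tau,
                 "phase_offset": sp.phase_offset}
                for sp in species
            ],
            **({"mz_window": list(r["window"])} if "window" in r else {}),
        }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tr in fixtures.items():
            arr = tr.samples.astype("<f8")
            np.save(outdir / f"{name}.npy", arr)
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(metas[name], fh, indent=1, sort_keys=True)
                fh.write("\n")
    return fixtures


def load_fixture(outdir, name: str):
    """Load one serialized fixture back into (Transient, PhaseModel, MzCalibration)."""
    outdir = Path(outdir)
    samples = np.load(outdir / f"{name}.npy")
    with open(outdir / f"{name}.json") as fh:
        meta = json.load(fh)
    spec = TransientSpec(**meta["spec"])
    phase = PhaseModel(phi0=meta["phase"]["phi0"], t0=meta["phase"]["t0"])
    calib = MzCalibration(C=meta["calibration"]["C"])
    truth = tuple(
        IonSpecies(
            mz=d["mz"], amplitude=d["amplitude"],
            decay_tau=np.inf if d["decay_tau"] is None else d["decay_tau"],
            phase_offset=d["phase_offset"],
        )
        for d in meta["truth"]
    )
    return Transient(samples=samples, spec=spec, truth=truth), phase, calib
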