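"""Centroiding, the neighboring-peak-pair resolving-power statistic, and the
nominal resolution model.

Orbitrap resolving power scales as R = R0 * (T/T0) * sqrt(m0/m): linear in
transient length T and inversely proportional to sqrt(m/z). The pair
statistic inverts this: every pair of neighboring centroids closer than the
tolerance window m / R(m) implied by a reference resolving power testifies
that the producing spectrum actually resolved at R = (m/z)/(dm/z) >= that
reference - a way to measure delivered resolving power from centroided data
alone, with abundance filters to reject noise-derived pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import MzCalibration


@dataclass(frozen=True)
class CentroidList:
    """Centroided mass spectrum: ascending m/z with nonnegative intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) >= 0):
            raise ValueError("centroid m/z must be ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class ResolutionModel:
    """Reference triple (T0, R0, m0) encoding R(T, m) = R0*(T/T0)*sqrt(m0/m)."""

    T0: float = 0.032
    R0: float = 15000.0
    m0: float = 200.0

    def __post_init__(self) -> None:
        if not (self.T0 > 0 and self.R0 > 0 and self.m0 > 0):
            raise ValueError("T0, R0 and m0 must all be > 0")

    def resolution(self, T: float, mz: float) -> float:
        if not (T > 0 and mz > 0):
            raise ValueError("T and mz must be > 0")
        return self.R0 * (T / self.T0) * np.sqrt(self.m0 / mz)


@dataclass(frozen=True)
class PairFinderConfig:
    """Filters of the neighboring-pair search.

    Tolerance windows assume a nominal resolving power ``ref_resolution`` at
    ``ref_mz``; centroids below ``rel_abundance_min`` of the base peak are
    ignored and pairs more unbalanced than ``max_abundance_ratio`` rejected.
    """

    ref_resolution: float = 30000.0
    ref_mz: float = 200.0
    rel_abundance_min: float = 0.04
    max_abundance_ratio: float = 4.0

    def __post_init__(self) -> None:
        for name in ("ref_resolution", "ref_mz", "rel_abundance_min",
                     "max_abundance_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PeakPair:
    mz_low: float
    mz_high: float
    intensity_low: float
    intensity_high: float

    def __post_init__(self) -> None:
        if not self.mz_low < self.mz_high:
            raise ValueError("mz_low must be < mz_high")

    @property
    def delta_mz(self) -> float:
        return self.mz_high - self.mz_low

    @property
    def required_R(self) -> float:
        """Resolving power needed to separate the pair: (m/z)/(dm/z) at the
        lower-m/z member (documented convention)."""
        return self.mz_low / self.delta_mz

    @property
    def required_R_at_200(self) -> float:
        return pair_resolution_at_200(self)


def nominal_resolution(T: float, mz: float, model: ResolutionModel) -> float:
    """Nominal resolving power R0*(T/T0)*sqrt(m0/mz) at transient T and m/z."""
    return float(model.resolution(T, mz))


def min_resolvable_separation(T: float, mz: float, model: ResolutionModel) -> float:
    """Smallest peak separation (Th) resolvable at the nominal resolving power."""
    return mz / nominal_resolution(T, mz, model)


def pair_tolerance_window(mz: float, cfg: PairFinderConfig) -> float:
    """Neighbor-pair tolerance window at ``mz``: m / (R_ref * sqrt(m_ref/m))."""
    if not mz > 0:
        raise ValueError("mz must be > 0")
    return mz / (cfg.ref_resolution * np.sqrt(cfg.ref_mz / mz))


def pair_resolution_at_200(p: PeakPair, ref_mz: float = 200.0) -> float:
    """Rescale a pair's required resolving power to the m/z-200 reference."""
    return p.required_R * np.sqrt(p.mz_low / ref_mz)


def pick_centroids(
    sp,
    calib: MzCalibration,
    min_rel_intensity: float = 0.0,
) -> CentroidList:
    """Peak-pick a profile spectrum into centroids in m/z.

    Strict local maxima above ``min_rel_intensity`` of the spectrum maximum
    are refined by 3-point parabolic interpolation of the apex in frequency,
    then converted to m/z. On a plateau of equal maxima the leftmost sample
    is the apex (no interpolation).
    """
    f, v = sp.freqs, sp.values
    if len(v) == 0:
        raise ValueError("empty spectrum")
    floor = min_rel_intensity * v.max()
    mzs, ints = [], []
    for i in range(1, len(v) - 1):
        if not (v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > 0 and v[i] >= floor):
            continue
        if v[i] > v[i + 1]:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            delta = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
            apex_f = f[i] + delta * (f[i + 1] - f[i])
            apex_v = v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta
        else:  # plateau: leftmost sample, documented tie-break
            apex_f, apex_v = f[i], v[i]
        mzs.append(float(calib.frequency_to_mz(apex_f)))
        ints.append(float(apex_v))
    order = np.argsort(mzs)
    return CentroidList(mz=np.asarray(mzs)[order], intensity=np.asarray(ints)[order])


def find_neighbor_pairs(c: CentroidList, cfg: PairFinderConfig = PairFinderConfig()):
    """Neighboring peak pairs under the tolerance window and abundance filters.

    Pairs are formed between list-adjacent centroids (after dropping peaks
    below the relative-abundance floor). A pair is kept when its spacing is
    <= the tolerance window evaluated at the lower-m/z member (inclusive) and
    neither peak is more than ``max_abundance_ratio`` times the other.
    """
    floor = cfg.rel_abundance_min * c.base_peak_intensity
    keep = c.intensity >= floor
    mz, inten = c.mz[keep], c.intensity[keep]
    pairs = []
    for i in range(len(mz) - 1):
        lo, hi = mz[i], mz[i + 1]
        if hi - lo > pair_tolerance_window(lo, cfg):
            continue
        a, b = inten[i], inten[i + 1]
        if max(a, b) > cfg.max_abundance_ratio * min(a, b):
            continue
        pairs.append(PeakPair(mz_low=lo, mz_high=hi, intensity_low=a,
                              intensity_high=b))
    return pairs


@dataclass(frozen=True)
class MassErrorStats:
    bias_ppm: float
    spread_ppm: float
    n: int


def mass_error_stats(observed: CentroidList, truth, gate_ppm: float = 10.0) -> MassErrorStats:
    """Signed ppm errors of observed centroids against ground-truth species.

    Each truth m/z is matched to its nearest observed centroid; matches
    farther than ``gate_ppm`` are discarded. Raises when nothing matches.
    """
    truth_mz = np.asarray([sp.mz for sp in truth], dtype=float)
    if len(observed) == 0 or truth_mz.size == 0:
        raise ValueError("need non-empty observed and truth lists")
    errors = []
    for tm in truth_mz:
        j = int(np.argmin(np.abs(observed.mz - tm)))
        err = (observed.mz[j] - tm) / tm * 1e6
        if abs(err) <= gate_ppm:
            errors.append(err)
    if not errors:
        raise ValueError(f"no truth species matched within {gate_ppm} ppm")
    errors = np.asarray(errors)
    return MassErrorStats(
        bias_ppm=float(errors.mean()),
        spread_ppm=float(errors.std(ddof=0)),
        n=len(errors),
    )
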