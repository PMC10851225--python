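"""DIA isolation-window schemes and cycle-time / points-per-peak budgets.

A data-independent acquisition method slices the precursor range into
``floor(span/width)`` consecutive windows, each widened symmetrically by half
the overlap on either edge so adjacent windows share exactly ``overlap`` Th.
The cycle budget is one survey (MS1) transient plus one MS2 transient per
window, plus a configurable per-cycle overhead; dividing the chromatographic
peak width by the cycle time gives the expected data points per peak, which
method design aims to keep at three or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiaScheme:
    precursor_range: tuple
    window_width: float
    overlap: float
    n_windows: int
    ms1_transient: float = 0.128
    ms2_transient: float = 0.032
    overhead_per_cycle: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.precursor_range
        if not lo < hi:
            raise ValueError("degenerate precursor range")
        if not self.window_width > self.overlap >= 0:
            raise ValueError("need window_width > overlap >= 0")
        if self.n_windows != int((hi - lo) / self.window_width):
            raise ValueError("n_windows inconsistent with floor(span/width)")

    @property
    def window_edges(self) -> np.ndarray:
        """(n_windows, 2) array of [lower, upper] m/z edges, overlap included."""
        lo, _ = self.precursor_range
        i = np.arange(self.n_windows)
        lower = lo + i * self.window_width - self.overlap / 2.0
        upper = lo + (i + 1) * self.window_width + self.overlap / 2.0
        return np.column_stack([lower, upper])

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_edges.mean(axis=1)


@dataclass(frozen=True)
class GradientProfile:
    """LC gradient with its reported chromatographic peak width.

    ``peak_width`` follows the 1.7 * FWHM base-width convention of common
    DIA software reports.
    """

    name: str
    peak_width: float

    def __post_init__(self) -> None:
        if not self.peak_width > 0:
            raise ValueError("peak width must be > 0")


def make_windows(precursor_range, width: float, overlap: float = 0.0,
                 ms1_transient: float = 0.128, ms2_transient: float = 0.032,
                 overhead_per_cycle: float = 0.0) -> DiaScheme:
    """Build a DIA scheme over ``precursor_range`` with the floor-count rule.

    n_windows = floor(span / width); each window's edges are widened by
    overlap/2 so neighbors share exactly ``overlap`` Th. Note the floor
    convention: a 600 Th span at 15.4 Th yields 38 windows even though
    600/15.4 rounds to 39.
    """
    lo, hi = precursor_range
    span = hi - lo
    if not span > 0:
        raise ValueError("degenerate precursor range")
    if width >= span:
        raise ValueError("window width must be smaller than the precursor span")
    if not width > overlap >= 0:
        raise ValueError("need width > overlap >= 0")
    n = int(span / width)
    return DiaScheme(
        precursor_range=(float(lo), float(hi)), window_width=float(width),
        overlap=float(overlap), n_windows=n, ms1_transient=ms1_transient,
        ms2_transient=ms2_transient, overhead_per_cycle=overhead_per_cycle,
    )


def cycle_transient_time(s: DiaScheme) -> float:
    """Total transient time of one DIA cycle: MS1 + n_windows * MS2 (+ overhead)."""
    return s.ms1_transient + s.n_windows * s.ms2_transient + s.overhead_per_cycle


def points_per_peak(g: GradientProfile, s: DiaScheme) -> float:
    """Expected chromatographic data points per peak: peak width / cycle time."""
    cycle = cycle_transient_time(s)
    if not cycle > 0:
        raise ValueError("cycle time must be > 0")
    return g.peak_width / cycle
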