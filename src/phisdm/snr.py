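"""XIC-based signal-to-noise statistic and outlier filtering.

SNR here follows the definition used for DIA peptide quantification reports:
fragment XICs are summed per time point; signal is the maximum of the summed
trace inside the chromatographic peak boundaries and noise is the average of
the summed trace strictly outside them. Pairs of SNRs from two processing
methods are filtered for overestimation outliers (cases where no empirical
noise could be determined) before summarizing their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class XicSet:
    """Per-fragment extracted ion chromatograms with peak boundaries.

    ``traces`` has shape (n_fragments, n_times); ``peak_bounds`` is
    (t_start, t_end) in the same time units, boundary samples counting as
    inside the peak.
    """

    times: np.ndarray
    traces: np.ndarray
    peak_bounds: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        object.__setattr__(self, "traces", traces)
        if traces.shape[0] < 1 or traces.shape[1] != len(self.times):
            raise ValueError("traces must be (n_fragments, n_times) matching times")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly ascending")
        t0, t1 = self.peak_bounds
        if not (self.times[0] <= t0 <= t1 <= self.times[-1]):
            raise ValueError("peak bounds must lie within the time range")
        if not np.any((self.times < t0) | (self.times > t1)):
            raise ValueError("need at least one sample outside the peak bounds")


@dataclass(frozen=True)
class SnrFilterConfig:
    """Outlier cutoffs on log2 SNR for the two compared methods (x, y axes)."""

    log2_max_x: float = 13.0
    log2_max_y: float = 14.0

    def __post_init__(self) -> None:
        if not (self.log2_max_x > 0 and self.log2_max_y > 0):
            raise ValueError("cutoffs must be > 0")


def compute_snr(x: XicSet) -> float:
    """max(summed XIC inside bounds) / mean(summed XIC outside bounds).

    Raises when the outside mean is zero: without an empirical noise value
    the SNR is undefined (the overestimation case the outlier filter later
    removes).
    """
    summed = x.traces.sum(axis=0)
    t0, t1 = x.peak_bounds
    inside = (x.times >= t0) & (x.times <= t1)
    if not np.any(inside):
        raise ValueError("no samples inside the peak bounds")
    noise = summed[~inside].mean()
    if noise == 0:
        raise ValueError("outside-bounds mean is zero: SNR undefined")
    return float(summed[inside].max() / noise)


def filter_snr_outliers(pairs, cfg: SnrFilterConfig = SnrFilterConfig()):
    """Drop (snr_x, snr_y) pairs with log2 SNR at or above either cutoff."""
    out = []
    for sx, sy in pairs:
        if sx <= 0 or sy <= 0:
            raise ValueError("SNRs must be > 0")
        if np.log2(sx) >= cfg.log2_max_x or np.log2(sy) >= cfg.log2_max_y:
            continue
        out.append((sx, sy))
    return out


def snr_ratio_summary(paired) -> float:
    """Median of snr_a / snr_b over filtered pairs."""
    paired = list(paired)
    if not paired:
        raise ValueError("no SNR pairs to summarize")
    ratios = [a / b for a, b in paired]
    return float(np.median(ratios))
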