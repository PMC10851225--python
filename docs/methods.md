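# Methods

## Signal model

A transient is modeled as a sum of exponentially damped cosines plus white
Gaussian noise, sampled at rate f_s for N = round(T·f_s) samples:

    s(t) = Σ_j A_j · e^{−t/τ_j} · cos(2π f_j t + φ(f_j) + Δφ_j) + n(t),
    f_j = C / sqrt(m/z_j)

The phase law φ(f) = φ₀ + 2πf·t₀ is global (a stable, precalibrated property
of the detection chain; t₀ is an effective group delay). The frequency
calibration constant C defaults to 5.66·10⁵·√200 Hz·Th^½ so that a 32 ms
transient delivers the conventional nominal eFT resolving power of ~15,000
at m/z 200; it is a free parameter everywhere.

Simulation happens at a *reduced* sampling rate (≈2.5× the highest species
frequency, ~10⁵ samples for 32 ms band-limited scenarios) rather than MHz
instrument rates: finite-window Fourier analysis is rate invariant, and this
keeps every test desk scale. One numerical subtlety: the Fourier grid
spacing is f_s/N, which equals 1/T only when T·f_s is an integer, so all
downstream processing uses the effective window length N/f_s.

## Spectra

The FFT is normalized by 2/N so an undamped on-grid tone of amplitude A
reads A at its bin with the tone's phase; DC and Nyquist bins are dropped
(Parseval bookkeeping: transient energy = N/(2·zf) × spectral energy,
exact for zero-mean band-interior signals). No apodization is applied —
the rectangular window is what gives the sinc lineshape the deconvolution
assumes. Magnitude-mode FWHM is 1.21/T; phased absorption mode
Re[S(f)·e^{−iφ(f)}], clipped at zero, gives the sinc(2dT) lineshape with
FWHM 0.60/T. The eFT spectrum is implemented as exactly this clipped
absorption mode: the published hybrid eFT weighting is proprietary, and only
its defining property — absorption-mode width, i.e. twice the magnitude-mode
resolving power at the same transient — matters here. FWHM is measured by
linear interpolation on a ×4 zero-filled grid; the un-filled grid samples an
absorption peak with ~1.2 points and cannot support a width measurement.

## Deconvolution

The complex spectrum on the native Fourier grid is fitted as
S(f_m) = Σ_q x_q·L(g_q − f_m) with L(d) = sinc(dT)·e^{iπdT} on a grid
refined ν-fold (default ν = 4; the separation benchmark uses ν = 8). The
sign convention is fixed repo-wide: the kernel argument is tone minus
observation frequency, the phase factor arising from a rectangular window
starting at t = 0. Each x_q is constrained to the convex cone
|arg(x_q·e^{−iφ(g_q)})| ≤ δ.

Key design choices, and why:

- **Input is the complex spectrum**, not the real eFT spectrum: the cone
  constraint needs the phase information, and the eFT spectrum is
  recoverable from it.
- **Solver: monotone FISTA.** Plain projected gradient with step
  1/λ_max(BᴴB) is the textbook baseline (available via `accelerate=False`),
  but on realistic bands it is far from converged after a few hundred
  iterations, leaving a smeared minimum-norm iterate with no
  super-resolution. The default takes an accelerated step only when it does
  not increase the residual and otherwise falls back to a plain step with a
  momentum restart, so the residual trace is non-increasing on every run
  while convergence fits ~2000 iterations.
- **Iteration cap 2000, tolerance 1e−9.** Real-time instrument
  implementations cap their own (scheme-specific, GPU) iteration count near
  150; that budget is not comparable currency for this solver family.
  Offline we run to convergence instead. The relative-residual tolerance
  must be tight because the accelerated iteration passes through long
  shallow plateaus that a loose tolerance mistakes for convergence.
- **Cone half-angle δ = 0.01 rad.** The cone exists to absorb
  phase-calibration error and must stay narrow: the sparsity of the optimum
  — and with it the sub-Fourier resolution — comes from the near-positivity
  of the constraint. Widening the cone to ~0.1 rad gives neighboring refined
  nodes enough phase freedom to mimic small frequency shifts; the optimum
  itself then becomes a smeared ridge with marginally lower residual
  (verified against an exact active-set nonnegative-least-squares solve of
  the δ = 0 problem). δ = 0 (exact phase) is supported.
- **Noise threshold** = 1.41 × the calibrated spectral σ, applied once after
  the final iteration; per-iteration pruning would change the optimization
  problem (and empirically changes nothing at this threshold level).
- **Band processing**: sub-bands of ≤ 512 Fourier bins with margin bins on
  each side, stitched by keeping each band's core sticks. With the sinc
  kernel this is exact up to the discarded margin leakage; it also makes
  narrow-band analyses (the benchmark, the worked example) cheap. Full-range
  deconvolution at these settings is minutes of CPU; on-instrument
  implementations use GPUs for real time.
- **Backfilling** exists only as an identity hook (`apply_backfill`); no
  specification of any backfilling variant was available, so none is
  implemented.

Stick clustering merges runs of sticks whose gaps are strictly smaller than
a threshold (one Fourier bin for mass-spectrum building). The strict
boundary matters: residual sticks of an imperfect fit sit exactly one bin
apart and must not chain into one feature. Conversion to m/z uses
m/z = (C/f)², with intensity-weighted mean frequencies for merged clusters.
When sub-Fourier doublets are the object of interest, merging within a bin
must be disabled (`merge_within_bin=False`) and clustering done at the
refined-node scale, as in the worked example.

## Calibration

- Phase fit: linear regression of unwrapped apex phases of ≥ 2 calibrant
  tones on frequency. The intercept is identifiable only modulo 2π (reported
  on the principal branch), and the calibrant spacing must satisfy
  spacing × t₀ < 0.5 cycles or aliasing silently maps t₀ to a wrong small
  value — a precondition, not something the fit can detect.
- Noise: MAD-type estimator on spectral magnitudes (median / sqrt(2 ln 2),
  the Rayleigh relation) with 3 rounds of > 5σ peak exclusion. For white
  time-domain noise of std σ_t the spectral level is σ_t·sqrt(2/N) under the
  2/N scaling; the estimator sits within a few percent of this.
- m/z calibration: least squares for C over known (f, m/z) pairs.

## Resolving-power analysis

Nominal resolution follows R(T, m) = R₀·(T/T₀)·√(m₀/m) with defaults
(32 ms, 15,000, m/z 200). The neighboring-pair statistic forms pairs of
list-adjacent centroids closer than the tolerance window
m/(R_ref·√(m_ref/m)) (inclusive boundary, evaluated at the lower-m/z member
— the convention is documented because the choice of member is otherwise
arbitrary), keeps both peaks ≥ 4 % of the base peak and intensity ratios
≤ 4, and annotates each pair with R = (m/z)/(Δm/z) and its √(m/200)
rescaling to the m/z-200 reference.

The separation benchmark simulates equal-amplitude doublets at m/z 988
(32 ms, spectral SNR 100, three independent noise realizations per
separation, majority vote) and asks, for each processing mode, for the
smallest separation from which everything larger stays resolved. "Resolved"
means: two distinct features, each within one refined-grid step (1/T)/ν of
its true frequency — centroided local maxima for the eFT spectrum, and for
the stick output additionally a valley between the matched sticks dipping
below half the smaller peak (the classic two-maxima-with-a-valley
criterion, which prevents a single smeared blob from counting as two
features at sub-node separations).

## DIA planning and SNR

Window schemes use n = floor(span/width) windows with the overlap added
symmetrically to each window's edges — the only convention consistent with
all three reference schemes (82×7.3, 53×11.3, 38×15.4 over m/z 400–1000
with 1 Th overlap; note 600/15.4 *rounds* to 39 but *floors* to 38). Cycle
time is MS1 + n·MS2 transients plus a configurable scalar overhead
(hardware-dependent, never modeled). Points per peak = chromatographic peak
width / cycle time.

XIC SNR = max of the per-time summed fragment traces inside the peak
boundaries / mean of the summed traces strictly outside (boundary samples
count as inside; "average" is the mean). A zero outside-mean raises — that
is the overestimation case the log₂ 13/14 outlier filter removes when
comparing two processing methods.

## What the synthetic data does and does not show

The generator produces ideal damped cosines with a global linear phase law,
white noise, and no interactions. It exercises exactly the assumptions the
deconvolution makes, so passing tests demonstrate correctness of the
algorithms and the internal consistency of the processing chain — not
robustness to space-charge frequency shifts, coalescence, phase-law
curvature across wide bands, non-white noise, or harmonics, none of which
are modeled. Decay (τ) is supported by the simulator but the quantitative
tests use undamped tones, as decay changes the lineshape away from the sinc
the kernel assumes. Identification-level results on real proteomes (peptide
counts, real SNR distributions) are outside what synthetic data can
establish.

## Numerical notes and degenerate inputs

Zero-signal bands return immediately with an empty solution. Plateau apexes
centroid to the leftmost sample (documented tie-break). The pair search and
SNR statistics use inclusive boundaries as stated above. All randomness
flows through explicit integer seeds; identical seeds give byte-identical
fixture files and CLI outputs. Problem sizes throughout (10³–10⁵-sample
transients, ≤ 100-bin analysis bands, 15-point sweeps with 3 replicates)
are the package's chosen desk-scale study conditions.
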