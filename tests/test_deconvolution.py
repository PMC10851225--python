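import numpy as np
import pytest

from phisdm import (IonSpecies, MzCalibration, NoiseModel, PhaseModel,
                    PhisdmConfig, TransientSpec, apply_backfill,
                    cluster_sticks, fourier_spectrum, phisdm_deconvolve,
                    project_to_phase_cone, simulate_transient, sinc_kernel,
                    sticks_to_mass_spectrum)
from phisdm.deconvolution import StickSpectrum

from conftest import make_tone


class TestSincKernel:
    def test_zero_offset_is_unity(self):
        assert sinc_kernel(0.0, 0.032) == pytest.approx(1.0 + 0.0j)

    @pytest.mark.parametrize("k", [-3, -1, 1, 2, 5])
    def test_vanishes_at_fourier_bin_multiples(self, k):
        T = 0.032
        assert abs(sinc_kernel(k / T, T)) <= 1e-12

    def test_half_bin_magnitude(self):
        T = 0.064
        assert abs(sinc_kernel(0.5 / T, T)) == pytest.approx(2 / np.pi,
                                                             abs=1e-9)


class TestPhaseConeProjection:
    def test_on_ray_unchanged(self):
        z = 3.0 * np.exp(1j * 0.7)
        assert project_to_phase_cone(z, 0.7, 0.1) == pytest.approx(z)

    def test_antiphase_projects_to_zero(self):
        z = 2.0 * np.exp(1j * (0.7 + np.pi))
        for delta in (0.0, 0.3, 1.0):
            assert abs(project_to_phase_cone(z, 0.7, delta)) == 0.0

    def test_orthogonal_point(self):
        z = 5.0 * np.exp(1j * (0.2 + np.pi / 2))
        assert abs(project_to_phase_cone(z, 0.2, 0.0)) == 0.0
        w = project_to_phase_cone(z, 0.2, np.pi / 4)
        assert abs(w) == pytest.approx(5.0 * np.cos(np.pi / 4), rel=1e-12)
        assert np.angle(w * np.exp(-1j * 0.2)) == pytest.approx(np.pi / 4)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50) + 1j * rng.normal(size=50)
        phi = rng.uniform(-np.pi, np.pi, 50)
        once = project_to_phase_cone(z, phi, 0.2)
        twice = project_to_phase_cone(once, phi, 0.2)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_matches_dense_feasible_search(self):
        # oracle: nearest point among a dense sample of the cone
        rng = np.random.default_rng(1)
        r = np.linspace(0, 8, 400)
        for _ in range(20):
            z = complex(rng.normal(scale=2), rng.normal(scale=2))
            phi = rng.uniform(-np.pi, np.pi)
            delta = rng.uniform(0, 1.2)
            th = np.linspace(-delta, delta, 201)
            cand = r[:, None] * np.exp(1j * (phi + th))[None, :]
            best = cand.flat[np.argmin(np.abs(cand - z))]
            proj = project_to_phase_cone(z, phi, delta)
            assert abs(proj - z) <= abs(best - z) + 1e-6


def tone_on_refined_node(calib, phase, fs, T=0.032, amplitude=100.0):
    spec = TransientSpec(duration_T=T, sampling_rate=fs)
    binw = fs / spec.n_samples
    f_on = round(float(calib.mz_to_frequency(500.0)) / binw) * binw
    tr = simulate_transient(
        [IonSpecies(mz=float(calib.frequency_to_mz(f_on)), amplitude=amplitude)],
        spec, phase, calib)
    return tr, f_on, binw


class TestDeconvolve:
    def test_single_tone_on_node_single_stick(self, calib, phase, fs):
        tr, f_on, binw = tone_on_refined_node(calib, phase, fs)
        band = fourier_spectrum(tr).band(f_on - 30.5 * binw, f_on + 30.5 * binw)
        st = phisdm_deconvolve(band, phase, NoiseModel(sigma_spec=0.5),
                               PhisdmConfig())
        assert len(st) == 1
        assert st.freqs[0] == pytest.approx(f_on, abs=1e-6)
        assert st.amplitudes[0] == pytest.approx(100.0, rel=0.005)

    def test_subfourier_doublet_recovered(self, calib, fs):
        phase = PhaseModel(phi0=0.3, t0=0.0)
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs)
        binw = fs / spec.n_samples
        T = spec.n_samples / fs
        f1 = round(float(calib.mz_to_frequency(500.0)) / binw) * binw
        f2 = f1 + 0.35 / T  # below the 0.60/T absorption-mode FWHM
        tr = simulate_transient(
            [IonSpecies(mz=float(calib.frequency_to_mz(f)), amplitude=100.0)
             for f in (f1, f2)], spec, phase, calib)
        cfg = PhisdmConfig()  # nu = 4
        band = fourier_spectrum(tr).band(f1 - 30.5 * binw, f1 + 30.5 * binw)
        st = phisdm_deconvolve(band, phase, NoiseModel(sigma_spec=0.5), cfg)
        tol = (1.0 / T) / (2 * cfg.refinement_factor)
        matches = []
        for f_true in (f1, f2):
            d = np.abs(st.freqs - f_true)
            if matches:
                d[matches] = np.inf
            j = int(np.argmin(d))
            assert d[j] <= tol
            matches.append(j)
        assert matches[0] != matches[1]

    def test_zero_signal_terminates_immediately(self, calib, phase, fs):
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs)
        tr = simulate_transient([], spec, phase, calib)
        binw = fs / spec.n_samples
        f0 = float(calib.mz_to_frequency(500.0))
        band = fourier_spectrum(tr).band(f0 - 20 * binw, f0 + 20 * binw)
        st = phisdm_deconvolve(band, phase, NoiseModel(sigma_spec=0.1),
                               PhisdmConfig())
        assert len(st) == 0
        assert st.residual_norm == 0.0
        assert st.iterations_run <= 2

    @pytest.mark.parametrize("accelerate", [False, True])
    def test_residual_monotone(self, calib, fs, accelerate):
        phase = PhaseModel(phi0=0.3, t0=0.0)
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs,
                             noise_sigma=30.0, seed=4)
        species = [IonSpecies(mz=500.0, amplitude=80.0),
                   IonSpecies(mz=500.05, amplitude=40.0)]
        tr = simulate_transient(species, spec, phase, calib)
        binw = fs / spec.n_samples
        f0 = float(calib.mz_to_frequency(500.0))
        band = fourier_spectrum(tr).band(f0 - 25 * binw, f0 + 25 * binw)
        cfg = PhisdmConfig(accelerate=accelerate, max_iterations=300)
        st = phisdm_deconvolve(band, phase,
                               NoiseModel(sigma_spec=0.4), cfg)
        assert np.all(np.diff(st.residual_trace) <= 1e-9)

    def test_objective_matches_dense_convex_oracle(self, calib, fs):
        # tiny band (<= 3 Fourier bins), nu = 2: exhaustively solve the
        # cone-constrained least squares with a generic NLP solver
        scipy_opt = pytest.importorskip("scipy.optimize")
        phase = PhaseModel(phi0=0.3, t0=0.0)
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs)
        binw = fs / spec.n_samples
        k0 = round(float(calib.mz_to_frequency(500.0)) / binw)
        f_tone = (k0 + 0.6) * binw
        tr = simulate_transient(
            [IonSpecies(mz=float(calib.frequency_to_mz(f_tone)),
                        amplitude=10.0)], spec, phase, calib)
        band = fourier_spectrum(tr).band((k0 - 1.01) * binw, (k0 + 1.01) * binw)
        assert len(band.freqs) <= 3
        cfg = PhisdmConfig(refinement_factor=2, cone_half_angle=0.01,
                           noise_threshold_multiplier=0.0)
        st = phisdm_deconvolve(band, phase, NoiseModel(sigma_spec=0.0), cfg)

        nodes = (len(band.freqs) - 1) * 2 + 1
        g = band.freqs[0] + (binw / 2) * np.arange(nodes)
        B = sinc_kernel(g[None, :] - band.freqs[:, None], band.duration_T)
        phi = phase(g)

        def objective(p):
            x = p[:nodes] * np.exp(1j * (phi + p[nodes:]))
            return float(np.sum(np.abs(band.values - B @ x) ** 2))

        rng = np.random.default_rng(3)
        best = np.inf
        bounds = [(0, None)] * nodes + [(-0.01, 0.01)] * nodes
        for _ in range(20):
            p0 = np.concatenate([rng.uniform(0, 12, nodes),
                                 rng.uniform(-0.01, 0.01, nodes)])
            res = scipy_opt.minimize(objective, p0, bounds=bounds,
                                     method="SLSQP",
                                     options={"maxiter": 500, "ftol": 1e-14})
            best = min(best, res.fun)
        assert st.residual_norm ** 2 == pytest.approx(best, rel=1e-4, abs=1e-12)

    def test_thresholding_floor_always_respected(self, calib, fs):
        phase = PhaseModel(phi0=0.3, t0=0.0)
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs,
                             noise_sigma=50.0, seed=8)
        species = [IonSpecies(mz=499.9 + 0.1 * i, amplitude=30.0 + 10 * i)
                   for i in range(4)]
        tr = simulate_transient(species, spec, phase, calib)
        binw = fs / spec.n_samples
        f0 = float(calib.mz_to_frequency(500.0))
        band = fourier_spectrum(tr).band(f0 - 30 * binw, f0 + 30 * binw)
        noise = NoiseModel(sigma_spec=50.0 * np.sqrt(2.0 / spec.n_samples))
        cfg = PhisdmConfig()
        st = phisdm_deconvolve(band, phase, noise, cfg)
        assert np.all(st.amplitudes >= 1.41 * noise.sigma_spec)
        assert np.all(np.abs(st.phase_residuals) <= cfg.cone_half_angle + 1e-12)

    def test_band_splitting_matches_single_band(self, calib, fs):
        # two tones far apart, processed with a small band size: both must
        # be recovered despite the stitching
        phase = PhaseModel(phi0=0.3, t0=0.0)
        spec = TransientSpec(duration_T=0.032, sampling_rate=fs)
        binw = fs / spec.n_samples
        k0 = round(float(calib.mz_to_frequency(520.0)) / binw)
        f_a, f_b = (k0 + 2) * binw, (k0 + 40) * binw
        tr = simulate_transient(
            [IonSpecies(mz=float(calib.frequency_to_mz(f)), amplitude=50.0)
             for f in (f_a, f_b)], spec, phase, calib)
        band = fourier_spectrum(tr).band((k0 - 5.5) * binw, (k0 + 47.5) * binw)
        cfg = PhisdmConfig(band_max_bins=20, band_margin_bins=6)
        st = phisdm_deconvolve(band, phase, NoiseModel(sigma_spec=0.5), cfg)
        for f_true in (f_a, f_b):
            assert np.min(np.abs(st.freqs - f_true)) < 1e-6
        amps = [st.amplitudes[np.argmin(np.abs(st.freqs - f))]
                for f in (f_a, f_b)]
        assert amps == pytest.approx([50.0, 50.0], rel=0.01)

    def test_zero_filled_input_rejected(self, calib, phase, tone_032):
        tr, _ = tone_032
        with pytest.raises(ValueError, match="zero-fill"):
            phisdm_deconvolve(fourier_spectrum(tr, 2), phase,
                              NoiseModel(sigma_spec=0.1), PhisdmConfig())

    def test_phase_band_mismatch_rejected(self, calib, tone_032):
        tr, f = tone_032
        narrow = PhaseModel(phi0=0.0, t0=0.0, valid_band=(f + 1e4, f + 2e4))
        with pytest.raises(ValueError, match="cover"):
            phisdm_deconvolve(fourier_spectrum(tr), narrow,
                              NoiseModel(sigma_spec=0.1), PhisdmConfig())


class TestSticksToMassSpectrum:
    def stick(self, freqs, amps, T=0.032):
        return StickSpectrum(freqs=np.asarray(freqs, float),
                             amplitudes=np.asarray(amps, float),
                             phase_residuals=np.zeros(len(freqs)),
                             residual_norm=0.0, iterations_run=1,
                             duration_T=T)

    def test_single_stick_maps_inverse(self, calib):
        f = float(calib.mz_to_frequency(500.0))
        c = sticks_to_mass_spectrum(self.stick([f], [10.0]), calib)
        assert len(c) == 1
        assert c.mz[0] == pytest.approx(500.0, abs=1e-9)

    def test_adjacent_sticks_merge_weighted(self, calib):
        T = 0.032
        f0 = float(calib.mz_to_frequency(500.0))
        node = (1.0 / T) / 4
        st = self.stick([f0, f0 + node], [1.0, 3.0], T=T)
        c = sticks_to_mass_spectrum(st, calib)
        assert len(c) == 1
        f_merged = (1.0 * f0 + 3.0 * (f0 + node)) / 4.0
        assert c.mz[0] == pytest.approx(
            float(calib.frequency_to_mz(f_merged)), rel=1e-12)
        assert c.intensity[0] == pytest.approx(4.0)

    def test_distant_sticks_not_merged(self, calib):
        T = 0.032
        f0 = float(calib.mz_to_frequency(500.0))
        st = self.stick([f0, f0 + 2.0 / T], [1.0, 1.0], T=T)
        assert len(sticks_to_mass_spectrum(st, calib)) == 2

    def test_empty_sticks(self, calib):
        c = sticks_to_mass_spectrum(self.stick([], []), calib)
        assert len(c) == 0

    def test_cluster_gap_rule(self):
        st = self.stick([100.0, 101.0, 105.0], [1.0, 1.0, 2.0])
        out = cluster_sticks(st, max_gap=2.0)
        assert len(out) == 2
        assert out.freqs[0] == pytest.approx(100.5)
        assert out.amplitudes.tolist() == [2.0, 2.0]


def test_backfill_hook_is_identity_only():
    st = StickSpectrum(freqs=np.array([1.0]), amplitudes=np.array([2.0]),
                       phase_residuals=np.array([0.0]), residual_norm=0.0,
                       iterations_run=1)
    assert apply_backfill(st, "none") is st
    with pytest.raises(NotImplementedError):
        apply_backfill(st, "v2")
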