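import numpy as np
import pytest

from hopspec import (
    extract_oscillations,
    fit_population_lifetime,
    ftmap_2d,
    global_fit,
    node_phase_analysis,
    wavenumber_to_period,
)
from hopspec.analysis import exp_conv_irf
from hopspec.spectroscopy import TAMap


def synth_map(delays, energies, components, irf_fwhm=30.0, noise=0.0, seed=0):
    """Sum of DAS_k(E) * [exp(-t/tau_k) conv IRF] plus optional noise."""
    M = np.zeros((delays.size, energies.size))
    for tau, das in components:
        M += np.outer(exp_conv_irf(delays, tau, irf_fwhm), das(energies))
    if noise > 0:
        rng = np.random.default_rng(seed)
        M += rng.normal(0, noise * np.max(np.abs(M)), M.shape)
    return TAMap(delays_fs=delays, probe_energies_ev=energies, delta_a=M)


DELAYS = np.arange(0.0, 1001.0, 2.0)
ENERGIES = np.arange(3.0, 4.41, 0.02)


def band(center, width=0.2, amp=1.0):
    return lambda E: amp * np.exp(-0.5 * ((E - center) / width) ** 2)


class TestWavenumberToPeriod:
    @pytest.mark.parametrize(
        "nu, period",
        [(600.0, 55.6), (750.0, 44.5), (33356.41, 1.0)],
    )
    def test_reference_values(self, nu, period):
        assert wavenumber_to_period(nu) == pytest.approx(period, abs=0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            wavenumber_to_period(0.0)


class TestGlobalFit:
    def test_single_exponential_recovered_exactly(self):
        tamap = synth_map(DELAYS, ENERGIES, [(500.0, band(3.8))])
        res = global_fit(tamap, n_exp=1, irf_fwhm_fs=30.0)
        assert res.taus_fs[0] == pytest.approx(500.0, abs=1.0)

    def test_biexponential_with_noise_recovered(self):
        comps = [(100.0, band(3.7, amp=-1.0)), (575.0, band(4.1, amp=0.6))]
        tamap = synth_map(DELAYS, ENERGIES, comps, noise=0.01, seed=3)
        res = global_fit(tamap, n_exp=2, irf_fwhm_fs=30.0)
        assert res.taus_fs[0] == pytest.approx(100.0, rel=0.05)
        assert res.taus_fs[1] == pytest.approx(575.0, rel=0.05)

    def test_nested_model_second_component_vanishes(self):
        tamap = synth_map(DELAYS, ENERGIES, [(300.0, band(3.8))])
        res = global_fit(tamap, n_exp=2, irf_fwhm_fs=30.0)
        i_true = int(np.argmin(np.abs(res.taus_fs - 300.0)))
        assert res.taus_fs[i_true] == pytest.approx(300.0, rel=0.02)
        amp = np.abs(res.das).max(axis=1)
        assert amp[1 - i_true] < 0.02 * amp[i_true]

    def test_reconstruction_matches_input(self):
        tamap = synth_map(DELAYS, ENERGIES, [(250.0, band(3.9))])
        res = global_fit(tamap, n_exp=1, irf_fwhm_fs=30.0)
        rec = res.reconstruct(DELAYS)
        assert np.max(np.abs(rec - tamap.delta_a)) < 1e-8

    def test_protocol_idempotence_on_refit(self, urd_ensemble):
        """Fitting a simulated map and refitting its own reconstruction
        yields the same time constants."""
        from hopspec import ensemble_ta_map

        tamap = ensemble_ta_map(urd_ensemble, sigma_e_ev=0.15, irf_fwhm_fs=30.0)
        res1 = global_fit(tamap, n_exp=2, irf_fwhm_fs=30.0)
        resynth = TAMap(
            delays_fs=tamap.delays_fs,
            probe_energies_ev=tamap.probe_energies_ev,
            delta_a=res1.reconstruct(tamap.delays_fs),
        )
        res2 = global_fit(resynth, n_exp=2, irf_fwhm_fs=30.0)
        assert np.allclose(res1.taus_fs, res2.taus_fs, rtol=0.02)

    def test_window_outside_grid_rejected(self):
        tamap = synth_map(DELAYS, ENERGIES, [(300.0, band(3.8))])
        with pytest.raises(ValueError, match="window"):
            global_fit(tamap, n_exp=1, t_fit_window=(-50.0, 2000.0))


class TestPopulationLifetime:
    def test_exact_exponential(self):
        t = np.arange(0.0, 1000.0, 1.0)
        tau, err = fit_population_lifetime(t, np.exp(-t / 300.0))
        assert tau == pytest.approx(300.0, abs=1e-6)

    def test_step_count_population_within_binomial_band(self):
        # parametric bootstrap oracle: 57 trajectories with exponential
        # decay times; the fitted tau must fall inside the spread of the
        # bootstrap distribution of fitted taus
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 1001.0, 1.0)
        truth = 750.0

        def fit_once(seed):
            r = np.random.default_rng(seed)
            times = r.exponential(truth, size=57)
            P = (times[None, :] > t[:, None]).mean(axis=1)
            keep = P > 0
            return fit_population_lifetime(t[keep], P[keep])[0]

        taus = np.array([fit_once(s) for s in range(60)])
        lo, hi = np.percentile(taus, [2.5, 97.5])
        assert lo < truth < hi
        assert fit_once(1234) == pytest.approx(truth, rel=0.35)

    def test_non_decaying_trace_raises(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError, match="decay"):
            fit_population_lifetime(t, np.full(t.size, 0.7))

    def test_populations_outside_unit_interval_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            fit_population_lifetime(t, np.linspace(1.5, 0.1, t.size))


class TestOscillationExtraction:
    def test_smooth_biexponential_leaves_tiny_residual(self):
        tamap = synth_map(DELAYS, ENERGIES, [(100.0, band(3.7)), (600.0, band(4.0))])
        resid = extract_oscillations(tamap, passband_cm=(300.0, 1200.0), t_start_fs=50.0)
        assert np.sqrt(np.mean(resid.delta_a**2)) < 1e-3 * np.sqrt(np.mean(tamap.delta_a**2))

    def test_injected_cosine_recovered_with_amplitude_and_phase(self):
        period = wavenumber_to_period(750.0)
        t = DELAYS
        osc = 0.1 * np.cos(2 * np.pi * (t[:, None] - 50.0) / period) * band(3.8)(ENERGIES)[None, :]
        base = np.outer(exp_conv_irf(t, 400.0, 30.0), band(3.8)(ENERGIES))
        tamap = TAMap(delays_fs=t, probe_energies_ev=ENERGIES, delta_a=base + osc)
        resid = extract_oscillations(tamap, passband_cm=(500.0, 1000.0), t_start_fs=50.0)
        j = np.argmin(np.abs(ENERGIES - 3.8))
        sel = (resid.delays_fs > 150) & (resid.delays_fs < 850)  # away from edges
        rec = resid.delta_a[sel, j]
        ref = osc[np.isin(t, resid.delays_fs[sel]), j]
        amp_rec = np.sqrt(2 * np.mean(rec**2))
        amp_ref = np.sqrt(2 * np.mean(ref**2))
        assert amp_rec == pytest.approx(amp_ref, rel=0.05)
        # zero phase lag: cross-correlation peaks at zero shift
        xc = np.correlate(rec, ref, mode="full")
        assert abs(np.argmax(xc) - (rec.size - 1)) <= 1

    def test_idempotent_on_band_interior_content(self):
        period = wavenumber_to_period(750.0)
        osc = 0.1 * np.cos(2 * np.pi * DELAYS[:, None] / period) * np.ones((1, ENERGIES.size))
        tamap = TAMap(delays_fs=DELAYS, probe_energies_ev=ENERGIES, delta_a=osc)
        once = extract_oscillations(tamap, passband_cm=(500.0, 1000.0), t_start_fs=0.0)
        twice = extract_oscillations(once, passband_cm=(500.0, 1000.0), t_start_fs=0.0)
        assert np.max(np.abs(twice.delta_a - once.delta_a)) < 1e-10

    def test_degenerate_passband_rejected(self):
        tamap = synth_map(DELAYS, ENERGIES, [(300.0, band(3.8))])
        with pytest.raises(ValueError, match="passband"):
            extract_oscillations(tamap, passband_cm=(700.0, 700.0))


class TestFTMap:
    def _residual_with_modes(self, modes, t_start=50.0):
        X = np.zeros((DELAYS.size, ENERGIES.size))
        for nu, amp in modes:
            period = wavenumber_to_period(nu)
            X += amp * np.cos(2 * np.pi * DELAYS[:, None] / period)
        tamap = TAMap(delays_fs=DELAYS, probe_energies_ev=ENERGIES, delta_a=X)
        return extract_oscillations(tamap, passband_cm=(300.0, 1200.0), t_start_fs=t_start)

    def test_single_mode_peak_within_one_padded_bin(self):
        resid = self._residual_with_modes([(750.0, 0.1)])
        osc = ftmap_2d(resid, zero_pad_factor=4)
        j = np.argmax(osc.amplitude[0])
        bin_width = osc.wavenumbers_cm[1] - osc.wavenumbers_cm[0]
        assert abs(osc.wavenumbers_cm[j] - 750.0) <= bin_width

    def test_two_modes_resolved_over_1ps_window(self):
        resid = self._residual_with_modes([(600.0, 0.1), (750.0, 0.1)])
        osc = ftmap_2d(resid, zero_pad_factor=4)
        amp = osc.amplitude[0]
        nus = osc.wavenumbers_cm
        i600 = np.argmin(np.abs(nus - 600.0))
        i750 = np.argmin(np.abs(nus - 750.0))
        i_mid = np.argmin(np.abs(nus - 675.0))
        assert amp[i600] > 2 * amp[i_mid] and amp[i750] > 2 * amp[i_mid]

    def test_parseval_consistency(self):
        resid = self._residual_with_modes([(700.0, 0.05)])
        t = resid.delays_fs
        n = t.size
        w = np.hanning(n)
        X = resid.delta_a[:, 0] * w
        n_pad = 4 * n
        spec = np.fft.rfft(X, n=n_pad)
        # Parseval for rfft with zero padding
        energy_time = np.sum(X**2)
        energy_freq = (np.abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:]) ** 2)
                       - (n_pad % 2 == 0) * np.abs(spec[-1]) ** 2) / n_pad
        assert energy_freq == pytest.approx(energy_time, rel=1e-8)

    def test_all_zero_residual_gives_zero_map(self):
        tamap = TAMap(delays_fs=DELAYS, probe_energies_ev=ENERGIES,
                      delta_a=np.zeros((DELAYS.size, ENERGIES.size)))
        osc = ftmap_2d(tamap)
        assert np.all(osc.amplitude == 0)

    def test_too_few_points_rejected(self):
        tamap = TAMap(delays_fs=np.arange(10.0), probe_energies_ev=ENERGIES,
                      delta_a=np.zeros((10, ENERGIES.size)))
        with pytest.raises(ValueError, match="16"):
            ftmap_2d(tamap)


def gap_modulation_map(center=3.80, nu=750.0, depth=0.04):
    """SE band whose center oscillates about ``center``: the classic
    wavepacket signature with an amplitude node at the band center and a
    pi phase jump across it."""
    period = wavenumber_to_period(nu)
    centers = center + depth * np.cos(2 * np.pi * DELAYS / period)
    M = -np.exp(-0.5 * ((ENERGIES[None, :] - centers[:, None]) / 0.15) ** 2)
    M *= np.exp(-DELAYS / 600.0)[:, None]
    return TAMap(delays_fs=DELAYS, probe_energies_ev=ENERGIES, delta_a=M)


class TestNodePhase:
    def test_node_at_mean_gap_with_pi_phase_jump(self):
        tamap = gap_modulation_map()
        resid = extract_oscillations(tamap, passband_cm=(400.0, 1100.0), t_start_fs=50.0)
        osc = ftmap_2d(resid)
        node = node_phase_analysis(osc, 750.0)
        assert node.found
        assert node.node_energy_ev == pytest.approx(3.80, abs=0.021)
        assert abs(node.phase_jump_rad) == pytest.approx(np.pi, abs=0.2)

    def test_constant_amplitude_oscillation_has_no_node(self):
        X = 0.1 * np.cos(2 * np.pi * DELAYS[:, None] / wavenumber_to_period(750.0))
        X = np.repeat(X, ENERGIES.size, axis=1)
        tamap = TAMap(delays_fs=DELAYS, probe_energies_ev=ENERGIES, delta_a=X)
        resid = extract_oscillations(tamap, passband_cm=(400.0, 1100.0), t_start_fs=50.0)
        node = node_phase_analysis(ftmap_2d(resid), 750.0)
        assert not node.found

    def test_mirrored_energy_axis_flips_phase_jump_sign(self):
        tamap = gap_modulation_map()
        resid = extract_oscillations(tamap, passband_cm=(400.0, 1100.0), t_start_fs=50.0)
        osc = ftmap_2d(resid)
        node = node_phase_analysis(osc, 750.0)
        # mirror: reverse the energy axis content
        osc_m = ftmap_2d(
            TAMap(delays_fs=resid.delays_fs, probe_energies_ev=resid.probe_energies_ev,
                  delta_a=resid.delta_a[:, ::-1])
        )
        node_m = node_phase_analysis(osc_m, 750.0)
        assert node_m.found
        e_mid = 0.5 * (ENERGIES[0] + ENERGIES[-1])
        assert node_m.node_energy_ev == pytest.approx(2 * e_mid - node.node_energy_ev, abs=0.021)
        assert node_m.phase_jump_rad == pytest.approx(-node.phase_jump_rad, abs=1e-6)
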