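import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hopspec import (
    decoherence_step,
    diabatic_rehop,
    hop_decision,
    make_pucker_model,
    rescale_momentum,
    run_ensemble,
    run_trajectory,
    tdse_step,
)
from hopspec.units import AMU_TO_ME, FS_TO_AU, wavenumber_to_angular_frequency_au

from conftest import make_harmonic_model


class Sample:
    def __init__(self, q, p):
        self.q = np.asarray(q, dtype=float)
        self.p = np.asarray(p, dtype=float)


class TestTdseStep:
    def test_decoupled_limit_preserves_moduli_and_advances_phases(self):
        c = np.array([np.sqrt(0.3), np.sqrt(0.7)], dtype=complex)
        E = np.array([0.1, 0.25])
        zero = np.zeros((2, 2))
        dt = 1.0 * FS_TO_AU
        out = tdse_step(c, E, E, zero, zero, dt)
        assert np.allclose(np.abs(out), np.abs(c), atol=1e-12)
        expected = c * np.exp(-1j * E * dt)
        assert np.allclose(out, expected, atol=1e-10)

    def test_constant_coupling_follows_rabi_solution(self):
        # constant gap dE and coupling s: P2(t) = s^2/Omega^2 sin^2(Omega t),
        # Omega^2 = s^2 + (dE/2)^2 (exact two-level solution)
        dE, s = 0.02, 0.008
        E = np.array([0.0, dE])
        sig = np.array([[0.0, s], [-s, 0.0]])
        c = np.array([1.0 + 0j, 0.0 + 0j])
        dt = 0.5 * FS_TO_AU
        t = 0.0
        Omega = np.sqrt(s**2 + (dE / 2) ** 2)
        for _ in range(200):
            c = tdse_step(c, E, E, sig, sig, dt, n_substeps=40)
            t += dt
            expected = (s**2 / Omega**2) * np.sin(Omega * t) ** 2
            assert abs(abs(c[1]) ** 2 - expected) < 1e-6

    def test_substep_self_convergence(self):
        rng = np.random.default_rng(5)
        E0 = np.array([0.0, 0.17, 0.18])
        E1 = E0 + rng.normal(0, 0.005, 3)
        s0 = rng.normal(0, 0.002, (3, 3))
        s0 = s0 - s0.T
        s1 = s0 + rng.normal(0, 0.0005, (3, 3))
        s1 = 0.5 * (s1 - s1.T)
        c = np.array([0.1, 0.9, 0.2], dtype=complex)
        c /= np.linalg.norm(c)
        dt = 1.0 * FS_TO_AU
        out40 = tdse_step(c, E0, E1, s0, s1, dt, n_substeps=40)
        out80 = tdse_step(c, E0, E1, s0, s1, dt, n_substeps=80)
        assert np.max(np.abs(out40 - out80)) < 1e-6

    def test_norm_is_conserved_to_1e8(self):
        c = np.array([0.6, 0.8], dtype=complex)
        E = np.array([0.0, 0.15])
        s = np.array([[0.0, 0.01], [-0.01, 0.0]])
        for _ in range(400):
            c = tdse_step(c, E, E, s, s, 0.25 * FS_TO_AU)
        assert abs(np.sum(np.abs(c) ** 2) - 1.0) < 1e-8

    def test_too_few_substeps_rejected(self):
        c = np.array([1.0, 0.0], dtype=complex)
        E = np.zeros(2)
        z = np.zeros((2, 2))
        with pytest.raises(ValueError, match="n_substeps"):
            tdse_step(c, E, E, z, z, 1.0, n_substeps=10)


class TestHopDecision:
    def test_zero_coupling_never_hops(self):
        c = np.array([0.6, 0.8], dtype=complex)
        sig = np.zeros((2, 2))
        for draw in (0.0, 0.5, 0.999):
            assert hop_decision(c, 0, sig, 1.0, draw) is None

    def test_threshold_behavior(self):
        # g sums to ~0.3: draw above -> no hop, draw below -> hop
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        s = 0.3 / (2 * 1.0 * 0.5 / 0.5)  # makes g_1 = 0.3 for dt=1
        sig = np.array([[0.0, s], [-s, 0.0]])
        assert hop_decision(c, 0, sig, 1.0, 0.95) is None
        assert hop_decision(c, 0, sig, 1.0, 0.1) == 1

    def test_flux_consistency_with_tdse(self):
        # summed hop probability per step tracks the active-population loss
        dE, s = 0.01, 0.004
        E = np.array([0.0, dE])
        sig = np.array([[0.0, s], [-s, 0.0]])
        c = np.array([1.0 + 0j, 0.0])
        dt = 0.05 * FS_TO_AU
        lost, proposed = 0.0, 0.0
        # stay within the first quarter Rabi period so the flux is one-way
        Omega = np.sqrt(s**2 + (dE / 2) ** 2)
        n_steps = int(0.25 * (np.pi / Omega) / dt)
        for _ in range(n_steps):
            pop_before = abs(c[0]) ** 2
            c = tdse_step(c, E, E, sig, sig, dt)
            g = 2 * dt * np.real(np.conj(c[0]) * c[1] * sig[0, 1]) / abs(c[0]) ** 2
            proposed += max(g, 0.0) * abs(c[0]) ** 2
            lost += pop_before - abs(c[0]) ** 2
        assert proposed == pytest.approx(lost, rel=0.03)

    def test_vanished_population_warns(self):
        c = np.array([1e-9 + 0j, 1.0])
        with pytest.warns(UserWarning, match="vanished"):
            assert hop_decision(c, 0, np.ones((2, 2)), 1.0, 0.5) is None


class TestRescaleMomentum:
    def test_downward_hop_always_accepted_and_exact(self):
        masses = np.array([1.0, 2.0]) * AMU_TO_ME
        p = np.array([1.0, -2.0])
        d = np.array([0.3, 0.7])
        p_new, ok, _ = rescale_momentum(p, masses, -0.05, d)
        assert ok
        ke = lambda pp: 0.5 * np.sum(pp**2 / masses)
        assert ke(p_new) - ke(p) == pytest.approx(0.05, abs=1e-12)

    def test_upward_hop_frustrated_when_kinetically_forbidden(self):
        masses = np.array([1.0]) * AMU_TO_ME
        p = np.array([1.0])  # KE ~ 2.7e-4 hartree
        p_new, ok, deficit = rescale_momentum(p, masses, 0.5, np.array([1.0]))
        assert not ok
        assert np.array_equal(p_new, p)
        assert deficit > 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_accepted_hops_conserve_energy_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 5)
        masses = rng.uniform(0.5, 20.0, n) * AMU_TO_ME
        p = rng.normal(0, 3, n)
        d = rng.normal(0, 1, n)
        if np.linalg.norm(d) == 0:
            return
        delta_e = rng.uniform(-0.02, 0.0005)
        ke = lambda pp: 0.5 * np.sum(pp**2 / masses)
        p_new, ok, _ = rescale_momentum(p, masses, delta_e, d)
        if ok:
            assert abs((ke(p_new) + delta_e) - ke(p)) < 1e-10

    def test_zero_direction_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            rescale_momentum(np.array([1.0]), np.array([1.0]), 0.0, np.array([0.0]))


class TestDecoherenceStep:
    def test_strong_decoherence_limit_collapses_to_active(self):
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        out = decoherence_step(c, 0, np.array([0.0, 10.0]), 0.5, dt_au=1e6, C=0.0)
        assert abs(out[1]) < 1e-12
        assert abs(abs(out[0]) - 1.0) < 1e-12

    def test_hand_computed_damping(self):
        # dt/tau = ln 2 damps the non-active amplitude by exactly 1/2
        gap, ekin, C = 0.01, 0.1, 0.1
        tau = (1.0 / gap) * (1.0 + C / ekin)
        dt = np.log(2.0) * tau
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], dtype=complex)
        out = decoherence_step(c, 0, np.array([0.0, gap]), ekin, dt, C)
        assert abs(out[1]) == pytest.approx(np.sqrt(0.5) / 2.0, abs=1e-12)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_states_untouched(self):
        c = np.array([0.6, 0.8], dtype=complex)
        out = decoherence_step(c, 0, np.array([0.2, 0.2]), 0.5, 100.0, C=0.1)
        assert np.allclose(out, c)

    def test_negative_C_rejected(self):
        with pytest.raises(ValueError):
            decoherence_step(np.array([1.0 + 0j]), 0, np.array([0.0]), 0.1, 1.0, C=-1)


class TestRunTrajectory:
    def test_harmonic_motion_matches_discrete_cosine_exactly(self):
        """On a single harmonic surface, velocity Verlet reproduces the
        exact discrete-dispersion cosine; over 10 periods the continuum
        cosine is also tracked closely."""
        m = make_harmonic_model(600.0, 1.0)
        omega = wavenumber_to_angular_frequency_au(600.0)
        dt_fs = 0.05
        dt = dt_fs * FS_TO_AU
        period_fs = 33356.41 / 600.0
        tr = run_trajectory(
            m, Sample([0.3], [0.0]), dt_fs=dt_fs, t_max_fs=10 * period_fs,
            seed=0, start_state=0, terminal_state=None,
        )
        t_au = tr.t_fs * FS_TO_AU
        omega_tilde = (2.0 / dt) * np.arcsin(omega * dt / 2.0)
        assert np.max(np.abs(tr.q[:, 0] - 0.3 * np.cos(omega_tilde * t_au))) < 1e-6
        assert np.max(np.abs(tr.q[:, 0] - 0.3 * np.cos(omega * t_au))) < 1e-3
        assert tr.valid and tr.energy_drift < 1e-7

    def test_same_seed_reproduces_trajectory_bitwise(self, pucker_model):
        from hopspec.initial import sample_for_model

        s = sample_for_model(pucker_model, 1, seed=3)[0]
        tr1 = run_trajectory(pucker_model, s, dt_fs=0.25, t_max_fs=60.0, seed=42)
        tr2 = run_trajectory(pucker_model, s, dt_fs=0.25, t_max_fs=60.0, seed=42)
        assert np.array_equal(tr1.q, tr2.q)
        assert np.array_equal(tr1.active, tr2.active)
        assert np.array_equal(tr1.amplitudes, tr2.amplitudes)

    def test_dimension_mismatch_raises(self, pucker_model):
        with pytest.raises(ValueError, match="dimension"):
            run_trajectory(pucker_model, Sample([0.0], [0.0]), t_max_fs=1.0)

    def test_invalid_dt_raises(self, pucker_model):
        from hopspec.initial import sample_for_model

        s = sample_for_model(pucker_model, 1, seed=0)[0]
        with pytest.raises(ValueError, match="dt"):
            run_trajectory(pucker_model, s, dt_fs=0.0, t_max_fs=1.0)


class TestEnsemble:
    def test_no_coupling_keeps_population_on_start_state(self):
        m = make_harmonic_model(600.0, 1.0)
        samples = [Sample([0.1], [0.0]) for _ in range(5)]
        ens = run_ensemble(m, samples, base_seed=0, dt_fs=0.5, t_max_fs=50.0,
                           terminal_state=None)
        t, P = ens.populations()
        assert np.allclose(P[:, 1], 1.0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_population_traces_match_recount_from_active_series(self, urd_ensemble):
        t_grid, P = urd_ensemble.populations()
        traj = [tr for tr in urd_ensemble.trajectories if tr.valid]
        for k in (0, len(t_grid) // 2, len(t_grid) - 1):
            counts = np.zeros(P.shape[1])
            for tr in traj:
                counts[tr.state_at(t_grid[k])] += 1
            assert np.allclose(P[k], counts / len(traj))

    def test_requested_count_and_distinct_seeds(self):
        m = make_harmonic_model(600.0, 1.0)
        samples = [Sample([0.05], [0.0]) for _ in range(57)]
        ens = run_ensemble(m, samples, base_seed=100, dt_fs=1.0, t_max_fs=3.0,
                           terminal_state=None)
        assert len(ens.trajectories) == 57
        seeds = [tr.seed for tr in ens.trajectories]
        assert len(set(seeds)) == 57

    def test_empty_sample_list_raises(self, pucker_model):
        with pytest.raises(ValueError):
            run_ensemble(pucker_model, [])

    def test_bright_population_non_increasing_on_funnel_model(self, urd_ensemble):
        t, P = urd_ensemble.populations()
        excited = 1.0 - P[:, 0]
        assert np.all(np.diff(excited) <= 1e-12)


class TestConservationSuite:
    def test_electronic_norm_every_step(self, urd_ensemble):
        for tr in urd_ensemble.trajectories[:10]:
            norms = np.sum(np.abs(tr.amplitudes) ** 2, axis=1)
            assert np.max(np.abs(norms - 1.0)) < 1e-8

    def test_energy_drift_between_hops_below_tolerance(self, urd_ensemble, heavy_ensemble):
        for ens in (urd_ensemble, heavy_ensemble):
            assert all(tr.valid for tr in ens.trajectories)
            assert max(tr.energy_drift for tr in ens.trajectories) < 1e-4

    def test_accepted_hops_conserve_total_energy(self, pucker_model):
        # the engine recomputes total energy around every accepted hop and
        # warns above 1e-10 hartree; a decaying trajectory must stay silent
        import warnings as _warnings

        from hopspec.initial import sample_for_model

        s = sample_for_model(pucker_model, 1, seed=8)[0]
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", UserWarning)
            tr = run_trajectory(pucker_model, s, dt_fs=0.1, t_max_fs=400.0, seed=5)
        assert any(ev.accepted for ev in tr.events)


class TestDiabaticRehop:
    def test_decoupled_extra_state_gives_zero_transfer(self, urd_ensemble):
        ext = make_pucker_model(dark_coupling_eV=0.0)
        r = diabatic_rehop(urd_ensemble, ext, seed=1)
        assert r["fraction"] == 0.0

    def test_degenerate_strongly_coupled_state_transfers_fully(self, urd_ensemble):
        ext = make_pucker_model(
            dark_offset_eV=0.0, dark_coupling_eV=0.3, dark_tracks_bright=True
        )
        r = diabatic_rehop(urd_ensemble, ext, seed=1, decoherence_C=None)
        assert r["fraction"] > 0.9

    def test_same_seed_gives_identical_decisions(self, urd_ensemble):
        ext = make_pucker_model(dark_coupling_eV=0.03, dark_tracks_bright=False)
        r1 = diabatic_rehop(urd_ensemble, ext, seed=7)
        r2 = diabatic_rehop(urd_ensemble, ext, seed=7)
        assert r1["departures"] == r2["departures"]
        assert r1["fraction"] == r2["fraction"]

    def test_dimension_mismatch_raises(self, urd_ensemble, tully1):
        with pytest.raises(ValueError, match="dimension"):
            diabatic_rehop(urd_ensemble, tully1)
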