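import numpy as np
import pytest

from hopspec import make_pucker_model, run_ensemble
from hopspec.fssh import Trajectory
from hopspec.initial import PhaseSpaceSample, excitation_window, sample_for_model
from hopspec.models import ElectronicModel


@pytest.fixture(scope="session")
def tully1():
    from hopspec import make_tully_model

    return make_tully_model("simple_avoided_crossing")


def make_harmonic_model(wavenumber_cm=600.0, mass_amu=1.0, n_modes=1, shift=None):
    """Uncoupled two-state model whose lower surface is harmonic."""
    from hopspec.units import AMU_TO_ME, wavenumber_to_angular_frequency_au

    omega = wavenumber_to_angular_frequency_au(wavenumber_cm)
    m_au = mass_amu * AMU_TO_ME
    k = m_au * omega**2
    q0 = np.zeros(n_modes) if shift is None else np.asarray(shift, dtype=float)

    def potential(q):
        d = q - q0
        V = np.array([[0.5 * k * float(d @ d), 0.0], [0.0, 0.2 + 0.5 * k * float(d @ d)]])
        dV = np.zeros((2, 2, n_modes))
        dV[0, 0] = k * d
        dV[1, 1] = k * d
        return V, dV

    def dipole(q):
        return np.array([[0.0, 1.0], [1.0, 0.0]])

    return ElectronicModel(
        n_states=2,
        n_modes=n_modes,
        masses_amu=np.full(n_modes, mass_amu),
        potential=potential,
        dipole=dipole,
        labels=("S0", "S1"),
        sampling_wavenumbers_cm=np.full(n_modes, wavenumber_cm),
        kind="harmonic-test",
    )


@pytest.fixture
def harmonic_model():
    return make_harmonic_model()


@pytest.fixture(scope="session")
def pucker_model():
    return make_pucker_model()


@pytest.fixture(scope="session")
def pucker_model_heavy():
    return make_pucker_model(
        pucker_mass_amu=15.0, solvent_coupling_eV=0.15, solvent_tau_fs=85.0
    )


def _windowed_samples(model, n_raw, n_keep, seed):
    res = excitation_window(sample_for_model(model, n_raw, seed=seed), model, (4.43, 4.75))
    return res.samples[:n_keep]


@pytest.fixture(scope="session")
def urd_ensemble(pucker_model):
    """Small bright-state decay ensemble of the light (H-puckering) system."""
    samples = _windowed_samples(pucker_model, 60, 30, seed=5)
    return run_ensemble(pucker_model, samples, base_seed=21, dt_fs=0.08, t_max_fs=500.0)


@pytest.fixture(scope="session")
def heavy_ensemble(pucker_model_heavy):
    """Small ensemble of the heavy (methyl-like) solvent-gated system."""
    samples = _windowed_samples(pucker_model_heavy, 60, 30, seed=5)
    return run_ensemble(
        pucker_model_heavy, samples, base_seed=23, dt_fs=0.2, t_max_fs=1000.0
    )


def make_fake_trajectory(
    hop_time_fs,
    t_max_fs=500.0,
    dt_fs=1.0,
    q_hop=None,
    n_modes=4,
    n_states=3,
    seed=0,
):
    """Synthetic trajectory record for classification/survival tests."""
    from hopspec.fssh import HopEvent

    t = np.arange(0.0, t_max_fs + 0.5 * dt_fs, dt_fs)
    S = t.size
    active = np.ones(S, dtype=np.int64)
    events = []
    hop = np.nan
    if hop_time_fs is not None and hop_time_fs <= t_max_fs:
        i_hop = int(np.round(hop_time_fs / dt_fs))
        active[i_hop:] = 0
        hop = t[i_hop]
        events.append(
            HopEvent(
                t_hop_fs=hop,
                from_state=1,
                to_state=0,
                accepted=True,
                q_at_hop=np.zeros(n_modes) if q_hop is None else np.asarray(q_hop, float),
            )
        )
    q = np.zeros((S, n_modes))
    p = np.zeros((S, n_modes))
    energies = np.tile(np.arange(n_states, dtype=float) * 0.1, (S, 1))
    dipoles = np.tile(np.ones((n_states, n_states)) - np.eye(n_states), (S, 1, 1))
    amps = np.zeros((S, n_states), dtype=complex)
    amps[np.arange(S), active] = 1.0
    return Trajectory(
        t_fs=t,
        q=q,
        p=p,
        active=active,
        amplitudes=amps,
        energies=energies,
        dipoles=dipoles,
        events=events,
        seed=seed,
        hop_to_gs_fs=hop,
    )
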