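"""Transient-absorption signal synthesis from trajectory ensembles.

Each trajectory contributes per-time-step stick spectra:

* stimulated emission (SE), negative, at the active-state -> S0 gap while
  the trajectory is electronically excited;
* excited-state absorption (ESA), positive, to states above the active
  one;
* hot-ground-state absorption after internal conversion, positive, at the
  S1 - S0 gap along the ground-state continuation, damped by an
  exponential vibrational-cooling factor.

Stick weights are |mu|^2 * (transition energy); the cubic-frequency
emission prefactor is deliberately omitted (recorded in metadata).
Sticks are Gaussian-broadened along probe energy, trajectory-averaged
and convolved along delay with a Gaussian instrument response function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .fssh import Ensemble, Trajectory
from .units import HARTREE_TO_EV

CHANNELS = ("SE", "ESA", "hotGS")


@dataclass
class TAMap:
    """Differential absorption on a (delay x probe energy) grid."""

    delays_fs: np.ndarray
    probe_energies_ev: np.ndarray
    delta_a: np.ndarray                      # (n_delay, n_energy)
    components: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.delays_fs, dtype=float)
        e = np.asarray(self.probe_energies_ev, dtype=float)
        if np.any(np.diff(d) <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("delay and probe-energy grids must be strictly increasing")
        self.delays_fs = d
        self.probe_energies_ev = e
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.delta_a.shape != (d.size, e.size):
            raise ValueError("delta_a shape does not match grids")

    def at(self, delay_fs: float, energy_ev: float) -> float:
        i = int(np.argmin(np.abs(self.delays_fs - delay_fs)))
        j = int(np.argmin(np.abs(self.probe_energies_ev - energy_ev)))
        return float(self.delta_a[i, j])


def trajectory_signals(
    traj: Trajectory,
    cooling_tau_fs: float = 2000.0,
) -> list[tuple[float, str, float, float]]:
    """Per-step stick spectra: (t_fs, channel, energy_eV, weight).

    Requires stored energies and dipoles at every step.
    """
    if traj.energies.size == 0 or traj.dipoles.size == 0:
        raise ValueError("trajectory carries no stored energies/dipoles")
    n_states = traj.energies.shape[1]
    sticks = []
    for k in range(traj.n_steps):
        if not np.all(np.isfinite(traj.dipoles[k])):
            raise ValueError(f"missing dipoles at step {k}")
        a = int(traj.active[k])
        E = traj.energies[k] * HARTREE_TO_EV
        mu = traj.dipoles[k]
        t = float(traj.t_fs[k])
        if a > 0:
            gap = E[a] - E[0]
            sticks.append((t, "SE", gap, -(mu[a, 0] ** 2) * gap))
            for b in range(a + 1, n_states):
                de = E[b] - E[a]
                sticks.append((t, "ESA", de, +(mu[a, b] ** 2) * de))
        else:
            gap = E[1] - E[0]
            damp = 1.0
            if not np.isnan(traj.hop_to_gs_fs) and cooling_tau_fs > 0:
                damp = np.exp(-max(t - traj.hop_to_gs_fs, 0.0) / cooling_tau_fs)
            sticks.append((t, "hotGS", gap, +(mu[1, 0] ** 2) * gap * damp))
    return sticks


def ensemble_ta_map(
    ensemble: Ensemble,
    sigma_e_ev: float = 0.15,
    irf_fwhm_fs: float = 30.0,
    delays_fs: np.ndarray | None = None,
    probe_energies_ev: np.ndarray | None = None,
    cooling_tau_fs: float = 2000.0,
) -> TAMap:
    """Trajectory-averaged, broadened, IRF-convolved TA map.

    Sticks outside the probe window are dropped (tallied in metadata).
    Trajectories that have terminated contribute nothing at later delays
    except their (cooling-damped) hot-ground-state absorption frozen at
    the final stored geometry.
    """
    if sigma_e_ev < 0:
        raise ValueError("sigma_e_ev must be >= 0 (0 = nearest-bin sticks)")
    if irf_fwhm_fs < 0:
        raise ValueError("irf_fwhm_fs must be >= 0")
    if delays_fs is None:
        delays_fs = ensemble.time_grid()
    if probe_energies_ev is None:
        probe_energies_ev = np.arange(1.8, 4.81, 0.02)
    delays_fs = np.asarray(delays_fs, dtype=float)
    E = np.asarray(probe_energies_ev, dtype=float)

    comps = {ch: np.zeros((delays_fs.size, E.size)) for ch in CHANNELS}
    dropped = 0
    n_traj = 0
    pad = 4.0 * sigma_e_ev
    for tr in ensemble.trajectories:
        if not tr.valid:
            continue
        n_traj += 1
        sticks = trajectory_signals(tr, cooling_tau_fs=cooling_tau_fs)
        t_arr = np.array([s[0] for s in sticks])
        ch_arr = np.array([s[1] for s in sticks])
        e_arr = np.array([s[2] for s in sticks])
        w_arr = np.array([s[3] for s in sticks])
        # trajectories terminated in S0 keep emitting hot-GS absorption
        # at their final geometry until the end of the delay grid
        if not np.isnan(tr.hop_to_gs_fs) and tr.t_fs[-1] < delays_fs[-1]:
            tail = delays_fs[delays_fs > tr.t_fs[-1]]
            gap = (tr.energies[-1, 1] - tr.energies[-1, 0]) * HARTREE_TO_EV
            mu = tr.dipoles[-1, 1, 0]
            damp = np.exp(-(tail - tr.hop_to_gs_fs) / cooling_tau_fs) if cooling_tau_fs > 0 else np.ones_like(tail)
            t_arr = np.concatenate([t_arr, tail])
            ch_arr = np.concatenate([ch_arr, np.full(tail.size, "hotGS")])
            e_arr = np.concatenate([e_arr, np.full(tail.size, gap)])
            w_arr = np.concatenate([w_arr, mu**2 * gap * damp])

        inside = (e_arr >= E[0] - pad) & (e_arr <= E[-1] + pad)
        dropped += int(np.sum(~inside))
        t_idx = np.searchsorted(delays_fs, t_arr[inside] - 1e-9)
        t_idx = np.clip(t_idx, 0, delays_fs.size - 1)
        if sigma_e_ev > 0:
            gauss = np.exp(
                -0.5 * ((E[None, :] - e_arr[inside, None]) / sigma_e_ev) ** 2
            ) / (sigma_e_ev * np.sqrt(2.0 * np.pi))
            contrib = w_arr[inside, None] * gauss
            for ch in CHANNELS:
                sel = ch_arr[inside] == ch
                if np.any(sel):
                    np.add.at(comps[ch], t_idx[sel], contrib[sel])
        else:  # delta sticks deposited into the nearest probe-energy bin
            e_idx = np.abs(E[None, :] - e_arr[inside, None]).argmin(axis=1)
            for ch in CHANNELS:
                sel = ch_arr[inside] == ch
                for ti, ei, w in zip(t_idx[sel], e_idx[sel], w_arr[inside][sel]):
                    comps[ch][ti, ei] += w

    for ch in CHANNELS:
        comps[ch] /= max(n_traj, 1)
        if irf_fwhm_fs > 0:
            d_delay = delays_fs[1] - delays_fs[0]
            sigma_t = irf_fwhm_fs / (2.0 * np.sqrt(2.0 * np.log(2.0))) / d_delay
            comps[ch] = gaussian_filter1d(comps[ch], sigma_t, axis=0, mode="nearest")

    total = comps["SE"] + comps["ESA"] + comps["hotGS"]
    return TAMap(
        delays_fs=delays_fs,
        probe_energies_ev=E,
        delta_a=total,
        components=comps,
        metadata={
            "sigma_e_ev": sigma_e_ev,
            "irf_fwhm_fs": irf_fwhm_fs,
            "cooling_tau_fs": cooling_tau_fs,
            "dropped_sticks": dropped,
            "n_trajectories": n_traj,
            "weight_convention": "|mu|^2 * transition_energy (no nu^3 prefactor)",
        },
    )


def polarization_weights(angle_rad: float, geometry: str = "magic") -> float:
    """Photoselection weight for a pump-probe polarization geometry.

    ``angle_rad`` is the angle between pump and probe transition dipoles.
    parallel: (1 + 2 cos^2)/15; orthogonal: (2 - cos^2)/15; magic angle:
    isotropic 1/9 independent of the angle.
    """
    c2 = np.cos(angle_rad) ** 2
    if geometry == "parallel":
        return (1.0 + 2.0 * c2) / 15.0
    if geometry == "orthogonal":
        return (2.0 - c2) / 15.0
    if geometry == "magic":
        return 1.0 / 9.0
    raise ValueError(f"unknown polarization geometry {geometry!r}")
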