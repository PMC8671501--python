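"""Excited-state minima, normal-mode analysis and mode-energy partitioning.

Normal modes come from a central-difference Hessian of the chosen
adiabatic surface, mass-weighted and diagonalized; imaginary frequencies
are reported as negative wavenumbers.  Per-mode vibrational energies
along a trajectory are harmonic energies in the mass-weighted normal
coordinates relative to the reference geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fssh import Trajectory
from .models import ElectronicModel, eval_adiabatic
from .units import angular_frequency_au_to_wavenumber


def _surface(model: ElectronicModel, state: int):
    def energy(q):
        return float(eval_adiabatic(model, q).energies[state])

    def gradient(q):
        return eval_adiabatic(model, q).gradients[state]

    return energy, gradient


def locate_minimum(
    model: ElectronicModel,
    state: int,
    q0: np.ndarray,
    gtol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Gradient minimization on one adiabatic surface.

    Converged when the gradient norm falls below 1e-7 hartree/bohr.
    """
    q0 = np.asarray(q0, dtype=float)
    if not np.all(np.isfinite(q0)):
        raise ValueError("q0 must be finite")
    energy, gradient = _surface(model, state)
    res = minimize(energy, q0, jac=gradient, method="BFGS",
                   options={"gtol": gtol, "maxiter": max_iter})
    gnorm = float(np.linalg.norm(gradient(res.x)))
    if gnorm > 1e-7:
        raise RuntimeError(
            f"minimization stalled at |grad| = {gnorm:.2e} hartree/bohr; last point {res.x}"
        )
    return res.x


@dataclass
class NormalModeSet:
    frequencies_cm: np.ndarray        # negative = imaginary
    mode_vectors: np.ndarray          # (n_modes, n_modes) mass-weighted, columns
    reference_q: np.ndarray
    state: int
    masses_amu: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_modes(self) -> int:
        return self.frequencies_cm.size


def normal_modes(
    model: ElectronicModel,
    state: int,
    q_min: np.ndarray,
    fd_step: float = 1e-3,
    force: bool = False,
) -> NormalModeSet:
    """Mass-weighted normal modes from a central-difference Hessian.

    Refuses to run off-minimum (gradient norm > 1e-6) unless ``force``.
    """
    q_min = np.asarray(q_min, dtype=float)
    energy, gradient = _surface(model, state)
    g = gradient(q_min)
    if np.linalg.norm(g) > 1e-6 and not force:
        raise ValueError(
            f"q_min is not stationary (|grad| = {np.linalg.norm(g):.2e}); "
            "pass force=True to override"
        )
    n = model.n_modes
    H = np.zeros((n, n))
    for k in range(n):
        qp = q_min.copy()
        qm = q_min.copy()
        qp[k] += fd_step
        qm[k] -= fd_step
        H[:, k] = (gradient(qp) - gradient(qm)) / (2.0 * fd_step)
    asym = float(np.max(np.abs(H - H.T)))
    H = 0.5 * (H + H.T)
    m = model.masses_au
    Hmw = H / np.sqrt(np.outer(m, m))
    w2, L = np.linalg.eigh(Hmw)
    freqs = np.sign(w2) * np.array(
        [angular_frequency_au_to_wavenumber(np.sqrt(abs(x))) for x in w2]
    )
    order = np.argsort(freqs)
    nms = NormalModeSet(
        frequencies_cm=freqs[order],
        mode_vectors=L[:, order],
        reference_q=q_min.copy(),
        state=state,
        masses_amu=model.masses_amu.copy(),
    )
    nms.hessian_asymmetry = asym
    return nms


def mode_energy_partition(traj: Trajectory, modes: NormalModeSet) -> np.ndarray:
    """Per-mode harmonic energy (hartree) vs time, shape (S, n_modes).

    E_k = (P_k^2 + omega_k^2 Q_k^2)/2 in mass-weighted normal coordinates
    relative to the reference geometry.
    """
    if traj.q.shape[1] != modes.n_modes:
        raise ValueError("trajectory and mode set dimension mismatch")
    from .units import AMU_TO_ME, wavenumber_to_angular_frequency_au

    m_au = modes.masses_amu * AMU_TO_ME
    sqm = np.sqrt(m_au)
    dq = (traj.q - modes.reference_q[None, :]) * sqm[None, :]
    pw = traj.p / sqm[None, :]
    Q = dq @ modes.mode_vectors          # (S, n_modes)
    P = pw @ modes.mode_vectors
    omega = np.array(
        [wavenumber_to_angular_frequency_au(abs(f)) if f != 0 else 0.0
         for f in modes.frequencies_cm]
    )
    return 0.5 * (P**2 + (omega[None, :] * Q) ** 2)


def export_normal_modes(modes: NormalModeSet, path_prefix) -> tuple:
    """Write a (mode index, wavenumber) table and the mode-vector matrix."""
    from pathlib import Path

    prefix = Path(path_prefix)
    table = prefix.with_suffix(".freq.tsv")
    with open(table, "w") as fh:
        fh.write("mode\twavenumber_cm\n")
        for i, f in enumerate(modes.frequencies_cm):
            fh.write(f"{i}\t{f:.4f}\n")
    matrix = prefix.with_suffix(".vectors.tsv")
    np.savetxt(matrix, modes.mode_vectors, delimiter="\t", fmt="%.12g")
    return table, matrix
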