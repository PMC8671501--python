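"""Fewest-switches surface hopping with decoherence correction.

Classical nuclei are propagated by velocity Verlet on the active
adiabatic surface; the electronic amplitudes follow the time-dependent
Schroedinger equation with energies and time-derivative couplings
(sigma_ij = d_ij . v) linearly interpolated across each nuclear step and
integrated by a fixed-substep 4th-order Runge-Kutta scheme in the
interaction picture (the dynamic phases are removed analytically, which
keeps the norm to ~1e-10 per step).  Stochastic hops follow the
fewest-switches prescription; accepted hops rescale the momentum along
the nonadiabatic coupling vector to conserve total energy; an
energy-based decoherence correction damps the non-active amplitudes.

Overdamped bath-like coordinates (e.g. a solvent mode) carry a friction
term; the dissipated work is tracked so that the energy-conservation
diagnostic remains meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import AdiabaticPoint, ElectronicModel, eval_adiabatic
from .units import FS_TO_AU, HARTREE_TO_EV

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _tdse_kernel(c, E0, E1, s0, s1, dt, n_sub):
    """Interaction-picture RK4 over ``n_sub`` substeps.

    The generator A(t)_ij = -sigma_ij(t) exp(i (phi_i - phi_j)(t)) is
    evaluated on the fly at node and half-node times; phi integrates the
    linearly interpolated energies analytically.
    """
    n = c.shape[0]
    h = dt / n_sub
    a = c.copy()
    k = np.empty(n, dtype=np.complex128)
    acc = np.empty(n, dtype=np.complex128)
    tmp = np.empty(n, dtype=np.complex128)
    A = np.empty((3, n, n), dtype=np.complex128)
    dE = E1 - E0
    for m in range(n_sub):
        # generator at t_m, t_m + h/2, t_m + h
        for node in range(3):
            t = (m + 0.5 * node) * h
            f = t / dt
            for i in range(n):
                phii = E0[i] * t + dE[i] * t * t / (2.0 * dt)
                for j in range(n):
                    phij = E0[j] * t + dE[j] * t * t / (2.0 * dt)
                    sig = s0[i, j] + f * (s1[i, j] - s0[i, j])
                    A[node, i, j] = -sig * np.exp(1j * (phii - phij))
        # RK4
        for i in range(n):
            k[i] = 0.0
            for j in range(n):
                k[i] += A[0, i, j] * a[j]
            acc[i] = k[i]
        for i in range(n):
            tmp[i] = a[i] + 0.5 * h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[1, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            acc[i] += 2.0 * k[i]
        for i in range(n):
            tmp[i] = a[i] + 0.5 * h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[1, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            acc[i] += 2.0 * k[i]
        for i in range(n):
            tmp[i] = a[i] + h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[2, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            a[i] = a[i] + (h / 6.0) * (acc[i] + k[i])
    for i in range(n):
        phi_end = E0[i] * dt + dE[i] * dt / 2.0
        a[i] = a[i] * np.exp(-1j * phi_end)
    return a


def tdse_step(
    c: np.ndarray,
    E0: np.ndarray,
    E1: np.ndarray,
    sigma0: np.ndarray,
    sigma1: np.ndarray,
    dt_au: float,
    n_substeps: int = 40,
) -> np.ndarray:
    """Propagate electronic amplitudes over one nuclear step.

    Energies and couplings are interpolated linearly in time.  The
    dynamic phase exp(-i int E_i dt) is applied analytically; only the
    coupling-driven part is integrated numerically (fixed-substep RK4),
    so norm conservation is limited by the tiny RK4 error on the
    couplings alone.
    """
    if n_substeps < 20:
        raise ValueError("n_substeps must be >= 20")
    c_new = _tdse_kernel(
        np.ascontiguousarray(c, dtype=np.complex128),
        np.ascontiguousarray(E0, dtype=np.float64),
        np.ascontiguousarray(E1, dtype=np.float64),
        np.ascontiguousarray(sigma0, dtype=np.float64),
        np.ascontiguousarray(sigma1, dtype=np.float64),
        float(dt_au),
        int(n_substeps),
    )
    norm = float(np.sum(np.abs(c_new) ** 2))
    if abs(norm - 1.0) > 1e-8:
        raise RuntimeError(
            f"electronic norm drifted to {norm:.12f} in one nuclear step; "
            "decrease dt or increase n_substeps"
        )
    return c_new


def hop_decision(
    c: np.ndarray,
    active: int,
    sigma: np.ndarray,
    dt_au: float,
    random_draw: float,
) -> int | None:
    """Fewest-switches hop proposal.

    g_{a->j} = max(0, 2 dt Re(c_a^* c_j sigma_aj) / |c_a|^2), compared
    cumulatively against ``random_draw``.  Returns the proposed target
    state or None.
    """
    if not 0.0 <= random_draw < 1.0:
        raise ValueError("random_draw must lie in [0, 1)")
    pop_a = float(np.abs(c[active]) ** 2)
    if pop_a < 1e-12:
        warnings.warn("active-state population vanished; skipping hop decision", stacklevel=2)
        return None
    g = 2.0 * dt_au * np.real(np.conj(c[active]) * c * sigma[active, :]) / pop_a
    g = np.maximum(g, 0.0)
    g[active] = 0.0
    cum = 0.0
    for j in range(c.size):
        cum += g[j]
        if random_draw < cum:
            return j
    return None


def rescale_momentum(
    p: np.ndarray,
    masses_au: np.ndarray,
    delta_e: float,
    direction: np.ndarray,
) -> tuple[np.ndarray, bool, float]:
    """Rescale the momentum component along ``direction`` to absorb a
    potential-energy change ``delta_e`` (hartree) at a hop.

    Returns ``(p_new, accepted, kinetic_deficit)``.  If the kinetic
    energy along the direction is insufficient for an upward hop the hop
    is frustrated and the momentum is returned unchanged.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0.0:
        raise ValueError("zero-norm rescaling direction")
    d = d / nrm
    a = 0.5 * float(np.sum(d * d / masses_au))
    b = float(np.sum(p * d / masses_au))
    disc = b * b - 4.0 * a * delta_e
    if disc < 0.0:
        deficit = (4.0 * a * delta_e - b * b) / (4.0 * a)
        return p, False, deficit
    sq = np.sqrt(disc)
    # root with the smaller momentum change
    g1 = (b - sq) / (2.0 * a)
    g2 = (b + sq) / (2.0 * a)
    gamma = g1 if abs(g1) <= abs(g2) else g2
    return p - gamma * d, True, 0.0


def decoherence_step(
    c: np.ndarray,
    active: int,
    energies: np.ndarray,
    kinetic_energy: float,
    dt_au: float,
    C: float = 0.1,
) -> np.ndarray:
    """Energy-based decoherence damping of non-active amplitudes.

    tau_i = (hbar/|E_i - E_a|) * (1 + C/E_kin); |c_i| is damped by
    exp(-dt/tau_i) and the active amplitude rescaled to restore the norm.
    Degenerate pairs (tau -> infinity) are left untouched.
    """
    if C < 0:
        raise ValueError("decoherence parameter C must be >= 0")
    c = c.copy()
    e_a = energies[active]
    others = 0.0
    for i in range(c.size):
        if i == active:
            continue
        gap = abs(energies[i] - e_a)
        if gap < 1e-12 or kinetic_energy <= 0.0:
            others += abs(c[i]) ** 2
            continue
        tau = (1.0 / gap) * (1.0 + C / kinetic_energy)
        c[i] *= np.exp(-dt_au / tau)
        others += abs(c[i]) ** 2
    pop_a = abs(c[active]) ** 2
    if pop_a > 0:
        c[active] *= np.sqrt(max(1.0 - others, 0.0) / pop_a)
    return c


# ---------------------------------------------------------------------------
# trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class HopEvent:
    t_hop_fs: float
    from_state: int
    to_state: int
    accepted: bool
    q_at_hop: np.ndarray
    kinetic_deficit_ev: float = 0.0


@dataclass
class TrajectoryState:
    t_fs: float
    q: np.ndarray
    p: np.ndarray
    active: int
    amplitudes: np.ndarray


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory (arrays per step)."""

    t_fs: np.ndarray
    q: np.ndarray                 # (S, n_modes) bohr
    p: np.ndarray                 # (S, n_modes) a.u.
    active: np.ndarray            # (S,) adiabatic state index
    amplitudes: np.ndarray        # (S, n_states) complex
    energies: np.ndarray          # (S, n_states) hartree
    dipoles: np.ndarray           # (S, n_states, n_states) a.u.
    events: list = field(default_factory=list)
    seed: int = 0
    valid: bool = True
    energy_drift: float = 0.0     # max drift between hops, SH phase (hartree)
    energy_drift_continuation: float = 0.0
    hop_to_gs_fs: float = np.nan  # time of the accepted hop to S0
    start_state: int = 1

    @property
    def n_steps(self) -> int:
        return self.t_fs.size

    def state_at(self, t_fs: float) -> int:
        """Active state at time t; trajectories that terminated after
        reaching the ground state count as S0 afterwards."""
        if t_fs <= self.t_fs[-1]:
            idx = int(np.searchsorted(self.t_fs, t_fs, side="right") - 1)
            return int(self.active[max(idx, 0)])
        return 0 if not np.isnan(self.hop_to_gs_fs) else int(self.active[-1])


@dataclass
class Ensemble:
    trajectories: list
    model: ElectronicModel | None = None
    base_seed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.trajectories[0].amplitudes.shape[1]

    def time_grid(self) -> np.ndarray:
        t_end = max(t.t_fs[-1] for t in self.trajectories)
        dt = self.trajectories[0].t_fs[1] - self.trajectories[0].t_fs[0]
        return np.arange(0.0, t_end + 0.5 * dt, dt)

    def populations(self, t_grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Fraction of trajectories on each adiabatic state vs time."""
        if t_grid is None:
            t_grid = self.time_grid()
        traj = [t for t in self.trajectories if t.valid]
        P = np.zeros((t_grid.size, self.n_states))
        for tr in traj:
            for k, t in enumerate(t_grid):
                P[k, tr.state_at(t)] += 1.0
        P /= len(traj)
        return t_grid, P


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def _sigma(point: AdiabaticPoint, v: np.ndarray) -> np.ndarray:
    return point.nac @ v


def run_trajectory(
    model: ElectronicModel,
    sample,
    dt_fs: float = 1.0,
    t_max_fs: float = 500.0,
    seed: int = 0,
    start_state: int | None = None,
    n_substeps: int = 40,
    decoherence_C: float = 0.1,
    frustrated_reversal: bool = False,
    gs_continuation_fs: float = 200.0,
    terminal_state: int | None = 0,
    drift_tol: float = 1e-4,
    continuation_substeps: int = 4,
) -> Trajectory:
    """Propagate one FSSH trajectory from a phase-space sample.

    After an accepted hop to the ground state the trajectory continues
    classically on S0 for ``gs_continuation_fs`` (feeding hot-ground-state
    spectra) with no further hopping, then terminates; that hot phase is
    integrated with ``continuation_substeps`` finer Verlet steps per
    stored step because the freshly formed hot ground state concentrates
    several eV of kinetic energy in the reaction coordinate.  Validity
    (``drift_tol``, hartree) is judged on the surface-hopping phase
    between hops; the continuation drift is tracked separately.  Fully
    reproducible for a given seed.
    """
    if dt_fs <= 0:
        raise ValueError("dt_fs must be positive")
    q = np.array(sample.q, dtype=float)
    p = np.array(sample.p, dtype=float)
    if q.size != model.n_modes:
        raise ValueError("sample dimension does not match model")
    masses = model.masses_au
    gamma = model.friction_au
    dt_au = dt_fs * FS_TO_AU
    rng = np.random.default_rng(seed)

    point = eval_adiabatic(model, q)
    if start_state is None:
        if model.n_states > 2:
            start_state = int(np.argmax(point.dipoles[0, 1:]) + 1)
        else:
            start_state = 1
    active = start_state
    n_states = model.n_states
    c = np.zeros(n_states, dtype=complex)
    c[active] = 1.0

    n_max = int(np.round(t_max_fs / dt_fs)) + 1
    T = np.empty(n_max)
    Q = np.empty((n_max, model.n_modes))
    Pm = np.empty((n_max, model.n_modes))
    Act = np.empty(n_max, dtype=np.int64)
    Amp = np.empty((n_max, n_states), dtype=complex)
    En = np.empty((n_max, n_states))
    Dip = np.empty((n_max, n_states, n_states))
    events: list[HopEvent] = []

    def kinetic(pv):
        return 0.5 * float(np.sum(pv * pv / masses))

    e_ref = point.energies[active] + kinetic(p)
    w_diss = 0.0
    max_drift = 0.0           # surface-hopping phase, between hops
    max_drift_cont = 0.0      # hot-ground-state continuation phase
    hop_to_gs = np.nan
    continuation_until = np.inf
    in_continuation = False

    step = 0
    t = 0.0
    while True:
        T[step] = t
        Q[step] = q
        Pm[step] = p
        Act[step] = active
        Amp[step] = c
        En[step] = point.energies
        Dip[step] = point.dipoles
        if t >= t_max_fs - 1e-9 or t >= continuation_until - 1e-9:
            step += 1
            break

        hopped_this_step = False
        # --- velocity Verlet with optional per-mode friction ----------
        n_nuc = continuation_substeps if in_continuation else 1
        h = dt_au / n_nuc
        q_new, p_new, new_point = q, p, point
        for _ in range(n_nuc):
            v = p_new / masses
            force = -new_point.gradients[active]
            acc = force / masses - gamma * v
            v_half = v + 0.5 * h * acc
            q_new = q_new + h * v_half
            new_point = eval_adiabatic(model, q_new, prev_U=new_point.U, validate=False)
            force_new = -new_point.gradients[active]
            v_new = (v_half + 0.5 * h * force_new / masses) / (1.0 + 0.5 * h * gamma)
            p_new = v_new * masses
            w_diss += float(np.sum(gamma * masses * v_half * v_half)) * h
        v = p / masses
        v_new = p_new / masses

        if not in_continuation:
            sig0 = _sigma(point, v)
            sig1 = _sigma(new_point, v_new)
            c = tdse_step(
                c, point.energies, new_point.energies, sig0, sig1, dt_au, n_substeps
            )
            sig_mid = 0.5 * (sig0 + sig1)
            target = hop_decision(c, active, sig_mid, dt_au, rng.random())
            if target is not None:
                delta_e = float(new_point.energies[target] - new_point.energies[active])
                direction = new_point.nac[active, target]
                if np.linalg.norm(direction) == 0.0 or not new_point.nac_reliable[
                    active, target
                ]:
                    direction = p_new.copy()  # fallback: full velocity
                e_before = new_point.energies[active] + kinetic(p_new)
                p_try, accepted, deficit = rescale_momentum(
                    p_new, masses, delta_e, direction
                )
                events.append(
                    HopEvent(
                        t_hop_fs=t + dt_fs,
                        from_state=active,
                        to_state=target,
                        accepted=accepted,
                        q_at_hop=q_new.copy(),
                        kinetic_deficit_ev=deficit * HARTREE_TO_EV,
                    )
                )
                if accepted:
                    p_new = p_try
                    active = target
                    hopped_this_step = True
                    e_after = new_point.energies[active] + kinetic(p_new)
                    if abs(e_after - e_before) > 1e-10:
                        warnings.warn(
                            f"hop energy mismatch {e_after - e_before:.2e} hartree",
                            stacklevel=2,
                        )
                    if terminal_state is not None and active == terminal_state:
                        hop_to_gs = t + dt_fs
                        continuation_until = min(t_max_fs, t + dt_fs + gs_continuation_fs)
                        in_continuation = True
                        c = np.zeros(n_states, dtype=complex)
                        c[0] = 1.0
                elif frustrated_reversal:
                    d = direction / np.linalg.norm(direction)
                    p_new = p_new - 2.0 * float(np.sum(p_new * d)) * d

            if not in_continuation and decoherence_C is not None:
                c = decoherence_step(
                    c, active, new_point.energies, kinetic(p_new), dt_au, decoherence_C
                )

        q, p, point = q_new, p_new, new_point
        t += dt_fs
        step += 1
        e_tot = point.energies[active] + kinetic(p)
        drift = abs(e_tot + w_diss - e_ref)
        if in_continuation:
            max_drift_cont = max(max_drift_cont, drift)
        else:
            max_drift = max(max_drift, drift)
        if hopped_this_step:
            # segment the drift diagnostic at hops (rescaling itself
            # conserves energy exactly, checked via the hop events)
            e_ref = e_tot + w_diss

    traj = Trajectory(
        t_fs=T[:step].copy(),
        q=Q[:step].copy(),
        p=Pm[:step].copy(),
        active=Act[:step].copy(),
        amplitudes=Amp[:step].copy(),
        energies=En[:step].copy(),
        dipoles=Dip[:step].copy(),
        events=events,
        seed=seed,
        valid=bool(max_drift <= drift_tol),
        energy_drift=max_drift,
        energy_drift_continuation=max_drift_cont,
        hop_to_gs_fs=hop_to_gs,
        start_state=start_state,
    )
    return traj


def run_ensemble(
    model: ElectronicModel,
    samples: Sequence,
    base_seed: int = 0,
    **traj_kwargs,
) -> Ensemble:
    """Independent FSSH trajectories with per-trajectory derived seeds."""
    if len(samples) == 0:
        raise ValueError("at least one sample is required")
    trajectories = []
    failures = 0
    for i, s in enumerate(samples):
        try:
            tr = run_trajectory(model, s, seed=base_seed + i, **traj_kwargs)
        except Exception as exc:  # partial failures are recorded, not fatal
            warnings.warn(f"trajectory {i} failed: {exc}", stacklevel=2)
            failures += 1
            continue
        trajectories.append(tr)
    if not trajectories or all(not t.valid for t in trajectories):
        raise RuntimeError("all trajectories failed or were invalid")
    return Ensemble(
        trajectories=trajectories,
        model=model,
        base_seed=base_seed,
        metadata={"n_requested": len(samples), "n_failed": failures},
    )


@njit(cache=True)
def _tdse_kernel_diabatic(c, V0, V1, dt, n_sub):
    """Interaction-picture RK4 for a diabatic Hamiltonian interpolated
    linearly across the step.  Diagonal phases are removed analytically;
    the generator is A_ij = -i V_ij(t) exp(i (phi_i - phi_j)(t)), i != j.
    """
    n = c.shape[0]
    h = dt / n_sub
    a = c.copy()
    k = np.empty(n, dtype=np.complex128)
    acc = np.empty(n, dtype=np.complex128)
    tmp = np.empty(n, dtype=np.complex128)
    A = np.empty((3, n, n), dtype=np.complex128)
    E0 = np.empty(n)
    dE = np.empty(n)
    for i in range(n):
        E0[i] = V0[i, i]
        dE[i] = V1[i, i] - V0[i, i]
    for m in range(n_sub):
        for node in range(3):
            t = (m + 0.5 * node) * h
            f = t / dt
            for i in range(n):
                phii = E0[i] * t + dE[i] * t * t / (2.0 * dt)
                for j in range(n):
                    if i == j:
                        A[node, i, j] = 0.0
                        continue
                    phij = E0[j] * t + dE[j] * t * t / (2.0 * dt)
                    vij = V0[i, j] + f * (V1[i, j] - V0[i, j])
                    A[node, i, j] = -1j * vij * np.exp(1j * (phii - phij))
        for i in range(n):
            k[i] = 0.0
            for j in range(n):
                k[i] += A[0, i, j] * a[j]
            acc[i] = k[i]
        for i in range(n):
            tmp[i] = a[i] + 0.5 * h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[1, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            acc[i] += 2.0 * k[i]
        for i in range(n):
            tmp[i] = a[i] + 0.5 * h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[1, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            acc[i] += 2.0 * k[i]
        for i in range(n):
            tmp[i] = a[i] + h * k[i]
        for i in range(n):
            s = 0.0 + 0.0j
            for j in range(n):
                s += A[2, i, j] * tmp[j]
            k[i] = s
        for i in range(n):
            a[i] = a[i] + (h / 6.0) * (acc[i] + k[i])
    for i in range(n):
        phi_end = E0[i] * dt + dE[i] * dt / 2.0
        a[i] = a[i] * np.exp(-1j * phi_end)
    return a


def hop_decision_diabatic(
    c: np.ndarray,
    active: int,
    V: np.ndarray,
    dt_au: float,
    random_draw: float,
) -> int | None:
    """Fewest-switches proposal in the diabatic representation.

    The population flux out of the active diabat towards j is
    -2 V_aj Im(c_a^* c_j); probabilities are clipped at zero and compared
    cumulatively against the random draw.
    """
    pop_a = float(np.abs(c[active]) ** 2)
    if pop_a < 1e-12:
        return None
    g = -2.0 * dt_au * V[active, :] * np.imag(np.conj(c[active]) * c) / pop_a
    g = np.maximum(g, 0.0)
    g[active] = 0.0
    cum = 0.0
    for j in range(c.size):
        cum += g[j]
        if random_draw < cum:
            return j
    return None


def diabatic_rehop(
    ensemble: Ensemble,
    extended_model: ElectronicModel,
    seed: int = 0,
    n_substeps: int = 40,
    decoherence_C: float | None = 0.1,
) -> dict:
    """Upper bound on transfer out of the bright state to added state(s).

    The electronic amplitudes are re-integrated in the *diabatic* basis of
    the extended model along the frozen nuclear paths of the ensemble;
    fewest-switches hop proposals towards the added (dark) diabats are
    counted without any kinetic-energy gate, yielding an upper limit for
    the fraction of trajectories that would depart from the bright state
    before their ground-state hop.  Re-running with the same seed
    reproduces every decision.
    """
    n_ext = extended_model.n_states
    if extended_model.n_modes != ensemble.trajectories[0].q.shape[1]:
        raise ValueError("extended model dimension does not match stored geometries")
    rng = np.random.default_rng(seed)
    departures = 0
    n_used = 0
    # the bright diabat is identified by its dipole to the ground diabat
    mu = np.asarray(extended_model.dipole(np.zeros(extended_model.n_modes)))
    bright = int(np.argmax(mu[0, 1:]) + 1)
    for tr in ensemble.trajectories:
        if not tr.valid:
            continue
        n_used += 1
        end = tr.n_steps
        if not np.isnan(tr.hop_to_gs_fs):
            end = int(np.searchsorted(tr.t_fs, tr.hop_to_gs_fs, side="right"))
        c = np.zeros(n_ext, dtype=complex)
        c[bright] = 1.0
        V_prev, _ = extended_model.potential(tr.q[0])
        departed = False
        for k in range(end - 1):
            dt_au = (tr.t_fs[k + 1] - tr.t_fs[k]) * FS_TO_AU
            V_next, _ = extended_model.potential(tr.q[k + 1])
            c = _tdse_kernel_diabatic(
                np.ascontiguousarray(c),
                np.ascontiguousarray(V_prev),
                np.ascontiguousarray(V_next),
                float(dt_au),
                int(n_substeps),
            )
            target = hop_decision_diabatic(
                c, bright, 0.5 * (V_prev + V_next), dt_au, rng.random()
            )
            if decoherence_C is not None:
                e_kin = 0.5 * float(
                    np.sum(tr.p[k + 1] ** 2 / extended_model.masses_au)
                )
                c = decoherence_step(
                    c, bright, np.diag(V_next).copy(), e_kin, dt_au, decoherence_C
                )
            V_prev = V_next
            if target is not None and target != 0 and target != bright:
                departed = True
                break
        if departed:
            departures += 1
    from .channels import wilson_interval

    frac = departures / n_used if n_used else np.nan
    lo, hi = wilson_interval(departures, n_used)
    return {
        "fraction": frac,
        "n": n_used,
        "departures": departures,
        "ci95": (lo, hi),
    }
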