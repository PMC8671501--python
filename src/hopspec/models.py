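"""Analytic multi-state vibronic model Hamiltonians.

These models stand in for on-the-fly excited-state electronic structure:
they expose a diabatic potential matrix V(q), its analytic gradient and a
transition-dipole matrix at any nuclear geometry, from which adiabatic
energies, gradients and nonadiabatic couplings are obtained by
diagonalization.

Two families are provided:

* the three canonical one-dimensional two-state scattering benchmarks
  (simple/dual avoided crossing, extended coupling) used to validate the
  surface-hopping engine against exact wavepacket propagation;
* a nucleoside-mimetic "pucker" model: a bright state that decays to the
  ground state through a barrier-controlled avoided crossing along a ring
  puckering coordinate, gap-modulating tuning modes (600/750 cm^-1 by
  default), a nearby dark state, and an overdamped solvent coordinate that
  gates the barrier height.

Internal units are atomic (hartree, bohr, electron mass); constructor
arguments use eV / cm^-1 / amu / fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .units import (
    AMU_TO_ME,
    EV_TO_HARTREE,
    FS_TO_AU,
    HARTREE_TO_EV,
    wavenumber_to_angular_frequency_au,
)

#: adiabatic gap (hartree) below which NAC vectors are flagged unreliable
DEGENERACY_TOL = 1e-5


@dataclass
class ElectronicModel:
    """Analytic diabatic vibronic model.

    ``potential(q)`` returns ``(V, dV)`` with ``V`` the symmetric diabatic
    matrix (hartree) and ``dV`` its gradient, shape ``(n, n, n_modes)``
    (hartree/bohr).  ``dipole(q)`` returns the symmetric non-negative
    transition-dipole magnitude matrix (a.u.).
    """

    n_states: int
    n_modes: int
    masses_amu: np.ndarray
    potential: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    dipole: Callable[[np.ndarray], np.ndarray]
    labels: Sequence[str]
    params: dict = field(default_factory=dict)
    #: per-mode sampling wavenumbers (cm^-1) for ground-state Wigner sampling
    sampling_wavenumbers_cm: np.ndarray | None = None
    #: per-mode friction coefficients (1/a.u. time); nonzero entries mark
    #: overdamped bath-like coordinates that are excluded from Wigner
    #: zero-point sampling and from hop momentum rescaling
    friction_au: np.ndarray | None = None
    #: named special coordinates, e.g. {"puckering": 0}
    coordinates: dict = field(default_factory=dict)
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.masses_amu = np.atleast_1d(np.asarray(self.masses_amu, dtype=float))
        if self.masses_amu.size != self.n_modes:
            raise ValueError("masses_amu length must equal n_modes")
        if np.any(self.masses_amu <= 0):
            raise ValueError("masses must be positive")
        if self.friction_au is None:
            self.friction_au = np.zeros(self.n_modes)
        else:
            self.friction_au = np.asarray(self.friction_au, dtype=float)

    @property
    def masses_au(self) -> np.ndarray:
        """Masses in electron-mass atomic units."""
        return self.masses_amu * AMU_TO_ME

    @property
    def overdamped_mask(self) -> np.ndarray:
        return self.friction_au > 0

    def diabatic(self, q: np.ndarray) -> np.ndarray:
        V, _ = self.potential(np.asarray(q, dtype=float))
        return V


@dataclass
class AdiabaticPoint:
    """Adiabatic electronic structure at one geometry.

    ``nac`` holds the derivative-coupling vectors d_ij (antisymmetric in
    i, j); pairs closer than the degeneracy tolerance have their coupling
    magnitude capped and are flagged in ``nac_reliable``.
    """

    q: np.ndarray
    energies: np.ndarray              # (n,) hartree, ascending
    gradients: np.ndarray             # (n, n_modes) hartree/bohr
    nac: np.ndarray                   # (n, n, n_modes)
    dipoles: np.ndarray               # (n, n) a.u., symmetric, >= 0
    U: np.ndarray                     # diabatic->adiabatic eigenvectors
    nac_reliable: np.ndarray          # (n, n) bool, False near degeneracy
    degenerate_pairs: list = field(default_factory=list)

    @property
    def energies_ev(self) -> np.ndarray:
        return self.energies * HARTREE_TO_EV


def eval_adiabatic(
    model: ElectronicModel,
    q: np.ndarray,
    prev_U: np.ndarray | None = None,
    nac_cap: float = 1e4,
    validate: bool = True,
) -> AdiabaticPoint:
    """Diagonalize the diabatic model at geometry ``q``.

    Energies are returned ascending.  Eigenvector phases are aligned with
    ``prev_U`` (maximum-overlap sign convention) to keep nonadiabatic
    couplings continuous along a trajectory.  NAC vectors for state pairs
    whose gap is below the degeneracy tolerance are capped at ``nac_cap``
    and flagged unreliable rather than silently diverging.  ``validate``
    can be switched off in propagation hot loops once the first point of
    a trajectory has been checked.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if q.size != model.n_modes:
        raise ValueError(f"geometry has {q.size} modes, model expects {model.n_modes}")
    if validate:
        if not np.all(np.isfinite(q)):
            raise ValueError("geometry contains non-finite values")

    V, dV = model.potential(q)
    if validate:
        V = np.asarray(V, dtype=float)
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("diabatic potential matrix is not symmetric")

    energies, U = np.linalg.eigh(V)
    if prev_U is not None:
        # sign alignment: flip eigenvector columns to maximize overlap
        overlaps = prev_U.T @ U
        signs = np.sign(np.diag(overlaps)).copy()
        signs[signs == 0] = 1.0
        U = U * signs[np.newaxis, :]

    n = model.n_states
    # transform gradient of V into the adiabatic basis: F_ij = <i|dV|j>
    # batched over modes: F[m] = U^T dV[:,:,m] U
    Fm = U.T @ np.moveaxis(dV, 2, 0) @ U          # (n_modes, n, n)
    F = np.moveaxis(Fm, 0, 2)                     # (n, n, n_modes)
    gradients = F[np.arange(n), np.arange(n), :].copy()

    gaps = energies[np.newaxis, :] - energies[:, np.newaxis]
    nac = np.zeros((n, n, model.n_modes))
    nac_reliable = np.ones((n, n), dtype=bool)
    degenerate_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            gap = gaps[i, j]
            if abs(gap) < DEGENERACY_TOL:
                d = F[i, j] / DEGENERACY_TOL
                norm = np.linalg.norm(d)
                if norm > nac_cap:
                    d = d * (nac_cap / norm)
                nac_reliable[i, j] = nac_reliable[j, i] = False
                degenerate_pairs.append((i, j))
            else:
                d = F[i, j] / gap
            nac[i, j] = d
            nac[j, i] = -d

    mu_diab = np.asarray(model.dipole(q), dtype=float)
    mu = np.abs(U.T @ mu_diab @ U)
    mu = 0.5 * (mu + mu.T)

    return AdiabaticPoint(
        q=q.copy(),
        energies=energies,
        gradients=gradients,
        nac=nac,
        dipoles=mu,
        U=U,
        nac_reliable=nac_reliable,
        degenerate_pairs=degenerate_pairs,
    )


# ---------------------------------------------------------------------------
# scattering benchmarks (1D, two states, mass 2000 m_e)
# ---------------------------------------------------------------------------

_TULLY_MASS_AMU = 2000.0 / AMU_TO_ME

_TULLY_PARAMS = {
    "simple_avoided_crossing": {"A": 0.01, "B": 1.6, "C": 0.005, "D": 1.0},
    "dual_avoided_crossing": {"A": 0.10, "B": 0.28, "C": 0.015, "D": 0.06, "E0": 0.05},
    "extended_coupling": {"A": 6e-4, "B": 0.10, "C": 0.90},
}


def make_tully_model(model_id: str) -> ElectronicModel:
    """Canonical 1D two-state scattering benchmarks.

    The particle mass is 2000 electron masses; all parameters are in
    atomic units and recorded in ``params``.
    """
    if model_id not in _TULLY_PARAMS:
        raise ValueError(
            f"unknown benchmark model {model_id!r}; choose from {sorted(_TULLY_PARAMS)}"
        )
    p = dict(_TULLY_PARAMS[model_id])

    if model_id == "simple_avoided_crossing":
        A, B, C, D = p["A"], p["B"], p["C"], p["D"]

        def potential(q):
            x = float(q[0])
            if x >= 0:
                v11 = A * (1.0 - np.exp(-B * x))
                d11 = A * B * np.exp(-B * x)
            else:
                v11 = -A * (1.0 - np.exp(B * x))
                d11 = A * B * np.exp(B * x)
            v12 = C * np.exp(-D * x * x)
            d12 = -2.0 * D * x * v12
            V = np.array([[v11, v12], [v12, -v11]])
            dV = np.array([[[d11], [d12]], [[d12], [-d11]]])
            return V, dV

    elif model_id == "dual_avoided_crossing":
        A, B, C, D, E0 = p["A"], p["B"], p["C"], p["D"], p["E0"]

        def potential(q):
            x = float(q[0])
            g = np.exp(-B * x * x)
            v22 = -A * g + E0
            d22 = 2.0 * A * B * x * g
            v12 = C * np.exp(-D * x * x)
            d12 = -2.0 * D * x * v12
            V = np.array([[0.0, v12], [v12, v22]])
            dV = np.array([[[0.0], [d12]], [[d12], [d22]]])
            return V, dV

    else:  # extended_coupling
        A, B, C = p["A"], p["B"], p["C"]

        def potential(q):
            x = float(q[0])
            if x < 0:
                v12 = B * np.exp(C * x)
                d12 = B * C * np.exp(C * x)
            else:
                v12 = B * (2.0 - np.exp(-C * x))
                d12 = B * C * np.exp(-C * x)
            V = np.array([[A, v12], [v12, -A]])
            dV = np.array([[[0.0], [d12]], [[d12], [0.0]]])
            return V, dV

    def dipole(q):
        return np.array([[0.0, 1.0], [1.0, 0.0]])

    return ElectronicModel(
        n_states=2,
        n_modes=1,
        masses_amu=np.array([_TULLY_MASS_AMU]),
        potential=potential,
        dipole=dipole,
        labels=("lower", "upper"),
        params={"model_id": model_id, **p, "mass_me": 2000.0},
        kind=f"tully:{model_id}",
    )


# ---------------------------------------------------------------------------
# nucleoside-mimetic pucker model
# ---------------------------------------------------------------------------

PUCKER_DEFAULTS = {
    # puckering coordinate
    "pucker_mass_amu": 1.0,          # ~1 for H out-of-plane, ~15 for CH3
    "pucker_wavenumber_cm": 400.0,   # ground-state curvature for mass 1 amu
    "barrier_eV": 0.0,               # static barrier height DE++
    "barrier_center_bohr": 1.2,
    "barrier_width_bohr": 0.28,
    "pucker_slope_eV": 0.005,         # bright-state gradient toward the seam
    # funnel towards the crossing with the ground state
    "drop_eV": 1.5,
    "drop_center_bohr": 2.2,
    "drop_width_bohr": 0.40,
    "gs_quartic_eV": 0.095,          # ground-state destabilization ~ a*x^4
    "wall_center_bohr": 3.6,
    "wall_width_bohr": 0.40,
    "wall_eV": 1.0,
    "coupling_eV": 0.25,             # diabatic bright/S0 coupling strength
    "coupling_width_bohr": 0.45,
    # vertical excitation and tuning modes
    "E_exc_eV": 4.6,
    # gap-modulating tuning modes: H-oop-like 600, ring-breathing-like 750,
    # and a fast C=C/C=O-stretch-like 1600 cm^-1 mode that carries the bulk
    # of the Stokes shift but whose oscillation is unresolvable under a
    # ~30 fs instrument response
    "tuning_wavenumbers_cm": (600.0, 750.0, 1600.0),
    "tuning_masses_amu": (1.0, 1.0, 1.0),
    "tuning_shift_eV": (0.04, 0.14, 0.22),  # per-mode reorganization energies
    # dark state
    "dark_offset_eV": 0.3,           # vertical offset from the bright state
    "dark_coupling_eV": 0.0,         # bright/dark diabatic coupling
    "dark_tracks_bright": True,      # dark state shares the tuning shifts
    # overdamped solvent coordinate gating the barrier
    "solvent_coupling_eV": 0.0,      # lambda_s
    "solvent_tau_fs": 85.0,
    "solvent_mass_amu": 10.0,
    # dipoles (a.u.)
    "mu_bright": 1.0,
    "mu_dark": 0.05,
    "mu_bright_dark": 0.3,
}


def make_pucker_model(params: dict | None = None, **kwargs) -> ElectronicModel:
    """Three-state (S0, bright, dark), four-mode nucleoside-mimetic model.

    Mode layout: ``[puckering, tuning-600, tuning-750, solvent]``.

    The bright state carries a Gaussian barrier of effective height
    ``barrier_eV + solvent_coupling_eV * (1 - s)`` along the puckering
    coordinate, followed by a funnel where the bright diabat drops while
    the destabilized ground-state diabat rises, producing an avoided
    crossing (the conical-intersection stand-in).  Tuning modes shift the
    bright (and, by default, the dark) state linearly, modulating the
    emission gap at 600 and 750 cm^-1.  The solvent coordinate is a
    critically damped harmonic mode whose excited-state equilibrium is
    displaced: its relaxation from s=0 to s=1 lowers the effective barrier.
    """
    p = dict(PUCKER_DEFAULTS)
    if params:
        p.update(params)
    p.update(kwargs)

    m_p = float(p["pucker_mass_amu"])
    if m_p <= 0:
        raise ValueError("pucker_mass_amu must be positive")
    tuning_nu = np.asarray(p["tuning_wavenumbers_cm"], dtype=float)
    tuning_m = np.asarray(p["tuning_masses_amu"], dtype=float)
    if np.any(tuning_nu <= 0) or np.any(tuning_m <= 0) or p["pucker_wavenumber_cm"] <= 0:
        raise ValueError("mode wavenumbers and masses must be positive")
    if p["solvent_coupling_eV"] < 0:
        raise ValueError("solvent_coupling_eV must be >= 0")
    n_tune = tuning_nu.size

    # --- internal (a.u.) parameters -----------------------------------
    m_p_au = m_p * AMU_TO_ME
    omega_x = wavenumber_to_angular_frequency_au(p["pucker_wavenumber_cm"])
    k_x = (1.0 * AMU_TO_ME) * omega_x**2          # force constant for 1 amu
    omega_t = np.array(
        [wavenumber_to_angular_frequency_au(nu) for nu in tuning_nu]
    )
    m_t_au = tuning_m * AMU_TO_ME
    k_t = m_t_au * omega_t**2
    lam = np.asarray(p["tuning_shift_eV"], dtype=float) * EV_TO_HARTREE
    kappa = np.sqrt(2.0 * lam * k_t)              # linear vibronic couplings

    E_exc = p["E_exc_eV"] * EV_TO_HARTREE
    dE = p["barrier_eV"] * EV_TO_HARTREE
    if not (0.0 <= p["barrier_eV"] <= 0.3):
        raise ValueError("barrier_eV outside the supported [0, 0.3] eV range")
    x_b, s_b = p["barrier_center_bohr"], p["barrier_width_bohr"]
    slope = p["pucker_slope_eV"] * EV_TO_HARTREE
    R = p["drop_eV"] * EV_TO_HARTREE
    x_d, s_d = p["drop_center_bohr"], p["drop_width_bohr"]
    a4 = p["gs_quartic_eV"] * EV_TO_HARTREE
    x_w, s_w, A_w = p["wall_center_bohr"], p["wall_width_bohr"], p["wall_eV"] * EV_TO_HARTREE
    c_gb = p["coupling_eV"] * EV_TO_HARTREE
    s_c = p["coupling_width_bohr"]
    dark_off = p["dark_offset_eV"] * EV_TO_HARTREE
    c_bd = p["dark_coupling_eV"] * EV_TO_HARTREE
    lam_s = p["solvent_coupling_eV"] * EV_TO_HARTREE

    tau_s_au = p["solvent_tau_fs"] * FS_TO_AU
    omega_s = 1.0 / tau_s_au
    m_s_au = p["solvent_mass_amu"] * AMU_TO_ME
    k_s = m_s_au * omega_s**2
    gamma_s = 2.0 * omega_s                       # critical damping

    sigma0 = 0.3                                  # left-wall switch width

    def _bright_base(x):
        """Bright diabat along x without the barrier bump."""
        conf = 0.5 * (1.0 - np.tanh(x / sigma0))
        theta = 0.5 * (1.0 + np.tanh((x - x_d) / s_d))
        wall = A_w * np.exp((x - x_w) / s_w)
        return E_exc + 0.5 * k_x * x * x * conf - slope * x - R * theta + wall

    def _bump_shape(x):
        return np.exp(-0.5 * ((x - x_b) / s_b) ** 2)

    # calibrate the bump amplitude so that the scanned minimum-energy
    # barrier (max minus preceding minimum, relaxed solvent) equals the
    # nominal barrier height despite the slope/drop background
    bump_corr = 0.0
    xs_cal = np.linspace(0.0, x_d, 800)
    base_cal = _bright_base(xs_cal)
    shape_cal = _bump_shape(xs_cal)
    if dE > 0:
        for _ in range(4):
            prof = base_cal + (dE + bump_corr) * shape_cal
            i_max = int(np.argmax(prof))
            i_min = int(np.argmin(prof[: i_max + 1]))
            bump_corr += dE - (prof[i_max] - prof[i_min])

    def _bright_diab(x):
        return _bright_base(x) + (dE + bump_corr) * _bump_shape(x)

    def _gs_diab(x):
        return 0.5 * k_x * x * x + a4 * x**4

    from scipy.optimize import brentq

    lo, hi = x_b, x_w
    f = lambda x: _bright_diab(x) - _gs_diab(x)
    if f(lo) * f(hi) < 0:
        x_ci = brentq(f, lo, hi, xtol=1e-10)
    else:  # no crossing in range (e.g. huge barrier); park coupling at drop
        x_ci = x_d
    E_ci = _gs_diab(x_ci)

    n_modes = 1 + n_tune + 1
    i_s = n_modes - 1

    def potential(q):
        x = float(q[0])
        qt = np.asarray(q[1 : 1 + n_tune], dtype=float)
        s = float(q[i_s])

        tanh0 = np.tanh(x / sigma0)
        conf = 0.5 * (1.0 - tanh0)
        dconf = -0.5 * (1.0 - tanh0**2) / sigma0
        tanhd = np.tanh((x - x_d) / s_d)
        theta = 0.5 * (1.0 + tanhd)
        dtheta = 0.5 * (1.0 - tanhd**2) / s_d
        wall = A_w * np.exp((x - x_w) / s_w)
        dwall = wall / s_w
        gauss_b = np.exp(-0.5 * ((x - x_b) / s_b) ** 2)
        dgauss_b = -((x - x_b) / s_b**2) * gauss_b
        B_eff = dE + bump_corr + lam_s * (1.0 - s)

        harm_t = 0.5 * k_t * qt * qt
        V00 = 0.5 * k_x * x * x + a4 * x**4 + np.sum(harm_t) + 0.5 * k_s * s * s
        V11 = (
            E_exc
            + 0.5 * k_x * x * x * conf
            - slope * x
            + B_eff * gauss_b
            - R * theta
            + wall
            + np.sum(harm_t + kappa * qt)
            + 0.5 * k_s * (s - 1.0) ** 2
        )
        if p["dark_tracks_bright"]:
            dark_t = np.sum(harm_t + kappa * qt)
        else:
            dark_t = np.sum(harm_t)
        V22 = (
            E_exc
            + dark_off
            + 0.5 * k_x * x * x * conf
            + wall
            + dark_t
            + 0.5 * k_s * s * s
        )
        gauss_c = np.exp(-0.5 * ((x - x_ci) / s_c) ** 2)
        V01 = c_gb * gauss_c
        dV01 = -((x - x_ci) / s_c**2) * V01

        V = np.zeros((3, 3))
        V[0, 0], V[1, 1], V[2, 2] = V00, V11, V22
        V[0, 1] = V[1, 0] = V01
        V[1, 2] = V[2, 1] = c_bd

        dV = np.zeros((3, 3, n_modes))
        # x derivatives
        dV[0, 0, 0] = k_x * x + 4.0 * a4 * x**3
        dV[1, 1, 0] = (
            0.5 * k_x * (2.0 * x * conf + x * x * dconf)
            - slope
            + B_eff * dgauss_b
            - R * dtheta
            + dwall
        )
        dV[2, 2, 0] = 0.5 * k_x * (2.0 * x * conf + x * x * dconf) + dwall
        dV[0, 1, 0] = dV[1, 0, 0] = dV01
        # tuning-mode derivatives
        for k in range(n_tune):
            dV[0, 0, 1 + k] = k_t[k] * qt[k]
            dV[1, 1, 1 + k] = k_t[k] * qt[k] + kappa[k]
            dV[2, 2, 1 + k] = k_t[k] * qt[k] + (
                kappa[k] if p["dark_tracks_bright"] else 0.0
            )
        # solvent derivatives
        dV[0, 0, i_s] = k_s * s
        dV[1, 1, i_s] = k_s * (s - 1.0) - lam_s * gauss_b
        dV[2, 2, i_s] = k_s * s
        return V, dV

    mu_b, mu_d, mu_bd = p["mu_bright"], p["mu_dark"], p["mu_bright_dark"]

    def dipole(q):
        return np.array(
            [
                [0.0, mu_b, mu_d],
                [mu_b, 0.0, mu_bd],
                [mu_d, mu_bd, 0.0],
            ]
        )

    masses_amu = np.concatenate(
        [[m_p], tuning_m, [p["solvent_mass_amu"]]]
    )
    # sampling wavenumbers: ground-state curvature per mode at q=0
    nu_x = p["pucker_wavenumber_cm"] / np.sqrt(m_p)
    nu_s = omega_s  # placeholder; the solvent mode is overdamped, not sampled
    sampling = np.concatenate(
        [[nu_x], tuning_nu, [nu_s * 219474.63 if nu_s > 0 else 1.0]]
    )
    friction = np.zeros(n_modes)
    friction[i_s] = gamma_s

    params_out = dict(p)
    params_out.update(
        {
            "x_ci_bohr": x_ci,
            "E_ci_eV": E_ci * HARTREE_TO_EV,
            "bump_correction_eV": bump_corr * HARTREE_TO_EV,
        }
    )

    return ElectronicModel(
        n_states=3,
        n_modes=n_modes,
        masses_amu=masses_amu,
        potential=potential,
        dipole=dipole,
        labels=("S0", "pipi*", "npi*"),
        params=params_out,
        sampling_wavenumbers_cm=sampling,
        friction_au=friction,
        coordinates={
            "puckering": 0,
            "ring_opening": 1,
            "O_oop": 2,
            "solvent": i_s,
        },
        kind="pucker",
    )


def puckering_barrier_scan(
    model: ElectronicModel,
    solvent_value: float = 1.0,
    x_range: tuple[float, float] = (0.0, None),
    n_points: int = 2000,
) -> dict:
    """Scan the bright adiabatic surface along the puckering coordinate.

    Tuning modes are held at zero and the solvent coordinate at
    ``solvent_value``.  Returns the minimum-energy barrier (eV) between
    the Franck-Condon-side minimum and the crossing region.
    """
    if "puckering" not in model.coordinates:
        raise ValueError("model has no puckering coordinate")
    i_x = model.coordinates["puckering"]
    x_hi = x_range[1] if x_range[1] is not None else model.params.get("x_ci_bohr", 3.0)
    xs = np.linspace(x_range[0], x_hi, n_points)
    bright = model.labels.index("pipi*") if "pipi*" in model.labels else 1
    energies = np.empty_like(xs)
    q = np.zeros(model.n_modes)
    if "solvent" in model.coordinates:
        q[model.coordinates["solvent"]] = solvent_value
    for k, x in enumerate(xs):
        q[i_x] = x
        V, _ = model.potential(q)
        w = np.linalg.eigvalsh(V)
        # follow the bright diabat by overlap with the diabatic bright state
        _, U = np.linalg.eigh(V)
        idx = int(np.argmax(np.abs(U[bright, :])))
        energies[k] = w[idx]
    e_ev = energies * HARTREE_TO_EV
    # FC-side minimum = lowest point left of the global maximum
    i_max = int(np.argmax(e_ev))
    i_min = int(np.argmin(e_ev[: max(i_max, 1)]))
    barrier = float(e_ev[i_max] - e_ev[i_min])
    return {
        "x": xs,
        "energy_eV": e_ev,
        "barrier_eV": barrier,
        "x_barrier": float(xs[i_max]),
        "x_min": float(xs[i_min]),
    }


# ---------------------------------------------------------------------------
# config round trip
# ---------------------------------------------------------------------------

def model_to_config(model: ElectronicModel) -> dict:
    """Serializable description from which the model can be rebuilt."""
    cfg = {
        "kind": model.kind,
        "states": list(model.labels),
        "modes": model.n_modes,
        "masses_amu": model.masses_amu.tolist(),
    }
    params = {
        k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
        for k, v in model.params.items()
    }
    cfg["params"] = params
    return cfg


def model_from_config(cfg: dict) -> ElectronicModel:
    kind = cfg.get("kind", "")
    params = dict(cfg.get("params", {}))
    if kind.startswith("tully:"):
        return make_tully_model(kind.split(":", 1)[1])
    if kind == "pucker":
        params.pop("x_ci_bohr", None)
        params.pop("E_ci_eV", None)
        params.pop("bump_correction_eV", None)
        return make_pucker_model(params)
    raise ValueError(f"cannot rebuild model of kind {kind!r} from config")
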