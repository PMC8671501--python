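"""Ground-state Wigner sampling of initial conditions.

Positions and momenta are drawn per mode from the T=0 harmonic-oscillator
Wigner function, i.e. independent Gaussians with

    Var(q) = hbar / (2 m omega),      Var(p) = hbar m omega / 2.

An excitation-window filter then keeps samples whose vertical gap to the
bright state falls inside the pump spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ElectronicModel, eval_adiabatic
from .units import AMU_TO_ME, HARTREE_TO_EV, wavenumber_to_angular_frequency_au


@dataclass
class PhaseSpaceSample:
    """One phase-space point (a.u.) with its bright-state vertical gap."""

    q: np.ndarray
    p: np.ndarray
    vertical_gap_ev: float = np.nan
    weight: float = 1.0


def wigner_sample(
    frequencies_cm: np.ndarray,
    masses_amu: np.ndarray,
    n: int,
    seed: int,
    skip_modes: np.ndarray | None = None,
) -> list[PhaseSpaceSample]:
    """Draw ``n`` T=0 Wigner samples for uncoupled harmonic modes.

    ``skip_modes`` marks overdamped/classical coordinates that are pinned
    at (q, p) = (0, 0) instead of being zero-point sampled.  Reproducible
    per ``seed``.
    """
    freqs = np.atleast_1d(np.asarray(frequencies_cm, dtype=float))
    masses = np.atleast_1d(np.asarray(masses_amu, dtype=float))
    if freqs.shape != masses.shape:
        raise ValueError("frequencies and masses must have the same length")
    if np.any(freqs <= 0):
        raise ValueError("all mode frequencies must be positive (no free rotors)")
    if n < 1:
        raise ValueError("n must be >= 1")

    omega = np.array([wavenumber_to_angular_frequency_au(f) for f in freqs])
    m_au = masses * AMU_TO_ME
    sigma_q = np.sqrt(1.0 / (2.0 * m_au * omega))
    sigma_p = np.sqrt(m_au * omega / 2.0)
    if skip_modes is not None:
        mask = np.asarray(skip_modes, dtype=bool)
        sigma_q = np.where(mask, 0.0, sigma_q)
        sigma_p = np.where(mask, 0.0, sigma_p)

    rng = np.random.default_rng(seed)
    qs = rng.normal(0.0, 1.0, size=(n, freqs.size)) * sigma_q
    ps = rng.normal(0.0, 1.0, size=(n, freqs.size)) * sigma_p
    return [PhaseSpaceSample(q=qs[i], p=ps[i]) for i in range(n)]


def sample_for_model(model: ElectronicModel, n: int, seed: int) -> list[PhaseSpaceSample]:
    """Wigner-sample a model's ground state and attach vertical gaps."""
    if model.sampling_wavenumbers_cm is None:
        raise ValueError("model carries no sampling wavenumbers")
    samples = wigner_sample(
        model.sampling_wavenumbers_cm,
        model.masses_amu,
        n,
        seed,
        skip_modes=model.overdamped_mask,
    )
    bright = model.labels.index("pipi*") if "pipi*" in model.labels else 1
    for s in samples:
        point = eval_adiabatic(model, s.q)
        # the bright adiabatic state is identified by its dipole to S0
        idx = bright
        if model.n_states > 2:
            idx = int(np.argmax(point.dipoles[0, 1:]) + 1)
        s.vertical_gap_ev = float(
            (point.energies[idx] - point.energies[0]) * HARTREE_TO_EV
        )
    return samples


@dataclass
class ExcitationWindowResult:
    samples: list = field(default_factory=list)
    acceptance_ratio: float = 0.0
    window_ev: tuple = (0.0, 0.0)


def excitation_window(
    samples: list[PhaseSpaceSample],
    model: ElectronicModel | None,
    window_ev: tuple[float, float],
) -> ExcitationWindowResult:
    """Keep samples whose bright-state vertical gap lies inside the window.

    Gaps missing from the samples are computed from ``model``.  An empty
    selection is returned (with a warning) rather than raised.
    """
    e_lo, e_hi = window_ev
    if not e_lo < e_hi:
        raise ValueError("window must satisfy E_lo < E_hi")
    kept = []
    for s in samples:
        gap = s.vertical_gap_ev
        if not np.isfinite(gap):
            if model is None:
                raise ValueError("sample lacks a vertical gap and no model was given")
            point = eval_adiabatic(model, s.q)
            idx = 1
            if model.n_states > 2:
                idx = int(np.argmax(point.dipoles[0, 1:]) + 1)
            gap = float((point.energies[idx] - point.energies[0]) * HARTREE_TO_EV)
            s.vertical_gap_ev = gap
        if e_lo <= gap <= e_hi:
            kept.append(s)
    ratio = len(kept) / len(samples) if samples else 0.0
    if not kept:
        import warnings

        warnings.warn("excitation window selected no samples", stacklevel=2)
    return ExcitationWindowResult(samples=kept, acceptance_ratio=ratio, window_ev=(e_lo, e_hi))


def samples_to_table(samples: list[PhaseSpaceSample]) -> np.ndarray:
    """Tabular (n, 2*n_modes+1) array: coordinates, momenta, gap (eV)."""
    rows = [np.concatenate([s.q, s.p, [s.vertical_gap_ev]]) for s in samples]
    return np.asarray(rows)
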