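"""Exact quantum reference: split-operator wavepacket propagation.

Grid-based propagation of a two-state wavepacket in the diabatic
representation, used as the independent benchmark for the surface-hopping
engine on the 1D scattering models.  Kinetic and potential propagators
alternate (Strang splitting); the 2x2 potential exponential is evaluated
in closed form per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ElectronicModel


def _diabatic_on_grid(model: ElectronicModel, x: np.ndarray) -> np.ndarray:
    V = np.empty((x.size, 2, 2))
    for k, xi in enumerate(x):
        Vk, _ = model.potential(np.array([xi]))
        V[k] = Vk
    return V


def _potential_propagator(V: np.ndarray, dt: float) -> np.ndarray:
    """exp(-i V dt) for a stack of real-symmetric 2x2 matrices."""
    a, b, c = V[:, 0, 0], V[:, 1, 1], V[:, 0, 1]
    mean = 0.5 * (a + b)
    dif = 0.5 * (a - b)
    r = np.sqrt(dif * dif + c * c)
    # exp(-i V dt) = e^{-i mean dt} [cos(r dt) I - i sin(r dt) (n . sigma)]
    cos = np.cos(r * dt)
    sinc = np.where(r > 0, np.sin(r * dt) / np.where(r > 0, r, 1.0), dt)
    phase = np.exp(-1j * mean * dt)
    U = np.empty((V.shape[0], 2, 2), dtype=complex)
    U[:, 0, 0] = phase * (cos - 1j * sinc * dif)
    U[:, 1, 1] = phase * (cos + 1j * sinc * dif)
    U[:, 0, 1] = U[:, 1, 0] = phase * (-1j * sinc * c)
    return U


@dataclass
class ScatteringResult:
    """Asymptotic branching of a scattered two-state wavepacket."""

    transmission_lower: float
    transmission_upper: float
    reflection_lower: float
    reflection_upper: float

    @property
    def population_lower(self) -> float:
        return self.transmission_lower + self.reflection_lower

    @property
    def population_upper(self) -> float:
        return self.transmission_upper + self.reflection_upper


def scatter_wavepacket(
    model: ElectronicModel,
    k0: float,
    x0: float = -10.0,
    sigma_x: float | None = None,
    x_span: tuple[float, float] = (-30.0, 30.0),
    n_grid: int = 4096,
    dt: float = 5.0,
    t_max: float | None = None,
    initial_state: int = 0,
) -> ScatteringResult:
    """Scatter a Gaussian wavepacket of mean momentum ``k0`` (a.u.).

    The packet starts on adiabatic ``initial_state`` (asymptotically equal
    to a diabatic state) left of the interaction region and is propagated
    until it has left the region; populations are then projected onto the
    local adiabatic states and split by transmission/reflection.
    """
    if model.n_states != 2 or model.n_modes != 1:
        raise ValueError("wavepacket oracle supports 1D two-state models only")
    mass = float(model.masses_au[0])
    if sigma_x is None:
        sigma_x = 20.0 / k0  # narrow momentum spread relative to k0

    x = np.linspace(*x_span, n_grid, endpoint=False)
    dx = x[1] - x[0]
    k = 2.0 * np.pi * np.fft.fftfreq(n_grid, d=dx)

    V = _diabatic_on_grid(model, x)
    # adiabatic basis per grid point (for initialization and projection)
    evals = np.linalg.eigvalsh(V)
    evecs = np.empty_like(V)
    for i in range(n_grid):
        _, U = np.linalg.eigh(V[i])
        evecs[i] = U

    gauss = np.exp(-((x - x0) ** 2) / (4.0 * sigma_x**2)) * np.exp(1j * k0 * x)
    gauss /= np.linalg.norm(gauss)
    psi = np.zeros((2, n_grid), dtype=complex)
    # populate the chosen adiabatic state at the starting location
    psi[0] = evecs[:, 0, initial_state] * gauss
    psi[1] = evecs[:, 1, initial_state] * gauss

    expT = np.exp(-1j * (k**2) / (2.0 * mass) * dt)
    expT_half = np.exp(-1j * (k**2) / (2.0 * mass) * (dt / 2.0))
    expV = _potential_propagator(V, dt)

    if t_max is None:
        # time to traverse the box twice at the mean group velocity
        t_max = 2.5 * (x_span[1] - x_span[0]) / (k0 / mass)
    n_steps = int(np.ceil(t_max / dt))

    # first half kinetic step
    psi = np.fft.ifft(expT_half * np.fft.fft(psi, axis=1), axis=1)
    edge = int(0.05 * n_grid)
    absorber = np.ones(n_grid)
    taper = np.sin(np.linspace(0, np.pi / 2, edge)) ** 2
    absorber[:edge] = taper
    absorber[-edge:] = taper[::-1]
    captured = np.zeros(4)  # [refl_lower, refl_upper, trans_lower, trans_upper]

    def _capture(psi):
        """Project the absorbed outgoing flux onto adiabatic channels."""
        amp_ad0 = evecs[:, 0, 0] * psi[0] + evecs[:, 1, 0] * psi[1]
        amp_ad1 = evecs[:, 0, 1] * psi[0] + evecs[:, 1, 1] * psi[1]
        w = 1.0 - absorber**2
        left = x < 0
        captured[0] += np.sum(w[left] * np.abs(amp_ad0[left]) ** 2)
        captured[1] += np.sum(w[left] * np.abs(amp_ad1[left]) ** 2)
        captured[2] += np.sum(w[~left] * np.abs(amp_ad0[~left]) ** 2)
        captured[3] += np.sum(w[~left] * np.abs(amp_ad1[~left]) ** 2)

    for step in range(n_steps):
        psi = np.einsum("xab,bx->ax", expV, psi)
        psi = np.fft.ifft(expT * np.fft.fft(psi, axis=1), axis=1)
        _capture(psi)
        psi *= absorber
        if np.sum(np.abs(psi) ** 2) < 1e-6:
            break

    # whatever remains on the grid, assign by position/state
    amp_ad0 = evecs[:, 0, 0] * psi[0] + evecs[:, 1, 0] * psi[1]
    amp_ad1 = evecs[:, 0, 1] * psi[0] + evecs[:, 1, 1] * psi[1]
    left = x < 0
    captured[0] += np.sum(np.abs(amp_ad0[left]) ** 2)
    captured[1] += np.sum(np.abs(amp_ad1[left]) ** 2)
    captured[2] += np.sum(np.abs(amp_ad0[~left]) ** 2)
    captured[3] += np.sum(np.abs(amp_ad1[~left]) ** 2)

    total = captured.sum()
    captured /= total
    return ScatteringResult(
        reflection_lower=captured[0],
        reflection_upper=captured[1],
        transmission_lower=captured[2],
        transmission_upper=captured[3],
    )
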