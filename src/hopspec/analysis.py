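"""Analysis protocol for transient-absorption maps.

The same pipeline is applied to simulated and measured maps:

* IRF-convolved global multi-exponential fitting by separable
  (variable-projection) least squares -> time constants and
  decay-associated spectra (DAS);
* mono-exponential population lifetime fits;
* zero-phase bandpass-Fourier extraction of the oscillatory residuals;
* windowed, zero-padded 2D Fourier-transform maps of the residuals with
  node and phase-jump detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.special import erfcx

from .spectroscopy import TAMap
from .units import PERIOD_FS_CM


def wavenumber_to_period(wavenumber_cm: float) -> float:
    """Vibrational period in fs: T = 33356.41 / wavenumber[cm^-1]."""
    if wavenumber_cm <= 0:
        raise ValueError("wavenumber must be positive")
    return PERIOD_FS_CM / wavenumber_cm


def exp_conv_irf(t: np.ndarray, tau: float, irf_fwhm: float, t0: float = 0.0) -> np.ndarray:
    """Exponential decay convolved with a Gaussian IRF (analytic).

    Overflow-safe via the scaled complementary error function.
    """
    t = np.asarray(t, dtype=float)
    if irf_fwhm <= 0:
        out = np.exp(-np.clip((t - t0) / tau, 0.0, 700.0))
        out[t < t0] = 0.0
        return out
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    x = t - t0
    arg = sigma / (np.sqrt(2.0) * tau) - x / (np.sqrt(2.0) * sigma)
    out = np.empty_like(x, dtype=float)
    early = arg >= 0  # rising edge: scaled erfc avoids exp overflow
    out[early] = 0.5 * np.exp(-0.5 * (x[early] / sigma) ** 2) * erfcx(arg[early])
    late = ~early  # decaying tail: the plain form is already stable
    from scipy.special import erfc

    out[late] = 0.5 * np.exp(sigma**2 / (2 * tau**2) - x[late] / tau) * erfc(arg[late])
    return out


@dataclass
class GlobalFitResult:
    taus_fs: np.ndarray
    das: np.ndarray                  # (n_exp, n_energy)
    irf_fwhm_fs: float
    t0_fs: float
    residual_rms: float
    tau_stderr_fs: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    n_iterations: int = 0

    def reconstruct(self, delays_fs: np.ndarray) -> np.ndarray:
        C = np.stack(
            [exp_conv_irf(delays_fs, tau, self.irf_fwhm_fs, self.t0_fs) for tau in self.taus_fs]
        )
        return C.T @ self.das


def _das_solve(M: np.ndarray, delays: np.ndarray, taus, irf_fwhm, t0):
    C = np.stack([exp_conv_irf(delays, tau, irf_fwhm, t0) for tau in taus])  # (k, T)
    das, *_ = np.linalg.lstsq(C.T, M, rcond=None)
    resid = M - C.T @ das
    return das, resid


def global_fit(
    tamap: TAMap,
    n_exp: int,
    irf_fwhm_fs: float = 30.0,
    t_fit_window: tuple[float, float] | None = None,
    fit_t0: bool = False,
    tau_guesses_fs: np.ndarray | None = None,
) -> GlobalFitResult:
    """Separable least-squares global fit of an IRF-convolved
    multi-exponential model.

    Nonlinear in the time constants (and optionally t0), linear in the
    decay-associated spectra.  Deterministic: a fixed multi-start grid of
    time-constant decades seeds the optimizer unless explicit guesses are
    given.
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    delays = tamap.delays_fs
    M = tamap.delta_a
    if t_fit_window is not None:
        lo, hi = t_fit_window
        if lo < delays[0] - 1e-9 or hi > delays[-1] + 1e-9:
            raise ValueError("fit window outside the delay grid")
        sel = (delays >= lo) & (delays <= hi)
        delays = delays[sel]
        M = M[sel]

    span = max(delays[-1] - max(delays[0], 0.0), 10.0)

    def pack(taus, t0):
        x = list(np.log(taus))
        if fit_t0:
            x.append(t0)
        return np.array(x)

    def unpack(x):
        taus = np.exp(x[:n_exp])
        t0 = x[n_exp] if fit_t0 else 0.0
        return taus, t0

    def residual(x):
        taus, t0 = unpack(x)
        _, resid = _das_solve(M, delays, taus, irf_fwhm_fs, t0)
        return resid.ravel()

    if tau_guesses_fs is not None:
        starts = [np.sort(np.asarray(tau_guesses_fs, dtype=float))]
    else:
        # multi-start over decades, log-spaced within the window span
        grid = np.geomspace(span / 100.0, span, 6)
        if n_exp == 1:
            starts = [np.array([g]) for g in grid]
        else:
            starts = []
            for i in range(len(grid) - n_exp + 1):
                starts.append(grid[i : i + n_exp])

    best = None
    for s in starts:
        try:
            sol = least_squares(residual, pack(s, 0.0), method="lm", max_nfev=400)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("global fit failed to converge from any start")

    taus, t0 = unpack(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    das, resid = _das_solve(M, delays, taus, irf_fwhm_fs, t0)
    das = das[order] if das.shape[0] == n_exp else das

    # per-tau confidence from the Jacobian of the projected problem
    J = best.jac
    dof = max(resid.size - J.shape[1], 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        stderr_log = np.sqrt(np.diag(cov))[:n_exp][order]
        tau_stderr = taus * stderr_log
    except np.linalg.LinAlgError:
        tau_stderr = np.full(n_exp, np.nan)

    return GlobalFitResult(
        taus_fs=taus,
        das=das,
        irf_fwhm_fs=irf_fwhm_fs,
        t0_fs=t0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        tau_stderr_fs=tau_stderr,
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )


def fit_population_lifetime(
    t_fs: np.ndarray,
    population: np.ndarray,
    model: str = "monoexp",
    t0_free: bool = False,
    plateau: bool = False,
) -> tuple[float, float]:
    """Mono-exponential fit of an excited-state population trace.

    Returns (tau_fs, stderr_fs).  Raises on a non-decaying trace.
    """
    if model != "monoexp":
        raise ValueError("only the mono-exponential model is supported")
    t = np.asarray(t_fs, dtype=float)
    P = np.asarray(population, dtype=float)
    if t.size == 0 or P.size == 0:
        raise ValueError("empty trace")
    if np.any((P < -1e-9) | (P > 1 + 1e-9)):
        raise ValueError("populations must lie in [0, 1]")
    if P[-1] >= P[0] - 1e-12:
        raise ValueError("population trace does not decay")

    half = t[-1] / 2 if t[-1] > 0 else 1.0
    mask = P > 1e-3
    tau0 = float(np.clip(-np.polyfit(t[mask], np.log(np.maximum(P[mask], 1e-12)), 1)[0] ** -1, 1.0, 10 * t[-1])) if mask.sum() > 2 else half

    if plateau and t0_free:
        f = lambda t, tau, t0, c: c + (1 - c) * np.exp(-np.clip((t - t0), 0, None) / tau)
        p0, bounds = [tau0, 0.0, 0.0], ([1e-3, -t[-1], 0.0], [np.inf, t[-1], 1.0])
    elif plateau:
        f = lambda t, tau, c: c + (1 - c) * np.exp(-t / tau)
        p0, bounds = [tau0, 0.0], ([1e-3, 0.0], [np.inf, 1.0])
    elif t0_free:
        f = lambda t, tau, t0: np.exp(-np.clip(t - t0, 0, None) / tau)
        p0, bounds = [tau0, 0.0], ([1e-3, -t[-1]], [np.inf, t[-1]])
    else:
        f = lambda t, tau: np.exp(-t / tau)
        p0, bounds = [tau0], ([1e-3], [np.inf])

    popt, pcov = curve_fit(f, t, P, p0=p0, bounds=bounds, maxfev=20000)
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


# ---------------------------------------------------------------------------
# oscillation extraction and 2D FT maps
# ---------------------------------------------------------------------------


def extract_oscillations(
    tamap: TAMap,
    passband_cm: tuple[float, float] = (300.0, 1200.0),
    t_start_fs: float = 50.0,
    n_baseline_exp: int = 12,
) -> TAMap:
    """Oscillatory-residual extraction, per probe energy.

    The slowly varying component and all out-of-band Fourier content are
    removed in one orthogonal least-squares projection: each probe-energy
    trace is fitted with a basis of decaying exponentials (a log-spaced
    dictionary of ``n_baseline_exp`` time constants, capturing the
    IRF-convolved population kinetics) plus all discrete Fourier modes
    outside the passband; the residual is the part of the trace that
    lives in the passband.  Being the complement of an orthogonal
    projection, the filter is exactly idempotent and zero-phase.
    """
    nu_lo, nu_hi = passband_cm
    if not nu_lo < nu_hi:
        raise ValueError("degenerate passband")
    delays = tamap.delays_fs
    sel = delays >= t_start_fs
    t = delays[sel]
    X = tamap.delta_a[sel]
    n = t.size
    dt = t[1] - t[0]
    freqs_cm = np.fft.rfftfreq(n, d=dt) * PERIOD_FS_CM  # fs^-1 -> cm^-1
    if nu_lo >= freqs_cm[-1]:
        raise ValueError("passband outside the FFT range of the delay grid")

    span = t[-1] - t[0]
    taus = np.geomspace(2.0 * dt, 5.0 * span, n_baseline_exp)
    cols = [np.ones(n)] + [np.exp(-(t - t[0]) / tau) for tau in taus]
    tt = t - t[0]
    for k, f in enumerate(freqs_cm):
        if nu_lo <= f <= nu_hi or k == 0:
            continue
        w = 2.0 * np.pi * np.fft.rfftfreq(n, d=dt)[k]
        cols.append(np.cos(w * tt))
        if k != n - k:  # sine vanishes at the Nyquist bin for even n
            cols.append(np.sin(w * tt))
    B = np.column_stack(cols)
    # QR-based orthogonal projection: exactly idempotent even though the
    # long-time-constant exponentials are nearly collinear
    Q, _ = np.linalg.qr(B)
    resid = X - Q @ (Q.T @ X)
    return TAMap(
        delays_fs=t,
        probe_energies_ev=tamap.probe_energies_ev,
        delta_a=resid,
        metadata={
            **tamap.metadata,
            "passband_cm": (nu_lo, nu_hi),
            "t_start_fs": t_start_fs,
            "n_baseline_exp": n_baseline_exp,
        },
    )


@dataclass
class OscillationMap:
    probe_energies_ev: np.ndarray
    wavenumbers_cm: np.ndarray
    amplitude: np.ndarray            # (n_energy, n_wavenumber)
    phase: np.ndarray                # rad, cosine convention at t_start
    metadata: dict = field(default_factory=dict)


def ftmap_2d(
    residuals: TAMap,
    window_fn: str = "hann",
    zero_pad_factor: int = 4,
) -> OscillationMap:
    """Windowed, zero-padded Fourier transform of residuals per energy.

    The phase is reported in the cosine convention relative to the first
    retained delay point.
    """
    t = residuals.delays_fs
    if t.size < 16:
        raise ValueError("need at least 16 time points for the FT map")
    X = residuals.delta_a
    n = t.size
    dt = t[1] - t[0]
    if window_fn == "hann":
        w = np.hanning(n)
    elif window_fn in ("boxcar", "rect", "none"):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window_fn!r}")
    n_pad = int(n * max(zero_pad_factor, 1))
    spec = np.fft.rfft(X * w[:, None], n=n_pad, axis=0)
    wavenumbers = np.fft.rfftfreq(n_pad, d=dt) * PERIOD_FS_CM
    amplitude = np.abs(spec).T * 2.0 / np.sum(w)
    phase = np.angle(spec).T
    return OscillationMap(
        probe_energies_ev=residuals.probe_energies_ev,
        wavenumbers_cm=wavenumbers,
        amplitude=amplitude,
        phase=phase,
        metadata={
            "window": window_fn,
            "zero_pad_factor": zero_pad_factor,
            "dt_fs": dt,
            "n_time": n,
            "phase_convention": "cos(w (t - t_start) + phi)",
        },
    )


@dataclass
class NodeResult:
    found: bool
    node_energy_ev: float = np.nan
    phase_jump_rad: float = np.nan
    flank_lo_ev: float = np.nan
    flank_hi_ev: float = np.nan


def node_phase_analysis(oscmap: OscillationMap, wavenumber_cm: float) -> NodeResult:
    """Locate an amplitude node along probe energy at fixed wavenumber.

    The node is an amplitude minimum flanked by maxima; the phase jump is
    the circular difference between amplitude-weighted mean phases of the
    flanking regions.  Returns a "no node" result if no flanked minimum
    exists.
    """
    j = int(np.argmin(np.abs(oscmap.wavenumbers_cm - wavenumber_cm)))
    amp = oscmap.amplitude[:, j]
    ph = oscmap.phase[:, j]
    E = oscmap.probe_energies_ev
    i_max = int(np.argmax(amp))
    floor = 0.02 * amp[i_max]
    # candidate minima strictly between two local maxima
    best = None
    for i in range(1, E.size - 1):
        left_max = amp[:i].max() if i > 0 else 0.0
        right_max = amp[i + 1 :].max() if i < E.size - 1 else 0.0
        if (
            amp[i] < 0.5 * min(left_max, right_max)
            and left_max > floor
            and right_max > floor
        ):
            depth = min(left_max, right_max) - amp[i]
            if best is None or depth > best[1]:
                best = (i, depth)
    if best is None:
        return NodeResult(found=False)
    i_node = best[0]
    lo = slice(0, i_node)
    hi = slice(i_node + 1, E.size)

    def circ_mean(phases, weights):
        z = np.sum(weights * np.exp(1j * phases))
        return np.angle(z)

    ph_lo = circ_mean(ph[lo], amp[lo])
    ph_hi = circ_mean(ph[hi], amp[hi])
    jump = np.angle(np.exp(1j * (ph_hi - ph_lo)))
    return NodeResult(
        found=True,
        node_energy_ev=float(E[i_node]),
        phase_jump_rad=float(jump),
        flank_lo_ev=float(E[np.argmax(amp[lo])]),
        flank_hi_ev=float(E[i_node + 1 + np.argmax(amp[hi])]),
    )
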