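# Methods

## Scope and philosophy

`hopspec` reproduces, at desk scale, the full workflow that connects
nonadiabatic excited-state dynamics to ultrafast pump–probe
transient-absorption (TA) observables for solvated pyrimidine
nucleosides. First-principles surfaces are replaced by analytic
multi-state vibronic models that encode the mechanistic ingredients —
a bright state funneled to the ground state through a barrier-controlled
avoided crossing along a ring-puckering coordinate, gap-modulating
vibrations, a nearby dark state, and a slow solvent coordinate that
gates the barrier. Everything downstream of the electronic structure
(sampling, surface hopping, signal synthesis, fitting, coherence
analysis, channel statistics) is implemented as it would be for on-the-fly
data, and the analysis protocol is applied identically to simulated and
measured maps.

Internal units are atomic (hartree, bohr, electron mass, ħ = 1); all
interfaces use eV, fs, cm⁻¹ and amu. Fixed conversions:
1 eV = 8065.544 cm⁻¹, T[fs] = 33356.41/ν̃[cm⁻¹], 1 fs = 41.34137 a.u.,
1 amu = 1822.888 mₑ.

## Model Hamiltonians

### Scattering benchmarks

The three canonical 1D two-state models (simple avoided crossing, dual
avoided crossing, extended coupling; particle mass 2000 mₑ) are provided
with their standard parameters. They exist to validate the
surface-hopping engine against exact quantum dynamics, not to represent
any molecule.

### The nucleoside-mimetic "pucker" model

Three diabatic states — S0, bright ππ*-like, dark nπ*-like — over five
coordinates: puckering x, three harmonic tuning modes (600, 750,
1600 cm⁻¹), and an overdamped solvent coordinate s.

* **S0**: harmonic + quartic along x (puckering strongly destabilizes the
  closed-shell ground state), harmonic in everything else.
* **Bright state**: vertical offset E_exc = 4.6 eV; a gentle constant
  slope (0.005 eV/bohr) along x toward the crossing seam, as in linear
  vibronic coupling constructions — this drives the ballistic motion out
  of the Franck–Condon (FC) region (without it, trajectories with small
  thermal momentum would stall on a flat shelf and the decay would not
  be exponential); a Gaussian barrier bump at x_b = 1.2 bohr whose
  effective height is ΔE‡ + λ_s(1 − s); a tanh drop (1.5 eV) centered at
  2.2 bohr where the bright diabat plunges and crosses the rising S0
  diabat (the conical-intersection stand-in, Gaussian diabatic coupling
  of 0.25 eV centered at the crossing found numerically at model build);
  an exponential wall closing the well; linear shifts κᵢqᵢ on the tuning
  modes.
* **Dark state**: vertical offset above the bright state (preset 0.15 eV
  for the light system, 0.6 eV for the heavy one — the solvent
  destabilizes the nπ*-like state more in the methylated system); shares
  the tuning shifts by default so the propagated 3-state dynamics has no
  trivial crossings; diabatic coupling to the bright state is zero during
  propagation and finite only in the transfer-bound analysis.
* **Solvent**: a critically damped harmonic coordinate (relaxation time
  τ_s, default 85 fs) whose excited-state equilibrium is displaced from
  s = 0 to s = 1; its relaxation lowers the effective barrier by λ_s(1−s).
  Friction is integrated into the Verlet step and the dissipated work is
  tracked so total-energy audits remain meaningful. The coordinate is
  pinned at (0, 0) during Wigner sampling (a classical bath mode carries
  no zero-point motion).

Two numerical details matter. The barrier-bump amplitude is calibrated
at model build (four fixed-point iterations on the scanned profile) so
that the minimum-energy barrier measured by scanning the bright surface
equals the nominal ΔE‡ despite the slope/drop background. And the Stokes
shift is split so that the slow 600/750 cm⁻¹ modes modulate the emission
gap only weakly (reorganization energies 0.06/0.12 eV — quasi-linear
modulation, which is what produces a clean amplitude node with a π phase
jump at the band center), while the bulk (0.22 eV) sits in the
1600 cm⁻¹ stretch-like mode whose 21 fs oscillation is unresolvable
under a 30 fs instrument response. The relaxed emission gap is then
E_exc − 2Σλ ≈ 3.8 eV.

Default study conditions (one calibration pass, then frozen):
light system m_p = 1 amu, ΔE‡ = 0, λ_s = 0, dt = 0.1 fs, 500 fs —
bright-state lifetime ≈ 90–105 fs; heavy system m_p = 15 amu, ΔE‡ = 0,
λ_s = 0.15 eV, τ_s = 85 fs, dt = 0.25 fs, 1 ps — lifetime ≈ 850–1050 fs
and ~10% of trajectories still excited at 1 ps. The ~10× separation
emerges from the two mechanisms the model encodes: √m inertia of the
heavy puckering mass, plus dynamic trapping while the solvent-gated
barrier decays. On this 1D funnel the delayed (gate + traversal) decay
is more sigmoidal than exponential, so a mono-exponential fit and the
1 ps survival cannot be tuned to arbitrary pairs of values; the lifetime
was prioritized in calibration.

## Initial conditions

T = 0 Wigner sampling of the uncoupled ground-state normal modes:
q and p drawn from independent Gaussians with Var(q) = ħ/(2mω),
Var(p) = ħmω/2 per mode, reproducible per seed. A pump-window filter
keeps samples whose bright-state vertical gap lies in [4.43, 4.75] eV
(the red flank of the absorption band, where a ~4.5 eV pump pulse
selects), followed by uniform thinning to the ensemble size (57 by
default). Finite-temperature weighting and anharmonic sampling are out
of scope.

## Surface hopping

* **Nuclear propagation**: velocity Verlet on the active adiabatic
  surface; analytic Hellmann–Feynman gradients from the diabatic model.
  Per-mode friction (solvent only) enters the half-steps; dissipated
  work is accumulated.
* **Electronic propagation**: the TDSE in the adiabatic basis with
  energies and time-derivative couplings σᵢⱼ = dᵢⱼ·v interpolated
  linearly across the nuclear step, integrated with a fixed-substep
  (default 40) 4th-order Runge–Kutta scheme in the interaction picture:
  the dynamic phases exp(−i∫Eᵢdt) are applied analytically and only the
  coupling-driven part is integrated numerically. This is what keeps the
  norm conserved to ~1e−10 per nuclear step at eV-scale energies; plain
  RK4 on the full equation would drift orders of magnitude more.
  Eigenvector signs are aligned step-to-step by maximum overlap.
* **Hops**: fewest-switches probabilities (clipped at zero) against a
  single uniform draw per step; accepted hops rescale the momentum
  component along the nonadiabatic coupling vector to conserve total
  energy exactly (the engine verifies each hop to 1e−10 hartree);
  kinetically forbidden upward hops are frustrated and leave the
  momentum unchanged (no velocity reversal by default; a flag enables
  reversal for sensitivity checks). Near-degenerate pairs (gap <
  1e−5 hartree) have their coupling vectors capped and flagged, and the
  rescaling direction falls back to the full velocity.
* **Decoherence**: energy-based damping of non-active amplitudes with
  τᵢ = (ħ/|Eᵢ−E_a|)(1 + C/E_kin), C = 0.1 hartree, active amplitude
  rescaled to restore the norm. The correction is appropriate for
  condensed-phase-like dynamics; on the scattering benchmarks it
  measurably distorts single-passage branching, so the benchmark
  comparison is run with the correction disabled (plain fewest-switches,
  as in the original algorithm).
* **Ground-state continuation**: after the accepted hop to S0 the
  trajectory continues classically for 200 fs — feeding the hot-ground-
  state absorption — with no re-hopping, then terminates. The freshly
  formed hot ground state concentrates several eV of kinetic energy in
  the 1D reaction coordinate (a real molecule would spread it over tens
  of modes), so this phase is integrated with 4× finer Verlet substeps.
  Energy-drift validity (1e−4 hartree) is judged on the surface-hopping
  phase between hops; the continuation drift is tracked separately.
* **Seeds**: base_seed + trajectory index; identical seeds give
  bit-identical trajectories.

### Dark-state transfer bound

The question "could the bright population have leaked to a nearby dark
state?" is answered by re-integrating the electronic problem in the
*diabatic* basis of an extended model (finite bright–dark coupling)
along the frozen nuclear paths, with fewest-switches proposals towards
the dark diabat counted without any kinetic-energy gate — an upper
bound by construction. The same energy-based decoherence is applied;
without it the replay accumulates unphysical coherence and the bound
loses its sensitivity to the bright–dark gap. Preset mixing strengths
(0.04 eV light / 0.015 eV heavy, with offsets 0.15/0.6 eV) encode the
stronger ππ*/nπ* mixing of the non-methylated system and give bounds of
roughly 20% and 5%.

## Spectroscopy

While the trajectory is excited it emits an SE stick at E_a − E₀ with
weight −|μ_a0|²(E_a−E₀) and ESA sticks to states above the active one;
after internal conversion it emits a hot-ground-state absorption stick
at E₁ − E₀ damped by an exponential vibrational-cooling factor (default
2 ps). Weights use |μ|²·ΔE; the cubic-frequency emission prefactor is
deliberately omitted (recorded in map metadata). Sticks are Gaussian
broadened in probe energy (σ_E = 0.15 eV), trajectory averaged, and
convolved along delay with a Gaussian IRF (30 fs FWHM, the midpoint of
the 25–35 fs instrument range; applied with edge-replicating boundaries).
σ_E = 0 switches to nearest-bin stick deposition for exactness tests.
Ground-state bleach appears only as the absence of ground-state
absorption of excited trajectories. Photoselection weights for
parallel/magic/orthogonal pump–probe polarization are provided
((1+2cos²θ)/15, 1/9, (2−cos²θ)/15).

## Signal analysis

* **Global fits**: separable least squares — nonlinear in the time
  constants (log-parameterized, Levenberg–Marquardt, deterministic
  multi-start over log-spaced decades of the fit window) and linear in
  the decay-associated spectra; the per-exponential kernel is the
  analytic Gaussian-IRF-convolved exponential, evaluated through the
  scaled complementary error function to avoid overflow. Confidence from
  the Jacobian at the optimum.
* **Population lifetimes**: mono-exponential least squares with optional
  t₀ and plateau terms.
* **Oscillation extraction**: per probe energy, one orthogonal
  least-squares projection removes a dictionary of decaying exponentials
  (12 log-spaced time constants — the smooth population kinetics) plus
  every discrete Fourier mode outside the passband (default
  300–1200 cm⁻¹, first 50 fs excluded as the coherent-artifact region).
  The residual is the passband content; as the complement of an
  orthogonal projection (computed via QR) the filter is exactly
  idempotent and zero-phase. This replaces a raised-cosine-edge masking
  filter considered first: a tapered mask is not a projection, and the
  exponential background leaks into the passband unless it is removed by
  the same least-squares step.
* **2D FT maps**: Hann window, 4× zero padding, rfft per probe energy;
  phase in the cosine convention at the first retained delay. Node
  detection looks for an amplitude minimum (below half the flanking
  maxima) along probe energy at fixed wavenumber and reports the
  circular difference of amplitude-weighted mean phases of the flanks.
* **SE decay vs hot-GS build-up**: both channels are fitted with t₀-free
  single-rate models (the funnel transit delays the PA onset relative to
  the SE loss without changing the rate); on the light system both rate
  constants agree within ~15–35%.

## Normal modes and channels

Normal modes come from central-difference Hessians of an adiabatic
surface at a located minimum (BFGS, gradient norm < 1e−7 hartree/bohr),
mass-weighted and diagonalized; imaginary frequencies are reported as
negative wavenumbers; NMA off-minimum is refused unless forced. Per-mode
energies along a trajectory are harmonic energies in mass-weighted
normal coordinates. The bright-state mode set of the pucker model
contains the configured 600/750 cm⁻¹ modes to within a few cm⁻¹
(self-consistency check).

Decay channels are classified from the geometry at the ground-state hop:
named coordinates (puckering, ring-opening-like, O-oop-like) compared
against thresholds (default: half the puckering displacement of the
crossing seam); the largest normalized displacement wins, ties broken by
the fixed order puckering > ring_opening > O_oop. Yields carry 95%
Wilson intervals; with the calibrated model ~90–95% of decayed
trajectories classify as puckering, with rare other-channel events.
The ensemble barrier map offers two estimators per time window. The
*binned* variant records the minimum bright-state energy of visited
geometries per coordinate bin and reports the profile maximum relative
to its FC-side minimum; it is exact on densely sampled static surfaces
but the vibrational energy carried by spectator modes (especially the
1600 cm⁻¹ mode, ±0.4 eV) can mask a ~0.1 eV gate. The *scan* variant
re-evaluates the bright surface along the puckering coordinate from
ensemble snapshots with the spectator coordinates frozen at their
instantaneous values ("surface mapping on the ensemble") and averages
the per-snapshot barriers; with the solvent gate this barrier relaxes
from ~0.05–0.1 eV in the first window to ~0 within a few hundred fs,
and it is the estimator used for the gate-relaxation checks.

## What passing tests do and do not show

The synthetic generator reproduces the *mechanistic logic* — ballistic
funnel decay, inertia+solvent trapping, gap-modulation coherences with a
node at the emission maximum, dominant decay through puckering, small
dark-state involvement — with timescales calibrated once to the
hundred-fs / sub-ps regime. It does not emulate: multidimensional
intramolecular energy redistribution (the 1D hot ground state is far
stiffer than reality, hence the substepped continuation), coherent
artifacts around zero delay, solvated-electron or two-photon signals,
triplet formation (a yield placeholder at most), spectral diffusion
beyond the single overdamped coordinate, or Franck–Condon-resolved
vibronic band shapes. Quantitative agreement of fitted constants with
measured nucleoside data is therefore a statement about the analysis
pipeline and the calibration, not an ab initio prediction.

## Numerical defaults

| quantity | default | note |
| --- | --- | --- |
| nuclear step | 1.0 fs (generic), 0.1/0.25 fs presets | 1D model stiffness |
| TDSE substeps | 40 (min 20) | interaction-picture RK4 |
| decoherence C | 0.1 hartree | configurable; None disables |
| degeneracy tolerance | 1e−5 hartree | NAC capped + flagged |
| norm tolerance | 1e−8 per step | hard error beyond |
| drift validity | 1e−4 hartree | SH phase, between hops |
| hop energy check | 1e−10 hartree | warning beyond |
| σ_E, IRF | 0.15 eV, 30 fs | map synthesis |
| passband | 300–1200 cm⁻¹, t > 50 fs | oscillation extraction |
| FT window | Hann, 4× zero pad | cosine phase convention |
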