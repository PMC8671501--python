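"""Physical constants and unit conversions.

Internal working units throughout the package are atomic units
(hartree, bohr, electron mass, a.u. of time, hbar = 1).  Public
interfaces report energies in eV, times in fs, wavenumbers in cm^-1
and masses in amu, matching the conventions of ultrafast spectroscopy.
"""

# energy
HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
EV_TO_CM = 8065.544          # 1 eV in cm^-1
CM_TO_EV = 1.0 / EV_TO_CM
CM_TO_HARTREE = CM_TO_EV * EV_TO_HARTREE
HARTREE_TO_CM = 1.0 / CM_TO_HARTREE

# time
FS_TO_AU = 41.34137          # 1 fs in a.u. of time
AU_TO_FS = 1.0 / FS_TO_AU
PERIOD_FS_CM = 33356.41      # T[fs] = PERIOD_FS_CM / wavenumber[cm^-1]

# mass
AMU_TO_ME = 1822.888         # 1 amu in electron masses

# length
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

HBAR_AU = 1.0


def wavenumber_to_angular_frequency_au(wavenumber_cm: float) -> float:
    """Angular frequency (a.u.) of a vibrational wavenumber in cm^-1."""
    # E = hbar*omega; E[hartree] = wavenumber * CM_TO_HARTREE
    return wavenumber_cm * CM_TO_HARTREE / HBAR_AU


def angular_frequency_au_to_wavenumber(omega_au: float) -> float:
    return omega_au * HBAR_AU * HARTREE_TO_CM
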