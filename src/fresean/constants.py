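"""Physical constants and unit conversions.

The package works in GROMACS-style molecular units throughout:
length nm, time ps, mass amu, energy kJ/mol, temperature K.  In these
units ``1 kJ/mol == 1 amu nm^2/ps^2`` exactly, so kinetic energies,
spring constants and spectral intensities need no conversion factors.
Vibrational frequencies are quoted as wavenumbers in cm^-1.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kJ/mol/K.
KB = 0.008314462618

#: Speed of light, cm/ps (2.99792458e10 cm/s).
C_CM_PS = 0.0299792458


def wavenumber_to_thz(nu_cm: float) -> float:
    """Convert a wavenumber (cm^-1) to an ordinary frequency in THz."""
    return nu_cm * C_CM_PS  # cycles/ps == THz


def wavenumber_to_period_ps(nu_cm: float) -> float:
    """Oscillation period (ps) of a vibration at ``nu_cm`` cm^-1."""
    return 1.0 / (nu_cm * C_CM_PS)


def wavenumber_to_angular(nu_cm: float) -> float:
    """Angular frequency (rad/ps) of a vibration at ``nu_cm`` cm^-1."""
    return 2.0 * math.pi * C_CM_PS * nu_cm


def angular_to_wavenumber(omega: float) -> float:
    """Wavenumber (cm^-1) of an angular frequency ``omega`` in rad/ps."""
    return omega / (2.0 * math.pi * C_CM_PS)


#: Standard atomic masses (amu) for elements common in proteins.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
}

#: Three-letter codes accepted as standard amino-acid residues.
STANDARD_RESIDUES: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        # common protonation/termination variants
        "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "ASH",
        "GLH", "LYN",
    }
)
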