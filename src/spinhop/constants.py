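"""Physical constants and unit conversions (CODATA 2018).

All internal dynamics is carried out in Hartree atomic units (hbar = m_e =
e = 4*pi*eps0 = 1).  Public interfaces accept and emit spectroscopic units:
eV for electronic energies, cm^-1 for vibrational frequencies and SOC matrix
elements, fs for times, amu for reduced masses, degrees for angles.  The
conversion factors below are the single source of truth for every module.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """SI values of the fundamental constants used by the rate formulas."""

    e: float = 1.602176634e-19        # elementary charge [C]
    m: float = 9.1093837015e-31       # electron mass [kg]
    h: float = 6.62607015e-34         # Planck constant [J s]
    hbar: float = 1.054571817e-34     # reduced Planck constant [J s]
    eps0: float = 8.8541878128e-12    # vacuum permittivity [F/m]
    c: float = 299792458.0            # speed of light [m/s]
    k_B: float = 1.380649e-23         # Boltzmann constant [J/K]


CODATA2018 = PhysicalConstants()

# --- atomic-unit conversion factors -------------------------------------
HARTREE_EV = 27.211386245988          # 1 hartree in eV
HARTREE_CM1 = 219474.6313632          # 1 hartree in cm^-1
EV_CM1 = HARTREE_CM1 / HARTREE_EV     # 1 eV in cm^-1
AMU_ME = 1822.888486209               # 1 amu in electron masses
AU_TIME_FS = 0.02418884326586         # 1 atomic time unit in fs
FS_AU = 1.0 / AU_TIME_FS              # 1 fs in atomic time units
BOHR_ANGSTROM = 0.529177210903        # 1 bohr in Angstrom
KB_HARTREE = 3.1668115634556e-6       # Boltzmann constant in hartree/K
AU_TIME_S = AU_TIME_FS * 1e-15        # 1 atomic time unit in seconds


def ev_to_hartree(x):
    return x / HARTREE_EV


def hartree_to_ev(x):
    return x * HARTREE_EV


def cm1_to_hartree(x):
    return x / HARTREE_CM1


def hartree_to_cm1(x):
    return x * HARTREE_CM1


def amu_to_me(x):
    return x * AMU_ME


def fs_to_au(x):
    return x * FS_AU


def au_to_fs(x):
    return x * AU_TIME_FS


def omega_au_from_cm1(freq_cm1):
    """Angular frequency in atomic units from a wavenumber in cm^-1."""
    return cm1_to_hartree(freq_cm1)
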