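"""Physical constants (CODATA 2018) and unit conversion factors.

Internal unit conventions used throughout the package:

* molar energies in kJ/mol,
* molar entropies in J/(mol K),
* vibrational frequencies in cm^-1,
* pressure in Pa, temperature in K.

Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K (exact, 2019 SI redefinition).
KB = 1.380649e-23
#: Planck constant, J s (exact).
H = 6.62607015e-34
#: Avogadro constant, 1/mol (exact).
NA = 6.02214076e23
#: Speed of light, cm/s (exact; cm-based so that h*c*nu is an energy for nu in cm^-1).
C_CM = 2.99792458e10
#: Molar gas constant, J/(mol K); R = kB * NA by definition.
R = KB * NA
#: Standard pressure: 1 atm in Pa (the gas standard state used for dG_sub°).
P0 = 101325.0
#: Default temperature, K.
T_DEFAULT = 298.15
#: Atomic mass unit, kg.
AMU = 1.66053906660e-27

#: h*c*NA per cm^-1: molar energy of one wavenumber, J/(mol cm^-1) (~11.9627).
HC_NA = H * C_CM * NA

#: Label embedded in reports so provenance records which constant set was used.
CONSTANTS_VERSION = "CODATA-2018"


def rt_kj(T: float) -> float:
    """R*T in kJ/mol."""
    return R * T / 1000.0


def ln10_rt_kj(T: float) -> float:
    """R*T*ln(10) in kJ/mol — the free-energy step per log10 unit."""
    return rt_kj(T) * math.log(10.0)
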