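"""Sublimation leg of the thermodynamic cycle.

Assembles the lattice energy from its components, converts it into a
sublimation enthalpy either through the full harmonic route

    dH_sub = -E_latt + H_corr(gas) - [E_zpe(solid) + U_thermal(solid)]

or through the classical 2RT shortcut dH_sub = -E_latt - 2RT (valid only when
the six intermolecular crystal modes per molecule obey equipartition and
intramolecular modes match between phases), combines with entropies into
dG_sub at the 1 atm gas standard state, and converts between the 1 atm and
Ben-Naim (equal number density) standard states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import P0, R, T_DEFAULT, rt_kj
from .statmech import DomainError, ThermalCorrections

#: Tolerance on the negative-strain validation (numerical slack, kJ/mol).
STRAIN_TOL = 0.01


class ConsistencyError(ValueError):
    """Inputs are mutually inconsistent (e.g. temperatures differ)."""


@dataclass(frozen=True)
class LatticeComponents:
    """Lattice energy decomposition, kJ/mol.

    E_latt = U_inter + (E_mol_in_cryst - E_mol_min): the intermolecular
    binding plus the intramolecular strain of adopting the crystal
    conformation relative to the gas-phase global minimum.
    """

    U_inter: float
    E_mol_in_cryst: float
    E_mol_min: float

    @property
    def strain(self) -> float:
        return self.E_mol_in_cryst - self.E_mol_min

    @property
    def E_latt(self) -> float:
        return self.U_inter + self.strain


@dataclass(frozen=True)
class SublimationResult:
    """Sublimation thermodynamics at T; energies kJ/mol.

    dG_sub_std refers to the 1 atm gas standard state; dG_sub_star (if a molar
    volume was supplied) to the Ben-Naim equal-density convention.
    dG_minus_RT is a diagnostic only (dG_sub_std - RT); dH_plus_Elatt measures
    the departure from the 2RT approximation (equals -2RT when it holds).
    """

    dH_sub: float
    TdS_sub: float
    dG_sub_std: float
    T: float = T_DEFAULT
    dG_sub_star: float | None = None
    E_latt: float | None = None

    @property
    def dH_plus_Elatt(self) -> float | None:
        return None if self.E_latt is None else self.dH_sub + self.E_latt

    @property
    def dG_minus_RT(self) -> float:
        return self.dG_sub_std - rt_kj(self.T)


def lattice_energy(
    U_inter: float, E_mol_in_cryst: float, E_mol_min: float
) -> LatticeComponents:
    """Assemble lattice components, validating that the strain is non-negative."""
    for name, v in (
        ("U_inter", U_inter),
        ("E_mol_in_cryst", E_mol_in_cryst),
        ("E_mol_min", E_mol_min),
    ):
        if not math.isfinite(v):
            raise DomainError(f"{name} must be finite, got {v}")
    comp = LatticeComponents(U_inter, E_mol_in_cryst, E_mol_min)
    if comp.strain < -STRAIN_TOL:
        raise DomainError(
            "crystal conformer below claimed global minimum: "
            f"strain = {comp.strain:.4f} kJ/mol < 0"
        )
    return comp


def dH_sub_2RT(E_latt: float, T: float = T_DEFAULT) -> float:
    """Classical 2RT approximation: dH_sub = -E_latt - 2RT."""
    if E_latt >= 0:
        raise DomainError(f"E_latt must be negative (bound crystal), got {E_latt}")
    return -E_latt - 2.0 * rt_kj(T)


def dH_sub_full(
    E_latt: float,
    gas: ThermalCorrections,
    solid: ThermalCorrections,
    T: float | None = None,
) -> float:
    """Full harmonic sublimation enthalpy.

    ``gas.H_corr`` must follow the gas convention (includes ZPE, thermal
    translation/rotation/vibration and the pV = RT term); ``solid`` the
    condensed-phase convention (ZPE + thermal vibration only).  When the
    intramolecular modes are identical in both phases their contributions
    cancel and the expression reduces to -E_latt + 4RT - sum over the six
    intermolecular modes of (zpe + u_thermal).
    """
    if abs(gas.T - solid.T) > 1e-9:
        raise ConsistencyError(
            f"gas corrections at T={gas.T} K but solid at T={solid.T} K"
        )
    if T is not None and abs(T - gas.T) > 1e-9:
        raise ConsistencyError(f"requested T={T} K but corrections at T={gas.T} K")
    return -E_latt + gas.H_corr - (solid.E_zpe + solid.U_thermal)


def dG_sub(
    dH_sub: float,
    gas: ThermalCorrections,
    solid: ThermalCorrections,
    T: float | None = None,
    E_latt: float | None = None,
) -> SublimationResult:
    """Combine enthalpy with the entropy difference into dG_sub° (1 atm gas)."""
    if abs(gas.T - solid.T) > 1e-9:
        raise ConsistencyError(
            f"gas corrections at T={gas.T} K but solid at T={solid.T} K"
        )
    temp = gas.T if T is None else T
    TdS = temp * (gas.S - solid.S) / 1000.0
    return SublimationResult(
        dH_sub=dH_sub,
        TdS_sub=TdS,
        dG_sub_std=dH_sub - TdS,
        T=temp,
        E_latt=E_latt,
    )


def convert_std_to_star(dG_std: float, V_m: float, T: float = T_DEFAULT) -> float:
    """1 atm gas standard state -> Ben-Naim convention.

    ``V_m`` is the crystal molar volume in L/mol.  dG* = dG° - RT ln(p0 V_m / RT);
    at V_m = RT/p0 (~24.46 L/mol at 298.15 K) the two conventions coincide.
    """
    if V_m <= 0:
        raise DomainError(f"molar volume must be > 0 L/mol, got {V_m}")
    ratio = P0 * (V_m / 1000.0) / (R * T)
    return dG_std - rt_kj(T) * math.log(ratio)


def convert_star_to_std(dG_star: float, V_m: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`convert_std_to_star`."""
    if V_m <= 0:
        raise DomainError(f"molar volume must be > 0 L/mol, got {V_m}")
    ratio = P0 * (V_m / 1000.0) / (R * T)
    return dG_star + rt_kj(T) * math.log(ratio)
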