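"""Combine the sublimation and hydration legs into intrinsic solubility.

Thermodynamic cycle crystal -> gas -> aqueous solution, unit activity
coefficient.  With the sublimation leg at the 1 atm gas standard state and
the hydration leg in the Ben-Naim convention the molar volume cancels:

    S0 = (p0 / RT) exp[-(dG_sub° + dG_hyd*) / RT]        (mol/L)

and equivalently, with the Ben-Naim sublimation free energy,

    S0 = (1 / V_m) exp[-(dG_sub* + dG_hyd*) / RT].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import P0, R, T_DEFAULT, ln10_rt_kj
from .statmech import DomainError


def _log10_prefactor(T: float) -> float:
    """log10 of p0/RT expressed in mol/L (~ -1.3886 at 298.15 K)."""
    return math.log10(P0 / (R * T) / 1000.0)


@dataclass(frozen=True)
class SolubilityResult:
    """log10 intrinsic solubility (mol/L) with the legs that produced it."""

    logS0: float
    dG_sub_std: float
    dG_hyd_star: float
    T: float = T_DEFAULT
    sublimation_method: str = ""
    hydration_method: str = ""
    dG_hyd_stderr: float | None = None

    @property
    def dG_sol(self) -> float:
        """The cycle total dG_sub° + dG_hyd* (kJ/mol), the exponent of S0."""
        return self.dG_sub_std + self.dG_hyd_star


def log_s0(dG_sub_std: float, dG_hyd_star: float, T: float = T_DEFAULT) -> float:
    """log10 S0 (mol/L) from dG_sub° (1 atm gas) and dG_hyd* (Ben-Naim)."""
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    return _log10_prefactor(T) - (dG_sub_std + dG_hyd_star) / ln10_rt_kj(T)


def log_s0_vm(
    dG_sub_star: float, dG_hyd_star: float, V_m: float, T: float = T_DEFAULT
) -> float:
    """log10 S0 via the molar-volume route; identical to :func:`log_s0` when
    dG_sub_star = convert_std_to_star(dG_sub_std, V_m)."""
    if V_m <= 0:
        raise DomainError(f"molar volume must be > 0 L/mol, got {V_m}")
    return -math.log10(V_m) - (dG_sub_star + dG_hyd_star) / ln10_rt_kj(T)


def pseudo_experimental_dG_hyd(
    logS0_expt: float,
    dH_sub_expt: float,
    TdS_sub_calc: float,
    T: float = T_DEFAULT,
) -> float:
    """Back-calculate dG_hyd* from experimental solubility and sublimation data.

    Combines the experimental sublimation enthalpy with a computed TdS_sub
    into a pseudo-experimental dG_sub°, then inverts the solubility relation
    for dG_hyd* (kJ/mol).
    """
    dG_sub_pseudo = dH_sub_expt - TdS_sub_calc
    return (_log10_prefactor(T) - logS0_expt) * ln10_rt_kj(T) - dG_sub_pseudo


def fold_error(delta_g: float, T: float = T_DEFAULT) -> float:
    """Multiplicative solubility error implied by a free-energy error.

    A |delta_g| of one RT ln10 (~5.71 kJ/mol at 298.15 K) is a 10-fold error.
    """
    return 10.0 ** (abs(delta_g) / ln10_rt_kj(T))


def error_report(calc: SolubilityResult, expt_logS0: float) -> tuple[float, float]:
    """(signed, absolute) log-unit error, signed as experiment minus calculated."""
    signed = expt_logS0 - calc.logS0
    return signed, abs(signed)


def solubility_from_legs(
    dG_sub_std: float,
    dG_hyd_star: float,
    T: float = T_DEFAULT,
    sublimation_method: str = "",
    hydration_method: str = "",
    dG_hyd_stderr: float | None = None,
) -> SolubilityResult:
    return SolubilityResult(
        logS0=log_s0(dG_sub_std, dG_hyd_star, T),
        dG_sub_std=dG_sub_std,
        dG_hyd_star=dG_hyd_star,
        T=T,
        sublimation_method=sublimation_method,
        hydration_method=hydration_method,
        dG_hyd_stderr=dG_hyd_stderr,
    )
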