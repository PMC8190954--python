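"""Harmonic-oscillator and ideal-gas statistical thermodynamics primitives.

All vibrational quantities are quantum harmonic-oscillator results per mode:

* zero-point energy        zpe = (1/2) h c NA nu
* thermal internal energy  u   = R T x / (e^x - 1),      x = h c nu / (kB T)
* entropy                  s   = R [ x/(e^x - 1) - ln(1 - e^-x) ]
* Helmholtz correction     a   = zpe + u - T s

The translational and rotational gas-phase terms are the classical
Sackur–Tetrode and rigid-rotor expressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .constants import AMU, HC_NA, KB, H, P0, R, T_DEFAULT, rt_kj

logger = logging.getLogger(__name__)

Character = Literal["intermolecular", "intramolecular", "acoustic"]
CHARACTERS = ("intermolecular", "intramolecular", "acoustic")

#: Frequencies below this are numerical zero modes (acoustic translations/rotations
#: that survived diagonalization) and are dropped with a warning.
ACOUSTIC_CUTOFF_CM1 = 0.01


class DomainError(ValueError):
    """A physical quantity is outside its allowed domain."""


@dataclass(frozen=True)
class Mode:
    """One harmonic mode: frequency (cm^-1), multiplicity weight, character."""

    frequency: float
    weight: float = 1.0
    character: Character = "intramolecular"

    def __post_init__(self) -> None:
        if not math.isfinite(self.frequency):
            raise DomainError(f"mode frequency must be finite, got {self.frequency}")
        if self.frequency <= 0 and self.character != "acoustic":
            raise DomainError(
                f"imaginary/negative mode frequency {self.frequency} cm^-1 rejected"
            )
        if self.weight < 0 or not math.isfinite(self.weight):
            raise DomainError(f"mode weight must be finite and >= 0, got {self.weight}")
        if self.character not in CHARACTERS:
            raise DomainError(f"unknown mode character {self.character!r}")


@dataclass(frozen=True)
class ModeSpectrum:
    """Discrete harmonic spectrum for a molecule or a crystal Gamma point.

    ``molecules_per_cell`` (Z) matters only for crystal spectra, where the
    Gamma-point mode list covers the whole unit cell and per-molecule
    quantities require division by Z.
    """

    modes: tuple[Mode, ...]
    molecules_per_cell: int = 1

    def __post_init__(self) -> None:
        if self.molecules_per_cell < 1:
            raise DomainError(
                f"molecules_per_cell must be >= 1, got {self.molecules_per_cell}"
            )

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[float, float, str]],
        molecules_per_cell: int = 1,
    ) -> "ModeSpectrum":
        """Build from (frequency, weight, character) triples.

        Sub-cutoff frequencies (< 0.01 cm^-1) are reclassified as acoustic with
        a warning rather than rejected: phonon codes routinely emit numerically
        tiny translational modes.
        """
        modes = []
        for freq, weight, character in entries:
            if 0 < freq < ACOUSTIC_CUTOFF_CM1 and character != "acoustic":
                logger.warning(
                    "frequency %.3g cm^-1 below %.2g cm^-1 treated as acoustic",
                    freq,
                    ACOUSTIC_CUTOFF_CM1,
                )
                character = "acoustic"
            modes.append(Mode(freq, weight, character))  # type: ignore[arg-type]
        return cls(tuple(modes), molecules_per_cell)

    def select(self, characters: Iterable[str]) -> "ModeSpectrum":
        chars = set(characters)
        return ModeSpectrum(
            tuple(m for m in self.modes if m.character in chars),
            self.molecules_per_cell,
        )

    @property
    def total_weight(self) -> float:
        return sum(m.weight for m in self.modes if m.character != "acoustic")

    def check_mode_count(self, n_atoms: int) -> bool:
        """Warn (return False) if the non-acoustic weight differs from 3NZ - 3."""
        expected = 3 * n_atoms * self.molecules_per_cell - 3
        ok = math.isclose(self.total_weight, expected, rel_tol=0, abs_tol=0.5)
        if not ok:
            logger.warning(
                "crystal spectrum weight %.1f differs from expected 3NZ-3 = %d",
                self.total_weight,
                expected,
            )
        return ok


@dataclass(frozen=True)
class ThermalCorrections:
    """Thermal corrections at temperature T (kJ/mol; entropy in J/(mol K)).

    ``H_corr`` is the enthalpy correction: for a gas it includes the pV = RT
    term, for a condensed phase it is just E_zpe + U_thermal.  ``A_corr`` is
    the Helmholtz correction E_zpe + U_thermal - T*S (no pV).
    """

    E_zpe: float
    U_thermal: float
    H_corr: float
    S: float
    A_corr: float
    T: float = T_DEFAULT

    def validate(self, tol: float = 1e-9) -> None:
        a = self.E_zpe + self.U_thermal - self.T * self.S / 1000.0
        if abs(a - self.A_corr) > tol and abs(self.H_corr - rt_kj(self.T) - (
            self.E_zpe + self.U_thermal
        )) > tol:
            # Condensed-phase objects must satisfy A = ZPE + U - TS exactly;
            # gas objects carry +RT in H_corr instead.
            raise DomainError(
                f"inconsistent ThermalCorrections: A_corr={self.A_corr}, "
                f"E_zpe+U-TS={a}"
            )


def _zero_corrections(T: float) -> ThermalCorrections:
    return ThermalCorrections(0.0, 0.0, 0.0, 0.0, 0.0, T)


class ModeThermo(NamedTuple):
    """Per-mode thermal quantities: kJ/mol except entropy in J/(mol K)."""

    zpe: float
    u_thermal: float
    s: float
    a: float


def _vib_arrays(freq: np.ndarray, T: float) -> tuple[np.ndarray, ...]:
    """Vectorized per-mode (zpe, u, s) for strictly positive frequencies."""
    x = HC_NA * freq / (R * T)
    # x e^-x / (1 - e^-x) is overflow-safe for arbitrarily large x
    emx = np.exp(-x)
    occ = np.where(x > 0, x * emx / (1.0 - emx), 1.0)
    zpe = 0.5 * HC_NA * freq / 1000.0
    u = rt_kj(T) * occ
    s = R * (occ - np.log1p(-emx))
    return zpe, u, s


def mode_thermo(freq: float, T: float = T_DEFAULT) -> ModeThermo:
    """Quantum harmonic-oscillator thermal quantities for one mode.

    Parameters
    ----------
    freq : float
        Mode frequency in cm^-1; must be > 0.
    T : float
        Temperature in K; must be > 0.

    Returns
    -------
    ModeThermo
        (zpe, u_thermal, s, a) with energies in kJ/mol, entropy in J/(mol K).
    """
    if freq <= 0:
        raise DomainError(f"frequency must be > 0 cm^-1, got {freq}")
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    zpe, u, s = (float(v) for v in _vib_arrays(np.asarray(freq, dtype=float), T))
    return ModeThermo(zpe, u, s, zpe + u - T * s / 1000.0)


def spectrum_thermo(
    spectrum: ModeSpectrum,
    T: float = T_DEFAULT,
    characters: Iterable[str] = ("intermolecular", "intramolecular"),
) -> ThermalCorrections:
    """Weighted vibrational thermal corrections over selected mode characters.

    Acoustic modes are always excluded.  An empty selection yields all-zero
    corrections with a logged warning (useful for atoms / rigid molecules).
    No pV term: H_corr = E_zpe + U_thermal (condensed-phase convention).
    """
    chars = set(characters) - {"acoustic"}
    if not chars:
        raise DomainError("character filter must include at least one vibrational class")
    sel = [m for m in spectrum.modes if m.character in chars and m.weight > 0]
    if not sel:
        logger.warning("no modes matched filter %s; returning zero corrections", chars)
        return _zero_corrections(T)
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    freq = np.array([m.frequency for m in sel])
    w = np.array([m.weight for m in sel])
    zpe, u, s = _vib_arrays(freq, T)
    E_zpe = float(w @ zpe)
    U = float(w @ u)
    S = float(w @ s)
    return ThermalCorrections(
        E_zpe=E_zpe,
        U_thermal=U,
        H_corr=E_zpe + U,
        S=S,
        A_corr=E_zpe + U - T * S / 1000.0,
        T=T,
    )


def sackur_tetrode(mass_amu: float, T: float, p: float = P0) -> float:
    """Translational entropy of an ideal gas, J/(mol K)."""
    if mass_amu <= 0:
        raise DomainError(f"mass must be > 0 amu, got {mass_amu}")
    m = mass_amu * AMU
    q_over_n = (2.0 * math.pi * m * KB * T / H**2) ** 1.5 * KB * T / p
    return R * (math.log(q_over_n) + 2.5)


def _rotational_thermo(
    rotor: str,
    rotational_constants_cm1: Sequence[float] | None,
    symmetry_number: float,
    T: float,
) -> tuple[float, float]:
    """(U_rot in kJ/mol, S_rot in J/(mol K)) for the classical rigid rotor."""
    if rotor == "atom":
        return 0.0, 0.0
    if not rotational_constants_cm1:
        raise DomainError(f"rotor {rotor!r} requires rotational constants (cm^-1)")
    theta = [HC_NA * b / R for b in rotational_constants_cm1]  # K
    if any(t <= 0 for t in theta):
        raise DomainError("rotational constants must be > 0")
    if rotor == "linear":
        u = rt_kj(T)
        s = R * (math.log(T / (symmetry_number * theta[0])) + 1.0)
    elif rotor == "nonlinear":
        if len(theta) != 3:
            raise DomainError("nonlinear rotor requires three rotational constants")
        u = 1.5 * rt_kj(T)
        q = math.sqrt(math.pi) / symmetry_number * math.sqrt(
            T**3 / (theta[0] * theta[1] * theta[2])
        )
        s = R * (math.log(q) + 1.5)
    else:
        raise DomainError(f"unknown rotor type {rotor!r}")
    return u, s


def gas_thermo(
    mass_amu: float,
    rotor: Literal["atom", "linear", "nonlinear"],
    spectrum: ModeSpectrum | None = None,
    T: float = T_DEFAULT,
    p: float = P0,
    rotational_constants_cm1: Sequence[float] | None = None,
    symmetry_number: float = 1.0,
) -> ThermalCorrections:
    """Ideal-gas thermal corrections (rigid rotor + harmonic oscillator).

    H_corr = E_zpe + U_vib + 3/2 RT (trans) + U_rot + RT (pV), matching the
    enthalpy-correction convention of standard quantum-chemistry thermal
    analyses at pressure ``p`` (default 1 atm).  The symmetry number defaults
    to 1.  A_corr = H_corr - RT - T*S.
    """
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    vib = (
        spectrum_thermo(spectrum, T)
        if spectrum is not None and spectrum.modes
        else _zero_corrections(T)
    )
    u_rot, s_rot = _rotational_thermo(rotor, rotational_constants_cm1, symmetry_number, T)
    s_trans = sackur_tetrode(mass_amu, T, p)
    rt = rt_kj(T)
    U = vib.U_thermal + 1.5 * rt + u_rot
    S = s_trans + s_rot + vib.S
    H_corr = vib.E_zpe + U + rt
    return ThermalCorrections(
        E_zpe=vib.E_zpe,
        U_thermal=U,
        H_corr=H_corr,
        S=S,
        A_corr=H_corr - rt - T * S / 1000.0,
        T=T,
    )
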