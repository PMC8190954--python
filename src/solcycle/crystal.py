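"""Crystal-side thermal corrections from Gamma-point mode lists or a phonon DOS.

Two equivalent representations of the crystal vibrational problem are
supported: a discrete Gamma-point spectrum (per unit cell, normalized per
molecule by Z) and a phonon density of states already expressed per molecule.
Both feed the same harmonic per-mode formulas; the DOS route integrates them
by trapezoidal quadrature on the user-supplied grid (no re-gridding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import T_DEFAULT
from .statmech import (
    DomainError,
    ModeSpectrum,
    ThermalCorrections,
    _vib_arrays,
    spectrum_thermo,
)

logger = logging.getLogger(__name__)

#: Allowed relative violation of the DOS normalization integral.
DOS_NORM_RTOL = 0.005


class ValidationError(ValueError):
    """Input data fails a structural or normalization check."""


@dataclass(frozen=True)
class PhononDOS:
    """Phonon density of states per molecule of the crystal.

    ``density`` has units of modes per cm^-1 per molecule; its trapezoidal
    integral over ``grid`` must equal ``modes_total`` within 0.5%.
    """

    grid: np.ndarray
    density: np.ndarray
    modes_total: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)
        if grid.ndim != 1 or grid.shape != density.shape or grid.size < 2:
            raise ValidationError("grid and density must be equal-length 1-D arrays")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("DOS grid must be strictly ascending")
        if np.any(density < 0):
            raise ValidationError("DOS density must be >= 0 everywhere")
        if np.any(grid <= 0):
            raise ValidationError("DOS grid frequencies must be > 0 cm^-1")
        integral = float(np.trapezoid(density, grid))
        if self.modes_total == 0:
            ok = integral == 0
        else:
            ok = abs(integral - self.modes_total) <= DOS_NORM_RTOL * abs(self.modes_total)
        if not ok:
            raise ValidationError(
                f"DOS integral {integral:.6g} deviates from declared mode count "
                f"{self.modes_total:.6g} by more than {DOS_NORM_RTOL:.1%}"
            )


def dos_thermo(dos: PhononDOS, T: float = T_DEFAULT) -> ThermalCorrections:
    """Thermal corrections per molecule from a phonon density of states.

    Each per-mode quantity is integrated against the density by trapezoidal
    quadrature.  Condensed-phase convention: H_corr = E_zpe + U_thermal.
    """
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    if dos.modes_total == 0:
        return ThermalCorrections(0.0, 0.0, 0.0, 0.0, 0.0, T)
    zpe, u, s = _vib_arrays(dos.grid, T)
    E_zpe = float(np.trapezoid(dos.density * zpe, dos.grid))
    U = float(np.trapezoid(dos.density * u, dos.grid))
    S = float(np.trapezoid(dos.density * s, dos.grid))
    return ThermalCorrections(
        E_zpe=E_zpe,
        U_thermal=U,
        H_corr=E_zpe + U,
        S=S,
        A_corr=E_zpe + U - T * S / 1000.0,
        T=T,
    )


def gamma_point_thermo(spectrum: ModeSpectrum, T: float = T_DEFAULT) -> ThermalCorrections:
    """Per-molecule thermal corrections from a crystal Gamma-point spectrum.

    All non-acoustic modes are summed (the sublimation assembly later selects
    which terms enter the enthalpy) and divided by Z = molecules_per_cell.
    """
    cell = spectrum_thermo(spectrum, T)
    z = spectrum.molecules_per_cell
    return ThermalCorrections(
        E_zpe=cell.E_zpe / z,
        U_thermal=cell.U_thermal / z,
        H_corr=cell.H_corr / z,
        S=cell.S / z,
        A_corr=cell.A_corr / z,
        T=T,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O.  Published tables often print en-dash minus signs; pasted
# input is normalized before numeric conversion.

_MINUS_VARIANTS = str.maketrans({"–": "-", "−": "-", "—": "-"})


def normalize_minus(text: str) -> str:
    """Replace en-dash / unicode-minus / em-dash with ASCII '-'."""
    return text.translate(_MINUS_VARIANTS)


def _read_normalized_csv(path: str | Path) -> pd.DataFrame:
    text = normalize_minus(Path(path).read_text())
    from io import StringIO

    df = pd.read_csv(StringIO(text))
    df.columns = [c.strip() for c in df.columns]
    return df


def read_spectrum_csv(path: str | Path, molecules_per_cell: int = 1) -> ModeSpectrum:
    """Read a mode table with columns frequency_cm1, weight, character."""
    df = _read_normalized_csv(path)
    required = {"frequency_cm1", "weight", "character"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: spectrum CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    entries = [
        (float(r.frequency_cm1), float(r.weight), str(r.character).strip())
        for r in df.itertuples()
    ]
    return ModeSpectrum.from_entries(entries, molecules_per_cell=molecules_per_cell)


def write_spectrum_csv(spectrum: ModeSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_cm1": [m.frequency for m in spectrum.modes],
            "weight": [m.weight for m in spectrum.modes],
            "character": [m.character for m in spectrum.modes],
        }
    ).to_csv(path, index=False)


def read_dos_csv(path: str | Path, modes_total: float | None = None) -> PhononDOS:
    """Read a DOS table with columns frequency_cm1, density.

    If ``modes_total`` is omitted the trapezoidal integral is used (the
    normalization check then passes by construction).
    """
    df = _read_normalized_csv(path)
    required = {"frequency_cm1", "density"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: DOS CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    grid = df["frequency_cm1"].to_numpy(dtype=float)
    density = df["density"].to_numpy(dtype=float)
    if modes_total is None:
        modes_total = float(np.trapezoid(density, grid))
    return PhononDOS(grid=grid, density=density, modes_total=modes_total)


def spectrum_to_dos(
    spectrum: ModeSpectrum, n_bins: int = 2000, pad_cm1: float = 5.0
) -> PhononDOS:
    """Histogram a discrete spectrum into a DOS (per molecule).

    Mostly a cross-checking device: thermochemistry from the resulting DOS
    should agree with the discrete route to within the bin discretization.
    """
    sel = [m for m in spectrum.modes if m.character != "acoustic" and m.weight > 0]
    if not sel:
        raise ValidationError("cannot histogram an empty spectrum")
    freqs = np.array([m.frequency for m in sel])
    w = np.array([m.weight for m in sel]) / spectrum.molecules_per_cell
    lo = max(freqs.min() - pad_cm1, 1e-6)
    hi = freqs.max() + pad_cm1
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(freqs, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = hist / np.diff(edges)
    total = float(np.trapezoid(density, centers))
    return PhononDOS(grid=centers, density=density, modes_total=total)
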