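"""Hydration free energies from conformer ensembles or alchemical FEP samples.

Two routes are provided:

* Boltzmann conformer schemes (implicit-solvent free energies per conformer):

  - SFE1: ensemble of solution conformers vs a single reference gas conformer
    (the crystal-matched one),
  - SFE2: single lowest-free-energy solution conformer vs the same gas
    reference,
  - SFE3: ensemble in both phases.

* Bennett acceptance ratio (BAR) over per-lambda forward/backward
  potential-energy-difference samples from explicit-solvent FEP windows.

Sign convention: negative dG_hyd* means favorable hydration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import T_DEFAULT, rt_kj
from .crystal import ValidationError, _read_normalized_csv

Scheme = Literal["SFE1", "SFE2", "SFE3"]

#: Residual tolerance for the BAR self-consistent equation (dimensionless).
BAR_RESIDUAL_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """The BAR equation could not be bracketed/solved (poor phase-space overlap)."""


# ---------------------------------------------------------------------------
# Conformer ensembles


@dataclass(frozen=True)
class ConformerEnsemble:
    """Per-conformer free energies (kJ/mol) for one phase at temperature T."""

    phase: Literal["gas", "solution"]
    conformers: tuple[tuple[str, float], ...]
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValidationError(f"{self.phase} ensemble has no conformers")
        for cid, g in self.conformers:
            if not math.isfinite(g):
                raise ValidationError(f"conformer {cid!r} has non-finite G = {g}")

    def free_energy(self, cid: str) -> float:
        for c, g in self.conformers:
            if c == cid:
                return g
        raise KeyError(f"conformer id {cid!r} not in {self.phase} ensemble")

    def minimum(self) -> tuple[str, float]:
        """Lowest-G conformer; ties broken by lexicographic id."""
        return min(self.conformers, key=lambda cg: (cg[1], cg[0]))


def ensemble_free_energy(ensemble: ConformerEnsemble) -> float:
    """Boltzmann ensemble free energy G = -RT ln sum_i exp(-G_i / RT).

    Computed in log-sum-exp form, so arbitrarily large |G| values are safe.
    Always <= the minimum conformer G (population spreads lower the free
    energy); equality in the T -> 0 limit.
    """
    rt = rt_kj(ensemble.T)
    g = np.array([gi for _, gi in ensemble.conformers])
    return float(-rt * logsumexp(-g / rt))


def hydration_sfe(
    gas: ConformerEnsemble,
    solution: ConformerEnsemble,
    scheme: Scheme = "SFE2",
    gas_reference_id: str | None = None,
) -> float:
    """Hydration free energy dG_hyd* = G_solution - G_gas under one scheme.

    SFE1 and SFE2 use a single gas conformer named by ``gas_reference_id``
    (the conformer matching the sublimation calculation); SFE3 Boltzmann-
    weights both phases and ignores the reference id.
    """
    if gas.phase != "gas" or solution.phase != "solution":
        raise ValidationError(
            f"expected (gas, solution) ensembles, got ({gas.phase}, {solution.phase})"
        )
    if scheme in ("SFE1", "SFE2"):
        if gas_reference_id is None:
            raise ValidationError(f"{scheme} requires gas_reference_id")
        g_gas = gas.free_energy(gas_reference_id)
        if scheme == "SFE1":
            g_soln = ensemble_free_energy(solution)
        else:
            g_soln = solution.minimum()[1]
    elif scheme == "SFE3":
        g_gas = ensemble_free_energy(gas)
        g_soln = ensemble_free_energy(solution)
    else:
        raise ValidationError(f"unknown hydration scheme {scheme!r}")
    return g_soln - g_gas


def read_conformers_csv(
    path: str | Path, T: float = T_DEFAULT
) -> dict[str, ConformerEnsemble]:
    """Read a conformer table (columns phase, conformer_id, G_kJmol) per phase."""
    df = _read_normalized_csv(path)
    required = {"phase", "conformer_id", "G_kJmol"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: conformer CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, ConformerEnsemble] = {}
    for phase, grp in df.groupby("phase"):
        if phase not in ("gas", "solution"):
            raise ValidationError(f"{path}: unknown phase {phase!r}")
        out[str(phase)] = ConformerEnsemble(
            phase=str(phase),  # type: ignore[arg-type]
            conformers=tuple(
                (str(r.conformer_id), float(r.G_kJmol)) for r in grp.itertuples()
            ),
            T=T,
        )
    return out


# ---------------------------------------------------------------------------
# Bennett acceptance ratio


def _log_fermi_sum(t: np.ndarray) -> float:
    """log sum_i 1/(1 + e^{t_i}), overflow-safe."""
    return float(logsumexp(-np.logaddexp(0.0, t)))


def bar_window(
    forward: Sequence[float],
    backward: Sequence[float],
    T: float = T_DEFAULT,
) -> tuple[float, float]:
    """BAR free-energy difference for one window, with its standard error.

    ``forward`` holds potential-energy differences dU(low -> high) sampled in
    the low state; ``backward`` holds dU(high -> low) sampled in the high
    state (both kJ/mol).  Solves the self-consistent Bennett equation

        sum_F f(M + (w_F - dF)/RT) = sum_R f(-M + (w_R + dF)/RT),

    with f the Fermi function and M = ln(n_F / n_R), by bracketed
    root-finding to a residual below 1e-10.  The standard error is the
    standard Bennett variance estimator (equal-weight samples, no
    autocorrelation correction).
    """
    wf = np.asarray(forward, dtype=float)
    wr = np.asarray(backward, dtype=float)
    if wf.size < 2 or wr.size < 2:
        raise ValidationError("BAR needs >= 2 samples in each direction")
    rt = rt_kj(T)
    uf = wf / rt
    ur = wr / rt
    M = math.log(uf.size / ur.size)

    def residual(c: float) -> float:
        # increasing in c: log sum f rises on the forward side, falls on reverse
        return _log_fermi_sum(M + uf - c) - _log_fermi_sum(-M + ur + c)

    span = 10.0 * max(1.0, float(np.max(np.abs(uf))), float(np.max(np.abs(ur))))
    lo, hi = -span, span
    if residual(lo) > 0 or residual(hi) < 0:
        raise ConvergenceError(
            "BAR equation has no root within +/-10 max|dU|; "
            "forward/backward distributions likely have no overlap"
        )
    c = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=500)
    if abs(residual(c)) > BAR_RESIDUAL_TOL:
        raise ConvergenceError(f"BAR residual {residual(c):.2e} above tolerance")

    # Bennett variance estimate in kT^2
    ff = 1.0 / (1.0 + np.exp(np.clip(M + uf - c, -700, 700)))
    fr = 1.0 / (1.0 + np.exp(np.clip(-M + ur + c, -700, 700)))
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / ff.size + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / fr.size
    return c * rt, math.sqrt(max(var, 0.0)) * rt


def exp_averaging(forward: Sequence[float], T: float = T_DEFAULT) -> float:
    """One-sided exponential (Zwanzig) estimate, for cross-checks only."""
    wf = np.asarray(forward, dtype=float)
    rt = rt_kj(T)
    return float(-rt * (logsumexp(-wf / rt) - math.log(wf.size)))


# ---------------------------------------------------------------------------
# FEP datasets


@dataclass(frozen=True)
class FEPWindow:
    lambda_low: float
    lambda_high: float
    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", np.asarray(self.forward, dtype=float))
        object.__setattr__(self, "backward", np.asarray(self.backward, dtype=float))
        if not 0 <= self.lambda_low < self.lambda_high <= 1:
            raise ValidationError(
                f"invalid window [{self.lambda_low}, {self.lambda_high}]"
            )
        if self.forward.size < 2 or self.backward.size < 2:
            raise ValidationError(
                f"window [{self.lambda_low}, {self.lambda_high}] needs >= 2 samples "
                "in each direction"
            )


@dataclass(frozen=True)
class FEPDataset:
    """Ordered, contiguous lambda windows covering [0, 1].

    ``lambda0_coupled`` records the alchemical convention: True means lambda=0
    is the fully coupled (solvated) solute and lambda=1 the decoupled one, so
    the summed window free energy is a decoupling free energy and hydration is
    its negative.
    """

    windows: tuple[FEPWindow, ...]
    T: float = T_DEFAULT
    lambda0_coupled: bool = True

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValidationError("FEP dataset has no windows")
        lows = [w.lambda_low for w in self.windows]
        if sorted(lows) != lows:
            raise ValidationError("lambda windows must be sorted ascending")
        problems = []
        if abs(self.windows[0].lambda_low) > 1e-12:
            problems.append(f"first window starts at {self.windows[0].lambda_low}, not 0")
        if abs(self.windows[-1].lambda_high - 1.0) > 1e-12:
            problems.append(f"last window ends at {self.windows[-1].lambda_high}, not 1")
        for a, b in zip(self.windows, self.windows[1:]):
            if abs(a.lambda_high - b.lambda_low) > 1e-12:
                problems.append(
                    f"gap/overlap between [{a.lambda_low},{a.lambda_high}] and "
                    f"[{b.lambda_low},{b.lambda_high}]"
                )
        if problems:
            raise ValidationError("lambda schedule invalid: " + "; ".join(problems))


def fep_total(dataset: FEPDataset) -> tuple[float, float]:
    """Hydration free energy from a full FEP dataset (kJ/mol), via BAR.

    Window free energies are estimated independently and summed; variances
    add.  The sign is flipped when ``dataset.lambda0_coupled`` so the return
    value is the coupling (hydration) free energy.
    """
    total = 0.0
    var = 0.0
    for w in dataset.windows:
        df, se = bar_window(w.forward, w.backward, dataset.T)
        total += df
        var += se**2
    if dataset.lambda0_coupled:
        total = -total
    return total, math.sqrt(var)


def reverse_schedule(dataset: FEPDataset) -> FEPDataset:
    """The same samples traversed from lambda=1 to lambda=0 (roles swapped).

    The convention flag is kept, so the reversed dataset estimates the
    negated total — the estimator-level antisymmetry check.
    """
    rev = tuple(
        FEPWindow(1.0 - w.lambda_high, 1.0 - w.lambda_low, w.backward, w.forward)
        for w in reversed(dataset.windows)
    )
    return FEPDataset(rev, dataset.T, dataset.lambda0_coupled)


def read_fep_csv(
    path: str | Path, T: float = T_DEFAULT, lambda0_coupled: bool = True
) -> FEPDataset:
    """Read FEP samples: columns lambda_low, lambda_high, direction, delta_u_kJmol."""
    df = _read_normalized_csv(path)
    required = {"lambda_low", "lambda_high", "direction", "delta_u_kJmol"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: FEP CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    windows = []
    for (lo, hi), grp in sorted(df.groupby(["lambda_low", "lambda_high"])):
        fwd = grp.loc[grp.direction == "fwd", "delta_u_kJmol"].to_numpy(dtype=float)
        bwd = grp.loc[grp.direction == "bwd", "delta_u_kJmol"].to_numpy(dtype=float)
        windows.append(FEPWindow(float(lo), float(hi), fwd, bwd))
    return FEPDataset(tuple(windows), T=T, lambda0_coupled=lambda0_coupled)


def write_fep_csv(dataset: FEPDataset, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for w in dataset.windows:
        rows.extend(
            {"lambda_low": w.lambda_low, "lambda_high": w.lambda_high,
             "direction": "fwd", "delta_u_kJmol": v}
            for v in w.forward
        )
        rows.extend(
            {"lambda_low": w.lambda_low, "lambda_high": w.lambda_high,
             "direction": "bwd", "delta_u_kJmol": v}
            for v in w.backward
        )
    pd.DataFrame(rows).to_csv(path, index=False)
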