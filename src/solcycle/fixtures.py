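"""Seeded synthetic-input generators with independently computed ground truth.

Every generator records the truth it embeds via a brute-force/analytic path
(plain ``math`` loops, closed forms) that never touches the vectorized
production code it is used to test.  A single seeded ``numpy.random.Generator``
drives all randomness; seeds are recorded in manifests.

``TABLE_REPLAY`` carries the published per-compound thermodynamic summary
values (lattice/sublimation energetics and hydration free energies for
succinic acid, coronene, and desloratadine) as direct-route inputs, so the
end-to-end arithmetic can be exercised on real numbers without any
electronic-structure or simulation runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import CompoundConfig, dump_config, validate_config
from .constants import HC_NA, R, T_DEFAULT, rt_kj
from .crystal import write_spectrum_csv
from .hydration import FEPDataset, FEPWindow, write_fep_csv
from .statmech import DomainError, ModeSpectrum

# ---------------------------------------------------------------------------
# Published per-compound summary values (direct-route inputs).
# Energies kJ/mol; hydration models keyed by the level of theory used.

TABLE_REPLAY: dict[str, dict] = {
    "succinic acid": {
        "E_latt": -125.89,
        "dH_sub": 121.04,
        "TdS_sub": 69.50,
        "dH_sub_expt": 123.2,
        "logS0_expt": -0.22,
        "dG_hyd_expt": -61.08,
        "hydration": {
            "PBE/6-311++G(2d,p)/SMD": -49.33,
            "PBE0/6-311++G(2d,p)/SMD": -52.78,
            "PBE0-DH/6-311++G(2d,p)/SMD": -56.23,
            "GAFF/AM1-BCC, SPC/E": -57.47,
        },
    },
    "coronene": {
        "E_latt": -155.61,
        "dH_sub": 143.51,
        "TdS_sub": 64.46,
        "dH_sub_expt": 148.2,
        "logS0_expt": -9.33,
        "hydration": {
            "PBE/6-311++G(2d,p)/SMD": -18.68,
            "PBE0/6-311++G(2d,p)/SMD": -23.01,
            "PBE0-DH/6-311++G(2d,p)/SMD": -26.32,
            "GAFF/AM1-BCC, SPC/E": -40.00,
        },
    },
    "desloratadine": {
        "E_latt": -144.40,
        "dH_sub": 133.72,
        "TdS_sub": 73.95,
        "logS0_expt": -3.42,
        "hydration": {
            "PBE/6-311++G(2d,p)/SMD": -45.11,
            "PBE0/6-311++G(2d,p)/SMD": -48.08,
            "PBE0-DH/6-311++G(2d,p)/SMD": -50.38,
            "GAFF/AM1-BCC, SPC/E": -44.93,
        },
    },
}


def table_replay_config(compound: str) -> CompoundConfig:
    """Direct-route config for one of the three benchmark compounds."""
    if compound not in TABLE_REPLAY:
        raise KeyError(
            f"unknown compound {compound!r}; choose from {sorted(TABLE_REPLAY)}"
        )
    row = TABLE_REPLAY[compound]
    expt = {"logS0": row["logS0_expt"]}
    if "dH_sub_expt" in row:
        expt["dH_sub"] = row["dH_sub_expt"]
    if "dG_hyd_expt" in row:
        expt["dG_hyd"] = row["dG_hyd_expt"]
    raw = {
        "name": compound,
        "temperature": T_DEFAULT,
        "sublimation": {"dH_sub": row["dH_sub"], "TdS_sub": row["TdS_sub"]},
        "hydration": [
            {"name": model, "dG_hyd": value}
            for model, value in row["hydration"].items()
        ],
        "experimental": expt,
    }
    return validate_config(raw)


# ---------------------------------------------------------------------------
# Independent (non-vectorized) oracles


def direct_mode_sum(
    freqs_weights: list[tuple[float, float]], T: float
) -> dict[str, float]:
    """Brute-force per-mode harmonic sums using plain ``math`` only."""
    zpe = u = s = 0.0
    for freq, w in freqs_weights:
        x = HC_NA * freq / (R * T)
        zpe += w * 0.5 * HC_NA * freq / 1000.0
        u += w * (R * T / 1000.0) * x / math.expm1(x)
        s += w * R * (x / math.expm1(x) - math.log(1.0 - math.exp(-x)))
    return {"E_zpe": zpe, "U_thermal": u, "S": s, "A_corr": zpe + u - T * s / 1000.0}


# ---------------------------------------------------------------------------
# Generators


@dataclass(frozen=True)
class CrystalSpectrumFixture:
    spectrum: ModeSpectrum
    gas_spectrum: ModeSpectrum
    truth: dict


def gen_crystal_spectrum(
    seed: int,
    z: int = 1,
    n_inter_per_molecule: int = 6,
    band_cm1: tuple[float, float] = (20.0, 150.0),
    gas_frequencies_cm1: tuple[float, ...] = (),
    perturbation_cm1: float = 0.0,
    T: float = T_DEFAULT,
) -> CrystalSpectrumFixture:
    """Synthetic crystal Gamma-point spectrum with analytic ground truth.

    Emits 6 Z intermolecular modes uniform in ``band_cm1`` (the default
    20–150 cm^-1 band straddles the classical/quantum crossover at room
    temperature, where the 2RT shortcut degrades) plus Z copies of the gas
    intramolecular modes, optionally perturbed.  Ground-truth per-molecule
    corrections come from an independent direct sum.
    """
    lo, hi = band_cm1
    if lo >= hi or lo <= 0:
        raise DomainError(f"invalid intermolecular band {band_cm1}")
    rng = np.random.default_rng(seed)
    inter = sorted(rng.uniform(lo, hi, size=n_inter_per_molecule * z).tolist())
    intra = []
    for _ in range(z):
        for f in gas_frequencies_cm1:
            fp = f + (rng.normal(0.0, perturbation_cm1) if perturbation_cm1 else 0.0)
            intra.append(max(fp, 1.0))
    entries = [(f, 1.0, "intermolecular") for f in inter] + [
        (f, 1.0, "intramolecular") for f in intra
    ]
    spectrum = ModeSpectrum.from_entries(entries, molecules_per_cell=z)
    gas_spectrum = ModeSpectrum.from_entries(
        [(f, 1.0, "intramolecular") for f in gas_frequencies_cm1]
    )
    inter_truth = direct_mode_sum([(f, 1.0 / z) for f in inter], T)
    all_truth = direct_mode_sum([(f, 1.0 / z) for f in inter + intra], T)
    truth = {
        "seed": seed,
        "T": T,
        "inter_per_molecule": inter_truth,
        "total_per_molecule": all_truth,
        # analytic gap between the full and 2RT enthalpy routes when the
        # intramolecular sets match exactly: dH_full - dH_2RT
        #   = 6RT - sum_inter(zpe + u)
        "full_minus_2RT": 6.0 * rt_kj(T)
        - (inter_truth["E_zpe"] + inter_truth["U_thermal"]),
    }
    return CrystalSpectrumFixture(spectrum, gas_spectrum, truth)


def gen_fep_dataset(
    seed: int,
    dG_true_rt: float,
    sigma_rt: float = 1.0,
    n_samples: int = 1000,
    n_windows: int = 20,
    T: float = T_DEFAULT,
    lambda0_coupled: bool = True,
) -> tuple[FEPDataset, dict]:
    """Crooks-consistent Gaussian work samples over a uniform lambda schedule.

    ``dG_true_rt`` is the hydration (coupling) free energy in RT units.  Each
    window i carries a share dF_i of the decoupling free energy; forward work
    is N(dF_i + sigma^2/2, sigma^2) and backward work N(-dF_i + sigma^2/2,
    sigma^2) in RT units, which satisfies the Crooks relation with window free
    energy dF_i exactly.
    """
    if sigma_rt <= 0:
        raise DomainError(f"sigma must be > 0 RT, got {sigma_rt}")
    if n_samples < 10:
        raise DomainError(f"need >= 10 samples per direction, got {n_samples}")
    rng = np.random.default_rng(seed)
    rt = rt_kj(T)
    sum_rt = -dG_true_rt if lambda0_coupled else dG_true_rt
    # uneven but deterministic split of the total across windows
    shares = np.linspace(0.5, 1.5, n_windows)
    shares /= shares.sum()
    df_windows = sum_rt * shares
    lams = np.linspace(0.0, 1.0, n_windows + 1)
    windows = []
    for i, df in enumerate(df_windows):
        mu_f = df + sigma_rt**2 / 2.0
        mu_b = -df + sigma_rt**2 / 2.0
        fwd = rng.normal(mu_f, sigma_rt, size=n_samples) * rt
        bwd = rng.normal(mu_b, sigma_rt, size=n_samples) * rt
        windows.append(FEPWindow(float(lams[i]), float(lams[i + 1]), fwd, bwd))
    dataset = FEPDataset(tuple(windows), T=T, lambda0_coupled=lambda0_coupled)
    truth = {
        "seed": seed,
        "dG_true_kJmol": dG_true_rt * rt,
        "dG_true_rt": dG_true_rt,
        "sigma_rt": sigma_rt,
        "n_samples": n_samples,
        "window_dF_rt": df_windows.tolist(),
    }
    return dataset, truth


def gen_conformer_csv(
    seed: int,
    path: str | Path,
    n_gas: int = 3,
    n_solution: int = 4,
    spacing_kJmol: float = 2.0,
    dG_hyd_reference: float = -30.0,
) -> dict:
    """Conformer table with a known SFE ground truth (plain-math oracle)."""
    rng = np.random.default_rng(seed)
    rt = rt_kj(T_DEFAULT)
    gas_g = [0.0] + sorted(rng.uniform(0.5, spacing_kJmol * n_gas, n_gas - 1).tolist())
    soln_g = [dG_hyd_reference] + sorted(
        (dG_hyd_reference + rng.uniform(0.5, spacing_kJmol * n_solution,
                                        n_solution - 1)).tolist()
    )
    rows = ["phase,conformer_id,G_kJmol"]
    rows += [f"gas,g{i:02d},{g:.6f}" for i, g in enumerate(gas_g)]
    rows += [f"solution,s{i:02d},{g:.6f}" for i, g in enumerate(soln_g)]
    Path(path).write_text("\n".join(rows) + "\n")

    def lse_free_energy(gs: list[float]) -> float:
        return -rt * math.log(sum(math.exp(-g / rt) for g in gs))

    return {
        "seed": seed,
        "gas_reference": "g00",
        "SFE1": lse_free_energy(soln_g) - gas_g[0],
        "SFE2": min(soln_g) - gas_g[0],
        "SFE3": lse_free_energy(soln_g) - lse_free_energy(gas_g),
    }


def gen_compound_fixture(
    seed: int,
    out_dir: str | Path,
    E_latt: float = -110.0,
    mass_amu: float = 118.09,
    rotational_constants_cm1: tuple[float, float, float] = (0.16, 0.08, 0.05),
    gas_frequencies_cm1: tuple[float, ...] = (80.0, 450.0, 900.0, 1600.0, 3000.0),
    dG_hyd_direct: float = -45.0,
    fep_sigma_rt: float = 0.8,
    fep_samples: int = 800,
    T: float = T_DEFAULT,
) -> dict:
    """Emit a fully synthetic compound (config + CSVs) with known logS0.

    The ground-truth logS0 for the deterministic legs is assembled by the
    same closed-form arithmetic the production code implements, but computed
    here with plain ``math`` from the analytically known ingredients.  The FEP
    hydration model shares the direct model's dG_hyd as its true value, so the
    end-to-end stochastic recovery error is attributable to BAR noise alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))

    cry = gen_crystal_spectrum(
        seed=rng_seed,
        z=2,
        gas_frequencies_cm1=gas_frequencies_cm1,
        perturbation_cm1=0.0,
        T=T,
    )
    write_spectrum_csv(cry.spectrum, out / "crystal_modes.csv")
    write_spectrum_csv(cry.gas_spectrum, out / "gas_modes.csv")

    rt = rt_kj(T)
    dG_hyd_rt = dG_hyd_direct / rt
    fep, fep_truth = gen_fep_dataset(
        seed=rng_seed + 1,
        dG_true_rt=dG_hyd_rt,
        sigma_rt=fep_sigma_rt,
        n_samples=fep_samples,
        T=T,
    )
    write_fep_csv(fep, out / "fep.csv")

    config_raw = {
        "name": f"synthetic-{seed}",
        "temperature": T,
        "sublimation": {
            "E_latt": E_latt,
            "gas": {
                "mass_amu": mass_amu,
                "rotor": "nonlinear",
                "rotational_constants_cm1": list(rotational_constants_cm1),
                "spectrum": "gas_modes.csv",
            },
            "crystal": {"spectrum": "crystal_modes.csv", "molecules_per_cell": 2},
        },
        "hydration": [
            {"name": "direct", "dG_hyd": dG_hyd_direct},
            {"name": "fep", "fep": "fep.csv"},
        ],
    }
    config = validate_config(config_raw, base_dir=out)
    dump_config(config, out / "compound.yaml")

    # --- analytic ground truth, plain math -------------------------------
    from .constants import AMU, KB, H, P0

    gas_vib = direct_mode_sum([(f, 1.0) for f in gas_frequencies_cm1], T)
    m = mass_amu * AMU
    s_trans = R * (
        math.log((2 * math.pi * m * KB * T / H**2) ** 1.5 * KB * T / P0) + 2.5
    )
    ta, tb, tc = (HC_NA * b / R for b in rotational_constants_cm1)
    s_rot = R * (math.log(math.sqrt(math.pi) * math.sqrt(T**3 / (ta * tb * tc))) + 1.5)
    gas_H = gas_vib["E_zpe"] + gas_vib["U_thermal"] + 4.0 * rt
    gas_S = s_trans + s_rot + gas_vib["S"]

    solid = cry.truth["total_per_molecule"]
    dH = -E_latt + gas_H - (solid["E_zpe"] + solid["U_thermal"])
    TdS = T * (gas_S - solid["S"]) / 1000.0
    dG_sub = dH - TdS
    logS0_true = math.log10(P0 / (R * T) / 1000.0) - (dG_sub + dG_hyd_direct) / (
        rt * math.log(10.0)
    )

    manifest = {
        "seed": seed,
        "derived_rng_seed": rng_seed,
        "temperature_K": T,
        "E_latt_kJmol": E_latt,
        "dH_sub_true_kJmol": dH,
        "TdS_sub_true_kJmol": TdS,
        "dG_sub_std_true_kJmol": dG_sub,
        "dG_hyd_true_kJmol": dG_hyd_direct,
        "logS0_true": logS0_true,
        "fep": fep_truth,
        "provenance": "all values computed analytically by fixtures.direct sums",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
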