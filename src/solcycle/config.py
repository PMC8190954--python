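"""Per-compound configuration, validation, and pipeline orchestration.

A compound config (YAML or JSON) declares exactly one sublimation route and
one or more hydration models:

.. code-block:: yaml

    name: succinic acid
    temperature: 298.15
    sublimation:
      # EITHER direct table values
      dH_sub: 121.04
      TdS_sub: 69.50
      # OR a thermochemical route:
      # lattice: {U_inter: -125.89, E_mol_in_cryst: -1.0, E_mol_min: -1.0}
      # gas: {mass_amu: 118.09, rotor: nonlinear,
      #       rotational_constants_cm1: [0.16, 0.05, 0.04],
      #       spectrum: gas_modes.csv}
      # crystal: {spectrum: crystal_modes.csv, molecules_per_cell: 2}
      #   (or crystal: {dos: phonon_dos.csv})
    hydration:
      - {name: PBE/SMD, dG_hyd: -49.33}
      - {name: ensemble, scheme: SFE1, conformers: conf.csv, gas_reference: c0}
      - {name: MD/FEP, fep: fep.csv}
    experimental:
      logS0: -0.22
      dH_sub: 123.2
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import yaml

from . import crystal as _crystal
from . import hydration as _hyd
from . import sublimation as _sub
from .constants import CONSTANTS_VERSION, T_DEFAULT
from .crystal import ValidationError, normalize_minus
from .engine import SolubilityResult, error_report, solubility_from_legs
from .statmech import gas_thermo


class ConfigError(ValueError):
    """Configuration fails schema validation; message carries the field path."""


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _require(block: dict, key: str, path: str) -> Any:
    if key not in block:
        raise ConfigError(f"{path}: missing required key {key!r}")
    return block[key]


@dataclass(frozen=True)
class CompoundConfig:
    """Validated per-compound input description."""

    name: str
    temperature: float
    sublimation: dict
    hydration: tuple[dict, ...]
    experimental: dict = dc_field(default_factory=dict)
    base_dir: Path = Path(".")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "temperature": self.temperature,
            "sublimation": dict(self.sublimation),
            "hydration": [dict(h) for h in self.hydration],
            **({"experimental": dict(self.experimental)} if self.experimental else {}),
        }


_SUB_DIRECT = {"dH_sub", "TdS_sub"}
_SUB_THERMO = {"lattice", "E_latt", "gas", "crystal", "route"}
_HYD_KEYS = {"name", "dG_hyd", "scheme", "conformers", "gas_reference", "fep",
             "lambda0_coupled"}


def validate_config(raw: dict, base_dir: Path = Path(".")) -> CompoundConfig:
    """Validate a raw mapping into a :class:`CompoundConfig` (strict keys)."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, {"name", "temperature", "sublimation", "hydration",
                      "experimental"}, "config")
    name = str(_require(raw, "name", "config"))
    T = float(raw.get("temperature", T_DEFAULT))
    if T <= 0:
        raise ConfigError(f"config.temperature: must be > 0 K, got {T}")

    sub = _require(raw, "sublimation", "config")
    if not isinstance(sub, dict) or not sub:
        raise ConfigError("config.sublimation: must be a non-empty mapping")
    _check_keys(sub, _SUB_DIRECT | _SUB_THERMO, "config.sublimation")
    direct = _SUB_DIRECT & set(sub)
    thermo = (_SUB_THERMO - {"route"}) & set(sub)
    if direct and thermo:
        raise ConfigError(
            "config.sublimation: ambiguous route — give either direct "
            f"{sorted(direct)} or thermochemical {sorted(thermo)} inputs, not both"
        )
    if direct:
        if direct != _SUB_DIRECT:
            raise ConfigError(
                "config.sublimation: direct route needs both dH_sub and TdS_sub"
            )
    else:
        if "gas" not in sub or "crystal" not in sub:
            raise ConfigError(
                "config.sublimation: thermochemical route needs gas and crystal blocks"
            )
        if ("lattice" in sub) == ("E_latt" in sub):
            raise ConfigError(
                "config.sublimation: give exactly one of lattice or E_latt"
            )

    hyd = _require(raw, "hydration", "config")
    if not isinstance(hyd, list) or not hyd:
        raise ConfigError("config.hydration: must be a non-empty list")
    for i, h in enumerate(hyd):
        path = f"config.hydration[{i}]"
        if not isinstance(h, dict):
            raise ConfigError(f"{path}: must be a mapping")
        _check_keys(h, _HYD_KEYS, path)
        _require(h, "name", path)
        routes = [k for k in ("dG_hyd", "conformers", "fep") if k in h]
        if len(routes) != 1:
            raise ConfigError(
                f"{path}: give exactly one of dG_hyd, conformers, fep (got {routes})"
            )
        if "conformers" in h and "scheme" not in h:
            raise ConfigError(f"{path}: conformer route requires a scheme")

    expt = raw.get("experimental", {}) or {}
    _check_keys(expt, {"logS0", "dH_sub", "dG_hyd"}, "config.experimental")

    return CompoundConfig(
        name=name,
        temperature=T,
        sublimation=dict(sub),
        hydration=tuple(dict(h) for h in hyd),
        experimental=dict(expt),
        base_dir=Path(base_dir),
    )


def load_config(path: str | Path) -> CompoundConfig:
    """Load and validate a YAML/JSON compound config file."""
    p = Path(path)
    text = normalize_minus(p.read_text())
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    return validate_config(raw, base_dir=p.parent)


def dump_config(config: CompoundConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Pipeline


def _resolve(config: CompoundConfig, rel: str) -> Path:
    p = Path(rel)
    return p if p.is_absolute() else config.base_dir / p


def _sublimation_leg(config: CompoundConfig) -> tuple[_sub.SublimationResult, str]:
    sub = config.sublimation
    T = config.temperature
    if "dH_sub" in sub:
        dH = float(sub["dH_sub"])
        TdS = float(sub["TdS_sub"])
        return (
            _sub.SublimationResult(dH_sub=dH, TdS_sub=TdS, dG_sub_std=dH - TdS, T=T),
            "direct",
        )

    if "lattice" in sub:
        lat = sub["lattice"]
        _check_keys(lat, {"U_inter", "E_mol_in_cryst", "E_mol_min"},
                    "config.sublimation.lattice")
        comp = _sub.lattice_energy(
            float(_require(lat, "U_inter", "config.sublimation.lattice")),
            float(_require(lat, "E_mol_in_cryst", "config.sublimation.lattice")),
            float(_require(lat, "E_mol_min", "config.sublimation.lattice")),
        )
        E_latt = comp.E_latt
    else:
        E_latt = float(sub["E_latt"])

    gas_block = sub["gas"]
    _check_keys(
        gas_block,
        {"mass_amu", "rotor", "rotational_constants_cm1", "symmetry_number", "spectrum"},
        "config.sublimation.gas",
    )
    gas_spec = None
    if "spectrum" in gas_block:
        gas_spec = _crystal.read_spectrum_csv(_resolve(config, gas_block["spectrum"]))
    gas = gas_thermo(
        mass_amu=float(_require(gas_block, "mass_amu", "config.sublimation.gas")),
        rotor=_require(gas_block, "rotor", "config.sublimation.gas"),
        spectrum=gas_spec,
        T=T,
        rotational_constants_cm1=gas_block.get("rotational_constants_cm1"),
        symmetry_number=float(gas_block.get("symmetry_number", 1.0)),
    )

    cry_block = sub["crystal"]
    _check_keys(cry_block, {"spectrum", "dos", "molecules_per_cell", "modes_total"},
                "config.sublimation.crystal")
    if ("spectrum" in cry_block) == ("dos" in cry_block):
        raise ConfigError(
            "config.sublimation.crystal: give exactly one of spectrum or dos"
        )
    if "spectrum" in cry_block:
        spec = _crystal.read_spectrum_csv(
            _resolve(config, cry_block["spectrum"]),
            molecules_per_cell=int(cry_block.get("molecules_per_cell", 1)),
        )
        solid = _crystal.gamma_point_thermo(spec, T)
        route = "gamma-point"
    else:
        dos = _crystal.read_dos_csv(
            _resolve(config, cry_block["dos"]),
            modes_total=cry_block.get("modes_total"),
        )
        solid = _crystal.dos_thermo(dos, T)
        route = "dos"

    dH = _sub.dH_sub_full(E_latt, gas, solid, T)
    result = _sub.dG_sub(dH, gas, solid, T, E_latt=E_latt)
    return result, route


def _hydration_leg(
    config: CompoundConfig, h: dict
) -> tuple[float, float | None, str]:
    T = config.temperature
    name = str(h["name"])
    if "dG_hyd" in h:
        return float(h["dG_hyd"]), None, name
    if "conformers" in h:
        ensembles = _hyd.read_conformers_csv(_resolve(config, h["conformers"]), T=T)
        for phase in ("gas", "solution"):
            if phase not in ensembles:
                raise ValidationError(
                    f"{h['conformers']}: no {phase}-phase conformers for model {name!r}"
                )
        dG = _hyd.hydration_sfe(
            ensembles["gas"],
            ensembles["solution"],
            scheme=h["scheme"],
            gas_reference_id=h.get("gas_reference"),
        )
        return dG, None, name
    dataset = _hyd.read_fep_csv(
        _resolve(config, h["fep"]),
        T=T,
        lambda0_coupled=bool(h.get("lambda0_coupled", True)),
    )
    dG, se = _hyd.fep_total(dataset)
    return dG, se, name


def run_pipeline(config: CompoundConfig) -> list[SolubilityResult]:
    """Run the full cycle: one :class:`SolubilityResult` per hydration model."""
    sub_result, sub_route = _sublimation_leg(config)
    results = []
    for h in config.hydration:
        try:
            dG_hyd, se, name = _hydration_leg(config, h)
        except (ValidationError, KeyError) as exc:
            raise type(exc)(
                f"compound {config.name!r}, hydration model {h.get('name')!r}: {exc}"
            ) from exc
        results.append(
            solubility_from_legs(
                dG_sub_std=sub_result.dG_sub_std,
                dG_hyd_star=dG_hyd,
                T=config.temperature,
                sublimation_method=sub_route,
                hydration_method=name,
                dG_hyd_stderr=se,
            )
        )
    return results


def _file_hashes(config: CompoundConfig) -> dict[str, str]:
    hashes = {}
    blocks: list[dict] = [config.sublimation.get("gas", {}),
                          config.sublimation.get("crystal", {})]
    blocks.extend(config.hydration)
    for block in blocks:
        for key in ("spectrum", "dos", "conformers", "fep"):
            rel = block.get(key)
            if rel:
                p = _resolve(config, rel)
                hashes[str(rel)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return hashes


def build_report(config: CompoundConfig) -> dict:
    """Full JSON-serializable report: legs, per-model logS0, optional errors."""
    sub_result, sub_route = _sublimation_leg(config)
    results = run_pipeline(config)
    models = []
    for r in results:
        entry = {
            "hydration_method": r.hydration_method,
            "dG_hyd_star_kJmol": r.dG_hyd_star,
            "logS0": round(r.logS0, 2),
            "logS0_full_precision": r.logS0,
        }
        if r.dG_hyd_stderr is not None:
            entry["dG_hyd_stderr_kJmol"] = r.dG_hyd_stderr
        if "logS0" in config.experimental:
            signed, absolute = error_report(r, float(config.experimental["logS0"]))
            entry["error_vs_expt"] = round(signed, 2)
            entry["abs_error_vs_expt"] = round(absolute, 2)
        models.append(entry)
    report = {
        "compound": config.name,
        "temperature_K": config.temperature,
        "constants": CONSTANTS_VERSION,
        "sublimation": {
            "route": sub_route,
            "dH_sub_kJmol": sub_result.dH_sub,
            "TdS_sub_kJmol": sub_result.TdS_sub,
            "dG_sub_std_kJmol": sub_result.dG_sub_std,
            "dG_minus_RT_kJmol": sub_result.dG_minus_RT,
        },
        "hydration_models": models,
        "input_hashes": _file_hashes(config),
    }
    if sub_result.dH_plus_Elatt is not None:
        report["sublimation"]["dH_plus_Elatt_kJmol"] = sub_result.dH_plus_Elatt
    if config.experimental:
        report["experimental"] = dict(config.experimental)
    return report


def write_report(config: CompoundConfig, path: str | Path) -> dict:
    report = build_report(config)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
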