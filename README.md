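# solcycle

Physics-based prediction of **intrinsic aqueous solubility** — the equilibrium
concentration S₀ (mol/L) of the neutral solute in saturated solution — via the
sublimation thermodynamic cycle: crystal → gas → aqueous solution.

The package is for computational chemists who already have the expensive
electronic-structure and simulation outputs in hand (lattice energies,
harmonic vibrational/phonon spectra, conformer free energies, per-λ FEP work
samples) and need the thermodynamic assembly done carefully: sublimation
enthalpies **beyond the 2RT approximation**, entropies from phonon
thermochemistry, conformer-aware hydration free energies, and the
standard-state bookkeeping that links them to a solubility.

## The model

With unit activity coefficient, the cycle gives

```
ΔG_sol* = ΔG_sub* + ΔG_hyd*          S₀ = (1/V_m) exp(−ΔG_sol*/RT)
```

where `*` marks the Ben-Naim (equal number density) convention and V_m is the
crystal molar volume. Converting the sublimation leg to the conventional
1 atm gas standard state, `ΔG_sub° = ΔG_sub* + RT ln(p₀V_m/RT)`, makes V_m
cancel:

```
S₀ = (p₀/RT) · exp[−(ΔG_sub° + ΔG_hyd*)/RT]          (mol/L)
```

**Sublimation leg.** The lattice energy is assembled as
`E_latt = U_inter + (E_mol_in_cryst − E_mol_min)` (intermolecular binding plus
conformational strain). The classical shortcut `ΔH_sub ≈ −E_latt − 2RT`
assumes the six intermolecular crystal modes per molecule are classical
oscillators; instead, the full harmonic route evaluates every mode
quantum-mechanically,

```
ΔH_sub = −E_latt + H_corr(gas) − [E_ZPE(solid) + U_thermal(solid)]
```

from Γ-point mode lists or an integrated phonon density of states, and
`ΔG_sub° = ΔH_sub − TΔS_sub` with the gas entropy from the rigid-rotor /
harmonic-oscillator ideal gas at 1 atm.

**Hydration leg.** Either Boltzmann-weighted conformer schemes
(SFE1/SFE2/SFE3: solution ensemble vs single crystal-matched gas conformer;
single minimum each; ensemble in both phases), or the Bennett acceptance
ratio (BAR) applied window-by-window to forward/backward FEP work samples
over a λ schedule.

## Worked example

```python
from solcycle import run_pipeline
from solcycle.fixtures import table_replay_config

for r in run_pipeline(table_replay_config("succinic acid")):
    print(f"{r.hydration_method:<30s} logS0 = {r.logS0:6.2f}")
```

prints

```
PBE/6-311++G(2d,p)/SMD         logS0 =  -1.78
PBE0/6-311++G(2d,p)/SMD        logS0 =  -1.17
PBE0-DH/6-311++G(2d,p)/SMD     logS0 =  -0.57
GAFF/AM1-BCC, SPC/E            logS0 =  -0.35
```

— the predicted log₁₀ solubility of succinic acid under four hydration
models, from its computed sublimation free energy (51.54 kJ/mol) and each
model's hydration free energy. Experiment is −0.22: the MD/FEP hydration
model lands within 0.13 log units, while PBE/SMD underestimates solubility
by 1.56 log units (a 36-fold error) because it underbinds the solute in
water. The `examples/` directory has one short narrative script per
capability (mode thermochemistry, the sublimation routes, the hydration
models, the benchmark sweep).

There is also a thin CLI:

```
solcycle compute compound.yaml --output report.json
solcycle thermo --spectrum crystal_modes.csv --molecules-per-cell 2
solcycle bar fep.csv
solcycle report report1.json report2.json --output summary.csv
solcycle fixtures --seed 7 --out scratch/demo
```

Config files are YAML/JSON per compound (see `solcycle.config` docstring);
spectra, conformer tables and FEP samples are plain CSV. En-dash minus signs
in pasted table data are normalized at parse time.

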