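# Methods

## Thermodynamic model

Dissolution of a crystalline solute is decomposed through the gas phase:
crystal → gas (sublimation) → aqueous solution (hydration). With unit
activity coefficient the intrinsic solubility is

    S₀ = (p₀/RT) exp[−(ΔG_sub° + ΔG_hyd*)/RT]     [mol/L],

where ΔG_sub° is at a 1 atm gas standard state and ΔG_hyd* in the Ben-Naim
convention (transfer at fixed center of mass, equal number densities). The
equivalent molar-volume form S₀ = (1/V_m)·exp(−(ΔG_sub* + ΔG_hyd*)/RT) is
provided and is algebraically identical once
ΔG_sub* = ΔG_sub° − RT ln(p₀V_m/RT); the test suite asserts the two routes
agree to 1e-9 log units for arbitrary V_m. At 298.15 K the prefactor
contributes log₁₀(p₀/RT) = −1.3886 and each kJ/mol of cycle free energy moves
log S₀ by −0.1752.

## Sublimation leg

**Lattice energy.** E_latt = U_inter + (E_mol_in_cryst − E_mol_min). The
strain term must be ≥ 0 (the gas global minimum is by definition lowest); a
negative strain beyond 0.01 kJ/mol numerical slack is rejected as an input
error rather than silently absorbed.

**Enthalpy.** Two routes:

* *2RT shortcut*: ΔH_sub = −E_latt − 2RT. Valid only when the six
  intermolecular modes per molecule are classical (equipartition) and
  decoupled from intramolecular vibrations.
* *Full harmonic route*: ΔH_sub = −E_latt + H_corr(gas) − [E_ZPE + U_thermal]
  (solid), with every mode treated as a quantum harmonic oscillator. When the
  intramolecular sets match between phases this reduces to
  −E_latt + 4RT − Σ_inter(zpe + u), and the shortcut is recovered in the limit
  of vanishing intermolecular frequencies (asserted at 1 cm⁻¹ within
  0.05 kJ/mol). The diagnostic ΔH_sub + E_latt is always reported; its
  departure from −2RT (−4.96 kJ/mol at 298.15 K) measures how much the phonon
  treatment matters, and each RT·ln10 = 5.71 kJ/mol of departure is a 10-fold
  factor in predicted solubility.

The crystal side accepts either a Γ-point mode list (per unit cell,
normalized per molecule by Z) or a phonon density of states per molecule,
integrated by trapezoidal quadrature **on the supplied grid** — no
re-gridding, because the appropriate sampling is a property of the upstream
phonon calculation, not of this package. DOS inputs must integrate to their
declared mode count within 0.5%. The two crystal representations agree within
that tolerance on histogram round-trips (property-tested). Mode lists are
validated against the 3NZ−3 count with a warning, not an error, since
supercell conventions vary; frequencies below 0.01 cm⁻¹ are treated as
numerical acoustic zero-modes and dropped with a warning.

**Gas side.** Rigid-rotor / harmonic-oscillator ideal gas:
H_corr = E_ZPE + U_vib + 3/2RT + U_rot + RT, S = S_trans (Sackur–Tetrode at
1 atm) + S_rot + S_vib. The rotational symmetry number defaults to 1 and no
frequency scaling is applied — upstream thermal analyses differ on both
points, so the package takes the neutral default and accepts explicit values.
Then ΔG_sub° = ΔH_sub − T(S_gas − S_solid).

**Standard states and constants.** CODATA 2018 constants; 1 atm = 101325 Pa
exactly. Note that the Sackur–Tetrode entropy of argon at 298.15 K is
154.74 J/(mol K) at 1 atm and 154.85 at 1 bar — the package consistently uses
1 atm, matching the sublimation standard state. The solid pV term is
neglected (it is ~p₀V_m ≈ 0.01 kJ/mol for a molecular crystal).

## Hydration leg

**Conformer schemes.** Given per-conformer free energies G_i (solvation
included for the solution phase), the ensemble free energy is
−RT ln Σ exp(−G_i/RT), evaluated in log-sum-exp form so arbitrarily large
magnitudes are safe. SFE1 = solution ensemble − single crystal-matched gas
conformer; SFE2 = lowest-G solution conformer − the same gas reference (ties
broken by lexicographic conformer id); SFE3 = ensemble in both phases.
Whether the supplied per-conformer values include vibrational corrections is
the caller's choice; the package uses whatever free energy is given and does
not second-guess it.

**BAR.** Each λ window's free energy solves Bennett's self-consistent
equation Σ_F f(M + (w_F − ΔF)/RT) = Σ_R f(−M + (w_R + ΔF)/RT), with f the
Fermi function and M = ln(n_F/n_R). The left-minus-right residual is monotone
in ΔF, so a bracketed root-finder (Brent) on ±10·max|ΔU| converges reliably;
the residual is verified below 1e-10 and failure to bracket is reported as a
poor-overlap error. Uncertainty is the standard Bennett variance estimator
with equal-weight samples; **no autocorrelation correction is applied** —
samples are assumed independent, so stated errors are optimistic for
correlated trajectory data (known limitation). Window estimates sum; window
variances add in quadrature. The dataset records which λ endpoint is the
coupled solute, and the total is sign-flipped so the returned value is always
the hydration (coupling) free energy; negative = favorable.

## Synthetic data

Generators produce every input class with ground truth computed by an
independent plain-`math` path (never the vectorized production code):

* *Crystal spectra*: 6Z intermolecular modes uniform in 20–150 cm⁻¹ —
  a band chosen to straddle the classical/quantum crossover at room
  temperature, the regime where the 2RT shortcut degrades — plus
  intramolecular modes copied (optionally Gaussian-perturbed) from a supplied
  gas spectrum. With zero perturbation the intramolecular contributions
  cancel exactly in ΔH_sub, isolating the intermolecular correction.
* *FEP datasets*: 20 windows over the uniform 21-λ schedule; per-window
  forward work ~ N(ΔF_i + σ²/2, σ²) and backward ~ N(−ΔF_i + σ²/2, σ²) in RT
  units, which satisfies the Crooks fluctuation relation with window free
  energy ΔF_i exactly. Defaults σ = 0.8–1 RT and ~10³ samples/direction give
  per-window overlap typical of a well-spaced production schedule.
* *Compound fixtures*: a full config (lattice energy, gas + crystal spectra,
  direct and FEP hydration models) with the end-to-end log S₀ assembled
  analytically; recovery is asserted to 0.02 log units on the deterministic
  legs and 0.1 on the FEP leg at stated seeds.

All randomness flows from one seeded `numpy.random.Generator`; identical
seeds give byte-identical files. What the generators do **not** emulate:
anharmonicity, phonon dispersion beyond the supplied DOS, mode mixing between
inter- and intramolecular classes, correlated FEP time series, and non-Gaussian
work distributions. Passing tests therefore demonstrate correct thermodynamic
assembly and estimator behaviour, not the accuracy of any upstream
electronic-structure or force-field model.

## Numerical choices

* Energies in kJ/mol, entropies in J/(mol K) internally; conversions only at
  I/O boundaries.
* Per-mode occupations computed as x·e⁻ˣ/(1−e⁻ˣ) — overflow-safe at any
  frequency; high-frequency modes underflow gracefully to zero.
* log S₀ is kept at full precision internally and rounded half-up to two
  decimals only in the report layer.
* Benchmark problem sizes: the published-table replays are closed-form
  (instant); BAR property checks use 10⁴ samples/direction × 50 cases;
  end-to-end fixtures use 800–5000 samples/window. The whole suite runs in a
  few seconds on one CPU.

## Known limitations

Harmonic approximation throughout (no hindered rotors, no quasi-harmonic
volume dependence); single polymorph per run; activity coefficient fixed at
unity; no ionization correction (intrinsic, i.e. neutral-form, solubility
only); BAR per window rather than a multistate estimator across all windows.
One published-table column (the value sitting exactly RT below ΔG_sub°) has
no clear definition in its source and is surfaced only as the diagnostic
`dG_minus_RT`, unused by any computation.
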