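"""Harmonic thermochemistry of low-frequency lattice modes.

Builds a toy crystal spectrum of six intermolecular modes and shows how far
their quantum thermal corrections sit from the classical equipartition value
(RT per mode) that the 2RT sublimation shortcut assumes.
"""

from solcycle import mode_thermo, spectrum_thermo
from solcycle.constants import T_DEFAULT, rt_kj
from solcycle.statmech import ModeSpectrum

RT = rt_kj(T_DEFAULT)

print(f"T = {T_DEFAULT} K, RT = {RT:.4f} kJ/mol\n")
print(f"{'freq/cm^-1':>11} {'zpe':>8} {'u_thermal':>10} {'s/J/molK':>9} {'u/RT':>6}")
for freq in (20.0, 50.0, 100.0, 200.0, 500.0):
    mt = mode_thermo(freq, T_DEFAULT)
    print(f"{freq:11.0f} {mt.zpe:8.4f} {mt.u_thermal:10.4f} {mt.s:9.3f} "
          f"{mt.u_thermal / RT:6.3f}")

spec = ModeSpectrum.from_entries([(50.0, 6.0, "intermolecular")])
tc = spectrum_thermo(spec, T_DEFAULT, {"intermolecular"})
print(f"\nSix modes at 50 cm^-1: zpe + u = {tc.E_zpe + tc.U_thermal:.3f} kJ/mol "
      f"(classical 6RT would be {6 * RT:.3f})")
print("The gap between those two numbers is exactly the error the 2RT")
print("approximation makes for this spectrum's enthalpy contribution.")
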