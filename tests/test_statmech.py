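"""Harmonic-oscillator and ideal-gas thermochemistry primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solcycle import gas_thermo, mode_thermo, spectrum_thermo
from solcycle.constants import HC_NA, rt_kj
from solcycle.statmech import DomainError, ModeSpectrum, sackur_tetrode

T298 = 298.15
RT = rt_kj(T298)


class TestModeThermo:
    def test_equipartition_limit(self):
        # x -> 0: u -> RT with leading deviation RT*x/2 (~0.24% at 1 cm^-1)
        x = HC_NA * 1.0 / (8.31446261815324 * T298)
        u = mode_thermo(1.0, T298).u_thermal
        assert u == pytest.approx(RT, rel=3e-3)
        assert RT - u == pytest.approx(RT * x / 2, rel=1e-2)

    def test_frozen_mode_limit(self):
        mt = mode_thermo(5000.0, T298)
        assert mt.u_thermal < 1e-6
        assert mt.s < 1e-6

    def test_quantum_oscillator_at_100_cm1(self):
        # frozen values from direct evaluation of the QHO formulas
        mt = mode_thermo(100.0, T298)
        assert mt.zpe == pytest.approx(0.59813, abs=1e-4)
        assert mt.u_thermal == pytest.approx(1.92875, abs=1e-4)
        assert mt.a == pytest.approx(mt.zpe + mt.u_thermal - T298 * mt.s / 1000.0)

    def test_x_equals_one(self):
        # hc*nu = kB*T at 207.2 cm^-1: u = RT/(e-1)
        assert mode_thermo(207.2, T298).u_thermal == pytest.approx(
            RT / (math.e - 1.0), rel=1e-3
        )

    @pytest.mark.parametrize("freq,T", [(-10.0, 298.15), (0.0, 298.15), (100.0, 0.0)])
    def test_domain_errors(self, freq, T):
        with pytest.raises(DomainError):
            mode_thermo(freq, T)

    @given(st.floats(min_value=1.0, max_value=4000.0))
    @settings(deadline=None, max_examples=50)
    def test_u_bounded_by_rt(self, freq):
        assert 0.0 < mode_thermo(freq, T298).u_thermal <= RT

    def test_u_monotone_decreasing_in_frequency(self):
        freqs = np.linspace(1.0, 4000.0, 200)
        u = np.array([mode_thermo(f, T298).u_thermal for f in freqs])
        assert np.all(np.diff(u) < 0)

    def test_low_temperature_limit(self):
        # at T = 1 K: entropy -> 0 and A -> ZPE
        mt = mode_thermo(50.0, 1.0)
        assert mt.s < 1e-3
        assert mt.a == pytest.approx(mt.zpe, abs=1e-3)


class TestSpectrumThermo:
    def test_linearity_in_weight(self):
        single = mode_thermo(100.0, T298)
        spec = ModeSpectrum.from_entries([(100.0, 6.0, "intermolecular")])
        tc = spectrum_thermo(spec, T298, {"intermolecular"})
        assert tc.E_zpe == pytest.approx(6 * single.zpe)
        assert tc.U_thermal == pytest.approx(6 * single.u_thermal)
        assert tc.S == pytest.approx(6 * single.s)

    def test_character_additivity(self):
        spec = ModeSpectrum.from_entries(
            [(60.0, 2.0, "intermolecular"), (800.0, 3.0, "intramolecular"),
             (120.0, 1.0, "intermolecular")]
        )
        inter = spectrum_thermo(spec, T298, {"intermolecular"})
        intra = spectrum_thermo(spec, T298, {"intramolecular"})
        both = spectrum_thermo(spec, T298)
        for attr in ("E_zpe", "U_thermal", "S", "A_corr"):
            assert getattr(inter, attr) + getattr(intra, attr) == pytest.approx(
                getattr(both, attr), abs=1e-12
            )

    def test_six_modes_at_50(self):
        spec = ModeSpectrum.from_entries([(50.0, 6.0, "intermolecular")])
        tc = spectrum_thermo(spec, T298, {"intermolecular"})
        assert tc.E_zpe + tc.U_thermal == pytest.approx(14.946, abs=1e-3)

    def test_empty_selection_returns_zero(self, caplog):
        spec = ModeSpectrum.from_entries([(50.0, 6.0, "intermolecular")])
        with caplog.at_level("WARNING"):
            tc = spectrum_thermo(spec, T298, {"intramolecular"})
        assert tc.E_zpe == tc.U_thermal == tc.S == 0.0
        assert any("no modes matched" in r.message for r in caplog.records)

    def test_acoustic_always_excluded(self):
        spec = ModeSpectrum.from_entries(
            [(50.0, 6.0, "intermolecular"), (0.001, 3.0, "intermolecular")]
        )
        # the 0.001 cm^-1 entry is reclassified as acoustic at build time
        assert sum(m.character == "acoustic" for m in spec.modes) == 1
        tc = spectrum_thermo(spec, T298)
        assert tc.U_thermal == pytest.approx(
            spectrum_thermo(
                ModeSpectrum.from_entries([(50.0, 6.0, "intermolecular")]), T298
            ).U_thermal
        )

    def test_imaginary_frequency_rejected(self):
        with pytest.raises(DomainError):
            ModeSpectrum.from_entries([(-35.0, 1.0, "intermolecular")])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_bruteforce_sum(self, seed):
        """Vectorized sums equal the plain per-mode oracle for random spectra."""
        from solcycle.fixtures import direct_mode_sum

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        freqs = rng.uniform(5.0, 3500.0, n)
        weights = rng.uniform(0.0, 4.0, n)
        spec = ModeSpectrum.from_entries(
            [(f, w, "intramolecular") for f, w in zip(freqs, weights)]
        )
        truth = direct_mode_sum(
            [(f, w) for f, w in zip(freqs, weights) if w > 0], T298
        )
        tc = spectrum_thermo(spec, T298)
        assert tc.E_zpe == pytest.approx(truth["E_zpe"], rel=1e-12)
        assert tc.U_thermal == pytest.approx(truth["U_thermal"], rel=1e-12)
        assert tc.S == pytest.approx(truth["S"], rel=1e-12)


class TestGasThermo:
    def test_sackur_tetrode_argon(self):
        # closed form: 154.846 J/(mol K) at 1 bar, 154.736 at 1 atm
        assert sackur_tetrode(39.948, T298, 1e5) == pytest.approx(154.846, abs=0.01)
        assert gas_thermo(39.948, "atom", T=T298).S == pytest.approx(154.736, abs=0.01)

    def test_nonlinear_rotor_equipartition(self):
        tc = gas_thermo(100.0, "nonlinear", rotational_constants_cm1=[1.0, 0.5, 0.3])
        # no vibrations: thermal enthalpy = 3/2 RT (trans) + 3/2 RT (rot) + RT (pV)
        assert tc.H_corr - tc.E_zpe == pytest.approx(4 * RT, rel=1e-12)
        assert tc.A_corr == pytest.approx(tc.H_corr - RT - T298 * tc.S / 1000.0)

    def test_linear_rotor_equipartition(self):
        tc = gas_thermo(28.0, "linear", rotational_constants_cm1=[2.0])
        assert tc.H_corr == pytest.approx((1.5 + 1.0 + 1.0) * RT, rel=1e-12)

    def test_vibrational_mode_added(self):
        spec = ModeSpectrum.from_entries([(207.2, 1.0, "intramolecular")])
        tc = gas_thermo(100.0, "nonlinear", spec,
                        rotational_constants_cm1=[1.0, 1.0, 1.0])
        u_vib = tc.H_corr - tc.E_zpe - 4 * RT
        assert u_vib == pytest.approx(RT / (math.e - 1.0), rel=1e-3)

    def test_missing_rotational_constants(self):
        with pytest.raises(DomainError):
            gas_thermo(100.0, "nonlinear")

    def test_symmetry_number_lowers_entropy(self):
        kwargs = dict(rotational_constants_cm1=[1.0, 1.0, 1.0])
        s1 = gas_thermo(100.0, "nonlinear", symmetry_number=1, **kwargs).S
        s2 = gas_thermo(100.0, "nonlinear", symmetry_number=2, **kwargs).S
        assert s1 - s2 == pytest.approx(8.31446 * math.log(2.0), rel=1e-4)
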