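"""Hydration leg: Boltzmann conformer schemes and the BAR/FEP estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solcycle import (
    ConformerEnsemble,
    bar_window,
    ensemble_free_energy,
    exp_averaging,
    fep_total,
    hydration_sfe,
    read_conformers_csv,
    read_fep_csv,
)
from solcycle.constants import rt_kj
from solcycle.crystal import ValidationError
from solcycle.fixtures import gen_fep_dataset
from solcycle.hydration import FEPDataset, FEPWindow, reverse_schedule

T298 = 298.15
RT = rt_kj(T298)


def ens(phase, *gs):
    return ConformerEnsemble(phase, tuple((f"c{i}", g) for i, g in enumerate(gs)))


class TestEnsembleFreeEnergy:
    def test_single_conformer_identity(self):
        assert ensemble_free_energy(ens("gas", -10.0)) == pytest.approx(-10.0)

    def test_degeneracy_lowers_by_rt_ln2(self):
        assert ensemble_free_energy(ens("gas", -10.0, -10.0)) == pytest.approx(
            -10.0 - RT * math.log(2.0), abs=1e-9
        )

    def test_three_spaced_conformers(self):
        # G at 0, RT, 2RT: weights 1, e^-1, e^-2
        g = ensemble_free_energy(ens("gas", 0.0, 2.479, 4.958))
        assert g == pytest.approx(-1.011, abs=2e-3)

    def test_overflow_safe(self):
        g = ensemble_free_energy(ens("gas", -1e5, -1e5 + 1.0))
        assert math.isfinite(g) and g < -1e5

    @given(st.floats(min_value=-500, max_value=500))
    @settings(deadline=None, max_examples=30)
    def test_shift_covariance(self, c):
        base = ens("gas", 0.0, 1.5, 3.0)
        shifted = ens("gas", c, 1.5 + c, 3.0 + c)
        assert ensemble_free_energy(shifted) == pytest.approx(
            ensemble_free_energy(base) + c, abs=1e-6
        )

    def test_below_minimum_and_t0_limit(self):
        e = ens("gas", 1.0, 3.0)
        assert ensemble_free_energy(e) <= 1.0
        cold = ConformerEnsemble("gas", e.conformers, T=1.0)
        assert ensemble_free_energy(cold) == pytest.approx(1.0, abs=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ConformerEnsemble("gas", ())


class TestSfeSchemes:
    def test_schemes_coincide_for_single_conformers(self):
        gas = ens("gas", 2.0)
        soln = ens("solution", -30.0)
        for scheme in ("SFE1", "SFE2", "SFE3"):
            assert hydration_sfe(gas, soln, scheme, "c0") == pytest.approx(-32.0)

    def test_sfe1_below_sfe2_by_rt_ln2_for_degenerate_pair(self):
        gas = ens("gas", 0.0)
        soln = ens("solution", -30.0, -30.0)
        d1 = hydration_sfe(gas, soln, "SFE1", "c0")
        d2 = hydration_sfe(gas, soln, "SFE2", "c0")
        assert d2 - d1 == pytest.approx(RT * math.log(2.0), abs=1e-9)

    def test_sfe3_vs_sfe1_gas_ensemble_shift(self):
        # reference conformer 5 kJ/mol above the others
        gas = ens("gas", 5.0, 0.0, 0.0)  # reference = c0
        soln = ens("solution", -30.0, -28.0)
        d1 = hydration_sfe(gas, soln, "SFE1", "c0")
        d3 = hydration_sfe(gas, soln, "SFE3")
        g_gas_ens = ensemble_free_energy(gas)
        assert d3 - d1 == pytest.approx(5.0 - g_gas_ens, abs=1e-9)
        assert d3 > d1  # ensemble gas reference is more stable -> less negative

    def test_sfe2_tie_broken_lexicographically(self):
        soln = ConformerEnsemble("solution", (("b", -30.0), ("a", -30.0)))
        assert soln.minimum()[0] == "a"

    def test_unknown_reference_id(self):
        with pytest.raises(KeyError):
            hydration_sfe(ens("gas", 0.0), ens("solution", -30.0), "SFE1", "zz")

    def test_conformer_csv_round_trip(self, tmp_path):
        path = tmp_path / "conf.csv"
        path.write_text(
            "phase,conformer_id,G_kJmol\n"
            "gas,g0,0.0\ngas,g1,2.0\n"
            "solution,s0,–30.0\n"  # en-dash minus normalized at parse
        )
        ensembles = read_conformers_csv(path)
        assert ensembles["solution"].conformers[0][1] == pytest.approx(-30.0)
        assert hydration_sfe(
            ensembles["gas"], ensembles["solution"], "SFE2", "g0"
        ) == pytest.approx(-30.0)


class TestBarWindow:
    def test_delta_distributions(self):
        c = 3.7
        dF, se = bar_window([c] * 10, [-c] * 10, T298)
        assert dF == pytest.approx(c, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        f = rng.normal(2.0, 1.0, 500)
        b = rng.normal(-1.0, 1.0, 500)
        dF, _ = bar_window(f, b, T298)
        dR, _ = bar_window(b, f, T298)
        assert dF == pytest.approx(-dR, abs=1e-9)

    def test_gaussian_crooks_recovery(self):
        # work ~ N(dF + s^2/2, s^2) forward, N(-dF + s^2/2, s^2) backward
        rng = np.random.default_rng(2024)
        n = 10_000
        f = rng.normal(1.5, 1.0, n) * RT
        b = rng.normal(-0.5, 1.0, n) * RT
        dF, se = bar_window(f, b, T298)
        assert dF == pytest.approx(1.0 * RT, abs=3 * se)

    def test_unequal_sample_counts(self):
        # Crooks-consistent pair with dF = 0.6 kT, sigma = 0.8 kT
        rng = np.random.default_rng(9)
        f = rng.normal(0.92, 0.8, 4000) * RT
        b = rng.normal(-0.28, 0.8, 1000) * RT
        dF, se = bar_window(f, b, T298)
        assert dF == pytest.approx(0.6 * RT, abs=4 * se)

    def test_agrees_with_exponential_averaging_at_perfect_overlap(self):
        # identical distributions centered on dF: both estimators converge
        rng = np.random.default_rng(31)
        n = 10_000
        true = 0.8 * RT
        f = rng.normal(0.8, 0.05, n) * RT
        b = rng.normal(-0.8, 0.05, n) * RT
        dF, _ = bar_window(f, b, T298)
        assert abs(dF - exp_averaging(f, T298)) < 0.05 * RT
        assert dF == pytest.approx(true, abs=0.05 * RT)

    def test_separated_delta_distributions(self):
        # delta distributions at a (forward) and b (backward): dF = (a - b)/2
        dF, _ = bar_window([10 * RT] * 5, [4 * RT] * 5, T298)
        assert dF == pytest.approx(3 * RT, abs=1e-6)

    def test_parameter_recovery_50_fixtures(self):
        """>=95% of seeded Gaussian cases recover dF within 4 stderr."""
        rng = np.random.default_rng(123)
        hits = 0
        n = 10_000
        for _ in range(50):
            dF_true = rng.uniform(-5.0, 5.0)
            sigma = rng.uniform(0.5, 2.0)
            f = rng.normal(dF_true + sigma**2 / 2, sigma, n) * RT
            b = rng.normal(-dF_true + sigma**2 / 2, sigma, n) * RT
            est, se = bar_window(f, b, T298)
            if abs(est - dF_true * RT) <= 4 * se:
                hits += 1
        assert hits >= 48  # 95% of 50

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            bar_window([1.0], [1.0, 2.0], T298)


class TestFepTotal:
    def _window(self, lo, hi, dF):
        return FEPWindow(lo, hi, [dF, dF], [-dF, -dF])

    def test_zero_windows_sum_to_zero(self):
        ds = FEPDataset(
            tuple(self._window(i / 4, (i + 1) / 4, 0.0) for i in range(4)),
            lambda0_coupled=False,
        )
        dg, se = fep_total(ds)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_additivity(self):
        ds = FEPDataset(
            (self._window(0.0, 0.4, 1.0), self._window(0.4, 0.7, 2.0),
             self._window(0.7, 1.0, 3.0)),
            lambda0_coupled=False,
        )
        dg, se = fep_total(ds)
        assert dg == pytest.approx(6.0, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_sign_flip_for_coupled_convention(self):
        windows = (self._window(0.0, 0.5, 1.0), self._window(0.5, 1.0, 2.0))
        decouple = FEPDataset(windows, lambda0_coupled=True)
        assert fep_total(decouple)[0] == pytest.approx(-3.0, abs=1e-9)

    def test_reversed_schedule_negates(self):
        ds, _ = gen_fep_dataset(seed=77, dG_true_rt=-4.0, sigma_rt=0.6,
                                n_samples=50, n_windows=5)
        dg, _ = fep_total(ds)
        dg_rev, _ = fep_total(reverse_schedule(ds))
        assert dg_rev == pytest.approx(-dg, abs=1e-9)

    def test_gap_in_schedule_rejected(self):
        with pytest.raises(ValidationError, match="schedule"):
            FEPDataset((self._window(0.0, 0.4, 1.0), self._window(0.5, 1.0, 1.0)))

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(ValidationError, match="schedule"):
            FEPDataset((self._window(0.1, 1.0, 1.0),))

    def test_fep_csv_round_trip(self, tmp_path):
        from solcycle.hydration import write_fep_csv

        ds, truth = gen_fep_dataset(seed=4, dG_true_rt=-3.0, sigma_rt=0.5,
                                    n_samples=40, n_windows=4)
        path = tmp_path / "fep.csv"
        write_fep_csv(ds, path)
        back = read_fep_csv(path)
        dg_a, _ = fep_total(ds)
        dg_b, _ = fep_total(back)
        assert dg_a == pytest.approx(dg_b, abs=1e-9)
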