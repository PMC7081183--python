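"""Intine gel chemistry: ionization, Donnan partition, pressure terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollengel import (IntineGel, IonicEnvironment, default_gel,
                       divalent_binding, donnan_partition, elastic_pressure,
                       environment, free_swelling_ratio,
                       intine_swelling_pressure, ionic_osmotic_pressure,
                       ionization_fraction, mixing_pressure)
from pollengel.gel import R_GAS, V_M_WATER, IonSpecies


class TestIonization:
    def test_half_ionized_at_pka(self):
        assert ionization_fraction(3.5, 3.5) == pytest.approx(0.5)

    def test_acidic_and_basic_hand_values(self):
        assert ionization_fraction(2.0, 3.5) == pytest.approx(0.0307, abs=2e-4)
        assert ionization_fraction(12.0, 3.5) > 0.9999

    def test_strictly_increasing_in_pH(self):
        ph = np.linspace(0, 14, 100)
        a = np.array([ionization_fraction(p, 3.5) for p in ph])
        assert np.all(np.diff(a) > 0)
        assert np.all((a > 0) & (a < 1))


class TestDonnan:
    def test_no_fixed_charge_is_identity(self):
        env = environment(7.0, KCl=50.0, CaCl2=5.0)
        internal, y = donnan_partition(0.0, env)
        assert y == 0.0
        for s in env.ions:
            assert internal[s.name] == pytest.approx(s.c_mM)

    def test_univalent_closed_form(self):
        # 1:1 bath 100 mM, fixed -100 mM: quadratic gives
        # counter-ion 50(1+sqrt 5), co-ion 50(sqrt 5 - 1)
        env = environment(7.0, KCl=100.0)
        internal, y = donnan_partition(-100.0, env)
        assert internal["K+"] == pytest.approx(50 * (1 + np.sqrt(5)), rel=1e-10)
        assert internal["Cl-"] == pytest.approx(50 * (np.sqrt(5) - 1), rel=1e-10)

    def test_charge_sign_flip_swaps_roles(self):
        env = environment(7.0, KCl=40.0)
        int_m, y_m = donnan_partition(-30.0, env)
        int_p, y_p = donnan_partition(+30.0, env)
        assert y_p == pytest.approx(-y_m, rel=1e-10)
        assert int_p["Cl-"] == pytest.approx(int_m["K+"], rel=1e-10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(cf=st.floats(-300, 300), kcl=st.floats(1.0, 200.0),
           cacl2=st.floats(0.0, 100.0))
    def test_internal_electroneutrality(self, cf, kcl, cacl2):
        env = environment(7.0, KCl=kcl, CaCl2=cacl2)
        internal, y = donnan_partition(cf, env)
        zmap = {s.name: s.z for s in env.ions}
        resid = sum(zmap[n] * c for n, c in internal.items()) + cf
        strength = sum(abs(s.z) * s.c_mM for s in env.ions)
        assert abs(resid) < 1e-9 * max(strength, 1.0)

    def test_root_matches_grid_scan_oracle(self, rng):
        for _ in range(20):
            cf = rng.uniform(-200, 200)
            env = environment(7.0, KCl=rng.uniform(5, 150),
                              CaCl2=rng.uniform(0, 50))
            _, y = donnan_partition(cf, env)
            grid = np.linspace(-5, 5, 2_000_001)
            resid = np.zeros_like(grid)
            for s in env.ions:
                resid += s.z * s.c_mM * np.exp(-s.z * grid)
            resid += cf
            y_grid = grid[np.argmin(np.abs(resid))]
            assert y == pytest.approx(y_grid, abs=1e-5)

    def test_unneutralizable_charge_errors(self):
        env = IonicEnvironment(pH=7.0, ions=[])
        with pytest.raises(ValueError):
            donnan_partition(-10.0, env)


class TestOsmoticPressure:
    def test_zero_fixed_charge_zero_pressure(self):
        env = environment(7.0, KCl=80.0)
        internal, _ = donnan_partition(0.0, env)
        assert ionic_osmotic_pressure(internal, env) == 0.0

    def test_hand_value_univalent_case(self):
        # RT * (161.8 + 61.8 - 200) mol/m^3 at 298 K ~ 58.5 kPa
        env = environment(7.0, KCl=100.0)
        internal, _ = donnan_partition(-100.0, env)
        assert ionic_osmotic_pressure(internal, env) == pytest.approx(
            58.5, abs=0.1)

    def test_monotone_screening_in_salt(self):
        prev = np.inf
        for kcl in (5, 10, 20, 50, 100):
            env = environment(7.0, KCl=float(kcl))
            internal, _ = donnan_partition(-50.0, env)
            p = ionic_osmotic_pressure(internal, env)
            assert p < prev
            prev = p


class TestMixingAndElastic:
    def test_mixing_vanishes_at_large_swelling(self):
        assert mixing_pressure(50.0, 0.1, 0.45) == pytest.approx(0.0, abs=1e-3)

    def test_mixing_taylor_expansion_at_chi_half(self):
        # -[ln(1-phi)+phi+phi^2/2] = phi^3/3 + O(phi^4)
        for lam in (3.0, 4.0, 6.0):
            phi = 0.05 / lam**3
            expect = (R_GAS * 298.0 / V_M_WATER) * phi**3 / 3.0 * 1e-3
            assert mixing_pressure(lam, 0.05, 0.5) == pytest.approx(
                expect, rel=5e-2)

    def test_mixing_monotone_decreasing_in_lambda(self):
        lams = np.linspace(1.0, 3.0, 50)
        p = [mixing_pressure(l, 0.3, 0.45) for l in lams]
        assert np.all(np.diff(p) < 0)

    def test_mixing_domain_error(self):
        with pytest.raises(ValueError):
            mixing_pressure(0.5, 0.3, 0.45)  # phi = 2.4 >= 1

    def test_elastic_reference_and_hand_value(self):
        assert elastic_pressure(1.0, 10.0) == 0.0
        assert elastic_pressure(2.0, 10.0) == pytest.approx(-15.0)

    def test_elastic_sign_opposes_deformation(self):
        for lam in (0.5, 0.9, 1.1, 2.0):
            assert np.sign(elastic_pressure(lam, 5.0)) == -np.sign(lam - 1)


class TestDivalentBinding:
    def test_no_multivalent_no_effect(self, gel):
        env = environment(7.0, KCl=100.0)
        theta, g_eff, charge = divalent_binding(env, gel)
        assert theta == 0.0 and g_eff == gel.G_i and charge == 1.0

    def test_chelator_excess_fully_reverses(self, gel):
        env = environment(7.0, KCl=10.0, CaCl2=50.0, chelator_mM=50.0)
        theta, g_eff, _ = divalent_binding(env, gel)
        assert theta == 0.0 and g_eff == gel.G_i

    def test_calibration_100mM_ca_gives_ratio_0p15(self, gel, shell):
        # default shell realizes M_E/I = 1.6; full calcium loading stiffens
        # the intine until the effective ratio is 0.15
        from pollengel.gel import effective_intine_modulus_MPa
        env = environment(7.0, KCl=10.0, CaCl2=100.0)
        m_eff = 3.0 * shell.mu_e * 1e-3 / effective_intine_modulus_MPa(env, gel)
        assert m_eff == pytest.approx(0.15, rel=1e-3)

    def test_langmuir_monotone_in_dose(self, gel):
        thetas = [divalent_binding(environment(7.0, KCl=10.0, CaCl2=float(c)),
                                   gel)[0] for c in (0, 5, 10, 20, 50, 100)]
        assert np.all(np.diff(thetas) > 0) or thetas[0] == 0


class TestComposedPressure:
    def test_breakdown_sums_exactly(self, gel, env_ph7):
        b = intine_swelling_pressure(1.3, gel, env_ph7)
        assert b.total == b.pi_ion + b.pi_mix + b.pi_elastic

    def test_no_driving_force_without_charge_or_polymer(self, env_ph7):
        gel = IntineGel(c_coo_total=0.0, phi0=1e-9, G_i=0.0)
        for lam in (1.0, 1.5, 2.0):
            assert intine_swelling_pressure(
                lam, gel, env_ph7).total == pytest.approx(0.0, abs=1e-6)

    def test_total_strictly_decreasing_in_lambda(self, gel, env_ph7):
        lams = np.linspace(1.0, 2.0, 60)
        tot = [intine_swelling_pressure(l, gel, env_ph7).total for l in lams]
        assert np.all(np.diff(tot) < 0)

    def test_total_nondecreasing_in_pH(self, gel):
        for lam in (1.05, 1.2):
            tots = [intine_swelling_pressure(
                lam, gel, environment(ph, KCl=10.0)).total
                for ph in np.linspace(2, 12, 21)]
            assert np.all(np.diff(tots) >= -1e-12)

    def test_calcium_lowers_pressure_at_fixed_lambda(self, gel):
        plain = environment(7.0, KCl=10.0)
        ca = environment(7.0, KCl=10.0, CaCl2=100.0)
        for lam in (1.05, 1.2):
            assert (intine_swelling_pressure(lam, gel, ca).total
                    < intine_swelling_pressure(lam, gel, plain).total)


class TestFreeSwelling:
    def test_monotone_screening_of_equilibrium(self, gel):
        lams = [free_swelling_ratio(gel, environment(7.0, KCl=float(c)))
                for c in (5, 10, 20, 50, 100)]
        assert np.all(np.diff(lams) < 0)

    def test_nondecreasing_in_pH(self, gel):
        lams = [free_swelling_ratio(gel, environment(ph, KCl=10.0))
                for ph in np.linspace(2, 12, 11)]
        assert np.all(np.diff(lams) >= -1e-9)

    def test_ca_then_edta_restores_pressure_curve(self, gel):
        before = environment(7.0, KCl=10.0)
        after = environment(7.0, KCl=10.0, CaCl2=0.0, chelator_mM=60.0)
        loaded = environment(7.0, KCl=10.0, CaCl2=50.0, chelator_mM=50.0)
        for lam in np.linspace(1.0, 1.5, 6):
            p0 = intine_swelling_pressure(lam, gel, before).total
            p1 = intine_swelling_pressure(lam, gel, loaded).total
            assert p1 == pytest.approx(p0, rel=1e-12, abs=1e-12)


class TestEnvironmentValidation:
    def test_counterion_autocompletion(self):
        env = IonicEnvironment(pH=7.0, ions=[IonSpecies("Na+", 1, 10.0)])
        resid = sum(s.z * s.c_mM for s in env.ions)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_ph_range_enforced(self):
        with pytest.raises(ValueError):
            IonicEnvironment(pH=15.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            IonicEnvironment(pH=7.0, ions=[IonSpecies("K+", 1, -5.0)])
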