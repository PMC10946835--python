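"""Transporter kinetics: Nernst, GHK, gating, regulation, pumps, carriers."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from stomasim import (RegulationSpec, TransportedSolute, TransporterSpec,
                      carrier_flux, gating_open_probability, ghk_flux,
                      initial_state, membrane_iv, nernst_potential, pump_flux,
                      regulation_factor, steady_voltage)
from stomasim.constants import RT_KJ
from stomasim.transport import coupled_delta_g

VAL = {"K": 1, "Cl": -1, "Mal": -2, "Ca": 2, "H": 1, "Suc": 0, "ABA": 0}


def conc(d):
    return lambda s: d[s]


class TestNernst:
    def test_symmetric_concentrations_give_zero(self):
        assert nernst_potential(1, 50.0, 50.0) == pytest.approx(0.0)

    def test_tenfold_monovalent_gradient(self):
        # (RT/F) ln(10/100) = -59.16 mV at 298.15 K
        assert nernst_potential(1, 10.0, 100.0) == pytest.approx(-59.16,
                                                                 abs=0.01)

    @given(st.floats(0.1, 1000), st.floats(0.1, 1000))
    def test_antisymmetric_in_valence_sign(self, co, ci):
        assert nernst_potential(-1, co, ci) == pytest.approx(
            -nernst_potential(1, co, ci))

    def test_rejects_zero_valence_and_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            nernst_potential(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            nernst_potential(1, 0.0, 1.0)


class TestGHK:
    def test_equilibrium_zero_flux(self):
        assert ghk_flux(1e-3, 1, 0.0, 10.0, 10.0) == 0.0

    @given(st.integers(-2, 2).filter(lambda z: z != 0),
           st.floats(0.5, 500), st.floats(0.5, 500))
    def test_zero_exactly_at_nernst_potential(self, z, ci, co):
        v_rev = nernst_potential(z, co, ci)
        if abs(v_rev) > 290:
            return
        phi = ghk_flux(1e-3, z, v_rev, ci, co)
        assert abs(phi) < 1e-12 * 1e-3 * max(ci, co) * 50

    def test_hyperpolarized_cation_influx_matches_independent_formula(self):
        # independent evaluation of the constant-field expression
        p, z, v, ci, co = 2.0e-3, 1, -120.0, 100.0, 10.0
        u = z * v / 25.693
        efflux = p * u * (ci - co * math.exp(-u)) / (1.0 - math.exp(-u))
        assert ghk_flux(p, z, v, ci, co) == pytest.approx(-efflux)
        assert ghk_flux(p, z, v, ci, co) > 0  # inward-positive

    def test_continuous_and_differentiable_across_zero_voltage(self):
        """Finite-difference continuity check across the series-limit switch."""
        p, z, ci, co = 1e-3, 1, 80.0, 20.0
        vs = [-1e-3, -1e-5, -1e-7, 0.0, 1e-7, 1e-5, 1e-3]
        phis = [ghk_flux(p, z, v, ci, co) for v in vs]
        for a, b in zip(phis, phis[1:]):
            assert abs(a - b) < 1e-5
        # central slopes at two scales straddling the switch agree
        slope_wide = (ghk_flux(p, z, 1e-3, ci, co)
                      - ghk_flux(p, z, -1e-3, ci, co)) / 2e-3
        slope_narrow = (ghk_flux(p, z, 1e-5, ci, co)
                        - ghk_flux(p, z, -1e-5, ci, co)) / 2e-5
        assert slope_wide == pytest.approx(slope_narrow, rel=1e-3)


class TestGating:
    def test_half_activation_at_v_half(self):
        assert gating_open_probability(-100.0, -100.0, 2.0) == 0.5

    def test_boltzmann_value_one_rt_f_above_midpoint(self):
        p = gating_open_probability(-100.0 + 25.693, -100.0, 1.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-6)

    def test_saturation_limits(self):
        assert gating_open_probability(500.0, 0.0, 2.0) == pytest.approx(1.0)
        assert gating_open_probability(-500.0, 0.0, 2.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_modifiers_multiply_and_clip(self):
        base = gating_open_probability(-100.0, -100.0, 2.0)
        assert gating_open_probability(-100.0, -100.0, 2.0,
                                       (0.5,)) == pytest.approx(base * 0.5)
        assert gating_open_probability(-100.0, -100.0, 2.0, (10.0,)) == 1.0


class TestRegulation:
    def test_no_ligand_no_effect(self):
        spec = RegulationSpec("cytosolic_Ca", "inhibit", k_half=1e-3,
                              hill_n=2.0, floor=0.2)
        assert regulation_factor(spec, 0.0) == 1.0

    def test_half_inhibition_at_k_half_with_zero_floor(self):
        spec = RegulationSpec("cytosolic_Ca", "inhibit", k_half=1e-3,
                              hill_n=1.0, floor=0.0)
        assert regulation_factor(spec, 1e-3) == pytest.approx(0.5)

    def test_floor_reached_at_saturation(self):
        spec = RegulationSpec("cytosolic_Ca", "inhibit", k_half=1e-3,
                              hill_n=2.0, floor=0.2)
        assert regulation_factor(spec, 1e3) == pytest.approx(0.2, rel=1e-4)

    @given(st.floats(0, 1e3), st.sampled_from(["activate", "inhibit"]),
           st.floats(0.05, 0.9), st.floats(0.5, 4.0))
    def test_bounded_per_contract(self, x, mode, floor, n):
        """Inhibition lives in [floor, 1]; activation in [1, 1/floor]."""
        spec = RegulationSpec("cytosolic_Ca", mode, k_half=0.5, hill_n=n,
                              floor=floor)
        f = regulation_factor(spec, x)
        if mode == "inhibit":
            assert floor - 1e-12 <= f <= 1.0 + 1e-12
        else:
            assert 1.0 - 1e-12 <= f <= 1.0 / floor + 1e-12


def _proton_pump(population=1.0, turnover=1.0):
    return TransporterSpec(
        name="pump", membrane="plasma_membrane", kind="pump",
        population=population, turnover_max=turnover,
        transported=[TransportedSolute("H", 1.0, -1)],
        energized_delta_g_kj=-45.0)


class TestPump:
    def test_net_flux_zero_at_thermodynamic_stall(self):
        """At the reversal voltage computed from dG_ATP and the H gradient,
        the pump flux vanishes."""
        pump = _proton_pump()
        hc, ha = 1e-4, 3.16e-3
        # dG(V) = dG_ATP - RT ln(hc/ha) - F V = 0 at the stall voltage
        v_stall = (-45.0 - RT_KJ * math.log(hc / ha)) / 0.096485
        cyt = conc({"H": hc})
        apo = conc({"H": ha})
        flux = pump_flux(pump, v_stall, cyt, apo, VAL)
        assert abs(flux["H"]) < 1e-12

    def test_runs_downhill_near_stall(self):
        """20 mV to either side of the stall, flux sign equals sign(-dG)."""
        pump = _proton_pump()
        hc, ha = 1e-4, 3.16e-3
        v_stall = (-45.0 - RT_KJ * math.log(hc / ha)) / 0.096485
        cyt, apo = conc({"H": hc}), conc({"H": ha})
        # depolarized of stall: export favourable -> net H flux out (<0);
        # hyperpolarized of stall: the cycle reverses and H leaks in
        assert pump_flux(pump, v_stall + 20.0, cyt, apo, VAL)["H"] < 0
        assert pump_flux(pump, v_stall - 20.0, cyt, apo, VAL)["H"] > 0

    def test_flux_linear_in_population(self):
        cyt, apo = conc({"H": 1e-4}), conc({"H": 3e-3})
        f1 = pump_flux(_proton_pump(population=1e5), -150.0, cyt, apo, VAL)
        f2 = pump_flux(_proton_pump(population=2e5), -150.0, cyt, apo, VAL)
        assert f2["H"] == pytest.approx(2.0 * f1["H"])

    def test_zero_substrate_rejected(self):
        with pytest.raises(ValueError):
            pump_flux(_proton_pump(), -100.0, conc({"H": 0.0}),
                      conc({"H": 1e-3}), VAL)


def _symporter():
    return TransporterSpec(
        name="sym", membrane="plasma_membrane", kind="carrier",
        population=100.0, turnover_max=0.01,
        transported=[TransportedSolute("H", 2.0, 1),
                     TransportedSolute("Cl", 1.0, 1)])


def _antiporter():
    return TransporterSpec(
        name="cax", membrane="tonoplast", kind="carrier",
        population=100.0, turnover_max=0.01,
        transported=[TransportedSolute("Ca", 1.0, -1),
                     TransportedSolute("H", 3.0, 1)])


class TestCarrier:
    def test_all_fluxes_zero_at_constructed_equilibrium(self):
        """Gradients built so the coupled dG is exactly zero."""
        sym = _symporter()
        v = 0.0
        hc, ha = 1e-4, 1e-3
        # 2 RT ln(hc/ha) + RT ln(clc/cla) = 0 -> clc = cla * (ha/hc)^2
        cla = 5.0
        clc = cla * (ha / hc) ** 2
        fx = carrier_flux(sym, v, conc({"H": hc, "Cl": clc}),
                          conc({"H": ha, "Cl": cla}), VAL)
        assert all(abs(phi) < 1e-15 for phi in fx.values())

    def test_exact_stoichiometric_coupling(self):
        sym = _symporter()
        fx = carrier_flux(sym, -120.0, conc({"H": 1e-4, "Cl": 10.0}),
                          conc({"H": 3e-3, "Cl": 2.0}), VAL)
        assert fx["H"] == pytest.approx(2.0 * fx["Cl"])

    def test_antiporter_direction_matches_brute_force_delta_g(self):
        """Ca2+/3H+ exchange across the tonoplast: with a steep H gradient
        the independent dG evaluation says Ca moves into the vacuole."""
        cax = _antiporter()
        cyt = conc({"Ca": 1e-4, "H": 10 ** (3 - 7.4)})
        vac = conc({"Ca": 2e-2, "H": 10 ** (3 - 5.0)})
        v = -10.0
        dg = (1 * -1 * (RT_KJ * math.log(1e-4 / 2e-2) + 2 * 0.096485 * v)
              + 3 * (RT_KJ * math.log(10 ** (3 - 7.4) / 10 ** (3 - 5.0))
                     + 0.096485 * v))
        assert dg == pytest.approx(
            coupled_delta_g(cax, v, cyt, vac, VAL), rel=1e-9)
        fx = carrier_flux(cax, v, cyt, vac, VAL)
        assert dg < 0
        assert fx["Ca"] < 0   # Ca leaves the cytosol into the vacuole
        assert fx["H"] > 0


@settings(max_examples=200, deadline=None)
@given(st.floats(-200, 50), st.floats(1e-5, 10), st.floats(1e-5, 10),
       st.floats(1e-5, 10), st.floats(1e-5, 10),
       st.sampled_from(["pump", "carrier"]))
def test_pump_and_carrier_sign_is_minus_sign_of_delta_g(v, a1, a2, b1, b2,
                                                        kind):
    """Second law, property-tested over randomized states: the cycle rate of
    every energized pump and coupled carrier has the sign of -dG, and the
    flux vanishes below 1e-10 of maximum exactly at reversal."""
    if kind == "pump":
        spec = _proton_pump(population=100.0, turnover=0.01)
        cyt, oth = conc({"H": a1}), conc({"H": b1})
    else:
        spec = _symporter()
        cyt, oth = conc({"H": a1, "Cl": a2}), conc({"H": b1, "Cl": b2})
    dg = coupled_delta_g(spec, v, cyt, oth, VAL)
    fx = (pump_flux if kind == "pump" else carrier_flux)(spec, v, cyt, oth,
                                                         VAL)
    rate = fx["H"] / (2.0 if kind == "carrier" else 1.0) / (
        spec.transported[0].direction)
    max_rate = spec.population * spec.turnover_max
    if abs(dg) < 1e-12:
        assert abs(rate) < 1e-10 * max_rate
    else:
        assert rate * dg <= 0
        assert abs(rate) <= max_rate * (1.0 + 1e-12)


class TestMembraneIV:
    def test_total_iv_crosses_zero_at_free_running_voltage(self, base_model):
        state = initial_state(base_model)
        v_free = steady_voltage(base_model, state, "plasma_membrane")
        curve = membrane_iv(base_model, state, "plasma_membrane",
                            [v_free - 1.0, v_free, v_free + 1.0])
        total = curve.currents["total"]
        assert abs(total[1]) < 0.5
        assert total[0] < total[2]

    def test_k_channel_iv_crosses_zero_at_e_k(self, base_model):
        state = initial_state(base_model)
        k_cyt = state.cytosol.concentration("K")
        k_sub = state.subdomain_mm["K"]
        e_k = nernst_potential(1, k_sub, k_cyt)
        curve = membrane_iv(base_model, state, "plasma_membrane",
                            [e_k - 5.0, e_k, e_k + 5.0])
        i_k = curve.currents["pm_k_out"]
        assert abs(i_k[1]) < 1e-9
        assert i_k[0] * i_k[2] < 0

    def test_knockout_population_gives_identically_zero_curve(self,
                                                              base_model):
        import copy
        m = copy.deepcopy(base_model)
        m.transporter("pm_k_in").population = 0.0
        state = initial_state(m)
        curve = membrane_iv(m, state, "plasma_membrane",
                            list(range(-250, 60, 25)))
        assert all(i == 0.0 for i in curve.currents["pm_k_in"])

    def test_non_increasing_voltages_rejected(self, base_model):
        state = initial_state(base_model)
        with pytest.raises(ValueError):
            membrane_iv(base_model, state, "plasma_membrane", [0.0, 0.0])
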