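"""The iterative computational cycle.

Each time step runs one full loop: environment lookup -> regulation update
-> transporter and metabolic fluxes -> membrane voltages by charge
conservation -> compartment contents by mass conservation -> Ca2+/pH
buffering -> water flux, volume, turgor and aperture -> gas exchange ->
epidermal/subdomain exchange.

Voltages are advanced capacitively (C dV/dt = -I).  The plasma membrane
uses an exponential-relaxation step: the current is linearized around the
working point, the step's path-average voltage is computed from the
resulting exponential solution, and the applied fluxes are evaluated there,
with dV = -I_applied*dt/C exactly.  This keeps the scheme stable at time
steps far beyond the membrane RC time while making the charge ledger
(C*dV = -integral I dt) exact by construction and consistent with the mass
ledger.  The tonoplast can run the same way or, by default, quasi-steady
(I(V) = 0 root each step), which is fast because its relaxation time is
far below the stepping time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .gas_exchange import (GasState, solve_internal_co2, stomatal_conductance,
                           transpiration, wall_vapor_pressure,
                           water_use_efficiency, assimilation_rate)
from .constants import GS_GCO2_RATIO, saturation_vapour_pressure_mbar
from .hydromechanics import (MechanicalState, aperture_from_turgor,
                             epidermal_turgor_step, osmotic_potential,
                             subdomain_step, turgor_from_volume,
                             wall_water_potential, water_flux,
                             aperture_target)
from .metabolism import SignalState, metabolic_fluxes, signal_modifiers
from .model_io import ModelSpec, PROTON
from .transport import (membrane_current, regulation_factor,
                        transporter_fluxes)

V_GUARD_MIN_MV = -300.0
V_GUARD_MAX_MV = 100.0
PH_CYT_GUARD = (5.0, 9.0)
PH_VAC_GUARD = (3.8, 9.0)

#: a negative-amount clip larger than this faults the step (fmol)
CLIP_FAULT_FMOL = 1.0e-3

#: concentration floor used when evaluating thermodynamic terms (mM)
CONC_FLOOR_MM = 1.0e-12

#: numerical floor on CO2 diffusion conductance in the substomatal balance
G_CO2_FLOOR_MOL = 1.0e-6


class SolverFault(RuntimeError):
    """Model pathology detected during integration (guard rails, clips)."""


DEFAULT_ENV = {
    "blue_light": 0.0, "red_light": 0.0, "pco2": 400.0, "rh": 70.0,
    "rwf": None, "aba": 0.0,
}


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class MembraneState:
    voltage_mv: float
    capacitance_pf: float


@dataclass
class CompartmentState:
    volume_pl: float
    amounts_fmol: dict[str, float]

    def concentration(self, solute: str) -> float:
        return self.amounts_fmol.get(solute, 0.0) / self.volume_pl


@dataclass
class CellState:
    """Everything the engine integrates, at one instant."""
    pm: MembraneState
    tono: MembraneState
    cytosol: CompartmentState
    vacuole: CompartmentState
    subdomain_mm: dict[str, float]        # apoplastic subdomain, mM
    ph_cyt: float
    ph_vac: float
    mech: MechanicalState
    gas: GasState
    time_s: float = 0.0

    def clone(self) -> "CellState":
        return CellState(
            pm=replace(self.pm), tono=replace(self.tono),
            cytosol=CompartmentState(self.cytosol.volume_pl,
                                     dict(self.cytosol.amounts_fmol)),
            vacuole=CompartmentState(self.vacuole.volume_pl,
                                     dict(self.vacuole.amounts_fmol)),
            subdomain_mm=dict(self.subdomain_mm),
            ph_cyt=self.ph_cyt, ph_vac=self.ph_vac,
            mech=replace(self.mech), gas=replace(self.gas),
            time_s=self.time_s)


@dataclass
class FluxVector:
    """All fluxes of one instant; flux positive into the cytosol, fmol/s."""
    per_transporter: dict[str, dict[str, float]]
    pm_net: dict[str, float]
    tono_net: dict[str, float]
    metabolic: dict[str, float]
    h_load_metabolic: float = 0.0


@dataclass
class StepRecord:
    """Applied fluxes and diagnostics of one accepted step."""
    dt_s: float
    fluxes: FluxVector
    i_pm_pa: float
    i_tono_pa: float
    dv_pm_mv: float
    dv_tono_mv: float
    water_flux_pl_s: float
    metrics: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kinetic context: concentrations and regulation at one instant
# ---------------------------------------------------------------------------

def _free_fraction(kappa: float) -> float:
    return 1.0 / (1.0 + kappa)


class KineticContext:
    """Concentrations (with Ca buffering and ledger-derived protons) and
    per-transporter regulation multipliers, frozen for one step."""

    def __init__(self, model: ModelSpec, state: CellState,
                 env: dict | None = None):
        env = dict(DEFAULT_ENV) if env is None else env
        sig = model.signalling
        self.model = model
        self.valences = {s.name: s.valence for s in model.solutes}
        self.valences.setdefault(PROTON, 1)

        v_cyt = state.cytosol.volume_pl
        v_vac = state.vacuole.volume_pl
        cyt = {name: amt / v_cyt
               for name, amt in state.cytosol.amounts_fmol.items()}
        vac = {name: amt / v_vac
               for name, amt in state.vacuole.amounts_fmol.items()}
        self.ca_total_cyt = cyt.get("Ca", 0.0)
        cyt["Ca"] = self.ca_total_cyt * _free_fraction(sig.ca_buffer_kappa)
        vac["Ca"] = vac.get("Ca", 0.0) * _free_fraction(sig.ca_buffer_kappa_vac)
        cyt[PROTON] = 10.0 ** (3.0 - state.ph_cyt)
        vac[PROTON] = 10.0 ** (3.0 - state.ph_vac)
        sub = dict(state.subdomain_mm)
        sub[PROTON] = 10.0 ** (3.0 - sig.apoplast_ph)
        self.conc_cyt, self.conc_vac, self.conc_sub = cyt, vac, sub

        self.signal = SignalState(
            ca_total_cyt_mm=self.ca_total_cyt,
            ca_free_cyt_mm=cyt["Ca"],
            ph_cyt=state.ph_cyt, ph_vac=state.ph_vac,
            aba_cyt_mm=cyt.get("ABA", 0.0))
        self._relay = signal_modifiers(model, self.signal, state.gas.pci_ubar)
        self._ligands = {
            "cytosolic_Ca": cyt["Ca"],
            "cytosolic_pH": cyt[PROTON],
            "cytosolic_ABA": cyt.get("ABA", 0.0),
            "internal_CO2": state.gas.pci_ubar,
            "blue_light": env.get("blue_light", 0.0),
        }
        self._reg_cache: dict[str, float] = {}

    def regulation_multiplier(self, transporter) -> float:
        m = self._reg_cache.get(transporter.name)
        if m is None:
            m = 1.0
            for reg in transporter.regulation:
                m *= regulation_factor(reg, self._ligands[reg.ligand])
            if transporter.signal_class is not None:
                m *= self._relay.get(transporter.signal_class, 1.0)
            self._reg_cache[transporter.name] = m
        return m

    def concentrations(self, membrane: str):
        """(cytosol getter, trans-compartment getter) for a membrane."""
        other = self.conc_sub if membrane == "plasma_membrane" else self.conc_vac
        cyt = self.conc_cyt

        def get_cyt(s, _d=cyt):
            c = _d.get(s, 0.0)
            return c if c > CONC_FLOOR_MM else CONC_FLOOR_MM

        def get_other(s, _d=other):
            c = _d.get(s, 0.0)
            return c if c > CONC_FLOOR_MM else CONC_FLOOR_MM

        return get_cyt, get_other

    def membrane_sweep(self, membrane: str):
        """Closure v -> (per-transporter fluxes, net fluxes, outward current)."""
        transporters = [(t, self.regulation_multiplier(t))
                        for t in self.model.transporters
                        if t.membrane == membrane]
        get_cyt, get_other = self.concentrations(membrane)
        valences = self.valences

        def sweep(v_mv: float):
            per = {}
            net: dict[str, float] = {}
            for t, mult in transporters:
                fx = transporter_fluxes(t, v_mv, get_cyt, get_other,
                                        valences, mult)
                per[t.name] = fx
                for s, phi in fx.items():
                    if not math.isfinite(phi):
                        raise SolverFault(
                            f"non-finite flux from {t.name} ({s}) at "
                            f"{v_mv:.2f} mV")
                    net[s] = net.get(s, 0.0) + phi
            current = membrane_current(net, valences)
            return per, net, current

        return sweep


def kinetic_context(model: ModelSpec, state: CellState,
                    env: dict | None = None) -> KineticContext:
    return KineticContext(model, state, env)


# ---------------------------------------------------------------------------
# spec operations
# ---------------------------------------------------------------------------

def aggregate_fluxes(model: ModelSpec, state: CellState,
                     env: dict | None = None) -> FluxVector:
    """Evaluate every transporter and the metabolic source terms at the
    current voltages, concentrations and regulation state."""
    env = dict(DEFAULT_ENV) if env is None else env
    ctx = KineticContext(model, state, env)
    per: dict[str, dict[str, float]] = {}
    pm_net: dict[str, float] = {}
    tono_net: dict[str, float] = {}
    for membrane, v, net in (("plasma_membrane", state.pm.voltage_mv, pm_net),
                             ("tonoplast", state.tono.voltage_mv, tono_net)):
        sweep = ctx.membrane_sweep(membrane)
        p, n, _ = sweep(v)
        per.update(p)
        net.update(n)
    metabolic, h_load = metabolic_fluxes(
        model, env.get("red_light", 0.0),
        ctx.conc_cyt.get("Suc", 0.0), ctx.conc_cyt.get("Mal", 0.0),
        state.ph_cyt, state.cytosol.volume_pl)
    return FluxVector(per, pm_net, tono_net, metabolic, h_load)


def step_voltages(state: CellState, i_pm_pa: float, i_tono_pa: float,
                  dt_s: float) -> tuple[MembraneState, MembraneState]:
    """Advance both membrane voltages by charge conservation.

    ``C dV/dt = -I`` with outward-positive current; 1 pA for 1 s on 1 pF
    moves the voltage by 1000 mV.  Faults on a guard-rail breach.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    pm = MembraneState(
        state.pm.voltage_mv - 1000.0 * i_pm_pa * dt_s / state.pm.capacitance_pf,
        state.pm.capacitance_pf)
    tono = MembraneState(
        state.tono.voltage_mv
        - 1000.0 * i_tono_pa * dt_s / state.tono.capacitance_pf,
        state.tono.capacitance_pf)
    for m, label in ((pm, "plasma membrane"), (tono, "tonoplast")):
        if not (V_GUARD_MIN_MV <= m.voltage_mv <= V_GUARD_MAX_MV):
            raise SolverFault(f"{label} voltage {m.voltage_mv:.1f} mV outside "
                              f"[{V_GUARD_MIN_MV}, {V_GUARD_MAX_MV}] mV")
    return pm, tono


def steady_voltage(model: ModelSpec, state: CellState, membrane: str,
                   env: dict | None = None) -> float:
    """Free-running voltage: the root of I_total(V) = 0 to 0.01 mV.

    Scans the guard-rail window for a sign change and refines by Brent's
    method; faults when the total current never crosses zero (a model
    pathology such as a membrane with only one charge pathway).
    """
    ctx = KineticContext(model, state, env)
    sweep = ctx.membrane_sweep(membrane)

    def current(v):
        return sweep(v)[2]

    v_lo = None
    prev_v, prev_i = None, None
    v = V_GUARD_MIN_MV
    while v <= V_GUARD_MAX_MV + 1e-9:
        i = current(v)
        if i == 0.0:
            return v
        if prev_i is not None and (i > 0) != (prev_i > 0):
            v_lo = (prev_v, v)
            break
        prev_v, prev_i = v, i
        v += 2.0
    if v_lo is None:
        raise SolverFault(f"no zero-current crossing on {membrane} within "
                          f"[{V_GUARD_MIN_MV}, {V_GUARD_MAX_MV}] mV")
    return brentq(current, v_lo[0], v_lo[1], xtol=0.01)


def apply_fluxes(state: CellState, fluxes: FluxVector, dt_s: float,
                 model: ModelSpec) -> CellState:
    """Update compartment contents by mass conservation.

    Cytosol gains the plasma-membrane net, the tonoplast net and the
    metabolic sources; the vacuole loses the tonoplast net; the bulk
    apoplast is a reservoir and is never updated.  Proton fluxes are routed
    to the pH ledgers against the buffer capacities instead of a free pool.
    Small negative amounts are clipped at zero; a clip beyond tolerance
    faults.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    new = state.clone()
    sig = model.signalling
    cyt = new.cytosol.amounts_fmol
    vac = new.vacuole.amounts_fmol

    h_cyt = fluxes.h_load_metabolic
    h_vac = 0.0
    for s, phi in fluxes.pm_net.items():
        if s == PROTON:
            h_cyt += phi
        else:
            cyt[s] = cyt.get(s, 0.0) + phi * dt_s
    for s, phi in fluxes.tono_net.items():
        if s == PROTON:
            h_cyt += phi
            h_vac -= phi
        else:
            cyt[s] = cyt.get(s, 0.0) + phi * dt_s
            vac[s] = vac.get(s, 0.0) - phi * dt_s
    for s, phi in fluxes.metabolic.items():
        cyt[s] = cyt.get(s, 0.0) + phi * dt_s

    for comp, label in ((cyt, "cytosol"), (vac, "vacuole")):
        for s, amt in comp.items():
            if amt < 0.0:
                if -amt > CLIP_FAULT_FMOL:
                    raise SolverFault(
                        f"{label} {s} driven to {amt:.3e} fmol at "
                        f"t={state.time_s:.1f} s")
                comp[s] = 0.0

    # proton ledger: influx acidifies, divided by buffer capacity
    new.ph_cyt -= h_cyt * dt_s / (new.cytosol.volume_pl * sig.ph_buffer_beta_mm)
    new.ph_vac -= h_vac * dt_s / (new.vacuole.volume_pl
                                  * sig.ph_buffer_beta_vac_mm)
    if not (PH_CYT_GUARD[0] <= new.ph_cyt <= PH_CYT_GUARD[1]):
        raise SolverFault(f"cytosolic pH {new.ph_cyt:.2f} outside guard rails")
    if not (PH_VAC_GUARD[0] <= new.ph_vac <= PH_VAC_GUARD[1]):
        raise SolverFault(f"vacuolar pH {new.ph_vac:.2f} outside guard rails")
    return new


# ---------------------------------------------------------------------------
# the full computational cycle
# ---------------------------------------------------------------------------

def _exp_effective_voltage(sweep, v0: float, c_pf: float, dt_s: float):
    """Linearize I(V) at v0 and return the voltage at which to evaluate the
    applied (path-average) fluxes of an exponential relaxation step.

    For a locally linear current the resulting update
    ``dV = -I(v_eff)*dt/C`` reproduces exponential (A-stable) integration
    exactly, while keeping charge and mass bookkeeping consistent.
    """
    _, _, i0 = sweep(v0)
    dv_probe = 0.5
    _, _, i1 = sweep(v0 + dv_probe)
    g = (i1 - i0) / dv_probe          # pA/mV == nS
    if g <= 1e-9:
        return v0                      # non-restoring region: plain explicit
    x = 1000.0 * g * dt_s / c_pf       # dt over the RC time
    if x < 1e-6:
        return v0
    v_inf = v0 - i0 / g
    frac = (1.0 - math.exp(-x)) / x if x < 50.0 else 1.0 / x
    return v0 + (v_inf - v0) * (1.0 - frac)


def _tonoplast_root(sweep, v0: float) -> float:
    """Quasi-steady tonoplast voltage by damped Newton with Brent fallback."""
    v = v0
    for _ in range(60):
        _, _, i = sweep(v)
        if abs(i) < 1e-9:
            return v
        _, _, i2 = sweep(v + 0.25)
        g = (i2 - i) / 0.25
        if g <= 1e-12:
            break
        dv = -i / g
        if dv > 25.0:
            dv = 25.0
        elif dv < -25.0:
            dv = -25.0
        v = min(max(v + dv, V_GUARD_MIN_MV), V_GUARD_MAX_MV)
        if abs(dv) < 1e-8:
            return v
    # fallback: bracketed search
    def current(x):
        return sweep(x)[2]
    lo, hi = V_GUARD_MIN_MV, V_GUARD_MAX_MV
    prev_v, prev_i = None, None
    vv = lo
    while vv <= hi + 1e-9:
        ii = current(vv)
        if prev_i is not None and (ii > 0) != (prev_i > 0):
            return brentq(current, prev_v, vv, xtol=1e-4)
        prev_v, prev_i = vv, ii
        vv += 2.0
    raise SolverFault("no quasi-steady tonoplast voltage in guard window")


def step_cell(model: ModelSpec, state: CellState, env: dict, dt_s: float,
              tonoplast_mode: str = "quasi_steady") -> tuple[CellState, StepRecord]:
    """Advance the cell by one full cycle of duration ``dt_s``.

    Pure function: the input state is not modified.  Returns the advanced
    state and a :class:`StepRecord` with the applied fluxes and step
    metrics (used by the adaptive controller).
    """
    ctx = KineticContext(model, state, env)
    geom = model.geometry
    hyd = model.hydraulics

    # ---- membrane voltages and transport fluxes -----------------------
    pm_sweep = ctx.membrane_sweep("plasma_membrane")
    v_pm_eff = _exp_effective_voltage(pm_sweep, state.pm.voltage_mv,
                                      state.pm.capacitance_pf, dt_s)
    pm_per, pm_net, i_pm = pm_sweep(v_pm_eff)
    dv_pm = -1000.0 * i_pm * dt_s / state.pm.capacitance_pf

    if tonoplast_mode == "quasi_steady":
        v_tono_new = _tonoplast_root(ctx.membrane_sweep("tonoplast"),
                                     state.tono.voltage_mv)
        tono_per, tono_net, i_tono = ctx.membrane_sweep("tonoplast")(v_tono_new)
        dv_tono = v_tono_new - state.tono.voltage_mv
    elif tonoplast_mode == "capacitive":
        tono_sweep = ctx.membrane_sweep("tonoplast")
        v_tono_eff = _exp_effective_voltage(tono_sweep,
                                            state.tono.voltage_mv,
                                            state.tono.capacitance_pf, dt_s)
        tono_per, tono_net, i_tono = tono_sweep(v_tono_eff)
        dv_tono = -1000.0 * i_tono * dt_s / state.tono.capacitance_pf
        v_tono_new = state.tono.voltage_mv + dv_tono
    else:
        raise ValueError(f"unknown tonoplast mode {tonoplast_mode!r}")

    v_pm_new = state.pm.voltage_mv + dv_pm
    for v, label in ((v_pm_new, "plasma membrane"), (v_tono_new, "tonoplast")):
        if not (V_GUARD_MIN_MV <= v <= V_GUARD_MAX_MV):
            raise SolverFault(
                f"{label} voltage {v:.1f} mV outside guard rails at "
                f"t={state.time_s:.1f} s")

    metabolic, h_load = metabolic_fluxes(
        model, env.get("red_light", 0.0),
        ctx.conc_cyt.get("Suc", 0.0), ctx.conc_cyt.get("Mal", 0.0),
        state.ph_cyt, state.cytosol.volume_pl)
    fluxes = FluxVector(dict(pm_per, **tono_per), pm_net, tono_net,
                        metabolic, h_load)

    # ---- compartment contents and buffering ---------------------------
    new = apply_fluxes(state, fluxes, dt_s, model)
    new.pm.voltage_mv = v_pm_new
    new.tono.voltage_mv = v_tono_new

    # ---- water, volume, turgor, aperture ------------------------------
    rwf = env.get("rwf") or hyd.rwf_default
    psi_wall = wall_water_potential(state.gas.e_mmol_m2_s, hyd, rwf)
    v_tot = new.mech.volume_total_pl
    turgor = turgor_from_volume(v_tot, geom)
    osm = {s.name: (new.cytosol.amounts_fmol.get(s.name, 0.0)
                    + new.vacuole.amounts_fmol.get(s.name, 0.0)) / v_tot
           for s in model.solutes}
    coeffs = {s.name: s.osmotic_coefficient for s in model.solutes}
    pi_cell = osmotic_potential(osm, coeffs)
    phi_w = water_flux(psi_wall, turgor, pi_cell, hyd)
    v_tot_new = v_tot + phi_w * dt_s
    if v_tot_new <= 0:
        raise SolverFault("guard cell volume collapsed")
    new.mech.volume_total_pl = v_tot_new
    new.mech.psi_wall_mpa = psi_wall
    new.cytosol.volume_pl = geom.cytosol_fraction * v_tot_new
    new.vacuole.volume_pl = geom.vacuole_fraction * v_tot_new
    turgor_new = turgor_from_volume(v_tot_new, geom)
    new.mech.aperture_um = aperture_from_turgor(
        state.mech.aperture_um, turgor_new, state.mech.epidermal_turgor_mpa,
        geom, hyd, dt_s)

    # ---- gas exchange --------------------------------------------------
    light = env.get("blue_light", 0.0) + env.get("red_light", 0.0)
    gs = stomatal_conductance(new.mech.aperture_um, geom)
    wp, rh_i = wall_vapor_pressure(psi_wall)
    w_air = env.get("rh", 70.0) / 100.0 * saturation_vapour_pressure_mbar()
    e = transpiration(gs, wp, w_air)
    g_co2 = max(gs / GS_GCO2_RATIO, G_CO2_FLOOR_MOL)
    pci = solve_internal_co2(g_co2, env.get("pco2", 400.0), light,
                             model.assimilation)
    a = assimilation_rate(pci, light, model.assimilation)
    new.gas = GasState(gs, e, a, pci, wp, rh_i, water_use_efficiency(a, e))

    # ---- epidermal / subdomain (CRR) exchange -------------------------
    bulk = dict(model.compartments["apoplast"])
    if "ABA" in ctx.valences and "ABA" not in bulk:
        bulk["ABA"] = 0.0
    if "ABA" in bulk:
        bulk["ABA"] = env.get("aba", 0.0) * 1e-3   # uM -> mM
    new.subdomain_mm = subdomain_step(state.subdomain_mm, bulk, pm_net,
                                      hyd, dt_s)
    new.mech.epidermal_turgor_mpa = epidermal_turgor_step(
        state.mech.epidermal_turgor_mpa, state.subdomain_mm, bulk, hyd, dt_s)

    new.time_s = state.time_s + dt_s

    # ---- controller metrics -------------------------------------------
    frac = 0.0
    for comp_old, comp_new in ((state.cytosol, new.cytosol),
                               (state.vacuole, new.vacuole)):
        floor = 1.0e-3 * comp_old.volume_pl     # 1 uM-equivalent pool floor
        for s, amt_old in comp_old.amounts_fmol.items():
            d = abs(comp_new.amounts_fmol.get(s, 0.0) - amt_old)
            ref = max(amt_old, floor)
            if d / ref > frac:
                frac = d / ref
    metrics = {
        "dv_pm": abs(dv_pm),
        "dv_tono": abs(dv_tono),
        "frac_amount": frac,
        "dph": max(abs(new.ph_cyt - state.ph_cyt),
                   abs(new.ph_vac - state.ph_vac)),
        "frac_volume": abs(v_tot_new - v_tot) / v_tot,
    }
    rec = StepRecord(dt_s, fluxes, i_pm, i_tono, dv_pm, dv_tono, phi_w,
                     metrics)
    return new, rec


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------

def initial_state(model: ModelSpec, env: dict | None = None) -> CellState:
    """Build the starting state from the model's initial compositions.

    The cell volume is placed at water equilibrium with a fully wet wall
    (psi_wall = 0) at the stated concentrations; membrane voltages start at
    their free-running zero-current roots.
    """
    env = dict(DEFAULT_ENV) if env is None else env
    geom = model.geometry
    sig = model.signalling
    comp = model.compartments
    coeffs = {s.name: s.osmotic_coefficient for s in model.solutes}

    osm_conc = 0.0
    for s in model.solutes:
        if s.name == PROTON:
            continue
        c = (geom.cytosol_fraction * comp["cytosol"].get(s.name, 0.0)
             + geom.vacuole_fraction * comp["vacuole"].get(s.name, 0.0))
        osm_conc += coeffs[s.name] * c
    # solve eps*(V-V0)/V0 = pi with pi fixed by the stated concentrations
    pi = osm_conc * 2.4789e-3
    v_tot = geom.relaxed_volume_pl * (1.0 + pi / geom.elastic_modulus_mpa)
    v_cyt = geom.cytosol_fraction * v_tot
    v_vac = geom.vacuole_fraction * v_tot

    cyt = {name: c * v_cyt for name, c in comp["cytosol"].items()
           if name != PROTON}
    vac = {name: c * v_vac for name, c in comp["vacuole"].items()
           if name != PROTON}
    sub = {name: c for name, c in comp["apoplast"].items() if name != PROTON}

    turgor = turgor_from_volume(v_tot, geom)
    mech = MechanicalState(
        volume_total_pl=v_tot,
        aperture_um=aperture_target(turgor,
                                    model.hydraulics.epidermal_base_turgor_mpa,
                                    geom, model.hydraulics.epidermal_antagonism_m),
        epidermal_turgor_mpa=model.hydraulics.epidermal_base_turgor_mpa,
        psi_wall_mpa=0.0)

    state = CellState(
        pm=MembraneState(-130.0, model.capacitance_pm_pf),
        tono=MembraneState(-10.0, model.capacitance_tono_pf),
        cytosol=CompartmentState(v_cyt, cyt),
        vacuole=CompartmentState(v_vac, vac),
        subdomain_mm=sub,
        ph_cyt=sig.ph_cyt_init, ph_vac=sig.ph_vac_init,
        mech=mech, gas=GasState(), time_s=0.0)

    # start from the free-running voltages so spin-up transients are mild
    for membrane, attr in (("plasma_membrane", "pm"), ("tonoplast", "tono")):
        try:
            getattr(state, attr).voltage_mv = steady_voltage(
                model, state, membrane, env)
        except SolverFault:
            pass

    gs = stomatal_conductance(state.mech.aperture_um, geom)
    wp, rh_i = wall_vapor_pressure(0.0)
    w_air = env.get("rh", 70.0) / 100.0 * saturation_vapour_pressure_mbar()
    e = transpiration(gs, wp, w_air)
    light = env.get("blue_light", 0.0) + env.get("red_light", 0.0)
    g_co2 = max(gs / GS_GCO2_RATIO, G_CO2_FLOOR_MOL)
    pci = solve_internal_co2(g_co2, env.get("pco2", 400.0), light,
                             model.assimilation)
    a = assimilation_rate(pci, light, model.assimilation)
    state.gas = GasState(gs, e, a, pci, wp, rh_i, water_use_efficiency(a, e))
    return state
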