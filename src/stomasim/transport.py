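"""Single-population transporter kinetics.

Channels follow constant-field (Goldman-Hodgkin-Katz) unitary flux scaled by
Boltzmann steady-state gating and bounded ligand modifiers.  Pumps and
coupled carriers use a single-loop reversible cycle whose net rate is an
odd, bounded function of the total free energy of the cycle, so every
transporter stalls exactly at its thermodynamic reversal and always runs
downhill (rate sign = -sign(dG)).

Sign conventions (fixed, used everywhere):

* membrane voltage V = psi(cytosol) - psi(apoplast) for the plasma membrane
  and psi(cytosol) - psi(vacuole lumen) for the tonoplast;
* fluxes are positive INTO the cytosol;
* current is electrophysiological outward-positive:
  I [pA] = -96.485 * sum(z * flux_into_cytosol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import FARADAY_PA, F_KJ_PER_MV, RT_F_MV, RT_KJ, TEMPERATURE_K
from .model_io import (ModelSpec, RegulationSpec, TransporterSpec, PROTON)

__all__ = [
    "nernst_potential", "ghk_flux", "gating_open_probability",
    "regulation_factor", "pump_flux", "carrier_flux", "transporter_fluxes",
    "coupled_delta_g", "membrane_current", "membrane_iv", "IVCurve",
]

#: below this |zFV/RT| the GHK expression switches to its 2nd-order series
_GHK_SERIES_U = 1.0e-4

#: symmetry factor of the charge-translocating transition in the pump cycle
_PUMP_DELTA = 0.5

#: effective number of serial transitions sharing the driving force in the
#: pump cycle; spreads the exponential voltage dependence so the cycle rate
#: keeps a physiological slope (rather than saturating) over the working
#: range of membrane voltages
_PUMP_U_SCALE = 4.0


def nernst_potential(z: int, c_out: float, c_in: float,
                     temperature_k: float = TEMPERATURE_K) -> float:
    """Equilibrium (Nernst) potential in mV, inside-positive convention."""
    if z == 0:
        raise ValueError("Nernst potential undefined for uncharged solute")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    rtf = RT_F_MV * temperature_k / TEMPERATURE_K
    return rtf / z * math.log(c_out / c_in)


def ghk_flux(permeability: float, z: int, v_mv: float,
             c_in: float, c_out: float,
             temperature_k: float = TEMPERATURE_K) -> float:
    """Constant-field unitary flux, positive into the reference compartment.

    ``permeability`` is the unitary permeability in pL s^-1, concentrations
    in mM, so the flux is in fmol s^-1.  The expression is continuous at
    V = 0 (series limit) and vanishes exactly at the Nernst potential.
    """
    if c_in < 0 or c_out < 0:
        raise ValueError("concentrations must be non-negative")
    rtf = RT_F_MV * temperature_k / TEMPERATURE_K
    u = z * v_mv / rtf
    if abs(u) < _GHK_SERIES_U:
        # efflux ~ P*[(ci-co) + u(ci+co)/2 + u^2 (ci-co)/12]
        efflux = permeability * ((c_in - c_out)
                                 + u * (c_in + c_out) / 2.0
                                 + u * u * (c_in - c_out) / 12.0)
    else:
        if u > 500.0:
            u = 500.0
        elif u < -500.0:
            u = -500.0
        emu = math.exp(-u)
        efflux = permeability * u * (c_in - c_out * emu) / (1.0 - emu)
    return -efflux


def gating_open_probability(v_mv: float, v_half_mv: float,
                            gating_charge: float,
                            modifiers: tuple[float, ...] = ()) -> float:
    """Boltzmann steady-state open probability times bounded modifiers.

    ``1/(1 + exp(-g (V - V_half)/(RT/F)))`` clipped to [0, 1] after
    multiplying by the (positive) modifiers.  A negative gating charge gives
    hyperpolarization-activated (inward-rectifier-like) gating.
    """
    x = -gating_charge * (v_mv - v_half_mv) / RT_F_MV
    if x > 500.0:
        x = 500.0
    p = 1.0 / (1.0 + math.exp(x))
    for m in modifiers:
        if m <= 0:
            raise ValueError("gating modifiers must be positive")
        p *= m
    return min(max(p, 0.0), 1.0)


def regulation_factor(spec: RegulationSpec, ligand_value: float) -> float:
    """Bounded Hill multiplier for one ligand.

    The ligand enters as its excess over ``spec.baseline`` so the factor is
    exactly 1 at (or below) the resting level.  Inhibition descends from 1
    to ``floor``; activation is the reciprocal form rising from 1 to
    ``1/floor``.
    """
    if ligand_value < 0:
        raise ValueError("ligand value must be >= 0")
    x = ligand_value - spec.baseline
    if x <= 0.0:
        return 1.0
    h = (x / spec.k_half) ** spec.hill_n
    inhibited = spec.floor + (1.0 - spec.floor) / (1.0 + h)
    if spec.mode == "inhibit":
        return inhibited
    return 1.0 / inhibited


def coupled_delta_g(spec: TransporterSpec, v_mv: float,
                    conc_cyt, conc_other, valences: dict[str, int],
                    include_energized: bool = True) -> float:
    """Total free energy of one forward cycle, kJ mol^-1.

    Sums the electrochemical potential change of every transported solute in
    the transporter's stated direction (positive direction = into the
    cytosol) plus, for pumps, the energized substrate term (e.g. ATP).
    ``conc_cyt``/``conc_other`` are callables solute -> mM.
    """
    dg = 0.0
    if include_energized and spec.energized_delta_g_kj is not None:
        dg += spec.energized_delta_g_kj
    for leg in spec.transported:
        ci = conc_cyt(leg.solute)
        co = conc_other(leg.solute)
        if ci <= 0 or co <= 0:
            raise ValueError(
                f"{spec.name}: non-positive concentration of transported "
                f"solute {leg.solute}")
        z = valences[leg.solute]
        dmu_in = RT_KJ * math.log(ci / co) + z * F_KJ_PER_MV * v_mv
        dg += leg.stoich * leg.direction * dmu_in
    return dg


def _saturation(spec: TransporterSpec, conc_cyt, conc_other) -> float:
    """Michaelis saturation product over transported solutes.

    ``k_m`` saturates on the side each solute moves *from* in the
    transporter's forward direction (direction +1 -> trans compartment,
    -1 -> cytosol); ``k_i`` is non-competitive product inhibition by the
    accumulating concentration on the side the solute moves *to*.
    """
    sat = 1.0
    for leg in spec.transported:
        km = spec.k_m.get(leg.solute)
        if km is not None:
            c = (conc_other(leg.solute) if leg.direction > 0
                 else conc_cyt(leg.solute))
            sat *= c / (km + c)
        ki = spec.k_i.get(leg.solute)
        if ki is not None:
            c = (conc_cyt(leg.solute) if leg.direction > 0
                 else conc_other(leg.solute))
            sat *= ki / (ki + c)
    return sat


def _cycle_rate_pump(u: float) -> float:
    """Bounded reversible two-state cycle rate as a fraction of turnover_max.

    ``u = -dG_total/RT`` is the dimensionless driving force; the rate is
    ``(exp(d*u') - exp(-(1-d)*u')) / (1 + exp(d*u') + exp(-(1-d)*u'))`` with
    symmetry factor d = 0.5 and ``u' = u/n`` for n serial transitions:
    zero exactly at u = 0, odd-signed, saturating to +-1 for strong
    driving.
    """
    u = u / _PUMP_U_SCALE
    a = _PUMP_DELTA * u
    b = (1.0 - _PUMP_DELTA) * u
    if a > 60.0:
        a = 60.0
    if b > 60.0:
        b = 60.0
    ea = math.exp(a)
    eb = math.exp(-b)
    return (ea - eb) / (1.0 + ea + eb)


def pump_flux(spec: TransporterSpec, v_mv: float, conc_cyt, conc_other,
              valences: dict[str, int],
              regulation_multiplier: float = 1.0) -> dict[str, float]:
    """Per-solute flux of a primary pump population, fmol s^-1 into cytosol.

    The reversible cycle stalls exactly where the total dG (including the
    energized substrate) is zero and runs with sign -sign(dG) otherwise.
    """
    if spec.kind != "pump":
        raise ValueError(f"{spec.name} is not a pump")
    dg = coupled_delta_g(spec, v_mv, conc_cyt, conc_other, valences)
    rate = (spec.population * spec.turnover_max * regulation_multiplier
            * _saturation(spec, conc_cyt, conc_other)
            * _cycle_rate_pump(-dg / RT_KJ))
    return {leg.solute: rate * leg.stoich * leg.direction
            for leg in spec.transported}


def carrier_flux(spec: TransporterSpec, v_mv: float, conc_cyt, conc_other,
                 valences: dict[str, int],
                 regulation_multiplier: float = 1.0) -> dict[str, float]:
    """Per-solute flux of a coupled carrier population, fmol s^-1 into cytosol.

    Flux = population * turnover_max * saturation * tanh(-dG/(2RT)): an odd,
    bounded driving function that vanishes at dG = 0, with exact
    stoichiometric coupling between the transported solutes.
    """
    if spec.kind != "carrier":
        raise ValueError(f"{spec.name} is not a carrier")
    dg = coupled_delta_g(spec, v_mv, conc_cyt, conc_other, valences)
    rate = (spec.population * spec.turnover_max * regulation_multiplier
            * _saturation(spec, conc_cyt, conc_other)
            * math.tanh(-dg / (2.0 * RT_KJ)))
    return {leg.solute: rate * leg.stoich * leg.direction
            for leg in spec.transported}


def channel_flux(spec: TransporterSpec, v_mv: float, conc_cyt, conc_other,
                 valences: dict[str, int],
                 regulation_multiplier: float = 1.0) -> dict[str, float]:
    """Per-solute flux of a channel population, fmol s^-1 into cytosol."""
    leg = spec.transported[0]
    z = valences[leg.solute]
    p_open = regulation_multiplier
    if spec.gating is not None:
        g = spec.gating
        boltz = gating_open_probability(v_mv, g.v_half_mv, g.gating_charge)
        p_open = (g.p_min + (1.0 - g.p_min) * boltz) * regulation_multiplier
    p_open = min(max(p_open, 0.0), 1.0)
    phi = (spec.population * p_open
           * ghk_flux(spec.permeability_pl_s, z, v_mv,
                      conc_cyt(leg.solute), conc_other(leg.solute)))
    return {leg.solute: phi}


def transporter_fluxes(spec: TransporterSpec, v_mv: float, conc_cyt,
                       conc_other, valences: dict[str, int],
                       regulation_multiplier: float = 1.0) -> dict[str, float]:
    """Dispatch on transporter kind; flux positive into the cytosol."""
    if spec.population == 0.0:
        return {leg.solute: 0.0 for leg in spec.transported}
    if spec.kind == "channel":
        return channel_flux(spec, v_mv, conc_cyt, conc_other, valences,
                            regulation_multiplier)
    if spec.kind == "pump":
        return pump_flux(spec, v_mv, conc_cyt, conc_other, valences,
                         regulation_multiplier)
    return carrier_flux(spec, v_mv, conc_cyt, conc_other, valences,
                        regulation_multiplier)


def membrane_current(fluxes: dict[str, float],
                     valences: dict[str, int]) -> float:
    """Outward-positive membrane current in pA from per-solute fluxes."""
    return -FARADAY_PA * sum(valences[s] * phi for s, phi in fluxes.items())


@dataclass
class IVCurve:
    """Current-voltage relation per transporter population plus the total."""
    voltages: list[float]
    currents: dict[str, list[float]]   # name -> pA; key "total" included

    def __post_init__(self):
        for v0, v1 in zip(self.voltages, self.voltages[1:]):
            if v1 <= v0:
                raise ValueError("voltages must be strictly increasing")


def membrane_iv(model: ModelSpec, state, membrane: str,
                v_grid, env: dict | None = None) -> IVCurve:
    """Instantaneous I-V curves holding concentrations and regulation fixed.

    Currents are computed per transporter from its per-solute fluxes via
    I = -96.485 * sum(z * flux); the "total" row crosses zero at the
    free-running membrane voltage.
    """
    from .solver import kinetic_context  # late import avoids a cycle
    ctx = kinetic_context(model, state, env)
    conc_cyt, conc_other = ctx.concentrations(membrane)
    valences = ctx.valences
    v_list = [float(v) for v in v_grid]
    transporters = [t for t in model.transporters if t.membrane == membrane]
    currents: dict[str, list[float]] = {t.name: [] for t in transporters}
    currents["total"] = []
    for v in v_list:
        total = 0.0
        for t in transporters:
            fx = transporter_fluxes(t, v, conc_cyt, conc_other, valences,
                                    ctx.regulation_multiplier(t))
            i = membrane_current(fx, valences)
            currents[t.name].append(i)
            total += i
        currents["total"].append(total)
    return IVCurve(v_list, currents)
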