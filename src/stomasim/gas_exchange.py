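"""Leaf gas exchange: stomatal conductance from pore geometry, vapour
equilibration with the wall water potential, transpiration, the internal-CO2
balance against mesophyll assimilation, and water-use efficiency.

The boundary layer is taken as infinitely conductive (well-stirred cuvette
convention); the mesophyll A-Ci response is a rectangular hyperbola with a
compensation point, the minimal monotone-saturating form, and can be swapped
for a Farquhar-type callable without touching the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import (AIR_MOLAR_DENSITY, D_H2O_M2_S, GS_GCO2_RATIO,
                        P_ATM_MBAR, R_J, TEMPERATURE_K, V_W_M3_PER_MOL,
                        saturation_vapour_pressure_mbar)
from .model_io import AssimilationSpec, GeometrySpec


@dataclass
class GasState:
    """Leaf-scale gas exchange variables at one instant."""
    gs_mol_m2_s: float = 0.0      # stomatal conductance to water vapour
    e_mmol_m2_s: float = 0.0      # transpiration
    a_umol_m2_s: float = 0.0      # net assimilation
    pci_ubar: float = 400.0       # intercellular CO2 partial pressure
    wp_mbar: float = 31.67        # substomatal water vapour partial pressure
    rh_i_pct: float = 100.0
    wue_umol_mmol: float = float("nan")


def stomatal_conductance(aperture_um: float,
                         geometry: GeometrySpec) -> float:
    """Leaf conductance to water vapour, mol m^-2 s^-1.

    Single-pore diffusion through an elliptical pore (aperture = minor axis,
    pore length = major axis) of finite depth with an end correction of
    pi*r_eq/2 (both ends), multiplied by stomatal density and converted to
    molar units; monotone and concave in aperture, linear in density.
    ``g_CO2 = g_s / 1.6``.
    """
    if aperture_um < 0:
        raise ValueError("aperture must be >= 0")
    g = geometry.residual_conductance_mol
    if aperture_um > 0:
        area_m2 = math.pi * (aperture_um / 2.0) * (geometry.pore_length_um
                                                   / 2.0) * 1e-12
        r_eq = math.sqrt(area_m2 / math.pi)
        depth_eff = geometry.pore_depth_um * 1e-6 + math.pi * r_eq / 2.0
        g_pore = D_H2O_M2_S * area_m2 / depth_eff          # m^3 s^-1
        density_m2 = geometry.stomatal_density_mm2 * 1e6   # pores per m^2
        g += g_pore * density_m2 * AIR_MOLAR_DENSITY       # mol m^-2 s^-1
    return g


def wall_vapor_pressure(psi_wall_mpa: float,
                        temperature_k: float = TEMPERATURE_K
                        ) -> tuple[float, float]:
    """Substomatal vapour pressure (mbar) and RH_i (%) by the Kelvin relation.

    ``w_p = w_sat(T) * exp(psi * V_w / (R T))``; a (non-physical) positive
    wall potential is capped at saturation.
    """
    w_sat = saturation_vapour_pressure_mbar(temperature_k)
    psi_pa = min(psi_wall_mpa, 0.0) * 1e6
    w_p = w_sat * math.exp(psi_pa * V_W_M3_PER_MOL / (R_J * temperature_k))
    return w_p, 100.0 * w_p / w_sat


def transpiration(gs_mol_m2_s: float, wp_mbar: float, w_air_mbar: float,
                  p_atm_mbar: float = P_ATM_MBAR) -> float:
    """Transpiration E = g_s * (w_p - w_air) / P_atm, in mmol m^-2 s^-1."""
    return 1000.0 * gs_mol_m2_s * (wp_mbar - w_air_mbar) / p_atm_mbar


def light_factor(light_umol: float, spec: AssimilationSpec) -> float:
    """Saturating light response, 0 in darkness, ->1 at saturating light."""
    if light_umol <= 0:
        return 0.0
    return light_umol / (spec.light_half_sat_umol + light_umol)


def assimilation_rate(pci_ubar: float, light_umol: float,
                      spec: AssimilationSpec) -> float:
    """Net mesophyll assimilation A, umol m^-2 s^-1.

    ``A = A_max * f_L * (Ci - Gamma)/(K_m + Ci) - R_d * (1 - k * f_L)``:
    hyperbolic in Ci above the compensation point Gamma, saturating in
    light, with dark respiration partially suppressed in the light
    (fraction ``k``).  In darkness A = -R_d.
    """
    if pci_ubar < 0:
        raise ValueError("pCi must be >= 0")
    f = light_factor(light_umol, spec)
    gross = spec.a_max_umol * f * (pci_ubar - spec.gamma_ubar) / (
        spec.k_m_ubar + pci_ubar)
    resp = spec.r_d_umol * (1.0 - spec.light_resp_suppression * f)
    return gross - resp


def solve_internal_co2(g_co2_mol: float, pco2_atm_ubar: float,
                       light_umol: float, spec: AssimilationSpec) -> float:
    """Intercellular CO2 from the diffusion/fixation balance, ubar.

    Solves ``g_CO2 * (pCO2_atm - Ci) = A(Ci)`` for the unique root; with the
    hyperbolic A this is a quadratic (the positive root), verified and, if
    needed, refined by a bracketed root-find.  Conversion: at 1013 mbar a
    conductance of 1 mol m^-2 s^-1 moves 1 umol m^-2 s^-1 per ubar of CO2
    partial-pressure difference.
    """
    ca = pco2_atm_ubar
    f = light_factor(light_umol, spec)
    vg = spec.a_max_umol * f
    rd = spec.r_d_umol * (1.0 - spec.light_resp_suppression * f)
    km = spec.k_m_ubar
    gamma = spec.gamma_ubar
    if g_co2_mol <= 0:
        # closed pore: Ci settles where net A = 0, if photosynthesis can
        # balance respiration; in darkness there is no finite balance
        if vg <= rd:
            raise ValueError("no internal CO2 balance with a closed pore in "
                             "darkness")
        return (rd * km + vg * gamma) / (vg - rd)
    a = g_co2_mol
    b = vg - rd + g_co2_mol * (km - ca)
    c = -(g_co2_mol * ca * km + vg * gamma + rd * km)
    disc = b * b - 4.0 * a * c
    ci = (-b + math.sqrt(disc)) / (2.0 * a)
    resid = g_co2_mol * (ca - ci) - assimilation_rate(ci, light_umol, spec)
    tol = max(1e-6 * max(spec.a_max_umol, spec.r_d_umol, 1e-12), 1e-12)
    if not math.isfinite(ci) or abs(resid) > tol:
        hi = ca + (vg + rd) / g_co2_mol + 10.0
        ci = brentq(
            lambda x: g_co2_mol * (ca - x) - assimilation_rate(x, light_umol,
                                                               spec),
            1e-9, hi, xtol=1e-9)
    return ci


def water_use_efficiency(a_umol_m2_s: float, e_mmol_m2_s: float) -> float:
    """WUE = A/E in umol CO2 per mmol H2O; NaN marks the undefined E <= 0 case."""
    if e_mmol_m2_s <= 0:
        return float("nan")
    return a_umol_m2_s / e_mmol_m2_s
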