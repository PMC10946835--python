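"""Osmotics, water flux, turgor, aperture mechanics and apoplast-subdomain
(CRR) exchange.

The constraint-relaxation (CRR) machinery is implemented as two first-order
relaxations: the apoplastic subdomain composition relaxes toward the bulk
reservoir while guard-cell transport draws on the subdomain, and the
aperture relaxes viscoelastically toward its turgor-determined target.
Epidermal back-pressure opposes guard-cell turgor through the antagonism
ratio ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from .constants import VANT_HOFF_MPA_PER_MM, TEMPERATURE_K
from .model_io import GeometrySpec, HydraulicsSpec


@dataclass
class MechanicalState:
    """Mechanical variables of the guard cell at one instant."""
    volume_total_pl: float
    aperture_um: float
    epidermal_turgor_mpa: float
    psi_wall_mpa: float = 0.0


def osmotic_potential(concentrations_mm, osmotic_coefficients=None,
                      temperature_k: float = TEMPERATURE_K) -> float:
    """Van't Hoff osmotic potential, MPa: ``pi = RT * sum(phi_i * c_i)``.

    2.4789e-3 MPa per mM at 298.15 K.  ``concentrations_mm`` maps solute
    name to mM; missing osmotic coefficients default to 1.
    """
    factor = VANT_HOFF_MPA_PER_MM * temperature_k / TEMPERATURE_K
    total = 0.0
    for name, c in concentrations_mm.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
        phi = 1.0
        if osmotic_coefficients is not None:
            phi = osmotic_coefficients.get(name, 1.0)
        total += phi * c
    return factor * total


def turgor_from_volume(volume_pl: float, geometry: GeometrySpec) -> float:
    """Turgor from the linear-elastic wall: ``P = eps*(V - V0)/V0`` for
    V >= V0, zero below the relaxed volume."""
    if volume_pl <= 0:
        raise ValueError("volume must be > 0")
    v0 = geometry.relaxed_volume_pl
    if volume_pl <= v0:
        return 0.0
    return geometry.elastic_modulus_mpa * (volume_pl - v0) / v0


def equilibrium_volume(osmotic_amount_fmol: float,
                       geometry: GeometrySpec,
                       psi_wall_mpa: float = 0.0) -> float:
    """Volume at water equilibrium, where P(V) - pi(V) = psi_wall.

    With the linear wall and van't Hoff osmotics this is the positive root of
    ``eps*(V - V0)/V0 - RT*n/V = psi_wall``.
    """
    eps = geometry.elastic_modulus_mpa
    v0 = geometry.relaxed_volume_pl
    n = osmotic_amount_fmol * VANT_HOFF_MPA_PER_MM
    # eps/v0 * V^2 - (eps + psi) * V - n = 0
    a = eps / v0
    b = -(eps + psi_wall_mpa)
    c = -n
    disc = b * b - 4.0 * a * c
    v = (-b + math.sqrt(disc)) / (2.0 * a)
    return max(v, v0 * 1e-3)


def aperture_target(p_guard_mpa: float, p_epidermal_mpa: float,
                    geometry: GeometrySpec,
                    antagonism_m: float) -> float:
    """Target aperture from the turgor balance, um.

    ``a = a_max * x / (x + K)`` with ``x = P_guard - m * P_epidermal``
    clipped at zero: a saturating, monotone map that closes the pore when
    epidermal back-pressure wins.
    """
    if p_guard_mpa < 0 or p_epidermal_mpa < 0:
        raise ValueError("pressures must be >= 0")
    x = p_guard_mpa - antagonism_m * p_epidermal_mpa
    if x <= 0.0:
        return 0.0
    return geometry.aperture_max_um * x / (x + geometry.aperture_k_mpa)


def aperture_from_turgor(aperture_um: float, p_guard_mpa: float,
                         p_epidermal_mpa: float, geometry: GeometrySpec,
                         hydraulics: HydraulicsSpec, dt_s: float) -> float:
    """Viscoelastic first-order relaxation of aperture toward its target.

    The wall's constraint-relaxation lag is exponential with rate
    ``crr_aperture_rate_s``; the result is always within [0, a_max].
    """
    target = aperture_target(p_guard_mpa, p_epidermal_mpa, geometry,
                             hydraulics.epidermal_antagonism_m)
    decay = math.exp(-hydraulics.crr_aperture_rate_s * dt_s)
    a = target + (aperture_um - target) * decay
    return min(max(a, 0.0), geometry.aperture_max_um)


def wall_water_potential(e_mmol_m2_s: float,
                         hydraulics: HydraulicsSpec,
                         rwf: float | None = None) -> float:
    """Guard-cell wall water potential, MPa.

    ``psi_wall = psi_source - r * E / RWF``: the transpiration stream draws
    the wall down from the source in proportion to E, relieved by a large
    relative water feed (well-watered leaf) and aggravated by a small one.
    """
    if rwf is None:
        rwf = hydraulics.rwf_default
    if rwf <= 0:
        raise ValueError("RWF must be > 0")
    e = max(e_mmol_m2_s, 0.0)
    return hydraulics.psi_source_mpa - hydraulics.supply_resistance_mpa * e / rwf


def water_flux(psi_wall_mpa: float, turgor_mpa: float, pi_cell_mpa: float,
               hydraulics: HydraulicsSpec) -> float:
    """Transmembrane water flux into the guard cell, pL s^-1.

    ``phi_w = L * (psi_wall - (P - pi))``; zero at water equilibrium.
    """
    return hydraulics.hydraulic_conductance_pl_s_mpa * (
        psi_wall_mpa - (turgor_mpa - pi_cell_mpa))


def subdomain_step(conc_sub_mm: dict[str, float],
                   conc_bulk_mm: dict[str, float],
                   pm_net_flux_fmol_s: dict[str, float],
                   hydraulics: HydraulicsSpec, dt_s: float) -> dict[str, float]:
    """Advance the apoplastic subdomain composition by one step.

    First-order relaxation toward the bulk reservoir at the CRR exchange
    rate, with the guard cell's plasma-membrane fluxes drawn from (or
    released into) the subdomain pool.  At infinite rate the subdomain
    equals the reservoir; at zero rate it is a closed pool exchanging only
    with the guard cell.
    """
    k = hydraulics.crr_subdomain_rate_s
    v = hydraulics.subdomain_volume_pl
    out = {}
    for name, c_sub in conc_sub_mm.items():
        c_bulk = conc_bulk_mm.get(name, 0.0)
        uptake = pm_net_flux_fmol_s.get(name, 0.0)  # into cytosol
        c = c_sub + (k * (c_bulk - c_sub) - uptake / v) * dt_s
        out[name] = max(c, 0.0)
    return out


def epidermal_turgor_step(p_epi_mpa: float,
                          conc_sub_mm: dict[str, float],
                          conc_bulk_mm: dict[str, float],
                          hydraulics: HydraulicsSpec, dt_s: float) -> float:
    """Relax epidermal turgor toward its osmotic-exchange target.

    Solute the guard cell releases into the shared subdomain is partly taken
    up by the adjacent epidermal cell, raising its turgor above baseline by
    ``gain * (pi_subdomain - pi_bulk)`` — the antagonistic back-pressure.
    """
    pi_sub = osmotic_potential(conc_sub_mm)
    pi_bulk = osmotic_potential(conc_bulk_mm)
    target = (hydraulics.epidermal_base_turgor_mpa
              + hydraulics.epidermal_osmotic_gain * (pi_sub - pi_bulk))
    target = max(target, 0.0)
    decay = math.exp(-hydraulics.crr_epidermal_rate_s * dt_s)
    return target + (p_epi_mpa - target) * decay
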