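"""Guard-cell metabolism, Ca2+/pH buffering, and the hard-wired signal relays.

Sucrose and malate synthesis are light-saturating rates per guard cell
(fmol s^-1); breakdown is first order in the cytosolic pool.  Malate is
handled as the divalent anion with fixed speciation: making one Mal2- in the
cytosol releases two proton-equivalents onto the pH ledger, and breaking one
down consumes two.

Cytosolic free Ca2+ and pH are rapid-buffer approximations: free Ca is a
fixed fraction of the total pool (1/(1+kappa)), and pH moves as the running
net proton load divided by the buffer capacity beta.  Explicit kinase or
phosphatase states, and ROS/NO intermediates of ABA action, are subsumed in
the bounded Hill relays of :func:`signal_modifiers`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_io import MetabolismSpec, ModelSpec, SignallingSpec
from .transport import regulation_factor


@dataclass
class SignalState:
    """Instantaneous signalling variables of the guard cell."""
    ca_total_cyt_mm: float
    ca_free_cyt_mm: float
    ph_cyt: float
    ph_vac: float
    aba_cyt_mm: float


def synthesis_rates(light_red_umol: float,
                    spec: MetabolismSpec) -> tuple[float, float]:
    """Sucrose and malate synthesis, fmol s^-1 per guard cell.

    Michaelis-form light saturation above the dark baseline fraction:
    ``rate = base + (max - base) * L / (K + L)`` with ``base = f_dark * max``.
    """
    if light_red_umol < 0:
        raise ValueError("light must be >= 0")
    f = light_red_umol / (spec.light_half_sat_umol + light_red_umol)
    suc = spec.suc_rate_max_fmol_s * (spec.dark_fraction
                                      + (1.0 - spec.dark_fraction) * f)
    mal = spec.mal_rate_max_fmol_s * (spec.dark_fraction
                                      + (1.0 - spec.dark_fraction) * f)
    return suc, mal


def interconversion_flux(suc_cyt_mm: float, mal_cyt_mm: float, ph: float,
                         spec: MetabolismSpec) -> float:
    """Net Suc -> Mal interconversion flux factor, per mM (s^-1 scale).

    Reversible first-order exchange with a pH bias: an alkaline cytosol
    favours malate synthesis.  The returned value is a rate in
    mM s^-1-equivalents per unit volume; it is zero at the equilibrium
    ratio ``mal/suc = keq * 10**(slope*(pH - pH_ref))``.
    """
    if suc_cyt_mm < 0 or mal_cyt_mm < 0:
        raise ValueError("concentrations must be >= 0")
    kf = spec.interconversion_k_s * 10.0 ** (
        spec.interconversion_ph_slope * (ph - spec.ph_ref))
    kr = spec.interconversion_k_s / spec.interconversion_keq
    return kf * suc_cyt_mm - kr * mal_cyt_mm


#: proton-equivalents released per malate anion synthesized (Mal2- with
#: fixed speciation); breakdown consumes the same amount
H_PER_MAL = 2.0

#: malate anions produced per sucrose consumed in interconversion
MAL_PER_SUC = 2.0


def metabolic_fluxes(model: ModelSpec, light_red_umol: float,
                     suc_cyt_mm: float, mal_cyt_mm: float, ph_cyt: float,
                     v_cyt_pl: float) -> tuple[dict[str, float], float]:
    """Net cytosolic metabolic source terms, fmol s^-1, plus the proton yield.

    Combines light-driven synthesis, first-order breakdown and Suc<->Mal
    interconversion.  Returns ``(sources, h_load)`` with ``sources`` keyed by
    solute (positive = produced into the cytosol) and ``h_load`` the proton
    release in fmol s^-1 to be charged against the cytosolic buffer.
    """
    spec = model.metabolism
    suc_syn, mal_syn = synthesis_rates(light_red_umol, spec)
    # Davies pH-stat: alkalinization favours the H+-yielding Mal synthesis
    # and suppresses the H+-consuming breakdown, and vice versa
    dph = ph_cyt - spec.ph_ref
    mal_syn *= 10.0 ** (spec.ph_stat_synthesis_slope * dph)
    suc_break = spec.suc_breakdown_k_s * suc_cyt_mm * v_cyt_pl
    mal_break = (spec.mal_breakdown_k_s * mal_cyt_mm * v_cyt_pl
                 * 10.0 ** (-spec.ph_stat_breakdown_slope * dph))
    inter = interconversion_flux(suc_cyt_mm, mal_cyt_mm, ph_cyt, spec) * v_cyt_pl
    suc_net = suc_syn - suc_break - inter
    mal_net = mal_syn - mal_break + MAL_PER_SUC * inter
    h_load = H_PER_MAL * (mal_syn - mal_break + MAL_PER_SUC * inter)
    return {"Suc": suc_net, "Mal": mal_net}, h_load


def preview_metabolism(protocol, spec: MetabolismSpec, hours: float,
                       step_s: float = 60.0):
    """Open-loop preview of diurnal synthesis and breakdown rates.

    Integrates the cytosolic Suc and Mal pools under synthesis and
    first-order breakdown alone, ignoring solute transport between
    compartments entirely, so the series depends only on the light protocol
    and the metabolism parameters (a guide, not a simulation).  Returns a
    pandas DataFrame with one row per ``step_s``.
    """
    import pandas as pd

    red = protocol.tracks["red_light"]
    t = 0.0
    # nominal 0.2 pL cytosol for converting pools to concentrations
    v_cyt = 0.2
    suc = mal = 0.0  # fmol
    rows = []
    end = hours * 3600.0
    while t <= end + 1e-9:
        light = red.evaluate(t)
        suc_syn, mal_syn = synthesis_rates(light, spec)
        suc_break = spec.suc_breakdown_k_s * suc
        mal_break = spec.mal_breakdown_k_s * mal
        rows.append({
            "time_s": t,
            "red_light_umol_m2_s": light,
            "suc_synthesis_fmol_s": suc_syn,
            "mal_synthesis_fmol_s": mal_syn,
            "suc_breakdown_fmol_s": suc_break,
            "mal_breakdown_fmol_s": mal_break,
            "suc_pool_mM": suc / v_cyt,
            "mal_pool_mM": mal / v_cyt,
        })
        suc += (suc_syn - suc_break) * step_s
        mal += (mal_syn - mal_break) * step_s
        t += step_s
    return pd.DataFrame(rows)


def buffered_fractions(total_ca_mm: float, h_load_mm: float,
                       spec: SignallingSpec) -> tuple[float, float]:
    """Rapid-buffer mapping from totals to free [Ca2+]i and pH.

    ``free Ca = total / (1 + kappa)`` and ``pH = pH_ref - H_load / beta``
    where ``H_load`` is the cumulative net acid load in mM.  Both mappings
    are instantaneous.
    """
    if total_ca_mm < 0:
        raise ValueError("total Ca must be >= 0")
    free = total_ca_mm / (1.0 + spec.ca_buffer_kappa)
    ph = spec.ph_cyt_ref - h_load_mm / spec.ph_buffer_beta_mm
    if not (5.0 <= ph <= 9.0):
        raise ValueError(f"cytosolic pH {ph:.2f} outside the 5..9 guard rails")
    return free, ph


def signal_modifiers(model: ModelSpec, signal: SignalState,
                     pci_ubar: float) -> dict[str, float]:
    """Multiplicative factors per target transporter class from the relays.

    Evaluates every hard-wired relay (ABA, [Ca2+]i and pCi edges) at the
    current signalling state; factors for relays sharing a target compose
    multiplicatively (a commutative product), and they compose the same way
    with any transporter-local regulation.  At resting signal levels every
    factor is exactly 1.
    """
    values = {
        "aba": signal.aba_cyt_mm,
        "ca": signal.ca_free_cyt_mm,
        "pci": pci_ubar,
    }
    out: dict[str, float] = {}
    for relay in model.signalling.relays:
        f = regulation_factor(relay.response, values[relay.signal])
        out[relay.target_class] = out.get(relay.target_class, 1.0) * f
    return out
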