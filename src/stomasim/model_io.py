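"""Model parameter sets: definition, validation, (de)serialization and the
bundled Arabidopsis-like reference fixtures.

A model file (extension ``.ogj``) is canonical JSON: sorted keys, two-space
indent, shortest round-trip float formatting.  Saving the same model twice
produces byte-identical files, and ``load(save(m)) == m`` field for field.

Protons are special-cased throughout the package: the solute named ``"H"``
carries charge in every transmembrane flux, but it has no free compartment
pool.  Proton bookkeeping is a ledger against the cytosolic and vacuolar
buffer capacities (see :mod:`stomasim.metabolism`), its concentration for
kinetic and thermodynamic purposes is derived from compartment pH, and it is
excluded from osmolarity and from the electroneutrality check (where its
sub-micromolar free concentration is negligible anyway).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Optional

from .constants import DG_ATP_KJ, DG_PPI_KJ

SCHEMA_VERSION = "1"

#: name of the proton pseudo-solute (ledger-tracked, see module docstring)
PROTON = "H"

MEMBRANES = ("plasma_membrane", "tonoplast")
KINDS = ("channel", "pump", "carrier")
LIGANDS = ("cytosolic_Ca", "cytosolic_pH", "cytosolic_ABA", "internal_CO2",
           "blue_light")
SIGNALS = ("aba", "ca", "pci")


class ModelError(Exception):
    """Raised on parse failures or fatal validation violations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SoluteSpec:
    """One osmotically and electrically distinct solute species."""
    name: str
    valence: int
    osmotic_coefficient: float = 1.0
    is_signalling_only: bool = False


@dataclass
class RegulationSpec:
    """Hill-type ligand modifier acting on one transporter population.

    The multiplier is 1 exactly when the ligand sits at ``baseline`` (or
    below); an inhibitor descends to ``floor`` and an activator rises to
    ``1/floor`` as the ligand saturates.
    """
    ligand: str
    mode: str                 # "activate" | "inhibit"
    k_half: float             # ligand units (mM for solutes, ubar for CO2,
                              # umol m-2 s-1 for light), excess over baseline
    hill_n: float = 1.0
    floor: float = 0.05
    baseline: float = 0.0


@dataclass
class GatingSpec:
    """Boltzmann steady-state voltage gating.

    ``p_min`` is a residual open fraction outside voltage control (a small
    constitutively active sub-population).
    """
    v_half_mv: float
    gating_charge: float
    p_min: float = 0.0


@dataclass
class TransportedSolute:
    """One leg of a transporter's stoichiometry.

    ``direction`` is +1 when the solute moves into the cytosol in the
    transporter's forward (positive-rate) direction, -1 when it leaves.
    """
    solute: str
    stoich: float = 1.0
    direction: int = 1


@dataclass
class TransporterSpec:
    """One population of channels, pumps or coupled carriers on a membrane.

    ``population`` counts transporters per single guard cell; setting it to
    zero emulates a null mutant.  Channels use ``permeability_pl_s`` (unitary
    GHK permeability, pL s^-1); pumps and carriers use ``turnover_max``
    (cycles s^-1 per transporter).  ``k_m`` holds optional Michaelis constants
    (mM) applied to the concentration on the side each solute moves from.
    """
    name: str
    membrane: str
    kind: str
    population: float
    transported: list[TransportedSolute] = field(default_factory=list)
    permeability_pl_s: float = 0.0
    turnover_max: float = 0.0
    k_m: dict[str, float] = field(default_factory=dict)
    k_i: dict[str, float] = field(default_factory=dict)
    energized_delta_g_kj: Optional[float] = None
    gating: Optional[GatingSpec] = None
    regulation: list[RegulationSpec] = field(default_factory=list)
    signal_class: Optional[str] = None


@dataclass
class RelaySpec:
    """One hard-wired signal -> transporter-class edge.

    ``signal`` is one of ``aba`` (cytosolic ABA, mM), ``ca`` (cytosolic free
    Ca2+, mM) or ``pci`` (intercellular CO2, ubar); ``response`` maps the
    signal's excess over its resting baseline to a bounded multiplier.
    """
    signal: str
    target_class: str
    response: RegulationSpec


@dataclass
class MetabolismSpec:
    """Guard-cell sucrose/malate metabolism driven by red light.

    Synthesis saturates with light above a dark baseline fraction; breakdown
    is first order in the cytosolic pool, so each pool relaxes toward
    synthesis/breakdown balance with time constant 1/k.
    """
    suc_rate_max_fmol_s: float = 0.015
    mal_rate_max_fmol_s: float = 0.035
    light_half_sat_umol: float = 100.0
    dark_fraction: float = 0.05
    suc_breakdown_k_s: float = 5.0e-4
    mal_breakdown_k_s: float = 3.0e-3
    interconversion_k_s: float = 1.0e-4
    interconversion_keq: float = 1.0
    interconversion_ph_slope: float = 1.0
    ph_ref: float = 7.4
    # Davies pH-stat: malate synthesis is favoured in an alkaline cytosol
    # and breakdown in an acidic one, each by 10**(slope * dpH)
    ph_stat_synthesis_slope: float = 0.5
    ph_stat_breakdown_slope: float = 1.0


@dataclass
class SignallingSpec:
    """Buffering parameters and the hard-wired ABA / Ca2+ / pCi relay wiring."""
    ca_buffer_kappa: float = 999.0       # cytosolic bound:free Ca ratio
    ca_buffer_kappa_vac: float = 49.0
    ph_buffer_beta_mm: float = 100.0     # mM of strong acid per pH unit
    ph_buffer_beta_vac_mm: float = 30.0
    ph_cyt_ref: float = 7.4
    ph_cyt_init: float = 7.38
    ph_vac_init: float = 5.05
    apoplast_ph: float = 5.5
    ca_rest_free_mm: float = 1.0e-4      # 0.1 uM resting free Ca
    pci_ref_ubar: float = 400.0
    relays: list[RelaySpec] = field(default_factory=list)


@dataclass
class GeometrySpec:
    """Guard-cell and stomatal pore geometry."""
    relaxed_volume_pl: float = 2.0
    elastic_modulus_mpa: float = 5.0
    cytosol_fraction: float = 0.1
    vacuole_fraction: float = 0.9
    pore_depth_um: float = 5.0
    pore_length_um: float = 10.0
    aperture_max_um: float = 4.0
    aperture_k_mpa: float = 1.0          # half-saturation of the turgor map
    stomatal_density_mm2: float = 150.0
    residual_conductance_mol: float = 0.008


@dataclass
class HydraulicsSpec:
    """Water delivery, epidermal antagonism and CRR exchange parameters.

    The relative water feed (RWF) is the effective evaporative supply area
    divided by pore cross-section; 40 and above means a well-watered plant,
    10 and below imposes water restriction.  The wall water potential draws
    down from ``psi_source_mpa`` by ``supply_resistance * E / RWF``.
    """
    hydraulic_conductance_pl_s_mpa: float = 0.05
    rwf_default: float = 40.0
    psi_source_mpa: float = 0.0
    supply_resistance_mpa: float = 2.0   # MPa per (mmol m-2 s-1) at RWF = 1
    crr_subdomain_rate_s: float = 0.2
    crr_aperture_rate_s: float = 0.01
    crr_epidermal_rate_s: float = 0.005
    epidermal_antagonism_m: float = 1.0
    epidermal_base_turgor_mpa: float = 0.2
    epidermal_osmotic_gain: float = 0.5
    subdomain_volume_pl: float = 1.0


@dataclass
class AssimilationSpec:
    """Mesophyll A-Ci response: rectangular hyperbola with compensation point.

    ``A = A_max * f_L * (Ci - Gamma)/(K_m + Ci) - R_d * (1 - k * f_L)`` with
    ``f_L`` saturating in light; in darkness A = -R_d.
    """
    a_max_umol: float = 12.0
    k_m_ubar: float = 300.0
    gamma_ubar: float = 45.0
    light_half_sat_umol: float = 150.0
    r_d_umol: float = 1.0
    light_resp_suppression: float = 0.5


@dataclass
class ModelSpec:
    """Complete parameter set for one species model (the ``.ogj`` file)."""
    name: str = "model"
    schema_version: str = SCHEMA_VERSION
    temperature_k: float = 298.15
    solutes: list[SoluteSpec] = field(default_factory=list)
    compartments: dict[str, dict[str, float]] = field(default_factory=dict)
    transporters: list[TransporterSpec] = field(default_factory=list)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    metabolism: MetabolismSpec = field(default_factory=MetabolismSpec)
    signalling: SignallingSpec = field(default_factory=SignallingSpec)
    hydraulics: HydraulicsSpec = field(default_factory=HydraulicsSpec)
    assimilation: AssimilationSpec = field(default_factory=AssimilationSpec)
    capacitance_pm_pf: float = 5.0
    capacitance_tono_pf: float = 10.0
    elapsed_time_s: Optional[float] = None

    def solute(self, name: str) -> SoluteSpec:
        for s in self.solutes:
            if s.name == name:
                return s
        raise KeyError(name)

    def solute_names(self) -> set[str]:
        return {s.name for s in self.solutes}

    def transporter(self, name: str) -> TransporterSpec:
        for t in self.transporters:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class Violation:
    level: str      # "fatal" | "warning"
    code: str
    message: str


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _to_dict(obj):
    if is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def _from_dict(cls, data):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        t = f.name
        if v is None:
            kwargs[t] = None
        elif cls is ModelSpec and t == "solutes":
            kwargs[t] = [_from_dict(SoluteSpec, x) for x in v]
        elif cls is ModelSpec and t == "transporters":
            kwargs[t] = [_from_dict(TransporterSpec, x) for x in v]
        elif cls is ModelSpec and t == "geometry":
            kwargs[t] = _from_dict(GeometrySpec, v)
        elif cls is ModelSpec and t == "metabolism":
            kwargs[t] = _from_dict(MetabolismSpec, v)
        elif cls is ModelSpec and t == "signalling":
            kwargs[t] = _from_dict(SignallingSpec, v)
        elif cls is ModelSpec and t == "hydraulics":
            kwargs[t] = _from_dict(HydraulicsSpec, v)
        elif cls is ModelSpec and t == "assimilation":
            kwargs[t] = _from_dict(AssimilationSpec, v)
        elif cls is TransporterSpec and t == "transported":
            kwargs[t] = [_from_dict(TransportedSolute, x) for x in v]
        elif cls is TransporterSpec and t == "gating":
            kwargs[t] = _from_dict(GatingSpec, v)
        elif cls in (TransporterSpec,) and t == "regulation":
            kwargs[t] = [_from_dict(RegulationSpec, x) for x in v]
        elif cls is SignallingSpec and t == "relays":
            kwargs[t] = [_from_dict(RelaySpec, x) for x in v]
        elif cls is RelaySpec and t == "response":
            kwargs[t] = _from_dict(RegulationSpec, v)
        else:
            kwargs[t] = v
    return cls(**kwargs)


def model_to_json(model: ModelSpec) -> str:
    """Canonical serialization: sorted keys, stable float formatting."""
    return json.dumps(_to_dict(model), sort_keys=True, indent=2) + "\n"


def model_from_dict(data: dict) -> ModelSpec:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelError(f"unknown schema_version {version!r}; "
                         f"this build reads version {SCHEMA_VERSION!r}")
    return _from_dict(ModelSpec, data)


def save_model(model: ModelSpec, path) -> None:
    """Write a validated model to canonical ``.ogj`` text.

    Refuses to write a model with fatal validation violations.  The optional
    ``elapsed_time_s`` field records a checkpointed simulation clock; a
    reloaded model resumes at that time unless the field is reset.
    """
    fatal = [v for v in validate_model(model) if v.level == "fatal"]
    if fatal:
        raise ModelError("refusing to save invalid model: "
                         + "; ".join(v.message for v in fatal))
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> ModelSpec:
    """Load, parse and validate a model file; fatal violations abort."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(
            f"parse error in {path} at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from exc
    model = model_from_dict(data)
    fatal = [v for v in validate_model(model) if v.level == "fatal"]
    if fatal:
        raise ModelError(f"invalid model {path}: "
                         + "; ".join(v.message for v in fatal))
    return model


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

#: net-charge tolerance for initial compartment compositions, mM.  Far below
#: any solute pool; catches data-entry errors.
ELECTRONEUTRALITY_TOL_MM = 1.0


def net_charge_mm(model: ModelSpec, concentrations: dict[str, float]) -> float:
    """Net charge concentration sum(z*c) of a composition, mM (protons excluded)."""
    total = 0.0
    for name, conc in concentrations.items():
        if name == PROTON:
            continue
        total += model.solute(name).valence * conc
    return total


def validate_model(model: ModelSpec) -> list[Violation]:
    """Structural and physical validation; returns fatal and warning findings.

    Fatal: dangling transporter->solute references, compositions breaking
    electroneutrality beyond tolerance, nonpositive geometry/capacitance,
    malformed transporter stoichiometry.  Warnings: solutes with no
    transporter on a membrane (inert there) and zero-population transporters
    (intentional knockouts).
    """
    out: list[Violation] = []
    names = model.solute_names()

    seen = set()
    for s in model.solutes:
        if s.name in seen:
            out.append(Violation("fatal", "duplicate-solute",
                                 f"solute {s.name!r} defined twice"))
        seen.add(s.name)
        if s.valence not in (-2, -1, 0, 1, 2):
            out.append(Violation("fatal", "valence",
                                 f"solute {s.name!r} valence {s.valence} "
                                 "outside {-2..+2}"))
        if s.osmotic_coefficient < 0:
            out.append(Violation("fatal", "osmotic-coefficient",
                                 f"solute {s.name!r} has negative osmotic "
                                 "coefficient"))

    for comp in ("apoplast", "cytosol", "vacuole"):
        if comp not in model.compartments:
            out.append(Violation("fatal", "missing-compartment",
                                 f"no initial composition for {comp}"))
            continue
        for name, conc in model.compartments[comp].items():
            if name not in names and name != PROTON:
                out.append(Violation("fatal", "unknown-solute",
                                     f"{comp} lists unknown solute {name!r}"))
            if conc < 0:
                out.append(Violation("fatal", "negative-concentration",
                                     f"{comp} {name} = {conc} mM"))
        try:
            q = net_charge_mm(model, model.compartments[comp])
        except KeyError:
            q = 0.0
        if abs(q) > ELECTRONEUTRALITY_TOL_MM:
            out.append(Violation(
                "fatal", "electroneutrality",
                f"initial {comp} carries {q:+.3f} mM net charge "
                f"(tolerance {ELECTRONEUTRALITY_TOL_MM} mM)"))

    tseen = set()
    for t in model.transporters:
        if t.name in tseen:
            out.append(Violation("fatal", "duplicate-transporter",
                                 f"transporter {t.name!r} defined twice"))
        tseen.add(t.name)
        if t.membrane not in MEMBRANES:
            out.append(Violation("fatal", "membrane",
                                 f"{t.name}: unknown membrane {t.membrane!r}"))
        if t.kind not in KINDS:
            out.append(Violation("fatal", "kind",
                                 f"{t.name}: unknown kind {t.kind!r}"))
        if t.population < 0:
            out.append(Violation("fatal", "population",
                                 f"{t.name}: negative population"))
        elif t.population == 0:
            out.append(Violation("warning", "knockout",
                                 f"{t.name}: population 0 (null mutant)"))
        if not t.transported:
            out.append(Violation("fatal", "stoichiometry",
                                 f"{t.name}: transports nothing"))
        for leg in t.transported:
            if leg.solute not in names and leg.solute != PROTON:
                out.append(Violation(
                    "fatal", "dangling-solute",
                    f"transporter {t.name!r} references absent solute "
                    f"{leg.solute!r}"))
            if leg.direction not in (-1, 1) or leg.stoich <= 0:
                out.append(Violation("fatal", "stoichiometry",
                                     f"{t.name}: bad leg for {leg.solute}"))
        if t.kind == "channel":
            known = [leg for leg in t.transported
                     if leg.solute in names or leg.solute == PROTON]
            if len(t.transported) != 1 or (known and all(
                    leg.solute != PROTON
                    and model.solute(leg.solute).valence == 0
                    for leg in known)):
                out.append(Violation(
                    "fatal", "channel-stoichiometry",
                    f"channel {t.name!r} must transport exactly one "
                    "charged solute"))
        if t.kind == "pump" and t.energized_delta_g_kj is None:
            out.append(Violation("fatal", "pump-energy",
                                 f"pump {t.name!r} lacks an energized "
                                 "substrate free energy"))
        for reg in t.regulation:
            out.extend(_check_regulation(reg, t.name))

    for relay in model.signalling.relays:
        if relay.signal not in SIGNALS:
            out.append(Violation("fatal", "relay-signal",
                                 f"unknown relay signal {relay.signal!r}"))
        out.extend(_check_regulation(relay.response,
                                     f"relay {relay.signal}->{relay.target_class}"))

    g = model.geometry
    positives = [
        ("relaxed_volume_pl", g.relaxed_volume_pl),
        ("elastic_modulus_mpa", g.elastic_modulus_mpa),
        ("cytosol_fraction", g.cytosol_fraction),
        ("vacuole_fraction", g.vacuole_fraction),
        ("pore_depth_um", g.pore_depth_um),
        ("pore_length_um", g.pore_length_um),
        ("aperture_max_um", g.aperture_max_um),
        ("stomatal_density_mm2", g.stomatal_density_mm2),
        ("capacitance_pm_pf", model.capacitance_pm_pf),
        ("capacitance_tono_pf", model.capacitance_tono_pf),
        ("subdomain_volume_pl", model.hydraulics.subdomain_volume_pl),
        ("rwf_default", model.hydraulics.rwf_default),
    ]
    for label, value in positives:
        if value <= 0:
            out.append(Violation("fatal", "geometry",
                                 f"{label} must be > 0, got {value}"))
    if abs(g.cytosol_fraction + g.vacuole_fraction - 1.0) > 1e-9:
        out.append(Violation("fatal", "geometry",
                             "cytosol and vacuole volume fractions must sum "
                             "to 1"))

    # inert solutes: no transporter on a membrane
    for s in model.solutes:
        if s.is_signalling_only:
            continue
        for mem in MEMBRANES:
            if not any(t.membrane == mem
                       and any(leg.solute == s.name for leg in t.transported)
                       for t in model.transporters):
                out.append(Violation(
                    "warning", "inert-solute",
                    f"solute {s.name!r} has no transporter on {mem}; it is "
                    "inert there"))
    return out


def _check_regulation(reg: RegulationSpec, owner: str) -> list[Violation]:
    out = []
    if reg.ligand not in LIGANDS:
        out.append(Violation("fatal", "ligand",
                             f"{owner}: unknown ligand {reg.ligand!r}"))
    if reg.mode not in ("activate", "inhibit"):
        out.append(Violation("fatal", "regulation-mode",
                             f"{owner}: mode {reg.mode!r}"))
    if reg.hill_n < 0.5:
        out.append(Violation("fatal", "hill",
                             f"{owner}: hill_n {reg.hill_n} < 0.5"))
    if reg.k_half <= 0:
        out.append(Violation("fatal", "k-half",
                             f"{owner}: k_half must be > 0"))
    lo = 0.0 if reg.mode == "inhibit" else 1e-12
    if not (lo <= reg.floor <= 1.0) or (reg.mode == "activate"
                                        and reg.floor <= 0):
        out.append(Violation("fatal", "floor",
                             f"{owner}: floor {reg.floor} out of range"))
    return out


# ---------------------------------------------------------------------------
# reference fixtures
# ---------------------------------------------------------------------------

def _solutes_base() -> list[SoluteSpec]:
    return [
        SoluteSpec("K", +1),
        SoluteSpec("Cl", -1),
        SoluteSpec("Mal", -2),
        SoluteSpec("Suc", 0),
        SoluteSpec("Ca", +2),
        # impermeant macromolecular fixed charge; balances the initial
        # compositions and is osmotically subsumed in the wall mechanics
        SoluteSpec("Aorg", -1, osmotic_coefficient=0.0),
        # proton pseudo-solute: ledger-tracked, osmotically silent
        SoluteSpec(PROTON, +1, osmotic_coefficient=0.0,
                   is_signalling_only=True),
    ]


def _base_compartments() -> dict[str, dict[str, float]]:
    """Initial compositions on the model's own diurnal limit cycle.

    Values are the dawn (lights-on) state of a long spin-up of this
    fixture under the stock 12 h / 12 h protocol, so a fresh run starts
    essentially on the attractor.  The impermeant fixed charge ``Aorg``
    makes each compartment exactly electroneutral.
    """
    comps = {
        "apoplast": {"K": 0.5, "Cl": 2.0, "Mal": 0.25, "Ca": 1.0,
                     "Suc": 1.0, "Aorg": 0.0},
        "cytosol": {"K": 429.90, "Cl": 27.10, "Mal": 5.19, "Ca": 0.085,
                    "Suc": 21.03, "Aorg": 0.0},
        "vacuole": {"K": 182.42, "Cl": 63.74, "Mal": 30.53, "Ca": 3.21,
                    "Suc": 20.68, "Aorg": 0.0},
    }
    valence = {"K": 1, "Cl": -1, "Mal": -2, "Ca": 2, "Suc": 0, "Aorg": -1}
    for comp in comps.values():
        comp["Aorg"] = sum(valence[n] * c for n, c in comp.items()
                           if n != "Aorg")
    return comps


def _base_transporters() -> list[TransporterSpec]:
    """Order-of-magnitude Arabidopsis-like transporter inventory.

    Populations and unitary rates are literature-typical scales chosen so
    that resting net fluxes sit in the 0.1-0.5 fmol s^-1 range per guard
    cell and macroscopic pool turnover takes tens of minutes.  They are a
    documented synthetic calibration, not measured values.
    """
    return [
        # --- plasma membrane -------------------------------------------
        TransporterSpec(
            name="pm_h_atpase", membrane="plasma_membrane", kind="pump",
            population=5.0e5, turnover_max=6.0e-7,
            transported=[TransportedSolute(PROTON, 1.0, -1)],
            energized_delta_g_kj=DG_ATP_KJ,
            k_m={PROTON: 3.0e-4},
            regulation=[RegulationSpec("blue_light", "activate", k_half=10.0,
                                       hill_n=1.0, floor=0.22)],
            signal_class="pm_h_atpase"),
        TransporterSpec(
            name="pm_ca_atpase", membrane="plasma_membrane", kind="pump",
            population=2.0e4, turnover_max=9.0e-7,
            transported=[TransportedSolute("Ca", 1.0, -1),
                         TransportedSolute(PROTON, 2.0, 1)],
            energized_delta_g_kj=DG_ATP_KJ,
            k_m={"Ca": 3.0e-4},
            signal_class="pm_ca_atpase"),
        TransporterSpec(
            name="pm_ca_channel", membrane="plasma_membrane", kind="channel",
            population=200.0, permeability_pl_s=3.6e-6,
            transported=[TransportedSolute("Ca", 1.0, 1)],
            gating=GatingSpec(v_half_mv=-180.0, gating_charge=-2.0),
            signal_class="pm_ca_channel"),
        TransporterSpec(
            name="pm_k_in", membrane="plasma_membrane", kind="channel",
            population=1.0e4, permeability_pl_s=5.0e-6,
            transported=[TransportedSolute("K", 1.0, 1)],
            gating=GatingSpec(v_half_mv=-165.0, gating_charge=-3.0),
            signal_class="k_in_channel"),
        TransporterSpec(
            name="pm_k_out", membrane="plasma_membrane", kind="channel",
            population=1.0e4, permeability_pl_s=3.0e-6,
            transported=[TransportedSolute("K", 1.0, 1)],
            gating=GatingSpec(v_half_mv=-70.0, gating_charge=1.5),
            signal_class="k_out_channel"),
        TransporterSpec(
            name="pm_cl_channel", membrane="plasma_membrane", kind="channel",
            population=5.0e3, permeability_pl_s=2.5e-7,
            transported=[TransportedSolute("Cl", 1.0, 1)],
            gating=GatingSpec(v_half_mv=-60.0, gating_charge=1.2, p_min=0.02),
            signal_class="pm_anion_channel"),
        TransporterSpec(
            name="pm_mal_channel", membrane="plasma_membrane", kind="channel",
            population=5.0e3, permeability_pl_s=3.0e-8,
            transported=[TransportedSolute("Mal", 1.0, 1)],
            gating=GatingSpec(v_half_mv=-60.0, gating_charge=1.2, p_min=0.02),
            signal_class="pm_anion_channel"),
        TransporterSpec(
            name="pm_2h_cl_symporter", membrane="plasma_membrane",
            kind="carrier",
            population=1.0e5, turnover_max=2.0e-7,
            transported=[TransportedSolute(PROTON, 2.0, 1),
                         TransportedSolute("Cl", 1.0, 1)],
            k_m={"Cl": 2.0}, k_i={"Cl": 50.0}),
        TransporterSpec(
            name="pm_h_suc_symporter", membrane="plasma_membrane",
            kind="carrier",
            population=2.0e4, turnover_max=2.0e-7,
            transported=[TransportedSolute(PROTON, 1.0, 1),
                         TransportedSolute("Suc", 1.0, 1)],
            k_m={"Suc": 1.0}),
        # --- tonoplast -------------------------------------------------
        TransporterSpec(
            name="tono_v_atpase", membrane="tonoplast", kind="pump",
            population=2.0e5, turnover_max=2.0e-7,
            transported=[TransportedSolute(PROTON, 3.0, -1)],
            energized_delta_g_kj=DG_ATP_KJ,
            k_m={PROTON: 1.0e-4}),
        TransporterSpec(
            name="tono_h_ppase", membrane="tonoplast", kind="pump",
            population=1.0e5, turnover_max=2.0e-7,
            transported=[TransportedSolute(PROTON, 1.0, -1)],
            energized_delta_g_kj=DG_PPI_KJ,
            k_m={PROTON: 1.0e-4},
            signal_class="tono_h_ppase"),
        TransporterSpec(
            name="tono_ca_atpase", membrane="tonoplast", kind="pump",
            population=2.0e4, turnover_max=1.0e-8,
            transported=[TransportedSolute("Ca", 1.0, -1),
                         TransportedSolute(PROTON, 2.0, 1)],
            energized_delta_g_kj=DG_ATP_KJ,
            k_m={"Ca": 3.0e-4},
            signal_class="endo_ca_atpase"),
        TransporterSpec(
            name="tono_ca_h_antiporter", membrane="tonoplast", kind="carrier",
            population=1.0e4, turnover_max=1.0e-7,
            transported=[TransportedSolute("Ca", 1.0, -1),
                         TransportedSolute(PROTON, 1.0, 1)],
            k_m={"Ca": 1.0e-3}),
        TransporterSpec(
            name="tono_k_channel", membrane="tonoplast", kind="channel",
            population=5.0e3, permeability_pl_s=1.0e-6,
            transported=[TransportedSolute("K", 1.0, 1)],
            signal_class="vac_k_channel"),
        TransporterSpec(
            name="tono_cl_channel", membrane="tonoplast", kind="channel",
            population=5.0e3, permeability_pl_s=1.0e-6,
            transported=[TransportedSolute("Cl", 1.0, 1)],
            signal_class="vac_anion_channel"),
        TransporterSpec(
            name="tono_mal_channel", membrane="tonoplast", kind="channel",
            population=5.0e3, permeability_pl_s=5.0e-7,
            transported=[TransportedSolute("Mal", 1.0, 1)]),
    ]


def _base_relays() -> list[RelaySpec]:
    """Hard-wired [Ca2+]i and pCi relays shared by both fixture variants.

    Cytosolic free Ca2+ above rest inactivates the inward K+ channel,
    suppresses the plasma-membrane H+-ATPase and the tonoplast H+-PPase,
    and activates the plasma-membrane anion channels; elevated Ca2+ also
    opens the vacuolar K+ and anion release channels.  Intercellular CO2
    above its reference acts on the same target set as ABA, with its own
    half-saturations.
    """
    ca_rest = 1.0e-4   # mM free Ca
    return [
        RelaySpec("ca", "k_in_channel",
                  RegulationSpec("cytosolic_Ca", "inhibit", k_half=4.0e-4,
                                 hill_n=2.0, floor=0.02, baseline=ca_rest)),
        RelaySpec("ca", "pm_h_atpase",
                  RegulationSpec("cytosolic_Ca", "inhibit", k_half=6.0e-4,
                                 hill_n=2.0, floor=0.3, baseline=ca_rest)),
        RelaySpec("ca", "tono_h_ppase",
                  RegulationSpec("cytosolic_Ca", "inhibit", k_half=8.0e-4,
                                 hill_n=2.0, floor=0.2, baseline=ca_rest)),
        RelaySpec("ca", "pm_anion_channel",
                  RegulationSpec("cytosolic_Ca", "activate", k_half=3.0e-4,
                                 hill_n=2.0, floor=0.33, baseline=ca_rest)),
        RelaySpec("ca", "vac_k_channel",
                  RegulationSpec("cytosolic_Ca", "activate", k_half=4.0e-4,
                                 hill_n=2.0, floor=0.25, baseline=ca_rest)),
        RelaySpec("ca", "vac_anion_channel",
                  RegulationSpec("cytosolic_Ca", "activate", k_half=4.0e-4,
                                 hill_n=2.0, floor=0.25, baseline=ca_rest)),
        # pCi excess over its 400 ubar reference, same targets as ABA
        RelaySpec("pci", "pm_ca_channel",
                  RegulationSpec("internal_CO2", "activate", k_half=100.0,
                                 hill_n=2.0, floor=0.33, baseline=400.0)),
        RelaySpec("pci", "pm_ca_atpase",
                  RegulationSpec("internal_CO2", "inhibit", k_half=100.0,
                                 hill_n=2.0, floor=0.5, baseline=400.0)),
        RelaySpec("pci", "endo_ca_atpase",
                  RegulationSpec("internal_CO2", "inhibit", k_half=100.0,
                                 hill_n=2.0, floor=0.5, baseline=400.0)),
        RelaySpec("pci", "pm_h_atpase",
                  RegulationSpec("internal_CO2", "inhibit", k_half=150.0,
                                 hill_n=2.0, floor=0.6, baseline=400.0)),
    ]


def _aba_relays() -> list[RelaySpec]:
    """ABA wiring: activate the PM Ca2+ channel, inhibit the PM and
    endomembrane Ca2+-ATPases, and suppress the PM H+-ATPase.  Ligand is
    cytosolic ABA in mM (1 uM = 1e-3 mM)."""
    return [
        RelaySpec("aba", "pm_ca_channel",
                  RegulationSpec("cytosolic_ABA", "activate", k_half=1.5e-4,
                                 hill_n=1.5, floor=0.15)),
        RelaySpec("aba", "pm_ca_atpase",
                  RegulationSpec("cytosolic_ABA", "inhibit", k_half=1.5e-4,
                                 hill_n=1.5, floor=0.2)),
        RelaySpec("aba", "endo_ca_atpase",
                  RegulationSpec("cytosolic_ABA", "inhibit", k_half=1.5e-4,
                                 hill_n=1.5, floor=0.2)),
        RelaySpec("aba", "pm_h_atpase",
                  RegulationSpec("cytosolic_ABA", "inhibit", k_half=2.5e-4,
                                 hill_n=1.5, floor=0.35)),
    ]


def _aba_transporters() -> list[TransporterSpec]:
    return [
        TransporterSpec(
            name="pm_aba_uptake", membrane="plasma_membrane", kind="carrier",
            population=1.0e3, turnover_max=2.0e-9,
            transported=[TransportedSolute("ABA", 1.0, 1)],
            k_m={"ABA": 1.0e-3}),
        TransporterSpec(
            name="tono_aba_transport", membrane="tonoplast", kind="carrier",
            population=1.0e3, turnover_max=2.0e-10,
            transported=[TransportedSolute("ABA", 1.0, 1)],
            k_m={"ABA": 1.0e-3}),
    ]


def build_reference_model(variant: str = "base") -> ModelSpec:
    """Deterministic Arabidopsis-like reference fixture.

    ``base`` carries the full two-membrane K+/Cl-/Mal/Suc/Ca2+ inventory with
    the [Ca2+]i and pCi relays; ``with_aba`` additionally defines ABA as an
    apoplastic solute with saturable uptake across both membranes and wires
    cytosolic ABA to its relay targets.  Parameter values are
    order-of-magnitude literature-typical and documented inline; they are a
    synthetic calibration of this package.
    """
    if variant not in ("base", "with_aba"):
        raise ModelError(f"unknown fixture variant {variant!r}")
    model = ModelSpec(
        name="arabidopsis_like_base",
        solutes=_solutes_base(),
        compartments=_base_compartments(),
        transporters=_base_transporters(),
        signalling=SignallingSpec(relays=_base_relays()),
    )
    if variant == "with_aba":
        model.name = "arabidopsis_like_aba"
        model.solutes.append(SoluteSpec("ABA", 0, osmotic_coefficient=0.0,
                                        is_signalling_only=True))
        for comp in model.compartments.values():
            comp["ABA"] = 0.0
        model.transporters.extend(_aba_transporters())
        model.signalling.relays.extend(_aba_relays())
    return model


def strip_aba(model: ModelSpec) -> ModelSpec:
    """Remove the ABA-specific entries from a ``with_aba`` fixture.

    Inverse of the ``with_aba`` construction: dropping the ABA solute, its
    transporters, relays and compartment entries recovers the base fixture.
    """
    m = copy.deepcopy(model)
    m.name = "arabidopsis_like_base"
    m.solutes = [s for s in m.solutes if s.name != "ABA"]
    m.transporters = [t for t in m.transporters
                      if not any(leg.solute == "ABA" for leg in t.transported)]
    m.signalling.relays = [r for r in m.signalling.relays
                           if r.signal != "aba"]
    for comp in m.compartments.values():
        comp.pop("ABA", None)
    return m
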