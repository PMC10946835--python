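"""Diurnal environment protocols, the simulation loop, CSV logging and
checkpoint/resume.

A protocol holds one track per environmental input (blue and red light,
atmospheric pCO2, RH, the relative water feed and apoplastic ABA), each a
list of time-ordered nodes on a 24 h cycle with per-segment step or linear
interpolation.  Multi-day runs repeat the cycle.

The loop advances :func:`stomasim.solver.step_cell` under an adaptive time
step (local-change controller), logs at a fixed interval, and can pause at
a preset time by emitting a resumable checkpoint.  There is no randomness
anywhere: identical inputs give bitwise-identical trajectories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .model_io import (ModelSpec, ModelError, PROTON, _from_dict, _to_dict,
                       validate_model)
from .solver import (CellState, CompartmentState, MembraneState, SolverFault,
                     aggregate_fluxes, initial_state, step_cell)
from .hydromechanics import MechanicalState
from .gas_exchange import GasState

DAY_S = 86400.0

TRACK_NAMES = ("blue_light", "red_light", "pCO2", "RH", "RWF", "ABA")

#: physical bounds per track (min, max); None = unbounded above
TRACK_BOUNDS = {
    "blue_light": (0.0, None), "red_light": (0.0, None),
    "pCO2": (0.0, None), "RH": (0.0, 100.0), "RWF": (1e-6, None),
    "ABA": (0.0, None),
}

#: track name -> key used in the solver's environment dict
_ENV_KEYS = {"blue_light": "blue_light", "red_light": "red_light",
             "pCO2": "pco2", "RH": "rh", "RWF": "rwf", "ABA": "aba"}


class ProtocolError(ValueError):
    pass


@dataclass
class Node:
    time_s: float
    value: float
    interp: str = "step"        # interpolation of the segment starting here


@dataclass
class ProtocolTrack:
    """One diurnal input track; times live in [0, 86400) and wrap at 24 h."""
    name: str
    nodes: list[Node]

    def __post_init__(self):
        if not self.nodes:
            raise ProtocolError(f"track {self.name!r} has no nodes")
        self._check()

    def _check(self):
        lo, hi = TRACK_BOUNDS.get(self.name, (0.0, None))
        prev = -1.0
        for n in self.nodes:
            if not (0.0 <= n.time_s < DAY_S):
                raise ProtocolError(f"{self.name}: node time {n.time_s} "
                                    "outside [0, 86400)")
            if n.time_s <= prev:
                raise ProtocolError(f"{self.name}: node times must be "
                                    "strictly increasing")
            prev = n.time_s
            if n.value < lo or (hi is not None and n.value > hi):
                raise ProtocolError(f"{self.name}: value {n.value} outside "
                                    f"physical bounds")
            if n.interp not in ("step", "linear"):
                raise ProtocolError(f"{self.name}: bad interpolation "
                                    f"{n.interp!r}")

    def evaluate(self, t_s: float) -> float:
        """Piecewise evaluation at t (reduced mod 24 h), continuous from the
        right at step edges."""
        if t_s < 0:
            raise ProtocolError("time must be >= 0")
        t = t_s % DAY_S
        nodes = self.nodes
        # last node with time <= t; before the first node, wrap from the last
        idx = None
        for i, n in enumerate(nodes):
            if n.time_s <= t:
                idx = i
            else:
                break
        if idx is None:
            cur = nodes[-1]
            t0 = cur.time_s - DAY_S
            nxt = nodes[0]
            t1 = nxt.time_s
        else:
            cur = nodes[idx]
            t0 = cur.time_s
            if idx + 1 < len(nodes):
                nxt = nodes[idx + 1]
                t1 = nxt.time_s
            else:
                nxt = nodes[0]
                t1 = nodes[0].time_s + DAY_S
        if cur.interp == "step" or t1 == t0:
            return cur.value
        w = (t - t0) / (t1 - t0)
        return cur.value + w * (nxt.value - cur.value)

    # -- node editing ----------------------------------------------------

    def set_flat(self, value: float) -> "ProtocolTrack":
        return ProtocolTrack(self.name, [Node(0.0, value, "step")])

    def add_node(self, time_s: float, value: float,
                 interp: str = "step") -> "ProtocolTrack":
        if any(abs(n.time_s - time_s) < 1e-9 for n in self.nodes):
            raise ProtocolError(f"{self.name}: node at t={time_s} already "
                                "exists")
        nodes = sorted(self.nodes + [Node(time_s, value, interp)],
                       key=lambda n: n.time_s)
        return ProtocolTrack(self.name, nodes)

    def delete_node(self, time_s: float) -> "ProtocolTrack":
        nodes = [n for n in self.nodes if abs(n.time_s - time_s) >= 1e-9]
        if len(nodes) == len(self.nodes):
            raise ProtocolError(f"{self.name}: no node at t={time_s}")
        return ProtocolTrack(self.name, nodes)

    def move_node(self, time_s: float, new_time_s: float,
                  new_value: float | None = None) -> "ProtocolTrack":
        if abs(new_time_s - time_s) >= 1e-9 and any(
                abs(n.time_s - new_time_s) < 1e-9 for n in self.nodes):
            raise ProtocolError(f"{self.name}: t={new_time_s} occupied")
        nodes = []
        found = False
        for n in self.nodes:
            if abs(n.time_s - time_s) < 1e-9:
                found = True
                v = n.value if new_value is None else new_value
                nodes.append(Node(new_time_s, v, n.interp))
            else:
                nodes.append(n)
        if not found:
            raise ProtocolError(f"{self.name}: no node at t={time_s}")
        nodes.sort(key=lambda n: n.time_s)
        return ProtocolTrack(self.name, nodes)


def edit_track(track: ProtocolTrack, action: str, *args) -> ProtocolTrack:
    """Apply one named edit: set_flat(v), add_node(t, v[, interp]),
    delete_node(t), move_node(t, t_new[, v_new])."""
    try:
        method = getattr(track, action)
    except AttributeError:
        raise ProtocolError(f"unknown edit action {action!r}") from None
    return method(*args)


def evaluate_track(track: ProtocolTrack, t_s: float) -> float:
    return track.evaluate(t_s)


@dataclass
class EnvironmentProtocol:
    """All six diurnal input tracks plus optional preset pause times."""
    tracks: dict[str, ProtocolTrack]
    pause_at: list[float] = field(default_factory=list)

    def __post_init__(self):
        for name in TRACK_NAMES:
            if name not in self.tracks:
                self.tracks[name] = _default_track(name)

    def environment(self, t_s: float) -> dict[str, float]:
        return {_ENV_KEYS[name]: self.tracks[name].evaluate(t_s)
                for name in TRACK_NAMES}


def _default_track(name: str) -> ProtocolTrack:
    half = DAY_S / 2.0
    nodes = {
        "blue_light": [Node(0.0, 30.0), Node(half, 0.0)],
        "red_light": [Node(0.0, 300.0), Node(half, 0.0)],
        "pCO2": [Node(0.0, 400.0)],
        "RH": [Node(0.0, 70.0)],
        "RWF": [Node(0.0, 40.0)],
        "ABA": [Node(0.0, 0.0)],
    }[name]
    return ProtocolTrack(name, nodes)


def default_protocol() -> EnvironmentProtocol:
    """12 h light (hours 0-12) / 12 h dark, 400 ppm CO2, 70% RH, RWF 40."""
    return EnvironmentProtocol(tracks={})


def preset_co2_cycle() -> ProtocolTrack:
    """The stock daytime CO2 protocol: 1 h steps from 400 to 1000 ppm
    separated by periods at 400 ppm over the 24 h cycle."""
    nodes = []
    t = 0.0
    for hour in (2.0, 6.0, 10.0, 14.0):
        nodes.append(Node(t, 400.0))
        nodes.append(Node(hour * 3600.0, 1000.0))
        t = (hour + 1.0) * 3600.0
    nodes.append(Node(t, 400.0))
    return ProtocolTrack("pCO2", nodes)


def aba_pulse_protocol(aba_um: float = 1.0, start_h: float = 4.0,
                       end_h: float = 6.0) -> EnvironmentProtocol:
    """Constant light, 70% RH, 400 ubar CO2, with an apoplastic ABA pulse
    (default 1 uM over hours 4-6)."""
    p = EnvironmentProtocol(tracks={
        "blue_light": ProtocolTrack("blue_light", [Node(0.0, 30.0)]),
        "red_light": ProtocolTrack("red_light", [Node(0.0, 300.0)]),
        "pCO2": ProtocolTrack("pCO2", [Node(0.0, 400.0)]),
        "RH": ProtocolTrack("RH", [Node(0.0, 70.0)]),
        "RWF": ProtocolTrack("RWF", [Node(0.0, 40.0)]),
        "ABA": ProtocolTrack("ABA", [Node(0.0, 0.0),
                                     Node(start_h * 3600.0, aba_um),
                                     Node(end_h * 3600.0, 0.0)]),
    })
    return p


# ---------------------------------------------------------------------------
# simulation configuration, result, checkpoint
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Run controls.

    ``fast`` mode logs less often and omits the per-transporter flux
    columns; the physics is identical to ``full``.  The adaptive controller
    keeps |dV_pm| <= 1 mV and the fractional state change <= 0.5% per step
    within [dt_min, dt_max], halving the step on a breach and doubling after
    ten clean steps.  Pause times should lie on the logging grid so that a
    pause/resume splice reproduces the uninterrupted trajectory exactly.
    """
    duration_s: float
    mode: str = "full"
    log_interval_s: float | None = None
    dt_min_s: float = 1.0e-3
    dt_max_s: float = 2.0
    pause_at_s: float | None = None
    tonoplast_mode: str = "quasi_steady"
    max_dv_mv: float = 1.0
    max_frac_change: float = 5.0e-3
    max_dph: float = 0.01

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.mode not in ("full", "fast"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.log_interval_s is None:
            self.log_interval_s = 10.0 if self.mode == "full" else 60.0
        if self.log_interval_s < self.dt_min_s:
            raise ValueError("log interval below dt_min")


@dataclass
class Ledger:
    """Conservation bookkeeping accumulated over a run."""
    int_i_dt_pm_pa_s: float = 0.0
    int_abs_i_dt_pm_pa_s: float = 0.0
    int_i_dt_tono_pa_s: float = 0.0
    int_abs_i_dt_tono_pa_s: float = 0.0
    solute_in_fmol: dict[str, float] = field(default_factory=dict)
    abs_solute_in_fmol: dict[str, float] = field(default_factory=dict)
    water_in_pl: float = 0.0


@dataclass
class Checkpoint:
    """Everything needed to resume a paused run bit-for-bit."""
    model: ModelSpec
    state: CellState
    dt_s: float
    clean_steps: int

    def to_json(self) -> str:
        return json.dumps({
            "model": _to_dict(self.model),
            "state": _state_to_dict(self.state),
            "dt_s": self.dt_s,
            "clean_steps": self.clean_steps,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Checkpoint":
        d = json.loads(text)
        return cls(model=_from_dict(ModelSpec, d["model"]),
                   state=_state_from_dict(d["state"]),
                   dt_s=d["dt_s"], clean_steps=d["clean_steps"])

    def with_model(self, model: ModelSpec) -> "Checkpoint":
        """Replace the model (paused-run parameter edits), validating that
        the edit is fatal-violation-free and keeps the state's solute set."""
        fatal = [v for v in validate_model(model) if v.level == "fatal"]
        if fatal:
            raise ModelError("invalid edited model: "
                             + "; ".join(v.message for v in fatal))
        state_solutes = set(self.state.cytosol.amounts_fmol)
        model_solutes = {s.name for s in model.solutes if s.name != PROTON}
        missing = state_solutes - model_solutes
        if missing:
            raise ModelError(f"edit removes solutes present in the paused "
                             f"state: {sorted(missing)}")
        return Checkpoint(model, self.state, self.dt_s, self.clean_steps)


@dataclass
class SimulationResult:
    """Logged time series plus final state, ledgers and (optionally) the
    checkpoint emitted at a pause."""
    records: list[dict]
    final_state: CellState
    ledger: Ledger
    config: SimulationConfig
    checkpoint: Checkpoint | None = None
    start_state: CellState | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _state_to_dict(s: CellState) -> dict:
    return {
        "v_pm": s.pm.voltage_mv, "c_pm": s.pm.capacitance_pf,
        "v_tono": s.tono.voltage_mv, "c_tono": s.tono.capacitance_pf,
        "cyt_volume": s.cytosol.volume_pl, "cyt": dict(s.cytosol.amounts_fmol),
        "vac_volume": s.vacuole.volume_pl, "vac": dict(s.vacuole.amounts_fmol),
        "sub": dict(s.subdomain_mm),
        "ph_cyt": s.ph_cyt, "ph_vac": s.ph_vac,
        "mech": {"volume": s.mech.volume_total_pl,
                 "aperture": s.mech.aperture_um,
                 "p_epi": s.mech.epidermal_turgor_mpa,
                 "psi_wall": s.mech.psi_wall_mpa},
        "gas": {"gs": s.gas.gs_mol_m2_s, "e": s.gas.e_mmol_m2_s,
                "a": s.gas.a_umol_m2_s, "pci": s.gas.pci_ubar,
                "wp": s.gas.wp_mbar, "rh_i": s.gas.rh_i_pct,
                "wue": s.gas.wue_umol_mmol},
        "time_s": s.time_s,
    }


def _state_from_dict(d: dict) -> CellState:
    return CellState(
        pm=MembraneState(d["v_pm"], d["c_pm"]),
        tono=MembraneState(d["v_tono"], d["c_tono"]),
        cytosol=CompartmentState(d["cyt_volume"], dict(d["cyt"])),
        vacuole=CompartmentState(d["vac_volume"], dict(d["vac"])),
        subdomain_mm=dict(d["sub"]),
        ph_cyt=d["ph_cyt"], ph_vac=d["ph_vac"],
        mech=MechanicalState(d["mech"]["volume"], d["mech"]["aperture"],
                             d["mech"]["p_epi"], d["mech"]["psi_wall"]),
        gas=GasState(d["gas"]["gs"], d["gas"]["e"], d["gas"]["a"],
                     d["gas"]["pci"], d["gas"]["wp"], d["gas"]["rh_i"],
                     d["gas"]["wue"]),
        time_s=d["time_s"])


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _record_row(model: ModelSpec, state: CellState, env: dict,
                rec, mode: str) -> dict:
    from .hydromechanics import osmotic_potential, turgor_from_volume
    row = {
        "time_s": state.time_s,
        "v_pm_mV": state.pm.voltage_mv,
        "v_tono_mV": state.tono.voltage_mv,
        "volume_pL": state.mech.volume_total_pl,
        "turgor_MPa": turgor_from_volume(state.mech.volume_total_pl,
                                         model.geometry),
        "aperture_um": state.mech.aperture_um,
        "epidermal_turgor_MPa": state.mech.epidermal_turgor_mpa,
        "psi_wall_MPa": state.mech.psi_wall_mpa,
        "gs_mol_m2_s": state.gas.gs_mol_m2_s,
        "E_mmol_m2_s": state.gas.e_mmol_m2_s,
        "A_umol_m2_s": state.gas.a_umol_m2_s,
        "pci_ubar": state.gas.pci_ubar,
        "wp_mbar": state.gas.wp_mbar,
        "rh_i_pct": state.gas.rh_i_pct,
        "wue_umol_mmol": state.gas.wue_umol_mmol,
        "ph_cyt": state.ph_cyt,
        "ph_vac": state.ph_vac,
    }
    sig = model.signalling
    v_cyt = state.cytosol.volume_pl
    ca_total = state.cytosol.amounts_fmol.get("Ca", 0.0) / v_cyt
    row["ca_free_cyt_uM"] = 1000.0 * ca_total / (1.0 + sig.ca_buffer_kappa)
    row["aba_cyt_uM"] = 1000.0 * state.cytosol.amounts_fmol.get(
        "ABA", 0.0) / v_cyt
    for key, value in env.items():
        row[f"env_{key}"] = value if value is not None else float("nan")
    for s in model.solutes:
        if s.name == PROTON:
            continue
        row[f"cyt_{s.name}_mM"] = state.cytosol.concentration(s.name)
        row[f"vac_{s.name}_mM"] = state.vacuole.concentration(s.name)
        row[f"sub_{s.name}_mM"] = state.subdomain_mm.get(s.name, 0.0)
        row[f"amt_cyt_{s.name}_fmol"] = state.cytosol.amounts_fmol.get(
            s.name, 0.0)
        row[f"amt_vac_{s.name}_fmol"] = state.vacuole.amounts_fmol.get(
            s.name, 0.0)
    if rec is not None:
        row["dt_s"] = rec.dt_s
        row["i_pm_pA"] = rec.i_pm_pa
        row["i_tono_pA"] = rec.i_tono_pa
        for s, phi in rec.fluxes.pm_net.items():
            row[f"flux_net_pm_{s}_fmol_s"] = phi
        for s, phi in rec.fluxes.tono_net.items():
            row[f"flux_net_tono_{s}_fmol_s"] = phi
        if mode == "full":
            for name, fx in rec.fluxes.per_transporter.items():
                for s, phi in fx.items():
                    row[f"flux_{name}_{s}_fmol_s"] = phi
    return row


def run_simulation(model: ModelSpec, protocol: EnvironmentProtocol,
                   config: SimulationConfig,
                   _resume_from: Checkpoint | None = None) -> SimulationResult:
    """Run the computational cycle over a protocol.

    Deterministic: there is no randomness anywhere in the engine.  Solver
    faults are re-raised with the simulated-time stamp.  ``pause_at_s``
    (or the protocol's first preset pause inside the run window) stops the
    run at that simulated time and attaches a resumable checkpoint.
    """
    fatal = [v for v in validate_model(model) if v.level == "fatal"]
    if fatal:
        raise ModelError("invalid model: "
                         + "; ".join(v.message for v in fatal))

    if _resume_from is not None:
        state = _resume_from.state.clone()
        dt = _resume_from.dt_s
        clean = _resume_from.clean_steps
        log_initial = False
    else:
        t0 = model.elapsed_time_s or 0.0
        state = initial_state(model, protocol.environment(t0))
        state.time_s = t0
        dt = min(0.1, config.dt_max_s)
        clean = 0
        log_initial = True

    t_start = state.time_s
    t_end = t_start + config.duration_s
    pause_at = config.pause_at_s
    if pause_at is None:
        for p in sorted(protocol.pause_at):
            if t_start < p <= t_end:
                pause_at = p
                break
    if pause_at is not None and not (t_start < pause_at <= t_end):
        raise ValueError("pause time outside the run window")

    interval = config.log_interval_s
    # next log time on the absolute grid anchored at t_start
    n_logged = 0 if log_initial else int(round((t_start - 0.0) / interval))
    records: list[dict] = []
    ledger = Ledger()
    start_state = state.clone()

    if log_initial:
        env0 = protocol.environment(state.time_s)
        rec0 = None
        records.append(_record_row(model, state, env0, rec0, config.mode))
        next_log = t_start + interval
    else:
        next_log = (math.floor(t_start / interval + 0.5) + 1) * interval

    checkpoint = None
    while state.time_s < t_end - 1e-9:
        # cap dt to land exactly on log, pause and end times
        dt_cap = min(dt, t_end - state.time_s, next_log - state.time_s)
        if pause_at is not None:
            dt_cap = min(dt_cap, pause_at - state.time_s)
        dt_try = max(dt_cap, config.dt_min_s)
        env = protocol.environment(state.time_s)

        while True:
            try:
                new_state, rec = step_cell(model, state, env, dt_try,
                                           config.tonoplast_mode)
            except SolverFault as exc:
                if dt_try > config.dt_min_s * 1.0001:
                    dt_try = max(dt_try / 2.0, config.dt_min_s)
                    clean = 0
                    continue
                raise SolverFault(
                    f"t={state.time_s:.2f} s: {exc}") from exc
            m = rec.metrics
            ok = (m["dv_pm"] <= config.max_dv_mv
                  and m["frac_amount"] <= config.max_frac_change
                  and m["frac_volume"] <= config.max_frac_change
                  and m["dph"] <= config.max_dph)
            if ok or dt_try <= config.dt_min_s * 1.0001:
                break
            dt_try = max(dt_try / 2.0, config.dt_min_s)
            clean = 0

        state = new_state
        # ledgers use the applied fluxes and currents
        ledger.int_i_dt_pm_pa_s += rec.i_pm_pa * rec.dt_s
        ledger.int_abs_i_dt_pm_pa_s += abs(rec.i_pm_pa) * rec.dt_s
        ledger.int_i_dt_tono_pa_s += rec.i_tono_pa * rec.dt_s
        ledger.int_abs_i_dt_tono_pa_s += abs(rec.i_tono_pa) * rec.dt_s
        ledger.water_in_pl += rec.water_flux_pl_s * rec.dt_s
        for s in rec.fluxes.pm_net:
            if s == PROTON:
                continue
            total = (rec.fluxes.pm_net.get(s, 0.0)
                     + rec.fluxes.metabolic.get(s, 0.0))
            ledger.solute_in_fmol[s] = (ledger.solute_in_fmol.get(s, 0.0)
                                        + total * rec.dt_s)
            ledger.abs_solute_in_fmol[s] = (
                ledger.abs_solute_in_fmol.get(s, 0.0)
                + abs(total) * rec.dt_s)
        for s, phi in rec.fluxes.metabolic.items():
            if s not in rec.fluxes.pm_net:
                ledger.solute_in_fmol[s] = (ledger.solute_in_fmol.get(s, 0.0)
                                            + phi * rec.dt_s)
                ledger.abs_solute_in_fmol[s] = (
                    ledger.abs_solute_in_fmol.get(s, 0.0)
                    + abs(phi) * rec.dt_s)

        # controller bookkeeping: grid-capped steps do not count as breaches
        if rec.dt_s >= dt - 1e-12 or rec.dt_s >= dt_cap - 1e-12:
            clean += 1
        else:
            clean = 0
            dt = rec.dt_s
        if clean >= 10:
            dt = min(dt * 2.0, config.dt_max_s)
            clean = 0

        if state.time_s >= next_log - 1e-9:
            records.append(_record_row(model, state,
                                       protocol.environment(state.time_s),
                                       rec, config.mode))
            n_logged += 1
            next_log += interval
        if pause_at is not None and state.time_s >= pause_at - 1e-9:
            checkpoint = Checkpoint(model, state.clone(), dt, clean)
            break

    return SimulationResult(records, state, ledger, config, checkpoint,
                            start_state)


def resume_simulation(checkpoint: Checkpoint, protocol: EnvironmentProtocol,
                      config: SimulationConfig) -> SimulationResult:
    """Continue a paused run from its checkpoint.

    With an unedited model the spliced trajectory equals the uninterrupted
    run record for record (pause times on the log grid).  To test a
    parameter change, build an edited checkpoint with
    :meth:`Checkpoint.with_model` first; to restart the diurnal phase, set
    ``checkpoint.state.time_s`` back to zero.
    """
    return run_simulation(checkpoint.model, protocol, config,
                          _resume_from=checkpoint)


def write_csv(result: SimulationResult, path) -> None:
    """RFC-4180 CSV with unit-suffixed headers; numbers round-trip to 12
    significant digits; one row per log record in time order."""
    df = result.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g")


def write_checkpoint(checkpoint: Checkpoint, path) -> None:
    with open(path, "w") as fh:
        fh.write(checkpoint.to_json())


def read_checkpoint(path) -> Checkpoint:
    with open(path) as fh:
        return Checkpoint.from_json(fh.read())
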