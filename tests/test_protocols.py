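"""Diurnal tracks, node editing, the run loop, CSV logging, checkpointing."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from stomasim import (EnvironmentProtocol, Node, ProtocolTrack,
                      SimulationConfig, aba_pulse_protocol, default_protocol,
                      edit_track, evaluate_track, preset_co2_cycle,
                      read_checkpoint, resume_simulation, run_simulation,
                      write_checkpoint, write_csv)
from stomasim.protocols import ProtocolError


class TestTrackEvaluation:
    def test_preset_co2_cycle_mid_step_and_baseline(self):
        track = preset_co2_cycle()
        # middle of a 1 h elevated step -> 1000 ppm; baseline -> 400 ppm
        assert evaluate_track(track, 2.5 * 3600.0) == 1000.0
        assert evaluate_track(track, 6.5 * 3600.0) == 1000.0
        assert evaluate_track(track, 1.0 * 3600.0) == 400.0
        assert evaluate_track(track, 12.0 * 3600.0) == 400.0

    def test_aba_pulse_track_reads_1_um_mid_pulse(self):
        proto = aba_pulse_protocol(aba_um=1.0, start_h=4.0, end_h=6.0)
        track = proto.tracks["ABA"]
        assert evaluate_track(track, 5.0 * 3600.0) == 1.0
        assert evaluate_track(track, 3.0 * 3600.0) == 0.0
        assert evaluate_track(track, 7.0 * 3600.0) == 0.0

    def test_linear_segment_interpolates(self):
        track = ProtocolTrack("pCO2", [Node(0.0, 0.0, "linear"),
                                       Node(2 * 3600.0, 100.0)])
        assert evaluate_track(track, 3600.0) == pytest.approx(50.0)

    def test_wraps_at_24_h(self):
        track = preset_co2_cycle()
        assert evaluate_track(track, 2.5 * 3600.0 + 86400.0) == 1000.0

    def test_step_edges_continuous_from_the_right(self):
        track = ProtocolTrack("pCO2", [Node(0.0, 400.0),
                                       Node(3600.0, 1000.0)])
        assert evaluate_track(track, 3600.0) == 1000.0

    def test_empty_track_rejected(self):
        with pytest.raises(ProtocolError):
            ProtocolTrack("pCO2", [])

    def test_out_of_bounds_value_rejected(self):
        with pytest.raises(ProtocolError):
            ProtocolTrack("RH", [Node(0.0, 150.0)])


class TestTrackEditing:
    def test_set_flat_evaluates_constant_everywhere(self):
        track = edit_track(preset_co2_cycle(), "set_flat", 400.0)
        for h in (0, 2.5, 6.5, 13, 23.9):
            assert evaluate_track(track, h * 3600.0) == 400.0

    def test_add_then_delete_restores_original(self):
        track = preset_co2_cycle()
        edited = edit_track(track, "add_node", 5.5 * 3600.0, 800.0)
        restored = edit_track(edited, "delete_node", 5.5 * 3600.0)
        assert [(n.time_s, n.value) for n in restored.nodes] == \
            [(n.time_s, n.value) for n in track.nodes]

    def test_duplicate_node_time_rejected(self):
        track = preset_co2_cycle()
        t_existing = track.nodes[1].time_s
        with pytest.raises(ProtocolError):
            edit_track(track, "add_node", t_existing, 500.0)

    def test_move_to_occupied_time_rejected(self):
        track = preset_co2_cycle()
        with pytest.raises(ProtocolError):
            edit_track(track, "move_node", track.nodes[0].time_s,
                       track.nodes[1].time_s)

    def test_move_node_repositions(self):
        track = ProtocolTrack("pCO2", [Node(0.0, 400.0), Node(3600.0, 800.0)])
        moved = edit_track(track, "move_node", 3600.0, 7200.0)
        assert evaluate_track(moved, 5400.0) == 400.0
        assert evaluate_track(moved, 7300.0) == 800.0


class TestConfig:
    def test_mode_sets_default_log_interval(self):
        assert SimulationConfig(100.0, mode="full").log_interval_s == 10.0
        assert SimulationConfig(100.0, mode="fast").log_interval_s == 60.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(0.0)
        with pytest.raises(ValueError):
            SimulationConfig(10.0, mode="turbo")
        with pytest.raises(ValueError):
            SimulationConfig(10.0, log_interval_s=1e-6)


@pytest.fixture(scope="module")
def short_run(base_model):
    cfg = SimulationConfig(duration_s=600.0, mode="full", log_interval_s=60.0)
    return run_simulation(base_model, default_protocol(), cfg)


class TestRunSimulation:
    def test_first_record_is_the_initial_state(self, short_run):
        df = short_run.to_dataframe()
        assert df["time_s"].iloc[0] == 0.0
        first = df.iloc[0]
        assert first["aperture_um"] == pytest.approx(
            short_run.start_state.mech.aperture_um)

    def test_logs_on_the_interval_grid(self, short_run):
        times = short_run.to_dataframe()["time_s"].to_numpy()
        assert np.all(np.diff(times) > 0)
        assert np.allclose(times, np.arange(len(times)) * 60.0)

    def test_fast_and_full_modes_share_the_physics(self, base_model):
        """Run Fast differs only in logging: the trajectory is identical."""
        proto = default_protocol()
        full = run_simulation(base_model, proto,
                              SimulationConfig(300.0, mode="full",
                                               log_interval_s=60.0))
        fast = run_simulation(base_model, proto,
                              SimulationConfig(300.0, mode="fast",
                                               log_interval_s=60.0))
        assert full.final_state.pm.voltage_mv == \
            fast.final_state.pm.voltage_mv
        assert full.final_state.cytosol.amounts_fmol == \
            fast.final_state.cytosol.amounts_fmol
        full_cols = set(full.to_dataframe().columns)
        fast_cols = set(fast.to_dataframe().columns)
        assert any(c.startswith("flux_pm_h_atpase") for c in full_cols)
        assert not any(c.startswith("flux_pm_h_atpase") for c in fast_cols)

    def test_repeated_runs_bitwise_identical(self, base_model):
        cfg = SimulationConfig(300.0, mode="fast", log_interval_s=60.0)
        r1 = run_simulation(base_model, default_protocol(), cfg)
        r2 = run_simulation(base_model, default_protocol(), cfg)
        assert r1.records == r2.records

    def test_elapsed_time_in_model_offsets_the_clock(self, base_model):
        m = copy.deepcopy(base_model)
        m.elapsed_time_s = 6 * 3600.0
        cfg = SimulationConfig(120.0, mode="fast", log_interval_s=60.0)
        res = run_simulation(m, default_protocol(), cfg)
        assert res.start_state.time_s == 6 * 3600.0


class TestCheckpoint:
    def test_pause_resume_splices_identically(self, base_model):
        """Pause/resume with no edits equals the uninterrupted run record
        for record."""
        proto = default_protocol()
        cfg = SimulationConfig(600.0, mode="fast", log_interval_s=60.0)
        whole = run_simulation(base_model, proto, cfg)
        first = run_simulation(base_model, proto,
                               SimulationConfig(600.0, mode="fast",
                                                log_interval_s=60.0,
                                                pause_at_s=300.0))
        assert first.checkpoint is not None
        second = resume_simulation(first.checkpoint, proto,
                                   SimulationConfig(300.0, mode="fast",
                                                    log_interval_s=60.0))
        spliced = first.records + second.records
        assert spliced == whole.records

    def test_checkpoint_file_round_trip_resumes_identically(self, base_model,
                                                            tmp_path):
        proto = default_protocol()
        first = run_simulation(base_model, proto,
                               SimulationConfig(240.0, mode="fast",
                                                log_interval_s=60.0,
                                                pause_at_s=120.0))
        path = tmp_path / "ckpt.json"
        write_checkpoint(first.checkpoint, path)
        restored = read_checkpoint(path)
        cfg = SimulationConfig(120.0, mode="fast", log_interval_s=60.0)
        a = resume_simulation(first.checkpoint, proto, cfg)
        b = resume_simulation(restored, proto, cfg)
        assert a.records == b.records

    def test_paused_edit_changes_only_the_future(self, base_model):
        proto = default_protocol()
        paused = run_simulation(base_model, proto,
                                SimulationConfig(600.0, mode="fast",
                                                 log_interval_s=60.0,
                                                 pause_at_s=300.0))
        edited_model = copy.deepcopy(base_model)
        edited_model.transporter("pm_cl_channel").population *= 4.0
        edited = paused.checkpoint.with_model(edited_model)
        cfg = SimulationConfig(300.0, mode="fast", log_interval_s=60.0)
        plain = resume_simulation(paused.checkpoint, proto, cfg)
        changed = resume_simulation(edited, proto, cfg)
        assert plain.records[-1] != changed.records[-1]

    def test_edit_removing_a_state_solute_rejected(self, base_model):
        from stomasim import ModelError, strip_aba
        paused = run_simulation(base_model, default_protocol(),
                                SimulationConfig(180.0, mode="fast",
                                                 log_interval_s=60.0,
                                                 pause_at_s=120.0))
        broken = copy.deepcopy(base_model)
        broken.solutes = [s for s in broken.solutes if s.name != "Suc"]
        broken.transporters = [
            t for t in broken.transporters
            if not any(leg.solute == "Suc" for leg in t.transported)]
        for comp in broken.compartments.values():
            comp.pop("Suc", None)
        with pytest.raises(ModelError, match="Suc"):
            paused.checkpoint.with_model(broken)

    def test_resetting_elapsed_time_restarts_the_protocol_phase(
            self, aba_model):
        """A checkpoint resumed after zeroing its clock re-enters the
        diurnal cycle at hour 0 (here: before the ABA pulse)."""
        proto = aba_pulse_protocol()
        m = copy.deepcopy(aba_model)
        m.elapsed_time_s = 4.5 * 3600.0   # inside the 4-6 h ABA pulse
        paused = run_simulation(m, proto,
                                SimulationConfig(240.0, mode="fast",
                                                 log_interval_s=120.0,
                                                 pause_at_s=4.5 * 3600 + 120))
        assert paused.records[-1]["env_aba"] == 1.0
        ckpt = paused.checkpoint
        ckpt.state.time_s = 0.0
        restarted = resume_simulation(ckpt, proto,
                                      SimulationConfig(240.0, mode="fast",
                                                       log_interval_s=120.0))
        assert restarted.records[-1]["env_aba"] == 0.0


class TestCSV:
    def test_write_read_numerically_identical(self, short_run, tmp_path):
        path = tmp_path / "run.csv"
        write_csv(short_run, path)
        df0 = short_run.to_dataframe()
        df1 = pd.read_csv(path)
        assert list(df0.columns) == list(df1.columns)
        for col in df0.columns:
            a, b = df0[col].to_numpy(float), df1[col].to_numpy(float)
            mask = ~np.isnan(a)
            assert np.allclose(a[mask], b[mask], rtol=1e-11, atol=1e-300)
            assert np.isnan(b[~mask]).all()

    def test_time_column_strictly_increasing(self, short_run, tmp_path):
        path = tmp_path / "run.csv"
        write_csv(short_run, path)
        t = pd.read_csv(path)["time_s"]
        assert (t.diff().dropna() > 0).all()
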