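"""Protocols, electrode calibration, file round trips, pipeline and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from cpgph import (CONTROL_PH, PH_LADDER_11C, PHProtocol, PHStep,
                   build_protocol, calibrate_electrode, generate_experiment,
                   nernst_slope_mv, ph_to_voltage, voltage_to_ph)
from cpgph.cli import main as cli_main
from cpgph.io import (read_annotation_csv, read_events_csv, read_experiment_h5,
                      read_trace_csv, write_annotation_bed, write_annotation_csv,
                      write_events_csv, write_experiment_h5, write_trace_csv)
from cpgph.pipeline import StageError, run_pipeline
from cpgph.states import StateAnnotation


class TestCalibration:
    def ideal_points(self, temp, ph_values, offset=120.0):
        k = nernst_slope_mv(temp)
        return [(p, offset - k * p, temp) for p in ph_values]

    def test_nernst_slope_at_25C(self):
        model = calibrate_electrode(self.ideal_points(25.0, [4.0, 7.0, 10.0]))
        assert abs(model.slope_mv_per_ph(25.0)) == pytest.approx(59.16, abs=0.01)

    def test_slope_scales_with_absolute_temperature(self):
        m25 = calibrate_electrode(self.ideal_points(25.0, [4.0, 10.0]))
        m11 = calibrate_electrode(self.ideal_points(11.0, [4.0, 10.0]))
        ratio = m11.slope_mv_per_ph(11.0) / m25.slope_mv_per_ph(25.0)
        assert ratio == pytest.approx(284.15 / 298.15, rel=1e-9)

    def test_symmetric_points_isopotential_at_seven(self):
        k = nernst_slope_mv(20.0)
        model = calibrate_electrode([(4.0, 3 * k, 20.0), (10.0, -3 * k, 20.0)])
        assert voltage_to_ph(model, 0.0, 20.0) == pytest.approx(7.0)

    def test_round_trip_identity(self, rng):
        model = calibrate_electrode(self.ideal_points(11.0, [4.0, 7.0, 10.0]))
        ph = rng.uniform(4, 11, 100)
        back = voltage_to_ph(model, ph_to_voltage(model, ph, 11.0), 11.0)
        assert np.allclose(back, ph, atol=1e-9)

    def test_ph_decreases_with_voltage_for_cation_convention(self):
        model = calibrate_electrode(self.ideal_points(25.0, [4.0, 10.0]))
        sweep = voltage_to_ph(model, np.linspace(-200, 200, 50), 25.0)
        assert np.all(np.diff(sweep) < 0)

    def test_degenerate_and_unfitted_errors(self):
        with pytest.raises(ValueError):
            calibrate_electrode([(7.0, 0.0, 25.0), (7.0, 5.0, 25.0)])
        from cpgph import CalibrationModel
        with pytest.raises(RuntimeError):
            voltage_to_ph(CalibrationModel(), 0.0, 25.0)


class TestProtocol:
    def test_acid_ladder_labels(self):
        prot = build_protocol("acid_first", 5.5)
        assert [s.ph for s in prot.steps] == [7.8, 7.2, 6.7, 6.1, 5.5, 7.8]
        assert [s.role for s in prot.steps] == \
            ["control"] + ["step"] * 4 + ["recovery"]

    def test_base_ladder_has_six_steps(self):
        prot = build_protocol("base_first", 10.4)
        assert len(prot.steps) == 7  # control + 5 graded + recovery
        assert {s.ph for s in prot.steps} <= set(PH_LADDER_11C)

    def test_duration_conserved(self):
        prot = build_protocol("acid_first", 5.5, recovery_duration=2000.0)
        assert prot.duration == sum(s.duration for s in prot.steps)
        windows = prot.step_windows()
        assert windows[0][0] == 0.0 and windows[-1][1] == prot.duration

    def test_analysis_windows_are_last_eight_minutes(self):
        prot = build_protocol("acid_first", 5.5)
        for (w0, w1), (t0, t1) in zip(prot.analysis_windows(480.0),
                                      prot.step_windows()):
            assert w1 == t1 and w1 - w0 == 480.0

    def test_direction_sign_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_protocol("acid_first", 10.4)
        with pytest.raises(ValueError):
            PHProtocol((PHStep(6.0, 900.0, "step"),))

    def test_control_reference(self):
        assert CONTROL_PH == 7.8


class TestFileFormats:
    def test_trace_csv_round_trip(self, tmp_path, clean_burster):
        _, trace = clean_burster
        path = tmp_path / "trace.csv"
        sub = trace.slice(0.0, 2.0)
        write_trace_csv(sub, path)
        back = read_trace_csv(path, "PD")
        assert back.sample_rate == pytest.approx(sub.sample_rate, rel=1e-6)
        assert np.allclose(back.samples, sub.samples)

    def test_events_csv_round_trip(self, tmp_path):
        exp = generate_experiment("STG", seed=0)
        path = tmp_path / "events.csv"
        write_events_csv(exp.spike_trains, path)
        back = read_events_csv(path)
        assert set(back) == {"PD", "LP", "PY"}
        for u in back:
            assert np.allclose(back[u].times, exp.spike_trains[u].times)

    def test_experiment_h5_round_trip(self, tmp_path):
        exp = generate_experiment("CG", seed=5)
        path = tmp_path / "exp.h5"
        write_experiment_h5(exp, path)
        back = read_experiment_h5(path)
        assert back.ganglion == "CG" and back.seed == 5
        assert len(back.ground_truth) == len(exp.ground_truth)
        for a, b in zip(back.ground_truth, exp.ground_truth):
            assert a.state == b.state and a.params == b.params
            assert a.step.ph == b.step.ph
        for u in exp.spike_trains:
            assert np.allclose(back.spike_trains[u].times,
                               exp.spike_trains[u].times)

    def test_annotation_csv_and_bed(self, tmp_path):
        ann = StateAnnotation([("normal_triphasic", 0.0, 30.0),
                               ("all_silent", 30.0, 48.0)], (0.0, 48.0))
        cpath = tmp_path / "ann.csv"
        write_annotation_csv(ann, cpath)
        assert read_annotation_csv(cpath).segments == ann.segments
        bpath = tmp_path / "ann.bed"
        write_annotation_bed(ann, bpath)
        lines = bpath.read_text().splitlines()
        assert lines[0].split("\t") == ["rhythm", "0", "30000", "normal_triphasic"]


class TestPipeline:
    CFG = {"experiment": {"n_preparations": 3, "seed": 3}}

    def test_all_stages_complete_and_deterministic(self, tmp_path):
        m1 = run_pipeline(self.CFG, out_dir=tmp_path / "a")
        assert all(v == "completed" for v in m1["stages"].values())
        assert len(m1["stages"]) == 6
        m2 = run_pipeline(self.CFG, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "metrics.csv").read_bytes() == \
            (tmp_path / "b" / "metrics.csv").read_bytes()
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["config"]["experiment"]["seed"] == 3
        dc = manifest["detect_check"]
        assert dc["n_detected"] == dc["n_ground_truth"]

    def test_bad_input_aborts_with_stage_named_error(self, tmp_path):
        cfg = {"experiment": {"source": str(tmp_path / "missing.h5")}}
        with pytest.raises(StageError, match="simulate"):
            run_pipeline(cfg, out_dir=tmp_path / "out")
        marker = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert marker["stages"]["simulate"] == "failed"


class TestCli:
    def test_simulate_classify_round_trip(self, tmp_path):
        runner = CliRunner()
        h5 = tmp_path / "exp.h5"
        r = runner.invoke(cli_main, ["simulate", "--ganglion", "STG",
                                     "--seed", "1", "--out", str(h5)])
        assert r.exit_code == 0, r.output
        exp = read_experiment_h5(h5)
        ev = tmp_path / "events.csv"
        write_events_csv(exp.spike_trains, ev)
        ann = tmp_path / "ann.csv"
        r = runner.invoke(cli_main, ["classify", "--events", str(ev),
                                     "--ganglion", "STG", "--window", "420",
                                     "900", "--out", str(ann)])
        assert r.exit_code == 0, r.output
        assert read_annotation_csv(ann).segments[0][0] == "normal_triphasic"

    def test_detect_on_trace_csv(self, tmp_path, clean_burster):
        params, trace = clean_burster
        tr = tmp_path / "trace.csv"
        write_trace_csv(trace.slice(0.0, 5.0), tr)
        out = tmp_path / "spikes.csv"
        thr = params.v_min + params.slow_amplitude + 0.5 * params.spike_amplitude
        runner = CliRunner()
        r = runner.invoke(cli_main, ["detect", "--trace", str(tr),
                                     "--threshold", str(thr), "--label", "PD",
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(read_events_csv(out)["PD"]) == 25
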