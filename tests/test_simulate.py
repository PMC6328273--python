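"""Synthetic-recording generator: waveform geometry, pH modulation,
experiment assembly, and the metric-level generators."""

import numpy as np
import pandas as pd
import pytest

from cpgph import (BursterParams, InfeasibleParametersError, PHProtocol, PHStep,
                   apply_ph_response, build_protocol, burst_event_times,
                   default_cardiac_curves, default_pyloric_curve,
                   generate_burster_trace, generate_experiment,
                   generate_null_dataset, sample_population)
from cpgph.simulate import generate_correlated_frequencies


class TestBursterTrace:
    def test_sample_count_is_duration_times_rate(self):
        tr = generate_burster_trace(BursterParams(), 10.0, 10_000.0)
        assert len(tr) == 100_000

    def test_noiseless_spike_count_by_brute_force_crossings(self):
        """A 1 Hz burster with 5 spikes/burst must show exactly 50 upward
        threshold crossings in 10 s, counted directly on the raw samples."""
        p = BursterParams(burst_frequency=1.0, spikes_per_burst=5, noise_sd=0.0)
        v = generate_burster_trace(p, 10.0, 10_000.0).samples
        thr = p.v_min + p.slow_amplitude + 0.5 * p.spike_amplitude
        crossings = np.sum((v[:-1] < thr) & (v[1:] >= thr))
        assert crossings == 50

    def test_noiseless_extrema_forced_by_additive_construction(self):
        p = BursterParams(slow_amplitude=20.0, spike_amplitude=10.0,
                          v_min=-55.0, noise_sd=0.0)
        v = generate_burster_trace(p, 10.0, 10_000.0).samples
        assert v.min() == pytest.approx(-55.0, abs=1e-9)
        assert v.max() == pytest.approx(-25.0, abs=1e-9)

    def test_identical_seed_and_params_bit_identical(self):
        a = generate_burster_trace(BursterParams(), 5.0, 10_000.0, seed=7)
        b = generate_burster_trace(BursterParams(), 5.0, 10_000.0, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_spike_span_equals_duty_cycle(self):
        """First-to-last spike span of each burst equals duty * period."""
        p = BursterParams(duty_cycle=0.3, noise_sd=0.0)
        spikes, plateaus = burst_event_times(p, 10.0)
        spikes = spikes.reshape(10, 5)
        assert np.allclose(spikes[:, -1] - spikes[:, 0], 0.3)
        assert len(plateaus) == 10

    @pytest.mark.parametrize("kw", [dict(duration=0.0), dict(sample_rate=500.0)])
    def test_invalid_arguments_rejected(self, kw):
        args = dict(duration=1.0, sample_rate=10_000.0)
        args.update(kw)
        with pytest.raises(ValueError):
            generate_burster_trace(BursterParams(), args["duration"],
                                   args["sample_rate"])

    def test_infeasible_spike_packing_rejected(self):
        p = BursterParams(burst_frequency=1.0, duty_cycle=0.3,
                          spikes_per_burst=200)
        with pytest.raises(InfeasibleParametersError):
            generate_burster_trace(p, 1.0, 10_000.0)


class TestPHResponse:
    def test_identity_at_reference_ph(self):
        base = BursterParams(burst_frequency=1.3, duty_cycle=0.22,
                             spikes_per_burst=7, v_min=-61.0)
        out = apply_ph_response(base, default_pyloric_curve(), 7.8)
        assert out == base

    def test_default_pyloric_curve_silences_extreme_acid(self):
        assert default_pyloric_curve().state_at(5.5) == "all_silent"

    def test_frequency_non_increasing_into_base(self):
        curve = default_pyloric_curve()
        freqs = [apply_ph_response(BursterParams(), curve, ph).burst_frequency
                 for ph in (7.8, 8.3, 8.8, 9.3, 9.8, 10.4)]
        assert all(a >= b for a, b in zip(freqs[:-1], freqs[1:]))

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValueError):
            apply_ph_response(BursterParams(), default_pyloric_curve(), 4.9)


class TestExperiment:
    def test_step_bookkeeping(self):
        steps = tuple([PHStep(7.8, 900.0, "control")] +
                      [PHStep(ph, 900.0, "step")
                       for ph in (7.2, 6.7, 6.1, 5.5, 6.1, 6.7)])
        protocol = PHProtocol(steps, "acid_first")
        exp = generate_experiment("STG", protocol, seed=0)
        assert protocol.duration == 105 * 60
        assert len(exp.ground_truth) == 7

    def test_pd_lp_onsets_antiphase(self):
        """PD and LP burst onsets never coincide within 5% of the period."""
        exp = generate_experiment("STG", seed=1)
        gt = exp.ground_truth[0]  # control step, mid-range pH
        period = gt.params["PD"].period
        pd_on, _ = burst_event_times(gt.params["PD"], gt.t_end - gt.t_start)
        lp_on, _ = burst_event_times(gt.params["LP"], gt.t_end - gt.t_start)
        pd_onsets = pd_on.reshape(-1, gt.params["PD"].spikes_per_burst)[:, 0]
        lp_onsets = lp_on.reshape(-1, gt.params["LP"].spikes_per_burst)[:, 0]
        for onset in pd_onsets:
            assert np.min(np.abs(lp_onsets - onset)) > 0.05 * period

    def test_sc_only_step_has_zero_lc_spikes(self):
        exp = generate_experiment("CG", build_protocol("base_first", 10.4), seed=2)
        for gt in exp.ground_truth:
            lc = exp.spike_trains["LC"].between(gt.t_start, gt.t_end)
            if gt.state in ("sc_only", "all_silent"):
                assert len(lc) == 0
            elif gt.state == "sc_lc_bursting":
                assert len(lc) > 0

    def test_sc_bursts_carry_lc_spikes_when_co_bursting(self):
        exp = generate_experiment("CG", seed=3)
        gt = exp.ground_truth[0]
        assert gt.state == "sc_lc_bursting"
        lc = exp.spike_trains["LC"].between(gt.t_start, gt.t_end).times
        _, plateaus = burst_event_times(gt.params["SC"],
                                        gt.t_end - gt.t_start, gt.t_start)
        for (f0, f1) in plateaus:
            assert np.any((lc >= f0) & (lc <= f1))

    def test_mismatched_unit_labels_rejected(self):
        with pytest.raises(ValueError):
            generate_experiment("CG", base_params={"PD": BursterParams()})

    def test_render_trace_matches_events(self):
        """The rendered voltage trace and the analytic event list agree."""
        from cpgph import ThresholdSpec, detect_spikes

        exp = generate_experiment("STG", seed=4)
        gt = exp.ground_truth[0]
        tr = exp.render_trace("PD", gt.t_start, gt.t_start + 30.0, 10_000.0)
        p = gt.params["PD"]
        detected = detect_spikes(
            tr, ThresholdSpec(p.v_min + p.slow_amplitude + 0.5 * p.spike_amplitude))
        truth = exp.spike_trains["PD"].between(gt.t_start, gt.t_start + 30.0)
        assert len(detected) == len(truth)
        assert np.allclose(detected.times, truth.times, atol=1e-3)

    def test_population_spread_and_determinism(self):
        pop = sample_population("STG", 5, cv=0.2, seed=9)
        again = sample_population("STG", 5, cv=0.2, seed=9)
        assert pop == again
        freqs = [p["PD"].burst_frequency for p in pop]
        assert len(set(freqs)) == 5


class TestMetricLevelGenerators:
    def test_null_dataset_shape_and_balance(self):
        df = generate_null_dataset(15, 6, seed=0)
        assert len(df) == 90
        assert df.groupby("preparation")["condition"].count().eq(6).all()

    def test_null_dataset_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_null_dataset(2, 6)
        with pytest.raises(ValueError):
            generate_null_dataset(10, 1)

    def test_condition_effect_is_recovered(self):
        eff = np.array([0.0, 0.0, 5.0])
        df = generate_null_dataset(200, 3, effect=eff, seed=1)
        means = df.groupby("condition")["value"].mean()
        assert means["cond2"] - means["cond0"] == pytest.approx(5.0, abs=0.3)

    def test_correlated_frequencies_match_programmed_rho(self):
        rs = []
        for s in range(200):
            d = generate_correlated_frequencies(200, rho=0.8, seed=s)
            rs.append(np.corrcoef(d.baseline, d.extreme)[0, 1])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.02)
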