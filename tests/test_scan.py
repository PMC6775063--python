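"""Scan command generation, tuning, slice timing and frame budgets."""

import numpy as np
import pytest

from sheetscan import scan, synth
from sheetscan.scan import (
    ScanSpec,
    Waveform,
    frame_budget,
    interpolate_stack_pairs,
    make_triangle,
    plan_pulses,
    slice_times_from_sensor,
    smooth_command,
    tune_range,
)


class TestScanSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScanSpec(100, 100, 10, 10000, 5)
        with pytest.raises(ValueError):
            ScanSpec(0, 200, 10, 500, 5)  # sample rate too low
        with pytest.raises(ValueError):
            ScanSpec(0, 200, 10, 10000, 7)  # spacing does not divide range

    def test_plane_count_200um_5um(self):
        spec = ScanSpec(0, 200, 10, 10000, 5)
        assert spec.n_planes == 40


class TestTriangle:
    def test_geometry(self, scan_spec_700):
        tri = make_triangle(scan_spec_700)
        assert tri.peak_to_peak == pytest.approx(700.0)
        assert tri.period_samples == scan_spec_700.sample_rate / 20
        assert tri.one_period().mean() == pytest.approx(350.0)
        assert tri.samples[0] == pytest.approx(0.0)


class TestSmoothCommand:
    def test_range_restored(self, scan_spec_200):
        tri = make_triangle(scan_spec_200)
        result = smooth_command(tri)
        assert abs(result.waveform.peak_to_peak - 200.0) <= 0.1
        assert result.iterations >= 1

    def test_high_cutoff_is_identity(self, scan_spec_200):
        tri = make_triangle(scan_spec_200)
        result = smooth_command(tri, cutoff_factor=1e4)
        assert np.allclose(result.waveform.samples, tri.samples, atol=1e-9)

    def test_spectral_content_suppressed(self, scan_spec_200):
        """Above-cutoff harmonics sit at least 40 dB below the fundamental."""
        result = smooth_command(make_triangle(scan_spec_200))
        cycle = result.waveform.one_period()
        spectrum = np.abs(np.fft.rfft(cycle - cycle.mean()))
        fundamental = spectrum[1]
        cutoff_bin = int(np.ceil(3.25)) + 1
        assert spectrum[cutoff_bin + 1 :].max() < fundamental * 10 ** (-40 / 20)


class TestTuneRange:
    def test_unity_plant_converges_fast(self, unity_plant, scan_spec_700):
        result = tune_range(unity_plant, scan_spec_700)
        assert result.iterations <= 5
        last = result.history.iloc[-1]
        assert abs(last["error_lo_um"]) <= 0.1
        assert abs(last["error_hi_um"]) <= 0.1

    def test_simulated_plant_within_five_iterations(self, plant, scan_spec_700):
        result = tune_range(
            lambda c: synth.simulate_piezo(plant, c)[0], scan_spec_700
        )
        assert result.iterations <= 5

    def test_geometric_error_decay(self, unity_plant, scan_spec_700):
        """With unity gain the 90% correction shrinks the error 10x/iteration."""
        result = tune_range(unity_plant, scan_spec_700, tolerance=1e-6)
        errs = result.history["error_hi_um"].abs().to_numpy()
        ratios = errs[1:] / errs[:-1]
        assert np.all(ratios < 0.12)

    def test_trivial_tolerance_single_iteration(self, unity_plant, scan_spec_200):
        result = tune_range(unity_plant, scan_spec_200, tolerance=np.inf)
        assert result.iterations == 1

    @pytest.mark.parametrize("gain", [0.5, 0.8, 1.2, 1.5])
    def test_linear_gain_plants_converge(self, gain, scan_spec_200):
        def plant(command):
            center = 0.5 * (command.samples.max() + command.samples.min())
            return Waveform(
                center + gain * (command.samples - center),
                command.sample_rate,
                command.period_samples,
            )

        result = tune_range(plant, scan_spec_200)
        errs = np.maximum(
            result.history["error_lo_um"].abs(), result.history["error_hi_um"].abs()
        ).to_numpy()
        assert np.all(np.diff(errs[1:]) <= 1e-9)  # monotone after iteration 1


class TestSliceTimes:
    def test_perfect_triangle_uniform_intervals(self, scan_spec_200):
        tri = make_triangle(scan_spec_200)
        plan = slice_times_from_sensor(tri, scan_spec_200)
        for direction in ("forward", "reverse"):
            times = plan.direction(direction)["crossing_time_s"].to_numpy()
            gaps = np.diff(times)
            assert np.allclose(gaps, gaps[0], rtol=1e-6)
        assert len(plan.planes) == 40

    def test_smoothed_sensor_longest_interval_at_extremes(self, scan_spec_200):
        sensor = smooth_command(make_triangle(scan_spec_200)).waveform
        plan = slice_times_from_sensor(sensor, scan_spec_200)
        fwd = plan.direction("forward")["crossing_time_s"].to_numpy()
        gaps = np.diff(fwd)
        edge = max(gaps[0], gaps[-1])
        assert edge == gaps.max()
        assert gaps.min() < edge

    def test_symmetric_crossings_about_apex(self, scan_spec_200):
        """Forward/reverse crossings of one plane mirror about the maximum."""
        sensor = smooth_command(make_triangle(scan_spec_200)).waveform
        plan = slice_times_from_sensor(sensor, scan_spec_200)
        cycle = sensor.one_period()
        t_apex = (np.argmax(np.roll(cycle, -np.argmin(cycle))) + np.argmin(cycle)) / sensor.sample_rate
        fwd = plan.direction("forward").set_index("slice_index")["crossing_time_s"]
        rev = plan.direction("reverse").set_index("slice_index")["crossing_time_s"]
        for k in fwd.index:
            assert (t_apex - fwd[k]) == pytest.approx(rev[k] - t_apex, abs=2e-4)

    def test_ringing_sensor_rejected(self, scan_spec_200):
        tri = make_triangle(scan_spec_200)
        # ringing steep enough to reverse the sweep locally
        wob = tri.samples + 10.0 * np.sin(
            2 * np.pi * 120 * np.arange(tri.samples.size) / tri.sample_rate
        )
        bad = Waveform(wob, tri.sample_rate, tri.period_samples)
        with pytest.raises(ValueError):
            slice_times_from_sensor(bad, scan_spec_200)

    def test_plane_outside_range_rejected(self, scan_spec_200):
        tri = make_triangle(scan_spec_200, z_min=20.0, z_max=180.0)
        with pytest.raises(ValueError):
            slice_times_from_sensor(tri, scan_spec_200)


class TestInterpolation:
    def test_mean_and_count(self):
        rng = np.random.default_rng(0)
        stacks = [rng.random((3, 4, 4)) for _ in range(6)]
        virtual = interpolate_stack_pairs(stacks)
        assert len(virtual) == 5
        assert np.allclose(virtual[2], 0.5 * (stacks[2] + stacks[3]))
        # pairwise intensity conservation (mean property)
        for v, a, b in zip(virtual, stacks[:-1], stacks[1:]):
            assert v.sum() == pytest.approx(0.5 * (a.sum() + b.sum()))

    def test_identical_stacks_passthrough(self):
        s = np.ones((2, 3, 3)) * 7
        assert np.array_equal(interpolate_stack_pairs([s, s])[0], s)

    def test_scalar_example(self):
        a = np.full((1, 1, 1), 10.0)
        b = np.full((1, 1, 1), 20.0)
        assert interpolate_stack_pairs([a, b])[0].item() == 15.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            interpolate_stack_pairs([np.ones((2, 2)), np.ones((3, 3))])
        with pytest.raises(ValueError):
            interpolate_stack_pairs([np.ones((2, 2))])

    def test_timestamps_at_transitions(self):
        stacks = [np.ones((2, 2)) * i for i in range(4)]
        virtual, times = interpolate_stack_pairs(stacks, timestamps=[0.0, 0.05, 0.1, 0.15])
        assert np.allclose(times, [0.025, 0.075, 0.125])


class TestPulses:
    def test_paper_exposure_example(self):
        """580 us exposure at 5% gives a ~30 us pulse at the exposure end."""
        sched = plan_pulses(580e-6, 640e-6, 9.76e-6, 0.05)
        assert sched.pulse_duration == pytest.approx(29e-6, rel=0.05)
        assert sched.pulse_offset_in_exposure + sched.pulse_duration == pytest.approx(
            580e-6
        )

    def test_max_rate_has_no_global_window(self):
        with pytest.raises(ValueError):
            plan_pulses(9.76e-6, 9.76e-6, 9.76e-6, 0.05)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            plan_pulses(580e-6, 640e-6, 9.76e-6, 0.0)

    def test_pulse_must_fit_global_window(self):
        # exposure barely above minimum: 5% pulse exceeds the window
        with pytest.raises(ValueError):
            plan_pulses(10.0e-6, 12e-6, 9.76e-6, 0.05)


class TestFrameBudget:
    def test_perfect_triangle_zero_idle(self, scan_spec_200):
        tri = make_triangle(scan_spec_200)
        plan = slice_times_from_sensor(tri, scan_spec_200)
        fb = frame_budget(plan, scan_spec_200)
        assert fb.idle_fraction == pytest.approx(0.0, abs=1e-6)
        assert fb.uniform_interval == pytest.approx(1.25e-3)

    def test_average_scan_speed(self, scan_spec_700):
        tri = make_triangle(scan_spec_700)
        plan = slice_times_from_sensor(tri, scan_spec_700)
        fb = frame_budget(plan, scan_spec_700)
        assert fb.avg_scan_speed == pytest.approx(28.0)

    def test_speed_ratio_vs_prior_art(self):
        prior = ScanSpec(0, 200, 5, 10000, 5)
        tri = make_triangle(prior)
        fb = frame_budget(slice_times_from_sensor(tri, prior), prior)
        assert fb.avg_scan_speed == pytest.approx(2.0)
        assert 28.0 / fb.avg_scan_speed == pytest.approx(14.0)

    def test_smoothed_waveform_has_idle_time(self, scan_spec_200):
        sensor = smooth_command(make_triangle(scan_spec_200)).waveform
        plan = slice_times_from_sensor(sensor, scan_spec_200)
        fb = frame_budget(plan, scan_spec_200)
        assert 0.0 < fb.idle_fraction < 1.0
        assert fb.min_interval < fb.uniform_interval
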