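"""dF/F, spectra, heartbeat detection/removal and correlation bias."""

import numpy as np
import pytest

from sheetscan import synth, traces
from sheetscan.traces import (
    HeartbeatModel,
    TraceMatrix,
    compute_dff,
    correlation_delta,
    detect_heartbeat,
    filter_traces,
    sliding_roi_psd,
    welch_psd,
)


@pytest.fixture(scope="module")
def contaminated():
    """Heartbeat-contaminated recording at the standard conditions
    (20 Hz, 20 min, 2.5 Hz fundamental)."""
    spec = synth.ArtifactTraceSpec(seed=3)
    observed, clean, artifact = synth.make_heartbeat_traces(spec)
    return spec, observed, clean, artifact


@pytest.fixture(scope="module")
def heartbeat_model(contaminated):
    _, observed, _, _ = contaminated
    return detect_heartbeat(welch_psd(observed, 2048))


class TestDff:
    def test_constant_trace_is_zero(self):
        tm = TraceMatrix(np.full((2, 2000), 50.0), fs=20.0)
        dff = compute_dff(tm)
        assert np.allclose(dff.values, 0.0)

    def test_step_amplitude(self):
        """A brief +10% step on a constant baseline peaks near dF/F = 0.10."""
        fs = 20.0
        n = int(200 * fs)
        values = np.full((1, n), 100.0)
        start = n // 2
        values[0, start : start + int(2 * fs)] = 110.0  # 2 s transient
        dff = compute_dff(TraceMatrix(values, fs))
        # the moving average absorbs 2/60 of the step; closed form:
        peak_expected = (110.0 - (100 + 10 * 2 / 60.0)) / (100 + 10 * 2 / 60.0)
        assert dff.values.max() == pytest.approx(peak_expected, rel=0.02)

    def test_edges_trimmed(self):
        fs = 20.0
        tm = TraceMatrix(np.full((1, int(120 * fs)), 10.0), fs)
        dff = compute_dff(tm, baseline_window=60.0)
        assert dff.n_timepoints == tm.n_timepoints - int(60 * fs) + 1

    def test_nonpositive_baseline_rejected(self):
        tm = TraceMatrix(np.zeros((1, 4000)), fs=20.0)
        with pytest.raises(ValueError):
            compute_dff(tm)

    def test_short_recording_rejected(self):
        tm = TraceMatrix(np.ones((1, 100)), fs=20.0)
        with pytest.raises(ValueError):
            compute_dff(tm, baseline_window=60.0)


class TestWelch:
    def test_single_tone_at_right_bin(self):
        fs = 20.0
        t = np.arange(8192) / fs
        tm = TraceMatrix(np.sin(2 * np.pi * 2.5 * t)[None, :], fs)
        spec = welch_psd(tm, 2048)
        peak = spec.frequencies[np.argmax(spec.psd[0])]
        assert peak == pytest.approx(2.5, abs=spec.frequencies[1])

    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        fs = 20.0
        tm = TraceMatrix(rng.normal(0, 1, (1, 51200))[None][0], fs)
        spec = welch_psd(tm, 256)  # ~200 averaged segments
        interior = spec.psd[0][2:-2]
        assert interior.max() / interior.min() < 3.0

    def test_parseval(self):
        rng = np.random.default_rng(1)
        fs = 20.0
        x = rng.normal(0, 1, (3, 16384))
        x -= x.mean(axis=1, keepdims=True)
        tm = TraceMatrix(x, fs)
        spec = welch_psd(tm, 2048)
        df = spec.frequencies[1]
        power = spec.psd.sum(axis=1) * df
        assert np.allclose(power, x.var(axis=1), rtol=0.05)

    def test_segment_too_long_rejected(self):
        tm = TraceMatrix(np.random.default_rng(2).normal(0, 1, (1, 100)), 20.0)
        with pytest.raises(ValueError):
            welch_psd(tm, 2048)


class TestDetect:
    def test_fundamental_and_harmonics(self, heartbeat_model):
        """2.5 Hz artifact at fs 20 yields harmonics {2.5, 5.0, 7.5} Hz."""
        assert heartbeat_model.fundamental == pytest.approx(2.5, abs=0.05)
        assert len(heartbeat_model.harmonics) == 3
        for got, want in zip(heartbeat_model.harmonics, (2.5, 5.0, 7.5)):
            assert got == pytest.approx(want, abs=0.1)

    def test_artifact_free_is_empty(self):
        spec = synth.ArtifactTraceSpec(seed=4, target_spurious_corr=0.0)
        observed, _, _ = synth.make_heartbeat_traces(spec)
        model = detect_heartbeat(welch_psd(observed, 2048))
        assert model.empty
        assert model.fundamental is None

    def test_anesthesia_configuration_1p8hz(self):
        """Single-plane 100 Hz recording with a 1.8 Hz artifact: the 3.6 Hz
        harmonic is found alongside the fundamental."""
        spec = synth.ArtifactTraceSpec(
            fs=100.0, duration=60.0, fundamental=1.8, n_neurons=12, seed=5
        )
        observed, _, _ = synth.make_heartbeat_traces(spec)
        model = detect_heartbeat(welch_psd(observed, 2048))
        assert model.fundamental == pytest.approx(1.8, abs=0.05)
        assert model.harmonics[1] == pytest.approx(3.6, abs=0.1)

    def test_seeded_recovery_within_one_bin(self):
        """Fundamental recovered within one frequency bin across seeds."""
        for seed in range(10):
            spec = synth.ArtifactTraceSpec(seed=seed, duration=600.0)
            observed, _, _ = synth.make_heartbeat_traces(spec)
            s = welch_psd(observed, 2048)
            model = detect_heartbeat(s)
            df = s.frequencies[1]
            assert model.fundamental == pytest.approx(2.5, abs=df)

    def test_nyquist_guard(self):
        """At fs 10 the 7.5 Hz harmonic aliases and cannot be listed; at
        fs >= 15 every harmonic is representable — hence the 15 Hz
        minimum sampling-rate rule."""
        spec10 = synth.ArtifactTraceSpec(fs=10.0, seed=6)
        obs10, _, _ = synth.make_heartbeat_traces(spec10)
        m10 = detect_heartbeat(welch_psd(obs10, 2048), f_search=(1.0, 4.5))
        assert all(f < 5.0 for f in m10.harmonics)
        assert not any(abs(f - 7.5) < 0.3 for f in m10.harmonics)

        spec16 = synth.ArtifactTraceSpec(fs=16.0, seed=6)
        obs16, _, _ = synth.make_heartbeat_traces(spec16)
        m16 = detect_heartbeat(welch_psd(obs16, 2048), f_search=(1.0, 4.5))
        assert any(abs(f - 7.5) < 0.2 for f in m16.harmonics)

    def test_stopbands_disjoint_validated(self):
        with pytest.raises(ValueError):
            HeartbeatModel(2.5, (2.5, 5.0), ((2.0, 3.0), (2.8, 5.5)))


class TestFilter:
    def test_zero_phase_preserves_symmetry(self):
        fs = 20.0
        n = 4001
        t = np.arange(n) / fs
        pulse = np.exp(-0.5 * ((t - t[n // 2]) / 1.5) ** 2)
        tm = TraceMatrix(pulse[None, :], fs)
        out = filter_traces(tm, "bandstop", stopbands=[(2.25, 2.75)]).values[0]
        assert np.allclose(out, out[::-1], atol=1e-9)

    def test_stopband_tone_attenuated_40db(self):
        fs = 20.0
        t = np.arange(65536) / fs
        tone = np.sin(2 * np.pi * 2.5 * t)
        tm = TraceMatrix(tone[None, :], fs)
        out = filter_traces(tm, "bandstop", stopbands=[(2.25, 2.75)]).values[0]
        mid = slice(2000, -2000)
        assert np.abs(out[mid]).max() <= np.abs(tone).max() * 10 ** (-40 / 20)

    def test_out_of_band_tone_untouched(self):
        fs = 20.0
        t = np.arange(16384) / fs
        tone = np.sin(2 * np.pi * 0.6 * t)  # two octaves below 2.5 Hz
        tm = TraceMatrix(tone[None, :], fs)
        out = filter_traces(tm, "bandstop", stopbands=[(2.25, 2.75)]).values[0]
        mid = slice(2000, -2000)
        assert np.abs(out[mid] - tone[mid]).max() <= 0.01

    def test_double_scrub_changes_little(self, contaminated, heartbeat_model):
        _, observed, _, _ = contaminated
        once = filter_traces(observed, "bandstop", stopbands=heartbeat_model.stopbands)
        twice = filter_traces(once, "bandstop", stopbands=heartbeat_model.stopbands)
        # in-band residual already removed: < 1 dB further change
        num = np.linalg.norm(twice.values - once.values)
        assert num <= 0.12 * np.linalg.norm(once.values - observed.values)

    def test_provenance_recorded(self, contaminated):
        _, observed, _, _ = contaminated
        out = filter_traces(observed, "highpass", cutoff=1.0)
        assert any("highpass" in p for p in out.provenance)

    def test_invalid_edges_rejected(self, contaminated):
        _, observed, _, _ = contaminated
        with pytest.raises(ValueError):
            filter_traces(observed, "bandstop", stopbands=[(9.5, 10.5)])
        with pytest.raises(ValueError):
            filter_traces(observed, "highpass", cutoff=None)


class TestCorrelationDelta:
    def test_artifact_induces_delta_near_target(self, contaminated, heartbeat_model):
        """Shared-artifact coupling calibrated for ~0.1 spurious
        correlation shows up as |delta| ~ 0.1."""
        _, observed, _, _ = contaminated
        _, _, delta = correlation_delta(observed, heartbeat_model)
        off = ~np.eye(delta.shape[0], dtype=bool)
        assert 0.05 <= np.abs(delta[off]).max() <= 0.2

    def test_null_recording_small_delta(self, heartbeat_model):
        """Scrubbing an artifact-free recording moves correlations by less
        than 0.02 at 24,000 samples."""
        spec = synth.ArtifactTraceSpec(seed=7, target_spurious_corr=0.0)
        observed, _, _ = synth.make_heartbeat_traces(spec)
        _, _, delta = correlation_delta(observed, heartbeat_model)
        off = ~np.eye(delta.shape[0], dtype=bool)
        assert np.abs(delta[off]).max() <= 0.02

    def test_delta_diagonal_zero_and_symmetric(self, contaminated, heartbeat_model):
        _, observed, _, _ = contaminated
        before, after, delta = correlation_delta(observed, heartbeat_model)
        assert np.allclose(np.diag(delta), 0.0)
        assert np.allclose(delta, delta.T)
        assert np.allclose(np.diag(before), 1.0)
        assert np.allclose(np.diag(after), 1.0)

    def test_scrubbing_recovers_clean_traces(self, contaminated, heartbeat_model):
        """Per neuron, the scrubbed trace correlates better with the clean
        component than the contaminated one does."""
        _, observed, clean, _ = contaminated
        scrubbed = filter_traces(
            observed, "bandstop", stopbands=heartbeat_model.stopbands
        )
        for i in range(observed.n_neurons):
            c_obs = np.corrcoef(clean.values[i], observed.values[i])[0, 1]
            c_scr = np.corrcoef(clean.values[i], scrubbed.values[i])[0, 1]
            assert c_scr > c_obs

    def test_single_neuron_rejected(self, heartbeat_model):
        tm = TraceMatrix(np.random.default_rng(0).normal(0, 1, (1, 4000)), 20.0)
        with pytest.raises(ValueError):
            correlation_delta(tm, heartbeat_model)


class TestSlidingRoiPsd:
    fs = 100.0
    pixel = 0.65

    def _movie(self, flicker_amp, seed=0, n_t=1500, hw=48):
        rng = np.random.default_rng(seed)
        base = 100.0 + 20.0 * rng.random((hw, hw))
        t = np.arange(n_t) / self.fs
        flick = 1.0 + flicker_amp * np.sin(2 * np.pi * 1.8 * t)
        movie = base[None, :, :] * flick[:, None, None]
        return movie + rng.normal(0, 1.0, movie.shape)

    def test_global_flicker_peak(self):
        spec = sliding_roi_psd(
            self._movie(0.05), self.fs, self.pixel, roi_size=5.0, region=25.0
        )
        peak = spec.frequencies[np.argmax(spec.psd[0][1:]) + 1]
        assert peak == pytest.approx(1.8, abs=0.2)

    def test_static_movie_flat(self):
        quiet = self._movie(0.0)
        spec = sliding_roi_psd(quiet, self.fs, self.pixel, roi_size=5.0, region=25.0)
        psd = spec.psd[0][1:]
        assert psd.max() / np.median(psd) < 10.0

    def test_anesthetic_attenuates_peak(self):
        """Zeroing the flicker (simulated anaesthetic) removes the
        spectral peak down to the noise floor."""
        before = sliding_roi_psd(
            self._movie(0.05), self.fs, self.pixel, roi_size=5.0, region=25.0
        )
        after = sliding_roi_psd(
            self._movie(0.0), self.fs, self.pixel, roi_size=5.0, region=25.0
        )
        bin_18 = np.argmin(np.abs(before.frequencies - 1.8))
        assert before.psd[0][bin_18] > 100 * after.psd[0][bin_18]

    def test_region_exceeding_movie_rejected(self):
        with pytest.raises(ValueError):
            sliding_roi_psd(self._movie(0.0), self.fs, self.pixel, region=1000.0)
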