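"""Signal-processing chain: filters, noise integration, detection, averaging."""

import numpy as np
import pytest

from muxecog.analysis import (
    BANDS,
    BandDef,
    average_ssep,
    bandpass,
    crosstalk_db,
    detect_ripples,
    gamma_power_map,
    hilbert_rms_power,
    inband_noise,
    noise_report,
    ripple_stats,
    spatiotemporal_frames,
    spectrogram,
    stitch_glitches,
)
from muxecog.io import GridGeometry, TraceSet

FS = 1000.0


def tone(freq, fs=FS, duration=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = tone(100.0, duration=20.0)
        y = bandpass(x, FS, BANDS["gamma"], zero_phase=False)
        seg = slice(5000, 15000)
        assert np.max(np.abs(y[seg])) == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        x = 5.0 + tone(100.0, duration=20.0)
        y = bandpass(x, FS, BANDS["broadband"], order=1)
        # interior window: the zero-phase backward pass leaves an edge
        # transient at the very end of the trace
        assert abs(np.mean(y[5000:15000])) < 0.01 * 5.0

    def test_white_noise_psd_follows_butterworth_magnitude(self, rng):
        """Output PSD = |H(f)|^2 x input density for the 1-500 Hz first-order
        band-pass (zero-phase doubles the order in power)."""
        from scipy import signal as sps

        fs = 2000.0
        x = rng.standard_normal(int(fs * 60))
        y = bandpass(x, fs, BANDS["broadband"], order=1, zero_phase=True)
        f, psd = sps.welch(y, fs=fs, nperseg=int(fs))
        w, h = sps.sosfreqz(
            sps.butter(1, (1.0, 500.0), btype="bandpass", fs=fs, output="sos"),
            worN=f[1:], fs=fs,
        )
        expected = (np.abs(h) ** 4) * (1.0 / (fs / 2))  # |H|^2 twice (filtfilt)
        sel = (f[1:] > 20) & (f[1:] < 800)
        ratio = psd[1:][sel] / expected[sel]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(tone(10.0), 800.0, BANDS["gamma"])


class TestInbandNoise:
    def test_zero_trace(self):
        assert inband_noise(np.zeros(int(FS * 10)), FS) == 0.0

    def test_sinusoid_parseval(self):
        a = 3.0
        assert inband_noise(tone(100.0, amplitude=a), FS) == pytest.approx(
            a / np.sqrt(2), rel=0.02
        )

    def test_white_noise_flat_spectrum_integral(self, rng):
        """sigma=1 white noise at 1 kHz: in-band (1-500 Hz) noise
        ~ sqrt(499/500), Monte-Carlo over 50 runs."""
        vals = [
            inband_noise(rng.standard_normal(int(FS * 10)), FS) for _ in range(50)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(499.0 / 500.0), rel=0.03)

    def test_quadrature_additivity_of_independent_sources(self, rng):
        """In-band noise of a sum of independent sources equals the
        quadrature sum of their individual values (+-5%)."""
        x = rng.standard_normal(int(FS * 10))
        y = 2.0 * rng.standard_normal(int(FS * 10))
        nx = inband_noise(x, FS)
        ny = inband_noise(y, FS)
        nxy = inband_noise(x + y, FS)
        assert nxy == pytest.approx(np.hypot(nx, ny), rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            inband_noise(np.zeros(100), FS)

    def test_defective_channel_masking(self, rng):
        """Channels above 10 uVrms are excluded from the statistics."""
        geom = GridGeometry(rows=2, cols=2, pitch_um=500,
                            electrode_diameter_um=300)
        n = int(FS * 10)
        data = np.vstack(
            [
                3e-6 * rng.standard_normal(n),
                3e-6 * rng.standard_normal(n),
                3e-6 * rng.standard_normal(n),
                50e-6 * rng.standard_normal(n),  # defective
            ]
        )
        rep = noise_report(TraceSet(data=data, fs=FS, geometry=geom))
        assert rep.n_defective == 1
        assert bool(rep.defective[3])
        assert rep.mean_uv == pytest.approx(3.0, rel=0.1)
        tab = rep.to_frame()
        assert list(tab.columns) == ["channel", "row", "col", "vrms_uv",
                                     "defective"]


class TestRippleDetection:
    def make_burst_trace(self, rng, events, duration=60.0, noise_uv=5.0,
                         freq=120.0):
        """Background + Gaussian-windowed bursts at known times."""
        n = int(duration * FS)
        t = np.arange(n) / FS
        x = noise_uv * rng.standard_normal(n)
        for center, amp, dur in events:
            sigma = dur / 3.6
            x += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.sin(
                2 * np.pi * freq * (t - center)
            )
        return x

    def test_zero_and_flat_traces_give_no_events(self):
        assert detect_ripples(np.zeros(int(FS * 10)), FS) == []
        assert detect_ripples(np.full(int(FS * 10), 3.3), FS) == []

    def test_single_injected_burst_detected_with_frequency(self, rng):
        x = self.make_burst_trace(rng, [(30.0, 60.0, 0.1)], noise_uv=3.0)
        events = detect_ripples(x, FS)
        assert len(events) == 1
        ev = events[0]
        assert 20.0 <= ev.duration_ms <= 400.0
        assert ev.peak_freq_hz == pytest.approx(120.0, abs=5.0)
        assert abs((ev.start_s + ev.end_s) / 2 - 30.0) < 0.05
        assert ev.peak_envelope_z >= 2.5

    def test_nearby_bursts_merge(self, rng):
        """Two supra-threshold bursts 20 ms apart count as one event."""
        x = self.make_burst_trace(
            rng, [(30.0, 80.0, 0.06), (30.08, 80.0, 0.06)], noise_uv=2.0
        )
        events = detect_ripples(x, FS)
        assert len(events) == 1

    def test_distant_bursts_stay_separate(self, rng):
        x = self.make_burst_trace(
            rng, [(20.0, 80.0, 0.08), (21.0, 80.0, 0.08)], noise_uv=2.0
        )
        assert len(detect_ripples(x, FS)) == 2

    def test_overlong_events_discarded(self, rng):
        x = self.make_burst_trace(rng, [(30.0, 80.0, 0.9)], noise_uv=2.0)
        # a ~900 ms burst exceeds the 400 ms physiological cut
        assert detect_ripples(x, FS) == []


class TestRippleStats:
    def test_paper_rate_arithmetic(self):
        assert ripple_stats(97, 129.0).rate_per_s == 0.75

    def test_median_duration(self):
        from muxecog.analysis import RippleEvent

        events = [
            RippleEvent(0, 1.0, 1.05, 130.0, 3.0),
            RippleEvent(0, 2.0, 2.10, 130.0, 3.0),
            RippleEvent(0, 3.0, 3.15, 130.0, 3.0),
        ]
        st = ripple_stats(events, 10.0)
        assert st.median_duration_ms == pytest.approx(100.0)
        assert st.rate_per_s == pytest.approx(0.3)
        # invariant to ordering
        st_rev = ripple_stats(events[::-1], 10.0)
        assert st_rev.median_duration_ms == st.median_duration_ms

    def test_empty_population_flagged(self):
        st = ripple_stats([], 10.0)
        assert st.n == 0 and st.rate_per_s == 0.0
        assert np.isnan(st.median_duration_ms)


class TestHilbertPower:
    def test_pure_tone_envelope(self):
        # tone at the band's geometric center, where the Butterworth gain is 1
        x = tone(141.4, duration=20.0, amplitude=2.5)
        assert hilbert_rms_power(x, FS, BANDS["ripple_detect"]) == pytest.approx(
            2.5, rel=0.02
        )

    def test_out_of_band_rejection(self):
        x = tone(10.0, duration=20.0, amplitude=1.0)
        assert hilbert_rms_power(x, FS, BANDS["ripple_detect"]) < 0.01  # >40 dB

    def test_am_tone_closed_form(self):
        """A(1 + 0.5 cos wm t): envelope RMS = A sqrt(1 + 0.125)."""
        t = np.arange(int(FS * 30)) / FS
        x = 2.0 * (1 + 0.5 * np.cos(2 * np.pi * 4 * t)) * np.sin(
            2 * np.pi * 120 * t
        )
        got = hilbert_rms_power(x, FS, BandDef("wide", 80.0, 180.0))
        assert got == pytest.approx(2.0 * np.sqrt(1.125), rel=0.02)

    def test_window_bounds_checked(self):
        with pytest.raises(ValueError, match="window"):
            hilbert_rms_power(tone(120.0), FS, BANDS["ripple"], window_s=(5.0, 20.0))


class TestSSEPAveraging:
    def make_trials(self, geom, template, triggers, fs, noise_uv=0.0, rng=None):
        n = int((triggers[-1] + 1.0) * fs)
        data = np.zeros((geom.n_channels, n))
        if noise_uv and rng is not None:
            data += noise_uv * 1e-6 * rng.standard_normal(data.shape)
        for trig in triggers:
            i = int(trig * fs)
            data[:, i : i + template.size] += template * 1e-6
        return TraceSet(data=data, fs=fs, geometry=geom)

    def test_identical_trials_average_to_one_trial(self):
        geom = GridGeometry(2, 2, 500, 300)
        fs = 2000.0
        t = np.arange(int(0.1 * fs)) / fs
        template = 100.0 * np.exp(-0.5 * ((t - 0.02) / 0.004) ** 2)
        trig = 0.5 + np.arange(10) * 1.0
        traces = self.make_trials(geom, template, trig, fs)
        res = average_ssep(traces, trig)
        assert res.peak_amplitude_uv[0] == pytest.approx(100.0, rel=0.01)
        assert res.peak_latency_ms[0] == pytest.approx(20.0, abs=1.0)

    def test_noise_averages_down_as_sqrt_n(self, rng):
        """CLT oracle: residual RMS after averaging n trials ~ sigma/sqrt(n)."""
        geom = GridGeometry(1, 2, 500, 300)
        fs = 1000.0
        t = np.arange(int(0.1 * fs)) / fs
        template = 50.0 * np.exp(-0.5 * ((t - 0.02) / 0.005) ** 2)
        n_trials, sigma = 64, 20.0
        trig = 0.5 + np.arange(n_trials) * 0.5
        errs = []
        for _ in range(10):
            traces = self.make_trials(geom, template, trig, fs, noise_uv=sigma,
                                      rng=rng)
            res = average_ssep(traces, trig, window_s=(-0.05, 0.1))
            sel = (res.time_ms >= 0) & (res.time_ms < 100.0)
            recovered = res.average_uv[0][sel]
            errs.append(np.sqrt(np.mean((recovered - template[: sel.sum()]) ** 2)))
        assert np.mean(errs) == pytest.approx(sigma / np.sqrt(n_trials), rel=0.25)

    def test_linearity_in_amplitude(self):
        geom = GridGeometry(1, 1, 500, 300)
        fs = 1000.0
        t = np.arange(int(0.1 * fs)) / fs
        template = 80.0 * np.sin(2 * np.pi * 30 * t) * np.exp(-t / 0.03)
        trig = 0.5 + np.arange(5) * 1.0
        a = self.make_trials(geom, template, trig, fs)
        b = self.make_trials(geom, 3.0 * template, trig, fs)
        ra = average_ssep(a, trig)
        rb = average_ssep(b, trig)
        np.testing.assert_allclose(rb.average_uv, 3.0 * ra.average_uv, atol=1e-9)

    def test_edge_trials_dropped_with_warning(self):
        geom = GridGeometry(1, 1, 500, 300)
        fs = 1000.0
        traces = TraceSet(data=np.zeros((1, 2000)), fs=fs, geometry=geom)
        with pytest.warns(UserWarning, match="dropped"):
            average_ssep(traces, np.array([0.5, 1.95]))


class TestMapsAndFrames:
    def test_gamma_map_argmax_at_responsive_channel(self):
        geom = GridGeometry(3, 3, 500, 300)
        fs = 2000.0
        n = int(10 * fs)
        data = np.zeros((9, n))
        trig = 0.5 + np.arange(8) * 1.0
        t = np.arange(int(0.06 * fs)) / fs
        burst = 100e-6 * np.sin(2 * np.pi * 120 * t)
        for tr in trig:
            i = int((tr + 0.015) * fs)
            data[4, i : i + burst.size] += burst
        traces = TraceSet(data=data, fs=fs, geometry=geom)
        gmap = gamma_power_map(traces, trig)
        assert np.unravel_index(np.argmax(gmap), gmap.shape) == (1, 1)
        assert gmap[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_flat_traces_zero_map(self):
        geom = GridGeometry(2, 2, 500, 300)
        traces = TraceSet(data=np.zeros((4, 8000)), fs=2000.0, geometry=geom)
        gmap = gamma_power_map(traces, np.array([1.0, 2.0]))
        assert np.all(gmap == 0.0)

    @pytest.mark.parametrize(
        "span_ms, bin_ms, n_frames", [(650.0, 50.0, 13), (55.0, 5.0, 11)]
    )
    def test_frame_counts(self, span_ms, bin_ms, n_frames):
        geom = GridGeometry(2, 2, 500, 300)
        traces = TraceSet(data=np.ones((4, 2000)) * 1e-6, fs=1000.0, geometry=geom)
        frames = spatiotemporal_frames(traces, 0.1, span_ms / 1e3, bin_ms)
        assert frames.shape == (n_frames, 2, 2)
        np.testing.assert_allclose(frames, 1.0)

    def test_bin_larger_than_span_rejected(self):
        geom = GridGeometry(2, 2, 500, 300)
        traces = TraceSet(data=np.zeros((4, 2000)), fs=1000.0, geometry=geom)
        with pytest.raises(ValueError, match="bin"):
            spatiotemporal_frames(traces, 0.0, 0.05, 100.0)


class TestSpectrogram:
    def test_tone_ridge_in_high_range(self):
        f, t, sxx = spectrogram(tone(120.0, duration=30.0), FS, "high")
        ridge = f[np.argmax(sxx.mean(axis=1))]
        assert ridge == pytest.approx(120.0, abs=3.0)
        assert f.min() >= 50.0 and f.max() <= 500.0

    def test_chirp_monotone_ridge_in_low_range(self):
        """Instantaneous-frequency oracle: a 10->40 Hz chirp's ridge rises."""
        from scipy.signal import chirp

        fs = 1000.0
        t = np.arange(int(fs * 60)) / fs
        x = chirp(t, f0=10.0, f1=40.0, t1=60.0, method="linear")
        f, tt, sxx = spectrogram(x, fs, "low")
        ridge = f[np.argmax(sxx, axis=0)]
        # compare against the known instantaneous frequency at frame centers
        expected = 10.0 + (40.0 - 10.0) * tt / 60.0
        inner = (tt > 3) & (tt < 57)
        assert np.corrcoef(ridge[inner], expected[inner])[0, 1] > 0.99
        assert np.all(np.diff(ridge[inner]) > -3.0)  # monotone up to bin size

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            spectrogram(np.zeros(100), FS, "low")


class TestCrosstalk:
    @pytest.mark.parametrize("ratio_db", [0.0, -40.0, -53.0])
    def test_known_amplitude_ratios(self, ratio_db):
        victim = tone(160.0, duration=20.0, amplitude=10 ** (ratio_db / 20))
        assert crosstalk_db(victim, 1.0, 160.0, FS) == pytest.approx(
            ratio_db, abs=0.5
        )

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            crosstalk_db(tone(100.0), 1.0, 600.0, FS)


class TestStitchGlitches:
    def test_clean_trace_identity(self):
        x = tone(5.0, duration=10.0, amplitude=1e-4)
        y, log = stitch_glitches(x, FS)
        np.testing.assert_array_equal(x, y)
        assert log.empty

    def test_single_step_removed(self):
        """100 uV sinusoid + 10 mV DC step: residual < 1% RMS."""
        x = tone(5.0, duration=10.0, amplitude=1e-4)
        dirty = x.copy()
        dirty[4000:] += 10e-3
        y, log = stitch_glitches(dirty, FS)
        assert len(log) == 1
        assert log.t_s.iloc[0] == pytest.approx(4.0, abs=0.01)
        resid = np.sqrt(np.mean((y - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert resid < 0.01

    def test_multiple_mixed_sign_steps(self, rng):
        x = tone(5.0, duration=20.0, amplitude=1e-4)
        dirty = x.copy()
        for i, step in [(3000, 5e-3), (9000, -8e-3), (15000, 12e-3)]:
            dirty[i:] += step
        y, log = stitch_glitches(dirty, FS)
        assert len(log) == 3
        resid = np.sqrt(np.mean((y - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert resid < 0.01

    def test_idempotent(self):
        x = tone(5.0, duration=10.0, amplitude=1e-4)
        x[2000:] += 10e-3
        once, _ = stitch_glitches(x, FS)
        twice, log2 = stitch_glitches(once, FS)
        np.testing.assert_array_equal(once, twice)
        assert log2.empty
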