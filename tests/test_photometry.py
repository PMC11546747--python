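"""Isosbestic detrending, peri-event z-scoring, window metrics, transients."""

import numpy as np
import pytest

from rewardseek import synth
from rewardseek.photometry import (
    PhotometryRecording,
    WindowSpec,
    detect_transients,
    detrend_isosbestic,
    event_psth,
    trapezoid_window,
    window_metrics,
)


class TestDetrend:
    def test_pure_artifact_removed(self):
        rng = np.random.default_rng(0)
        iso = 1.0 + 0.05 * rng.standard_normal(2000).cumsum() / 50
        rec = PhotometryRecording(signal_470=2.0 * iso, iso_405=iso, fs=100.0)
        dff = detrend_isosbestic(rec, lowpass_hz=None)
        assert np.abs(dff).max() < 1e-10

    def test_planted_transient_recovered_within_10pct(self):
        spec = synth.PhotometryGenSpec(
            duration=120.0, transient_times=np.arange(10, 110, 10.0),
            transient_amp=0.05, seed=2,
        )
        rec = synth.gen_photometry_session(spec)
        dff = detrend_isosbestic(rec)
        cues = spec.transient_times
        peaks = [dff[int(c * rec.fs) : int((c + 2) * rec.fs)].max() for c in cues]
        assert np.mean(peaks) == pytest.approx(0.05, rel=0.10)

    def test_uncorrelated_iso_gets_near_zero_slope(self):
        rng = np.random.default_rng(1)
        n = 20000
        sig = 1.0 + 0.01 * rng.standard_normal(n)
        iso = 1.0 + 0.01 * rng.standard_normal(n)
        rec = PhotometryRecording(sig, iso, fs=100.0)
        dff = detrend_isosbestic(rec, lowpass_hz=None, mode="subtract")
        # residual variance ~ signal variance: iso explained nothing
        assert dff.var() == pytest.approx(sig.var(), rel=0.01)

    def test_constant_iso_degenerate(self):
        rec = PhotometryRecording(np.ones(100) + 0.01, np.ones(100), fs=10.0)
        with pytest.raises(ValueError, match="degenerate"):
            detrend_isosbestic(rec, lowpass_hz=None)

    def test_subtraction_mode_idempotent(self):
        spec = synth.PhotometryGenSpec(duration=60.0, transient_times=np.array([10.0]), seed=3)
        rec = synth.gen_photometry_session(spec)
        once = detrend_isosbestic(rec, lowpass_hz=None, mode="subtract")
        twice = detrend_isosbestic(
            PhotometryRecording(once, rec.iso_405, rec.fs), lowpass_hz=None, mode="subtract"
        )
        assert np.abs(once - twice).max() < 1e-8


class TestEventPSTH:
    def _trace(self):
        rng = np.random.default_rng(4)
        return 0.1 * rng.standard_normal(6000), 100.0  # 60 s at 100 Hz

    def test_baseline_window_zero_mean_unit_sd(self):
        trace, fs = self._trace()
        psth = event_psth(trace, fs, events=[10.0, 20.0, 30.0])
        ws = WindowSpec()
        bmask = (psth.time >= ws.baseline[0]) & (psth.time < ws.baseline[1])
        for row in psth.z:
            assert abs(row[bmask].mean()) < 1e-9
            assert row[bmask].std() == pytest.approx(1.0)

    def test_incomplete_span_dropped_with_warning(self):
        trace, fs = self._trace()
        with pytest.warns(UserWarning, match="dropped"):
            psth = event_psth(trace, fs, events=[2.0, 30.0])
        assert psth.z.shape[0] == 1

    def test_constant_trace_zero_variance_error(self):
        with pytest.raises(ValueError, match="trial 0"):
            event_psth(np.ones(6000), 100.0, events=[30.0])

    def test_planted_response_recovered(self):
        rng = np.random.default_rng(5)
        fs, sd = 100.0, 0.1
        trace = sd * rng.standard_normal(200_000)
        events = np.arange(20.0, 1980.0, 50.0)
        for ev in events:
            i = int(ev * fs)
            trace[i : i + 100] += 3 * sd  # 3x baseline-noise amplitude
        psth = event_psth(trace, fs, events)
        peak = psth.mean_trace[(psth.time >= 0) & (psth.time < 1)].mean()
        assert peak == pytest.approx(3.0, rel=0.2)


class TestWindowMetrics:
    def _psth_from(self, time, mean):
        from rewardseek.photometry import EventPSTH

        return EventPSTH(
            z=np.tile(mean, (3, 1)), time=time,
            baseline_mean=np.zeros(3), baseline_sd=np.ones(3),
            event_times=np.zeros(3),
        )

    def test_rectangle(self):
        t = np.linspace(-4, 8, 1201)
        p = self._psth_from(t, np.where((t >= 0) & (t <= 2), 1.0, 0.0))
        m = window_metrics(p, (0.0, 2.0))
        assert m["auc"] == pytest.approx(2.0, abs=0.02)
        assert m["peak"] == 1.0

    def test_triangle(self):
        t = np.linspace(-4, 8, 1201)
        tri = np.clip(4.0 * (1 - np.abs(t - 1.0)), 0.0, None)
        p = self._psth_from(t, tri)
        m = window_metrics(p, (0.0, 2.0))
        assert m["auc"] == pytest.approx(4.0, abs=0.01)
        assert m["peak"] == pytest.approx(4.0)

    def test_window_outside_span(self):
        t = np.linspace(-4, 8, 121)
        p = self._psth_from(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            window_metrics(p, (7.0, 9.0))

    def test_trapezoid_linearity(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 10, 101)
        y = rng.standard_normal(101)
        a = trapezoid_window(t, y, (1.0, 9.0))
        assert trapezoid_window(t, 3.5 * y, (1.0, 9.0)) == pytest.approx(3.5 * a)


class TestTransients:
    def test_flat_trace_no_events(self):
        out = detect_transients(np.zeros(1000), 100.0)
        assert len(out) == 0

    def test_planted_peaks_exact_count(self):
        fs = 100.0
        trace = np.zeros(6000)
        for c in [500, 1500, 2500, 3500, 4500]:
            trace[c - 50 : c + 50] += 2.0 * np.hanning(100)
        out = detect_transients(trace, fs, min_prominence=1.0)
        assert len(out) == 5
        assert np.allclose(out["amplitude"], 2.0, atol=1e-3)

    def test_subthreshold_prominence_excluded(self):
        trace = np.zeros(2000)
        trace[400:600] += 0.5 * np.hanning(200)
        assert len(detect_transients(trace, 100.0, min_prominence=1.0)) == 0

    def test_count_monotone_in_prominence(self):
        rng = np.random.default_rng(7)
        trace = rng.standard_normal(5000).cumsum() / 30
        counts = [
            len(detect_transients(trace, 100.0, min_prominence=p))
            for p in (0.25, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)


def test_group_amplitude_contrast_ratio():
    """Planted 2x cue amplitude contrast shows up as ~2x peak ratio."""
    ratios = []
    for seed in range(20):
        recs = {}
        for grp, amp in (("A", 0.10), ("B", 0.05)):
            spec = synth.PhotometryGenSpec(
                duration=400.0, transient_times=np.arange(20, 390, 12.0),
                transient_amp=amp, seed=seed * 7 + (grp == "A"),
            )
            rec = synth.gen_photometry_session(spec)
            dff = detrend_isosbestic(rec)
            psth = event_psth(dff, rec.fs, spec.transient_times[2:-2])
            recs[grp] = window_metrics(psth, (0.0, 2.0))["peak"]
        ratios.append(recs["A"] / recs["B"])
    assert 1.6 <= np.mean(ratios) <= 2.4
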