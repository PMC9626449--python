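"""Trace processing: decimation, detection rules, binning, diel rates."""

import numpy as np
import pandas as pd
import pytest

from rorqualrisk.synthetic import TraceSpec, gen_tag_trace
from rorqualrisk.tagproc import (
    DEPTH_BINS,
    DielLungeRates,
    TagTrace,
    TraceMetadata,
    bin_by_depth,
    daily_lunge_count,
    decimate_trace,
    depth_bin_label,
    detect_lunges,
    diel_rates,
)


def make_trace(speed, depth=None, fs=10.0, start="2019-08-01T12:00:00"):
    speed = np.asarray(speed, dtype=float)
    depth = np.full(len(speed), 10.0) if depth is None else np.asarray(depth, dtype=float)
    idx = pd.Timestamp(start, tz="UTC") + pd.to_timedelta(np.arange(len(speed)) / fs, unit="s")
    return TagTrace(pd.DataFrame({"depth_m": depth, "speed_ms": speed}, index=idx))


class TestDecimate:
    def test_constant_trace_invariant(self):
        tr = make_trace(np.full(1000, 1.7), fs=50.0)
        out = decimate_trace(tr, 10.0)
        assert len(out.data) == 200
        np.testing.assert_allclose(out.data["speed_ms"].values, 1.7, rtol=1e-9)
        assert out.sample_rate == pytest.approx(10.0)

    def test_length_arithmetic(self):
        tr = make_trace(np.random.default_rng(0).uniform(1, 2, 1000), fs=50.0)
        assert len(decimate_trace(tr, 10.0).data) == 200

    def test_timestamps_preserved_on_kept_samples(self):
        tr = make_trace(np.full(500, 1.0), fs=50.0)
        out = decimate_trace(tr, 10.0)
        assert (out.data.index == tr.data.index[::5][: len(out.data)]).all()

    def test_slow_sinusoid_matches_subsampling(self):
        """A 0.1 Hz sinusoid is far below the anti-alias cutoff, so FIR
        decimation agrees with direct subsampling away from the edges."""
        fs, f0 = 50.0, 0.1
        t = np.arange(0, 100, 1 / fs)
        tr = make_trace(2.0 + np.sin(2 * np.pi * f0 * t), fs=fs)
        out = decimate_trace(tr, 10.0)
        direct = 2.0 + np.sin(2 * np.pi * f0 * t[::5][: len(out.data)])
        core = slice(30, len(out.data) - 30)
        np.testing.assert_allclose(out.data["speed_ms"].values[core], direct[core], atol=1e-3)

    def test_non_integer_factor_rejected(self):
        tr = make_trace(np.full(100, 1.0), fs=25.0)
        with pytest.raises(ValueError, match="integer"):
            decimate_trace(tr, 10.0)


class TestDetector:
    def test_constant_speed_no_events(self):
        assert detect_lunges(make_trace(np.full(6000, 3.0))) == []

    def test_embedded_signatures_detected(self):
        trace, truth = gen_tag_trace(TraceSpec(n_lunges=5, duration=1.0, seed=21))
        events = detect_lunges(trace)
        assert len(events) == 5
        det_s = np.array([(e.time - trace.data.index[0]).total_seconds() for e in events])
        assert np.all(np.abs(np.sort(det_s) - np.sort(truth["time_s"].values)) <= 5.0)

    def test_refractory_merge_keeps_larger_peak(self):
        """Two signatures 10 s apart merge into one event at the higher
        peak, matching a brute-force scan applying the same rule."""
        fs = 10.0
        n = 2000
        speed = np.full(n, 1.5)

        def add(peak_idx, peak):
            ramp = np.linspace(1.5, peak, 51)
            speed[peak_idx - 50 : peak_idx + 1] = np.maximum(
                speed[peak_idx - 50 : peak_idx + 1], ramp
            )
            dec = 1.5 + (peak - 1.5) * np.exp(-np.arange(1, 101) / (4 * fs))
            speed[peak_idx + 1 : peak_idx + 101] = np.maximum(
                speed[peak_idx + 1 : peak_idx + 101], dec
            )

        add(600, 3.2)
        add(700, 3.8)  # 10 s later, higher
        events = detect_lunges(make_trace(speed), refractory=60.0)
        assert len(events) == 1
        assert events[0].peak_speed == pytest.approx(3.8, abs=0.01)

    def test_nan_speed_names_timestamp(self):
        speed = np.full(100, 1.5)
        speed[40] = np.nan
        with pytest.raises(ValueError, match="NaN speed"):
            detect_lunges(make_trace(speed))

    def test_empty_trace(self):
        tr = TagTrace(pd.DataFrame({"depth_m": [], "speed_ms": []},
                                   index=pd.DatetimeIndex([], tz="UTC")))
        assert detect_lunges(tr) == []

    def test_threshold_monotonicity(self, small_trace):
        """Raising the peak-speed threshold never increases the event count."""
        trace, _ = small_trace
        counts = [len(detect_lunges(trace, peak_speed_min=th)) for th in (2.0, 2.5, 3.0, 3.6)]
        assert counts == sorted(counts, reverse=True)


class TestDepthBinning:
    def test_one_event_per_bin(self):
        labels = [depth_bin_label(d) for d in (0.3, 3.0, 30.0, 100.0, 300.0)]
        assert labels == list(DEPTH_BINS)

    def test_half_open_boundary_goes_deeper(self):
        assert depth_bin_label(50.0) == "moderate"
        assert depth_bin_label(0.5) == "sub-surface"
        assert depth_bin_label(150.0) == "deep"

    def test_histogram_oracle(self):
        """Bin counts over 10,000 uniform depths match an independent
        histogram with the same edges exactly, and conserve the total."""
        rng = np.random.default_rng(8)
        depths = rng.uniform(0, 400, 10_000)
        labels = depth_bin_label(depths)
        counts = {b: int((labels == b).sum()) for b in DEPTH_BINS}
        hist, _ = np.histogram(depths, bins=[0.0, 0.5, 5.0, 50.0, 150.0, np.inf])
        assert list(counts.values()) == hist.tolist()
        assert sum(counts.values()) == 10_000

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_bin_label(-1.0)


class TestDielRates:
    def test_rates_from_synthetic_deployment(self, small_trace):
        """Counts split by diel period over period hours; conservation of
        the total across bins and periods."""
        trace, truth = small_trace
        events = detect_lunges(trace)
        rec = diel_rates(events, trace)
        hours = rec.hours()
        assert sum(hours.values()) == pytest.approx(trace.duration_hours, abs=1e-6)
        total_from_periods = sum(
            rec.rates()[p] * hours[p] for p in hours if hours[p] > 0 and np.isfinite(rec.rates()[p])
        )
        assert total_from_periods == pytest.approx(len(events), abs=1e-6)
        assert sum(bin_by_depth(events).values()) == len(events)

    def test_day_only_weights_give_zero_night_rates(self):
        """A deployment whose lunges all carry day weights shows zero
        twilight and night rates."""
        trace, truth = gen_tag_trace(
            TraceSpec(n_lunges=10, duration=24.0, diel_weights=(1.0, 0.0, 0.0), seed=13)
        )
        events = detect_lunges(trace)
        rec = diel_rates(events, trace)
        assert rec.rate_twilight == 0.0 or np.isnan(rec.rate_twilight)
        assert rec.rate_night == 0.0 or np.isnan(rec.rate_night)
        assert rec.rate_day > 0

    def test_zero_events_zero_rates(self):
        trace, _ = gen_tag_trace(TraceSpec(n_lunges=0, duration=1.0, seed=2))
        rec = diel_rates([], trace)
        for r in rec.rates().values():
            assert r == 0.0 or np.isnan(r)


class TestDailyLungeCount:
    REC = DielLungeRates("d0", 20.0, 10.0, 5.0, 6.0, 2.0, 4.0)

    def test_hand_arithmetic(self):
        assert daily_lunge_count(self.REC, (12.0, 2.0, 10.0)) == pytest.approx(310.0)

    def test_zero_rates(self):
        rec = DielLungeRates("d0", 0.0, 0.0, 0.0, 6.0, 2.0, 4.0)
        assert daily_lunge_count(rec, (12.0, 2.0, 10.0)) == 0.0

    def test_single_period_day(self):
        assert daily_lunge_count(self.REC, (24.0, 0.0, 0.0)) == pytest.approx(480.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            daily_lunge_count(self.REC, (-1.0, 15.0, 10.0))
        with pytest.raises(ValueError):
            daily_lunge_count(self.REC, (10.0, 2.0, 10.0))

    def test_daily_count_tracks_ground_truth(self):
        """Across 20 seeded deployments, the median relative error of the
        estimated daily lunge count versus embedded truth is <= 10%."""
        errors = []
        for seed in range(20):
            trace, truth = gen_tag_trace(TraceSpec(n_lunges=20, duration=4.0, seed=200 + seed))
            rec = diel_rates(detect_lunges(trace), trace)
            hours = np.array([rec.hours_day, rec.hours_twilight, rec.hours_night])
            h24 = tuple(24.0 * hours / hours.sum())
            est = daily_lunge_count(rec, h24)
            true_daily = len(truth) * 24.0 / trace.duration_hours
            errors.append(abs(est - true_daily) / true_daily)
        assert np.median(errors) <= 0.10
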