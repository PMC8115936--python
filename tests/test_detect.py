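"""Segmentation, rule-based classification, decoding, bouts, evaluation."""

import numpy as np
import pytest

from hivefield.detect import (
    DetectorConfig,
    SignalEvent,
    count_waggles,
    decode_distance,
    detect_events,
    evaluate,
    events_frame,
    events_from_frame,
    fuse_channels,
    group_bouts,
    segment_band,
)
from hivefield.errors import ParameterError, UsageError
from hivefield.simulate import (
    EventTruth,
    FanningSpec,
    SrsSpec,
    WaggleRunSpec,
    make_fanning,
    make_srs,
    make_tone_burst,
    make_waggle_run,
)
from hivefield.spectral import BandPowerTrace, DEFAULT_BANDS

from conftest import FS, embed_waveforms


@pytest.fixture(scope="module")
def cfg():
    return DetectorConfig()


def _trace(power, hop=0.05, window=0.2, band="SRS"):
    power = np.asarray(power, dtype=float)
    times = window / 2 + hop * np.arange(power.size)
    return BandPowerTrace(
        times=times, power=power, band=DEFAULT_BANDS[band], hop_s=hop,
        window_s=window,
    )


class TestSegmentBand:
    def test_flat_trace_no_intervals(self, cfg):
        assert segment_band(_trace(np.ones(400)), cfg) == []

    def test_rectangular_burst_one_interval(self, cfg):
        power = np.ones(400)
        power[200:240] = 50.0
        (iv,) = segment_band(_trace(power), cfg)
        hop, window = 0.05, 0.2
        t_lo = window / 2 + 200 * hop
        t_hi = window / 2 + 239 * hop
        assert abs(iv.t_start - (t_lo - window / 2)) <= hop
        assert abs(iv.t_end - (t_hi + window / 2)) <= hop
        assert iv.peak_power == 50.0

    def test_bursts_within_merge_gap_merge(self, cfg):
        power = np.ones(400)
        power[100:110] = 50.0
        power[111:120] = 50.0  # 1 frame = 0.05 s gap < 0.1 s merge gap
        assert len(segment_band(_trace(power), cfg)) == 1

    def test_bursts_beyond_merge_gap_stay_separate(self, cfg):
        power = np.ones(400)
        power[100:110] = 50.0
        power[150:160] = 50.0
        assert len(segment_band(_trace(power), cfg)) == 2

    def test_empty_trace(self, cfg):
        assert segment_band(_trace(np.empty(0)), cfg) == []


class TestClassifyRules:
    """Each class example runs end-to-end on a clean synthetic recording."""

    def test_regular_fanning_is_frs(self, cfg):
        wave, _ = make_fanning(FanningSpec(freq=100.0, duration=20.0, jitter=0.0), FS)
        rec = embed_waveforms([(0, 30.0, wave)], 120.0)
        events = detect_events(rec, cfg, channels=[0])
        assert [e.label for e in events] == ["FRS"]
        assert events[0].regularity >= cfg.frs_regularity_min
        assert events[0].duration >= 15.0

    def test_high_pulse_is_srs(self, cfg):
        wave, _ = make_srs(SrsSpec(fundamental=400.0, duration=0.5), FS)
        rec = embed_waveforms([(1, 10.0, wave)], 30.0)
        events = detect_events(rec, cfg, channels=[1])
        assert [e.label for e in events] == ["SRS"]
        assert events[0].duration <= 1.0

    def test_waggle_run_is_wrs(self, cfg):
        wave, truth = make_waggle_run(WaggleRunSpec(), FS)
        rec = embed_waveforms([(2, 10.0, wave)], 30.0)
        events = detect_events(rec, cfg, channels=[2])
        assert [e.label for e in events] == ["WRS"]
        assert abs(events[0].n_waggles - truth.n_waggles) <= 1
        assert events[0].distance_m == events[0].n_waggles * 75.0

    def test_ten_second_100hz_burst_is_nothing(self, cfg):
        # fails the fanning duration rule and lies outside the other bands
        wave = make_tone_burst(100.0, 10.0, 1.0, FS)
        rec = embed_waveforms([(0, 30.0, wave)], 120.0)
        assert detect_events(rec, cfg, channels=[0]) == []

    def test_irregular_long_wave_is_not_frs(self, cfg):
        rng = np.random.default_rng(6)
        wave, _ = make_fanning(
            FanningSpec(freq=100.0, duration=20.0, jitter=0.3), FS, rng=rng
        )
        rec = embed_waveforms([(0, 30.0, wave)], 120.0)
        assert all(e.label != "FRS" for e in detect_events(rec, cfg, channels=[0]))

    def test_low_band_without_wing_is_not_wrs(self, cfg):
        wave, _ = make_waggle_run(
            WaggleRunSpec(n_waggles=20, wing_sync_fraction=0.0), FS
        )
        rec = embed_waveforms([(0, 10.0, wave)], 40.0)
        assert detect_events(rec, cfg, channels=[0]) == []


class TestSignalEventInvariants:
    def test_srs_longer_than_one_second_rejected(self):
        with pytest.raises(ParameterError):
            SignalEvent("SRS", 0, 0.0, 1.2, mean_power=1.0)

    def test_frs_shorter_than_fifteen_seconds_rejected(self):
        with pytest.raises(ParameterError):
            SignalEvent("FRS", 0, 0.0, 12.0, mean_power=1.0)


class TestWaggleCountAndDistance:
    @pytest.mark.parametrize("n", [5, 13])
    def test_clean_run_count(self, cfg, n):
        wave, _ = make_waggle_run(WaggleRunSpec(n_waggles=n), FS)
        rec = embed_waveforms([(0, 5.0, wave)], 15.0)
        truth = EventTruth("WRS", 0, 5.0, 5.0 + wave.size / FS, 13.0, n)
        assert abs(count_waggles(rec, truth, cfg) - n) <= 1

    def test_non_wrs_event_rejected(self, cfg):
        rec = embed_waveforms([], 30.0)
        frs = EventTruth("FRS", 0, 5.0, 25.0, 100.0)
        with pytest.raises(UsageError):
            count_waggles(rec, frs, cfg)

    def test_pure_noise_span_flagged_low_confidence(self, cfg):
        rng = np.random.default_rng(2)
        pink = np.fft.irfft(
            np.fft.rfft(rng.standard_normal(int(10 * FS)))
            * np.concatenate([[0], 1 / np.sqrt(np.fft.rfftfreq(int(10 * FS), 1 / FS)[1:])])
        )
        rec = embed_waveforms([(0, 0.0, pink)], 10.0)
        event = SignalEvent("WRS", 0, 4.0, 6.0, mean_power=1.0)
        count_waggles(rec, event, cfg)
        assert event.count_low_confidence

    def test_decode_constants(self, cfg):
        assert decode_distance(1, cfg) == 75.0
        assert decode_distance(0, cfg) == 0.0
        assert decode_distance(10, cfg) == 750.0

    def test_decode_linearity(self, cfg):
        for a, b in [(3, 4), (0, 9), (12, 30)]:
            assert decode_distance(a + b, cfg) == (
                decode_distance(a, cfg) + decode_distance(b, cfg)
            )

    def test_decode_negative_rejected(self, cfg):
        with pytest.raises(UsageError):
            decode_distance(-1, cfg)


def _wrs(channel, t0, dur=1.0, n=10, power=1.0):
    return SignalEvent(
        "WRS", channel, t0, t0 + dur, mean_power=power, n_waggles=n
    )


class TestBouts:
    def test_close_runs_form_one_bout(self, cfg):
        events = [_wrs(0, t, n=n) for t, n in [(0, 10), (3, 12), (6, 11), (9, 13)]]
        (bout,) = group_bouts(events, cfg)
        assert len(bout.members) == 4
        assert bout.median_waggles == 11.5
        assert bout.distance_m == 11.5 * 75.0
        assert bout.total_waggles == 46

    def test_distant_runs_stay_singletons(self, cfg):
        events = [_wrs(0, 0.0), _wrs(0, 9.0)]  # gap 8 s > 5 s
        bouts = group_bouts(events, cfg)
        assert [len(b.members) for b in bouts] == [1, 1]

    def test_channels_never_mix(self, cfg):
        events = [_wrs(0, 0.0), _wrs(1, 2.0)]
        assert len(group_bouts(events, cfg)) == 2

    def test_empty(self, cfg):
        assert group_bouts([], cfg) == []


class TestFuseChannels:
    def test_same_dance_on_two_channels_merges(self):
        a = _wrs(2, 10.0, dur=2.0, power=5.0)
        b = _wrs(3, 10.2, dur=2.0, power=1.0)
        (merged,) = fuse_channels([a, b])
        assert merged.channel == 2  # strongest member wins
        assert merged.t_start == 10.0
        assert merged.t_end == 12.2

    def test_disjoint_events_unchanged(self):
        a, b = _wrs(2, 0.0), _wrs(3, 5.0)
        assert len(fuse_channels([a, b])) == 2

    def test_transitive_chain_merges_once(self):
        a = _wrs(0, 0.0, dur=2.0)
        b = _wrs(1, 1.0, dur=2.0)
        c = _wrs(2, 2.0, dur=2.0)
        (merged,) = fuse_channels([a, b, c])
        assert merged.t_start == 0.0 and merged.t_end == 4.0

    def test_different_labels_never_merge(self):
        a = SignalEvent("SRS", 0, 0.0, 0.5, mean_power=1.0)
        b = _wrs(1, 0.0, dur=0.5)
        assert len(fuse_channels([a, b])) == 2


def _truths():
    return [
        EventTruth("WRS", ch, 10.0 * i, 10.0 * i + 1.0, 13.0, 10)
        for i, ch in enumerate([0, 1, 2, 3, 4, 0, 1, 2, 3, 4])
    ]


class TestEvaluate:
    def test_perfect_detection(self):
        truth = _truths()
        detected = [
            SignalEvent(t.label, t.channel, t.t_start, t.t_end, 1.0,
                        n_waggles=t.n_waggles)
            for t in truth
        ]
        res = evaluate(detected, truth)
        assert res.pooled.precision == 1.0 and res.pooled.recall == 1.0

    def test_empty_detected_flags_precision(self):
        res = evaluate([], _truths())
        assert res.pooled.recall == 0.0
        assert res.pooled.precision == 0.0
        assert not res.pooled.precision_defined

    def test_partial_detection_counts(self):
        truth = _truths()
        detected = [
            SignalEvent(t.label, t.channel, t.t_start, t.t_end, 1.0,
                        n_waggles=t.n_waggles)
            for t in truth[:8]
        ]
        detected += [_wrs(5, 500.0), _wrs(5, 600.0)]  # two spurious
        res = evaluate(detected, truth)
        assert res.pooled.recall == pytest.approx(0.8)
        assert res.pooled.precision == pytest.approx(0.8)
        m = res.per_class["WRS"]
        assert (m.tp, m.fp, m.fn) == (8, 2, 2)

    def test_label_mismatch_is_no_match(self):
        truth = [EventTruth("FRS", 0, 0.0, 20.0, 100.0)]
        detected = [_wrs(0, 0.0, dur=20.0)]
        res = evaluate(detected, truth)
        assert res.pooled.recall == 0.0

    def test_one_to_one_matching(self):
        truth = [EventTruth("WRS", 0, 0.0, 1.0, 13.0, 10)]
        detected = [_wrs(0, 0.0), _wrs(0, 0.1)]  # both overlap the one truth
        res = evaluate(detected, truth)
        assert res.pooled.tp == 1 and res.pooled.fp == 1


class TestDeterminism:
    def test_identical_input_identical_event_csv(self, cfg):
        wave, _ = make_waggle_run(WaggleRunSpec(), FS)
        srs, _ = make_srs(SrsSpec(), FS)

        def run():
            rec = embed_waveforms([(0, 10.0, wave), (1, 20.0, srs)], 40.0, seed=5)
            events = detect_events(rec, cfg, channels=[0, 1])
            return events_frame(events).to_csv(index=False)

        assert run() == run()

    def test_event_csv_round_trip(self, cfg):
        wave, _ = make_waggle_run(WaggleRunSpec(), FS)
        rec = embed_waveforms([(0, 10.0, wave)], 40.0)
        events = detect_events(rec, cfg, channels=[0])
        import io

        import pandas as pd

        csv = events_frame(events).to_csv(index=False)
        back = events_from_frame(pd.read_csv(io.StringIO(csv)))
        assert len(back) == len(events)
        assert back[0].label == events[0].label
        assert back[0].n_waggles == events[0].n_waggles
        assert back[0].t_start == pytest.approx(events[0].t_start, abs=1e-5)
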