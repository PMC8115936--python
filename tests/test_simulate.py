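"""Waveform generators, noise model, scenario rendering, activity, telemetry."""

import numpy as np
import pytest

from hivefield.errors import ParameterError, ScenarioError
from hivefield.simulate import (
    EventTruth,
    FanningSpec,
    NoiseSpec,
    Scenario,
    ScenarioEvent,
    SrsSpec,
    WaggleRunSpec,
    make_activity,
    make_fanning,
    make_noise,
    make_srs,
    make_telemetry,
    make_tone_burst,
    make_waggle_run,
    render_scenario,
    scenario_from_dict,
    scenario_to_dict,
)
from hivefield.spectral import DEFAULT_BANDS, band_power, stft_spectrogram

FS = 5000.0


def _psd(x, fs=FS):
    from scipy import signal as sps

    win = sps.windows.hann(x.size, sym=False)
    p = np.abs(np.fft.rfft(x * win)) ** 2
    return np.fft.rfftfreq(x.size, 1 / fs), p


class TestWaggleRun:
    def test_cycle_count_and_duration_without_fm(self):
        spec = WaggleRunSpec(
            waggle_freq=13.0, n_waggles=13, fm_depth=0.0, wing_sync_fraction=0.0
        )
        wave, truth = make_waggle_run(spec, FS)
        assert truth.duration == pytest.approx(1.0, abs=1e-6)
        assert truth.n_waggles == 13
        # 13 positive-going zero crossings of the low band, one per cycle
        rising = np.sum((wave[:-1] <= 0) & (wave[1:] > 0))
        assert rising == 13

    def test_fm_profile_changes_duration_only_slightly(self):
        base = make_waggle_run(WaggleRunSpec(fm_depth=0.0), FS)[1].duration
        fm = make_waggle_run(WaggleRunSpec(fm_depth=0.2), FS)[1].duration
        assert fm > base  # edge cycles run below the plateau frequency
        assert fm < 1.3 * base

    def test_wing_component_gated_off(self):
        wave, _ = make_waggle_run(WaggleRunSpec(wing_sync_fraction=0.0), FS)
        freqs, p = _psd(wave)
        high = p[(freqs >= 190) & (freqs < 230)].sum()
        assert high < 1e-9 * p.sum()

    def test_concurrent_low_and_high_ridges(self):
        wave, truth = make_waggle_run(WaggleRunSpec(n_waggles=26), FS)
        spec = stft_spectrogram(wave, FS, 0.2, 0.05)
        low = band_power(spec, DEFAULT_BANDS["WRS_L"]).power
        high = band_power(spec, DEFAULT_BANDS["WRS_H"]).power
        assert low.max() > 0 and high.max() > 0
        # both bands active over most of the run simultaneously
        active = (low > 0.1 * low.max()) & (high > 0.01 * high.max())
        assert active.mean() > 0.5

    def test_instantaneous_frequency_rises_then_falls(self):
        wave, truth = make_waggle_run(
            WaggleRunSpec(waggle_freq=13.0, n_waggles=30, fm_depth=0.3,
                          wing_sync_fraction=0.0),
            FS,
        )
        idx = np.nonzero((wave[:-1] <= 0) & (wave[1:] > 0))[0]
        freqs = FS / np.diff(idx)
        assert freqs[0] < freqs[freqs.size // 2]  # initial increase
        assert freqs[-1] < freqs[freqs.size // 2]  # final decrease

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            WaggleRunSpec(waggle_freq=30.0)
        with pytest.raises(ParameterError):
            WaggleRunSpec(n_waggles=0)
        with pytest.raises(ParameterError):
            WaggleRunSpec(wing_sync_fraction=1.5)


class TestSrs:
    def test_harmonic_peaks(self):
        wave, truth = make_srs(
            SrsSpec(fundamental=400.0, duration=0.5, n_harmonics=2), FS
        )
        freqs, p = _psd(wave)
        for f0 in (400, 800, 1200):
            region = p[(freqs > f0 - 20) & (freqs < f0 + 20)].sum()
            assert region > 0.01 * p.sum()
        assert truth.duration == pytest.approx(0.5)

    def test_duration_bound(self):
        with pytest.raises(ParameterError):
            SrsSpec(duration=1.2)

    def test_zero_amplitude_still_annotated(self):
        wave, truth = make_srs(SrsSpec(amplitude=0.0), FS)
        assert np.all(wave == 0)
        assert truth.label == "SRS"


class TestFanning:
    def test_duration_bound(self):
        with pytest.raises(ParameterError):
            FanningSpec(duration=10.0)

    def test_band_bound(self):
        with pytest.raises(ParameterError):
            FanningSpec(freq=150.0)

    def test_jitter_zero_is_pure_tone(self):
        wave, truth = make_fanning(FanningSpec(freq=100.0, duration=16.0), FS)
        freqs, p = _psd(wave)
        peak = freqs[np.argmax(p)]
        assert abs(peak - 100.0) < 0.2
        assert truth.duration == pytest.approx(16.0)


class TestEventTruthInvariants:
    def test_srs_duration_cap(self):
        with pytest.raises(ParameterError):
            EventTruth("SRS", 0, 0.0, 1.5, 400.0)

    def test_frs_duration_floor(self):
        with pytest.raises(ParameterError):
            EventTruth("FRS", 0, 0.0, 10.0, 100.0)

    def test_wrs_requires_waggle_count(self):
        with pytest.raises(ParameterError):
            EventTruth("WRS", 0, 0.0, 1.0, 13.0)


class TestNoise:
    def test_all_zero_spec(self):
        spec = NoiseSpec(white_rms=0, pink_rms=0, mains_rms=0, crowd_rms=0)
        assert np.all(make_noise(2.0, spec, FS, seed=3) == 0)

    def test_seed_determinism(self):
        spec = NoiseSpec()
        a = make_noise(2.0, spec, FS, seed=11)
        b = make_noise(2.0, spec, FS, seed=11)
        assert np.array_equal(a, b)

    def test_pink_spectral_slope(self):
        from scipy import signal as sps

        spec = NoiseSpec(white_rms=0, pink_rms=1.0, mains_rms=0, crowd_rms=0)
        x = make_noise(40.0, spec, FS, seed=5)
        f, p = sps.welch(x, FS, nperseg=16384)
        m = (f >= 10) & (f <= 500)
        slope = np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_rms_calibration(self):
        spec = NoiseSpec(white_rms=0.5, pink_rms=0, mains_rms=0, crowd_rms=0)
        x = make_noise(10.0, spec, FS, seed=2)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(0.5, rel=0.05)


class TestScenario:
    def test_empty_scenario_pure_noise(self):
        sc = Scenario(duration=2.0, events=[], noise=NoiseSpec(), seed=9)
        rec, truths = render_scenario(sc)
        assert truths == []
        assert rec.n_samples == 10000
        assert rec.channels.std() > 0

    def test_three_events_three_channels(self):
        sc = Scenario(
            duration=30.0,
            events=[
                ScenarioEvent(0, 2.0, WaggleRunSpec()),
                ScenarioEvent(1, 5.0, SrsSpec()),
                ScenarioEvent(2, 8.0, FanningSpec(duration=16.0)),
            ],
            noise=NoiseSpec(),
            seed=4,
        )
        rec, truths = render_scenario(sc)
        assert [t.label for t in truths] == ["WRS", "SRS", "FRS"]
        assert truths[0].t_start == 2.0
        assert truths[2].t_end == pytest.approx(24.0)

    def test_same_channel_overlap_rejected(self):
        sc = Scenario(
            duration=40.0,
            events=[
                ScenarioEvent(0, 2.0, FanningSpec(duration=16.0)),
                ScenarioEvent(0, 10.0, SrsSpec()),
            ],
            seed=0,
        )
        with pytest.raises(ScenarioError, match="overlap"):
            render_scenario(sc)

    def test_event_beyond_duration_rejected(self):
        sc = Scenario(
            duration=10.0, events=[ScenarioEvent(0, 5.0, FanningSpec(duration=16.0))]
        )
        with pytest.raises(ScenarioError):
            render_scenario(sc)

    def test_determinism_identical_bytes(self):
        def build():
            return Scenario(
                duration=20.0,
                events=[ScenarioEvent(3, 2.0, WaggleRunSpec()),
                        ScenarioEvent(1, 4.0, SrsSpec())],
                noise=NoiseSpec(),
                seed=77,
            )

        rec1, _ = render_scenario(build())
        rec2, _ = render_scenario(build())
        assert np.array_equal(rec1.channels, rec2.channels)

    def test_event_energy_zero_outside_span(self):
        silent = NoiseSpec(white_rms=0, pink_rms=0, mains_rms=0, crowd_rms=0)
        sc = Scenario(
            duration=10.0,
            events=[ScenarioEvent(2, 3.0, WaggleRunSpec())],
            noise=silent,
            seed=0,
        )
        rec, truths = render_scenario(sc)
        t = truths[0]
        i0, i1 = int(t.t_start * FS), int(np.ceil(t.t_end * FS))
        assert np.all(rec.channels[2, :i0] == 0)
        assert np.all(rec.channels[2, i1 + 1:] == 0)
        assert np.all(rec.channels[[0, 1, 3, 4, 5]] == 0)

    @pytest.mark.parametrize(
        "spec,band",
        [
            (WaggleRunSpec(), "WRS_L"),
            (SrsSpec(), "SRS"),
            (FanningSpec(duration=16.0), "FRS"),
        ],
    )
    def test_spectral_centroid_inside_labeled_band(self, spec, band):
        if isinstance(spec, WaggleRunSpec):
            wave, _ = make_waggle_run(spec, FS)
            lo, hi, cap = 5.0, 25.0, 50.0  # abdomen component below 50 Hz
        elif isinstance(spec, SrsSpec):
            wave, _ = make_srs(spec, FS)
            lo, hi, cap = 350.0, 2400.0, 2500.0
        else:
            wave, _ = make_fanning(spec, FS)
            lo, hi, cap = 90.0, 120.0, 2500.0
        freqs, p = _psd(wave)
        m = freqs <= cap
        centroid = np.sum(freqs[m] * p[m]) / np.sum(p[m])
        assert lo <= centroid < hi

    def test_yaml_dict_round_trip(self):
        sc = Scenario(
            duration=25.0,
            events=[ScenarioEvent(0, 1.0, WaggleRunSpec(n_waggles=7)),
                    ScenarioEvent(4, 3.0, SrsSpec(fundamental=500.0))],
            noise=NoiseSpec(mains_hz=60.0),
            seed=13,
        )
        back = scenario_from_dict(scenario_to_dict(sc))
        rec1, t1 = render_scenario(sc)
        rec2, t2 = render_scenario(back)
        assert np.array_equal(rec1.channels, rec2.channels)
        assert t1 == t2


class TestToneBurst:
    def test_envelopes(self):
        rect = make_tone_burst(100.0, 1.0, 1.0, FS, envelope="rect")
        hann = make_tone_burst(400.0, 0.5, 1.0, FS, envelope="hann")
        assert rect.size == 5000 and hann.size == 2500
        assert np.abs(rect).max() == pytest.approx(1.0, abs=0.01)
        assert np.abs(hann[:50]).max() < 0.05  # tapered start
        with pytest.raises(ParameterError):
            make_tone_burst(100.0, 1.0, 1.0, FS, envelope="boxcar")


class TestActivity:
    def test_clean_passages_counted_as_maxima(self):
        times = np.arange(10) * 2.0 + 1.0
        trace, n = make_activity(times, duration=22.0, noise_rms=0.0)
        assert n == 10
        x = trace.channels.mean(axis=0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(x, height=0.5)
        assert len(peaks) == 10

    def test_no_passages_flat(self):
        trace, n = make_activity([], duration=5.0, noise_rms=0.0)
        assert n == 0
        assert np.all(trace.channels == 0)

    def test_overlapping_passages_superpose(self):
        lone, _ = make_activity([5.0], duration=10.0, noise_rms=0.0)
        double, _ = make_activity([5.0, 5.0], duration=10.0, noise_rms=0.0)
        assert double.channels.max() == pytest.approx(
            2 * lone.channels.max(), rel=1e-6
        )

    def test_sample_rate_default(self):
        trace, _ = make_activity([1.0], duration=2.0)
        assert trace.sample_rate == 100.0
        assert trace.n_samples == 200


class TestTelemetry:
    def test_one_day_record_count(self):
        tel = make_telemetry(days=1)
        assert len(tel) == 720  # 86400 / 120
        assert np.all(np.diff(tel.timestamps) == 120.0)

    def test_zero_noise_holds_setpoint(self):
        tel = make_telemetry(days=1, temp_in_noise=0.0, brood_setpoint=35.0)
        assert np.all(tel.temp_in == 35.0)

    def test_diurnal_autocorrelation_peaks_at_24h(self):
        tel = make_telemetry(days=4, seed=3)
        x = tel.temp_out - tel.temp_out.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1:]
        ac /= ac[0]
        lag_day = 720
        window = ac[lag_day - 60 : lag_day + 60]
        assert np.argmax(window) == pytest.approx(60, abs=10)
        assert window.max() > 0.5
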