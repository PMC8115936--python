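"""Synthetic generator for hive monitoring streams with ground truth.

Produces the three streams a hive monitor records, with known annotations:

* ESF recordings containing parametric models of the three social-signal
  classes — waggle runs (5–25 Hz abdomen component with partially
  synchronised 190–230 Hz wing bursts), short pulses (<1 s, fundamental
  >350 Hz plus harmonics) and fanning (>15 s of highly regular 90–120 Hz
  waves) — embedded in realistic noise (white + 1/f + mains hum +
  low-frequency crowd clutter);
* entrance-capacitance traces with raised-cosine passage bumps;
* 120 s-cadence telemetry with diurnal structure.

The generator is the evaluation surface for the detector: every event is
returned with an :class:`EventTruth` annotation, and rendering is fully
deterministic under a scenario seed.

Waveform conventions
--------------------
Event waveforms are dimensionless floats with amplitude around 1; rendering
quantises the channel mix to ADC counts with a fixed gain of 2**18 counts
per unit, comfortably inside the 24-bit range.  The waggle-run abdomen
component is frequency modulated with a ramp (first 10 % of cycles) –
plateau (80 %) – decay (last 10 %) profile of fractional depth ``fm_depth``,
realising the characteristic initial rise, plateau and final fall of the
waggle frequency; phase is integrated so there are no discontinuities.
Band-local SNR is defined as RMS of the event waveform inside its defining
band over its span, divided by the in-band noise RMS, in dB.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParameterError, ScenarioError
from .formats import (
    ActivityTrace,
    ESFRecording,
    HiveMetadata,
    TelemetrySeries,
)
from .spectral import DEFAULT_BANDS, BandDef, bandpass

__all__ = [
    "EventTruth",
    "WaggleRunSpec",
    "SrsSpec",
    "FanningSpec",
    "NoiseSpec",
    "ScenarioEvent",
    "Scenario",
    "make_tone_burst",
    "make_waggle_run",
    "make_srs",
    "make_fanning",
    "make_noise",
    "render_scenario",
    "benchmark_scenario",
    "band_noise_rms",
    "make_activity",
    "make_telemetry",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "truth_frame",
    "truth_from_frame",
    "ADC_GAIN",
    "DEFAULT_UTC_START",
]

ADC_GAIN = float(2**18)  # counts per unit amplitude when quantising

#: 2020-04-20 06:00:00 UTC — recordings start at 06:00 UTC by default,
#: matching the monitor's operational window (06:00–23:59 UTC).
DEFAULT_UTC_START = 1_587_362_400

LABELS = ("WRS", "SRS", "FRS")


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth annotation of one social signal in a recording."""

    label: str
    channel: int
    t_start: float
    t_end: float
    fundamental_hz: float
    n_waggles: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.t_end > self.t_start:
            raise ParameterError("t_end must exceed t_start")
        dur = self.duration
        if self.label == "SRS" and dur >= 1.0:
            raise ParameterError(f"SRS events last less than 1 s, got {dur:.3f} s")
        if self.label == "FRS" and dur <= 15.0:
            raise ParameterError(f"FRS events last longer than 15 s, got {dur:.3f} s")
        if self.label == "WRS":
            if self.n_waggles is None or self.n_waggles < 1:
                raise ParameterError("WRS truth requires n_waggles >= 1")
        elif self.n_waggles is not None:
            raise ParameterError("n_waggles is defined for WRS only")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# Per-class waveform specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaggleRunSpec:
    """One waggle run: FM abdomen oscillation plus gated wing bursts.

    ``wing_sync_fraction`` is the share of waggle cycles that carry a wing
    burst ("partially synchronised"); ``fm_depth`` the fractional frequency
    excursion of the ramp–plateau–decay profile.
    """

    waggle_freq: float = 13.0  # Hz, abdomen waggling, 5–25
    wing_freq: float = 210.0  # Hz, wing vibration, 190–230
    n_waggles: int = 13
    wing_sync_fraction: float = 0.7
    amplitude: float = 1.0
    wing_amplitude: Optional[float] = None  # default: half the abdomen amplitude
    fm_depth: float = 0.2

    def __post_init__(self) -> None:
        if self.wing_amplitude is not None and self.wing_amplitude < 0:
            raise ParameterError("wing_amplitude must be >= 0")
        if not 5.0 <= self.waggle_freq <= 25.0:
            raise ParameterError("waggle_freq must lie in [5, 25] Hz")
        if not 190.0 <= self.wing_freq <= 230.0:
            raise ParameterError("wing_freq must lie in [190, 230] Hz")
        if self.n_waggles < 1:
            raise ParameterError("n_waggles must be >= 1")
        if not 0.0 <= self.wing_sync_fraction <= 1.0:
            raise ParameterError("wing_sync_fraction must lie in [0, 1]")
        if not 0.0 <= self.fm_depth < 1.0:
            raise ParameterError("fm_depth must lie in [0, 1)")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class SrsSpec:
    """One short pulse: Hann-windowed fundamental plus harmonics."""

    fundamental: float = 450.0  # Hz, > 350
    duration: float = 0.4  # s, < 1
    n_harmonics: int = 2
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.fundamental > 350.0:
            raise ParameterError("SRS fundamental must exceed 350 Hz")
        if not 0.0 < self.duration < 1.0:
            raise ParameterError("SRS duration must lie in (0, 1) s")
        if self.n_harmonics < 0:
            raise ParameterError("n_harmonics must be >= 0")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class FanningSpec:
    """One fanning episode: long, highly regular 90–120 Hz waves."""

    freq: float = 105.0  # Hz, 90–120
    duration: float = 20.0  # s, > 15
    jitter: float = 0.0  # fractional cycle-period jitter
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 90.0 <= self.freq <= 120.0:
            raise ParameterError("fanning frequency must lie in [90, 120] Hz")
        if not self.duration > 15.0:
            raise ParameterError("fanning lasts longer than 15 s")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive channel noise: white + 1/f + mains hum + crowd clutter.

    The crowd component models slow broadband clutter (<30 Hz) from many
    bees moving in front of the sensors, as a band-limited random walk.
    Default levels put a unit-amplitude event well above the floor; they
    are reporting conventions of this simulator, not field measurements.
    """

    white_rms: float = 0.05
    pink_rms: float = 0.10
    mains_hz: float = 50.0
    mains_rms: float = 0.05
    crowd_rms: float = 0.05

    def __post_init__(self) -> None:
        for name in ("white_rms", "pink_rms", "mains_rms", "crowd_rms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.mains_hz <= 0:
            raise ParameterError("mains_hz must be positive")

    def scaled(self, factor: float) -> "NoiseSpec":
        """All RMS levels multiplied by ``factor`` (hum frequency kept)."""
        return replace(
            self,
            white_rms=self.white_rms * factor,
            pink_rms=self.pink_rms * factor,
            mains_rms=self.mains_rms * factor,
            crowd_rms=self.crowd_rms * factor,
        )


EventSpec = Union[WaggleRunSpec, SrsSpec, FanningSpec]


@dataclass(frozen=True)
class ScenarioEvent:
    """Placement of one event spec on a channel at a start time."""

    channel: int
    t_start: float
    spec: EventSpec

    def __post_init__(self) -> None:
        if not 0 <= self.channel < ESFRecording.N_CHANNELS:
            raise ParameterError("channel must be in 0..5")
        if self.t_start < 0:
            raise ParameterError("t_start must be >= 0")


@dataclass
class Scenario:
    """A full synthetic recording: events, noise, duration and seed."""

    duration: float
    events: Sequence[ScenarioEvent] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    sample_rate: float = 5000.0
    meta: HiveMetadata = field(
        default_factory=lambda: HiveMetadata(
            "sim-hive", "sim-hw", utc_start=DEFAULT_UTC_START
        )
    )

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ScenarioError("scenario duration must be positive")


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------


def _phase_from_cycle_periods(periods: np.ndarray, sample_rate: float):
    """Sample grid and integrated phase for consecutive cycles.

    Each cycle ``c`` lasts ``periods[c]`` seconds at constant instantaneous
    frequency ``1/periods[c]``; the phase is continuous and advances by one
    full cycle per period.  Returns (waveform sample count, phase array).
    """
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    total = boundaries[-1]
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    cycle = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0,
                    periods.size - 1)
    frac = (t - boundaries[cycle]) / periods[cycle]
    phase = 2.0 * np.pi * (cycle + frac)
    return total, phase


def make_tone_burst(
    freq: float,
    duration: float,
    amplitude: float,
    sample_rate: float,
    envelope: str = "rect",
) -> np.ndarray:
    """A sinusoidal burst with a rectangular or Hann envelope.

    Building block for the per-class generators; also useful on its own for
    probing the detector with signals outside the class definitions (e.g.
    duration sweeps across the class boundaries).
    """
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = amplitude * np.sin(2.0 * np.pi * freq * t)
    if envelope == "hann":
        x *= 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))
    elif envelope != "rect":
        raise ParameterError(f"unknown envelope {envelope!r}")
    return x


def _gated_cycles(n_cycles: int, fraction: float) -> np.ndarray:
    """Deterministically pick ``round(fraction * n)`` cycles, evenly spread."""
    acc = np.floor((np.arange(n_cycles) + 1) * fraction + 1e-9)
    prev = np.floor(np.arange(n_cycles) * fraction + 1e-9)
    return (acc > prev)


def make_waggle_run(
    spec: WaggleRunSpec, sample_rate: float = 5000.0
) -> tuple[np.ndarray, EventTruth]:
    """Render one waggle run and its ground truth.

    The low-frequency component makes exactly ``n_waggles`` cycles; its
    instantaneous frequency ramps up over the first 10 % of cycles, holds a
    plateau at ``waggle_freq`` for 80 %, and decays over the last 10 %
    (excursion ``fm_depth``).  Wing bursts are amplitude-gated windows of a
    phase-continuous ``wing_freq`` oscillator placed on the selected share
    of cycles.
    """
    n = spec.n_waggles
    edge = max(1, int(round(0.1 * n))) if spec.fm_depth > 0 and n >= 3 else 0
    mult = np.ones(n)
    if edge:
        lo = 1.0 - spec.fm_depth
        # ramp ends at, and decay starts from, the plateau value
        mult[:edge] = np.linspace(lo, 1.0, edge + 1)[:-1]
        mult[n - edge:] = np.linspace(1.0, lo, edge + 1)[1:]
    periods = 1.0 / (spec.waggle_freq * mult)
    duration, phase = _phase_from_cycle_periods(periods, sample_rate)
    low = spec.amplitude * np.sin(phase)

    wave = low
    n_samples = low.size
    wing_amp = (
        spec.wing_amplitude
        if spec.wing_amplitude is not None
        else 0.5 * spec.amplitude
    )
    if spec.wing_sync_fraction > 0 and wing_amp > 0:
        t = np.arange(n_samples) / sample_rate
        wing = wing_amp * np.sin(2.0 * np.pi * spec.wing_freq * t)
        gate = np.zeros(n_samples)
        boundaries = np.concatenate([[0.0], np.cumsum(periods)])
        for c in np.nonzero(_gated_cycles(n, spec.wing_sync_fraction))[0]:
            # Hann bump over the central 60 % of the cycle
            a = boundaries[c] + 0.2 * periods[c]
            b = boundaries[c] + 0.8 * periods[c]
            i0, i1 = int(round(a * sample_rate)), int(round(b * sample_rate))
            i1 = min(i1, n_samples)
            if i1 > i0:
                m = i1 - i0
                gate[i0:i1] = np.maximum(
                    gate[i0:i1],
                    0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(m) / max(m - 1, 1))),
                )
        wave = low + gate * wing

    truth = EventTruth(
        label="WRS",
        channel=0,
        t_start=0.0,
        t_end=duration,
        fundamental_hz=spec.waggle_freq,
        n_waggles=n,
    )
    return wave, truth


def make_srs(
    spec: SrsSpec, sample_rate: float = 5000.0
) -> tuple[np.ndarray, EventTruth]:
    """Render one short pulse (Hann-windowed fundamental + harmonics)."""
    n = int(round(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    wave = np.zeros(n)
    nyq = sample_rate / 2.0
    for h in range(spec.n_harmonics + 1):
        f = spec.fundamental * (h + 1)
        if f >= nyq:
            break
        wave += (spec.amplitude / (h + 1)) * np.sin(2.0 * np.pi * f * t)
    wave *= 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))
    truth = EventTruth(
        label="SRS",
        channel=0,
        t_start=0.0,
        t_end=spec.duration,
        fundamental_hz=spec.fundamental,
    )
    return wave, truth


def make_fanning(
    spec: FanningSpec,
    sample_rate: float = 5000.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, EventTruth]:
    """Render one fanning episode: near-sinusoid with cycle-period jitter.

    ``jitter`` is the fractional standard deviation of the cycle period;
    0 gives a perfectly regular wave (regularity index ≈ 1) and larger
    values progressively smear the spectral line.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_cycles = int(round(spec.duration * spec.freq))
    base = 1.0 / spec.freq
    eps = np.clip(rng.standard_normal(n_cycles), -2.5, 2.5) if spec.jitter else 0.0
    periods = base * (1.0 + spec.jitter * eps) if spec.jitter else np.full(
        n_cycles, base
    )
    _, phase = _phase_from_cycle_periods(np.asarray(periods, float), sample_rate)
    wave = spec.amplitude * np.sin(phase)
    n_target = int(round(spec.duration * sample_rate))
    if wave.size >= n_target:
        wave = wave[:n_target]
    else:
        wave = np.pad(wave, (0, n_target - wave.size))
    truth = EventTruth(
        label="FRS",
        channel=0,
        t_start=0.0,
        t_end=spec.duration,
        fundamental_hz=spec.freq,
    )
    return wave, truth


def make_noise(
    duration: float,
    spec: NoiseSpec,
    sample_rate: float = 5000.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Additive noise: white + 1/f + mains sinusoid + crowd clutter.

    The 1/f component is white noise shaped in the frequency domain with a
    1/sqrt(f) amplitude profile (power slope −1); the crowd component is a
    mean-removed random walk low-passed below 30 Hz.  Each component is
    normalised to its requested RMS; reproducible under the seed.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    if spec.white_rms > 0:
        out += spec.white_rms * rng.standard_normal(n)
    if spec.pink_rms > 0:
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        shape = np.zeros_like(f)
        shape[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spectrum * shape, n=n)
        rms = np.sqrt(np.mean(pink**2))
        if rms > 0:
            out += spec.pink_rms / rms * pink
    if spec.mains_rms > 0:
        t = np.arange(n) / sample_rate
        phase = rng.uniform(0, 2 * np.pi)
        out += spec.mains_rms * math.sqrt(2.0) * np.sin(
            2.0 * np.pi * spec.mains_hz * t + phase
        )
    if spec.crowd_rms > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk -= walk.mean()
        from scipy import signal as sps

        sos = sps.butter(4, 30.0, btype="lowpass", fs=sample_rate, output="sos")
        walk = sps.sosfiltfilt(sos, walk)
        rms = np.sqrt(np.mean(walk**2))
        if rms > 0:
            out += spec.crowd_rms / rms * walk
    return out


# ---------------------------------------------------------------------------
# Scenario rendering
# ---------------------------------------------------------------------------


def _render_event(
    ev: ScenarioEvent, sample_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, EventTruth]:
    if isinstance(ev.spec, WaggleRunSpec):
        wave, truth = make_waggle_run(ev.spec, sample_rate)
    elif isinstance(ev.spec, SrsSpec):
        wave, truth = make_srs(ev.spec, sample_rate)
    elif isinstance(ev.spec, FanningSpec):
        wave, truth = make_fanning(ev.spec, sample_rate, rng=rng)
    else:
        raise ParameterError(f"unknown event spec {type(ev.spec).__name__}")
    truth = replace(
        truth,
        channel=ev.channel,
        t_start=ev.t_start,
        t_end=ev.t_start + truth.t_end,
    )
    return wave, truth


def render_scenario(sc: Scenario) -> tuple[ESFRecording, list[EventTruth]]:
    """Render a scenario to a 6-channel recording plus sorted ground truth.

    Each event waveform is added to its channel at its span on top of
    independent per-channel noise; event waveform energy is exactly zero
    outside the span.  Rendering is deterministic under ``sc.seed``.
    Same-channel events must not overlap.
    """
    fs = sc.sample_rate
    n = int(round(sc.duration * fs))
    root = np.random.SeedSequence(sc.seed)
    noise_seeds, event_seeds = root.spawn(2)
    channel_rngs = [np.random.default_rng(s) for s in noise_seeds.spawn(6)]
    event_rngs = [np.random.default_rng(s) for s in event_seeds.spawn(
        max(len(sc.events), 1)
    )]

    signal = np.zeros((ESFRecording.N_CHANNELS, n))
    truths: list[EventTruth] = []
    spans: dict[int, list[tuple[float, float]]] = {}
    for ev, rng in zip(sc.events, event_rngs):
        wave, truth = _render_event(ev, fs, rng)
        if truth.t_end > sc.duration + 1e-9:
            raise ScenarioError(
                f"event on channel {ev.channel} ends at {truth.t_end:.2f} s, "
                f"beyond the {sc.duration:.2f} s scenario"
            )
        for a, b in spans.setdefault(ev.channel, []):
            if truth.t_start < b and a < truth.t_end:
                raise ScenarioError(
                    f"events overlap on channel {ev.channel} near {a:.2f} s"
                )
        spans[ev.channel].append((truth.t_start, truth.t_end))
        i0 = int(round(truth.t_start * fs))
        i1 = min(i0 + wave.size, n)
        signal[ev.channel, i0:i1] += wave[: i1 - i0]
        truths.append(truth)

    for ch in range(ESFRecording.N_CHANNELS):
        signal[ch] += make_noise(sc.duration, sc.noise, fs, seed=channel_rngs[ch])

    counts = np.round(signal * ADC_GAIN)
    peak = np.abs(counts).max(initial=0)
    if peak > (2**23 - 1):
        raise ScenarioError(
            f"rendered signal exceeds the 24-bit ADC range (peak {peak:.0f} "
            "counts); lower amplitudes or noise levels"
        )
    rec = ESFRecording(
        channels=counts.astype(np.int32), sample_rate=fs, meta=sc.meta
    )
    truths.sort(key=lambda tr: tr.t_start)
    return rec, truths


def band_noise_rms(
    noise: NoiseSpec,
    band: BandDef,
    sample_rate: float = 5000.0,
    duration: float = 30.0,
    seed: int = 12345,
) -> float:
    """In-band RMS of a noise realisation (denominator of band-local SNR)."""
    x = make_noise(duration, noise, sample_rate, seed=seed)
    return float(np.sqrt(np.mean(bandpass(x, sample_rate, band) ** 2)))


def _event_band_rms(wave: np.ndarray, band: BandDef, sample_rate: float) -> float:
    filtered = bandpass(wave, sample_rate, band)
    return float(np.sqrt(np.mean(filtered**2)))


def benchmark_scenario(
    n_per_class: int = 50,
    snr_db: float = 10.0,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    sample_rate: float = 5000.0,
    gap_s: tuple[float, float] = (10.0, 18.0),
) -> Scenario:
    """Standard evaluation scenario: ``n_per_class`` events per class.

    Event parameters are drawn uniformly inside their class bands (waggle
    runs: 10–16 Hz with 8–25 waggles; pulses: 380–800 Hz fundamentals,
    0.2–0.8 s; fanning: 95–115 Hz, 16–24 s, 2 % jitter) and every event is
    scaled so its band-local SNR in its defining band equals ``snr_db``
    (waggle runs carry two defining bands, and the abdomen and wing
    components are scaled independently in theirs).  Events are dealt
    round-robin over the six channels with random inter-event gaps; the
    default gaps keep fanning below about a third of any channel's
    timeline, since the rolling-median detection baseline assumes events
    are sparse at the baseline-window scale.  The scenario length adapts to
    its content.
    """
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEE)))
    target = {
        name: band_noise_rms(noise, DEFAULT_BANDS[name], sample_rate)
        * 10.0 ** (snr_db / 20.0)
        for name in ("WRS_L", "WRS_H", "SRS", "FRS")
    }

    specs: list[EventSpec] = []
    for _ in range(n_per_class):
        specs.append(
            WaggleRunSpec(
                waggle_freq=rng.uniform(10.0, 16.0),
                wing_freq=rng.uniform(195.0, 225.0),
                n_waggles=int(rng.integers(8, 26)),
                wing_sync_fraction=0.7,
                amplitude=1.0,
                fm_depth=0.2,
            )
        )
    for _ in range(n_per_class):
        specs.append(
            SrsSpec(
                fundamental=rng.uniform(380.0, 800.0),
                duration=rng.uniform(0.2, 0.8),
                n_harmonics=2,
                amplitude=1.0,
            )
        )
    for _ in range(n_per_class):
        specs.append(
            FanningSpec(
                freq=rng.uniform(95.0, 115.0),
                duration=rng.uniform(16.0, 24.0),
                jitter=0.02,
                amplitude=1.0,
            )
        )
    rng.shuffle(specs)

    defining = {"WaggleRunSpec": "WRS_L", "SrsSpec": "SRS", "FanningSpec": "FRS"}
    events: list[ScenarioEvent] = []
    cursor = [1.0 + rng.uniform(0.0, 2.0) for _ in range(6)]
    probe_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFACE)))
    for i, spec in enumerate(specs):
        wave, truth = _render_event(
            ScenarioEvent(channel=0, t_start=0.0, spec=spec),
            sample_rate,
            probe_rng,
        )
        band = DEFAULT_BANDS[defining[type(spec).__name__]]
        rms = _event_band_rms(wave, band, sample_rate)
        scale = target[band.name] / max(rms, 1e-12)
        if isinstance(spec, WaggleRunSpec):
            # scale abdomen and wing components in their own bands
            rms_h = _event_band_rms(wave, DEFAULT_BANDS["WRS_H"], sample_rate)
            wing = spec.wing_amplitude
            if wing is None:
                wing = 0.5 * spec.amplitude
            spec = replace(
                spec,
                amplitude=spec.amplitude * scale,
                wing_amplitude=wing * target["WRS_H"] / max(rms_h, 1e-12),
            )
        else:
            spec = replace(spec, amplitude=spec.amplitude * scale)
        ch = i % 6
        events.append(ScenarioEvent(channel=ch, t_start=cursor[ch], spec=spec))
        cursor[ch] += truth.duration + rng.uniform(*gap_s)
    duration = max(cursor) + 2.0
    return Scenario(
        duration=duration, events=events, noise=noise, seed=seed,
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# Activity and telemetry streams
# ---------------------------------------------------------------------------


def make_activity(
    passage_times: Sequence[float],
    duration: float,
    bump_width: float = 0.3,
    amplitude_per_bee: float = 1.0,
    noise_rms: float = 0.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    channel_lag: float = 0.05,
    meta: Optional[HiveMetadata] = None,
) -> tuple[ActivityTrace, int]:
    """Entrance-capacitance trace with one raised-cosine bump per passage.

    Each bee passing through the entrance tube adds a raised-cosine bump of
    support ``bump_width`` seconds to both channels; the second channel lags
    by ``channel_lag`` (the tube has two sensors in series).  Overlapping
    passages superpose linearly.  Returns the trace and the true passage
    count.
    """
    times = np.asarray(passage_times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > duration):
        raise ParameterError("passage times must lie within the trace duration")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    channels = np.zeros((2, n), dtype=np.float64)
    half = bump_width / 2.0
    for t0 in times:
        for ch, lag in enumerate((0.0, channel_lag)):
            centre = t0 + lag
            i0 = max(0, int(math.floor((centre - half) * sample_rate)))
            i1 = min(n, int(math.ceil((centre + half) * sample_rate)) + 1)
            if i1 <= i0:
                continue
            tt = np.arange(i0, i1) / sample_rate - centre
            bump = np.where(
                np.abs(tt) <= half,
                0.5 * amplitude_per_bee * (1.0 + np.cos(np.pi * tt / half)),
                0.0,
            )
            channels[ch, i0:i1] += bump
    if noise_rms > 0:
        channels += noise_rms * rng.standard_normal(channels.shape)
    if meta is None:
        meta = HiveMetadata("sim-hive", "sim-hw", utc_start=DEFAULT_UTC_START)
    return (
        ActivityTrace(channels=channels, sample_rate=sample_rate, meta=meta),
        int(times.size),
    )


def make_telemetry(
    days: int,
    utc_start: int = DEFAULT_UTC_START,
    brood_setpoint: float = 35.0,
    temp_in_noise: float = 0.3,
    temp_out_mean: float = 18.0,
    temp_out_amp: float = 8.0,
    hum_out_mean: float = 65.0,
    hum_out_amp: float = 20.0,
    hive_mass_kg: float = 60.0,
    seed: int = 0,
    meta: Optional[HiveMetadata] = None,
) -> TelemetrySeries:
    """Telemetry at the monitor's 120 s cadence with diurnal structure.

    In-hive temperature is clamped near the brood-nest set point (bees
    thermoregulate the brood to ≈35 °C) with small noise; outdoor
    temperature and humidity follow anti-phase sinusoidal diurnal cycles
    (temperature peaking at 16:00 UTC) plus noise.  One day yields
    86400 / 120 = 720 records.
    """
    if days < 1:
        raise ParameterError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n = days * int(86400 / TelemetrySeries.NOMINAL_CADENCE_S)
    ts = utc_start + np.arange(n) * TelemetrySeries.NOMINAL_CADENCE_S
    hour = (ts % 86400) / 3600.0
    diurnal = np.sin(2.0 * np.pi * (hour - 10.0) / 24.0)  # peak at 16:00 UTC
    temp_out = temp_out_mean + temp_out_amp * diurnal + 0.5 * rng.standard_normal(n)
    hum_out = np.clip(
        hum_out_mean - hum_out_amp * diurnal + 2.0 * rng.standard_normal(n),
        0.0,
        100.0,
    )
    temp_in = brood_setpoint + temp_in_noise * rng.standard_normal(n)
    hum_in = np.clip(55.0 + 3.0 * rng.standard_normal(n), 0.0, 100.0)
    per_cell = hive_mass_kg / 3.0
    loads = per_cell + 0.05 * rng.standard_normal((3, n))
    mcu = temp_out + 4.0 + 0.3 * rng.standard_normal(n)
    if meta is None:
        meta = HiveMetadata("sim-hive", "sim-hw", utc_start=int(utc_start))
    return TelemetrySeries(
        timestamps=ts,
        temp_in=temp_in,
        temp_out=temp_out,
        hum_in=hum_in,
        hum_out=hum_out,
        load_cells=loads,
        mcu_temp=mcu,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Scenario serialisation (YAML/JSON-friendly dicts)
# ---------------------------------------------------------------------------

_SPEC_KINDS = {"waggle": WaggleRunSpec, "srs": SrsSpec, "fanning": FanningSpec}
_KIND_NAMES = {cls: kind for kind, cls in _SPEC_KINDS.items()}


def scenario_to_dict(sc: Scenario) -> dict:
    """Plain-dict form of a scenario (YAML/JSON round-trippable)."""
    events = []
    for ev in sc.events:
        d = dataclasses.asdict(ev.spec)
        d["kind"] = _KIND_NAMES[type(ev.spec)]
        d["channel"] = ev.channel
        d["t_start"] = ev.t_start
        events.append(d)
    return {
        "duration": sc.duration,
        "seed": sc.seed,
        "sample_rate": sc.sample_rate,
        "noise": dataclasses.asdict(sc.noise),
        "meta": {
            "hive_id": sc.meta.hive_id,
            "hardware_id": sc.meta.hardware_id,
            "utc_start": sc.meta.utc_start,
        },
        "events": events,
    }


def scenario_from_dict(data: dict) -> Scenario:
    """Build a scenario from its plain-dict form (inverse of
    :func:`scenario_to_dict`)."""
    events = []
    for d in data.get("events", []):
        d = dict(d)
        kind = d.pop("kind")
        if kind not in _SPEC_KINDS:
            raise ScenarioError(
                f"unknown event kind {kind!r}; expected one of "
                f"{sorted(_SPEC_KINDS)}"
            )
        channel = d.pop("channel")
        t_start = d.pop("t_start")
        events.append(
            ScenarioEvent(channel=channel, t_start=t_start,
                          spec=_SPEC_KINDS[kind](**d))
        )
    meta_d = data.get("meta", {})
    meta = HiveMetadata(
        hive_id=meta_d.get("hive_id", "sim-hive"),
        hardware_id=meta_d.get("hardware_id", "sim-hw"),
        utc_start=meta_d.get("utc_start", DEFAULT_UTC_START),
    )
    return Scenario(
        duration=data["duration"],
        events=events,
        noise=NoiseSpec(**data.get("noise", {})),
        seed=data.get("seed", 0),
        sample_rate=data.get("sample_rate", 5000.0),
        meta=meta,
    )


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML file."""
    import yaml

    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(sc: Scenario, path) -> None:
    """Write a scenario to a YAML file."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def truth_from_frame(df: pd.DataFrame) -> list[EventTruth]:
    """Parse ground-truth annotations from their CSV/DataFrame form."""
    truths = []
    for row in df.itertuples(index=False):
        n = getattr(row, "n_waggles", "")
        n_waggles = None
        if n != "" and not (isinstance(n, float) and math.isnan(n)):
            n_waggles = int(n)
        truths.append(
            EventTruth(
                label=row.label,
                channel=int(row.channel),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                fundamental_hz=float(row.fundamental_hz),
                n_waggles=n_waggles,
            )
        )
    return truths


def truth_frame(truths: Sequence[EventTruth]) -> pd.DataFrame:
    """Ground-truth annotations as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "label": [t.label for t in truths],
            "channel": [t.channel for t in truths],
            "t_start": [t.t_start for t in truths],
            "t_end": [t.t_end for t in truths],
            "n_waggles": [t.n_waggles if t.n_waggles is not None else "" for t in truths],
            "fundamental_hz": [t.fundamental_hz for t in truths],
        }
    )
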