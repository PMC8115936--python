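"""Detection, classification and decoding of honeybee social signals.

The detector works per ESF channel in four stages:

1. **Band-power segmentation** — STFT band-power traces (one per named
   band) are compared against ``k`` times a rolling-median baseline, with a
   hysteresis on the falling edge; contiguous supra-threshold frame runs
   become candidate intervals.
2. **Edge refinement** — each candidate's span is re-measured on the
   band-passed waveform itself: the amplitude envelope (analytic signal,
   lightly smoothed) is thresholded at the maximum of a relative floor and
   a noise-based floor, and the supported run containing the envelope peak
   gives the event span.  Waveform-level refinement avoids the up-to-one-
   window smearing of STFT frame edges, which matters against the 1 s
   short-pulse bound.
3. **Rule-based classification** — in priority order FRS > SRS > WRS:
   fanning (FRS) is a 90–120 Hz interval lasting at least 15 s whose
   regularity index clears a minimum; a short pulse (SRS) is a >350 Hz
   interval lasting at most 1 s; a waggle run (WRS) is a 5–25 Hz interval
   of plausible duration with a sufficiently concurrent 190–230 Hz wing
   interval.  A time span consumed by a higher-priority label is removed
   from the remaining candidate pools, so per-channel events never overlap.
4. **Decoding** — waggle cycles are counted as positive-going zero
   crossings of the zero-phase band-passed waveform, and distance follows
   the classical dance-decoding rule of 75 m per waggle.

Waggle runs typically occur in bouts; :func:`group_bouts` clusters
consecutive same-channel runs and decodes a per-bout distance from the
median waggle count.  :func:`evaluate` scores detections against ground
truth by greedy one-to-one interval matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

import yaml

from .errors import ParameterError, UsageError
from .formats import ESFRecording
from .simulate import EventTruth
from .spectral import (
    DEFAULT_BANDS,
    BandDef,
    BandPowerTrace,
    analysis_params,
    band_power,
    bandpass,
    regularity_index,
    stft_spectrogram,
)

__all__ = [
    "DetectorConfig",
    "CandidateInterval",
    "SignalEvent",
    "DanceBout",
    "ClassMetrics",
    "EvaluationResult",
    "segment_band",
    "classify",
    "detect_events",
    "count_waggles",
    "decode_distance",
    "group_bouts",
    "fuse_channels",
    "evaluate",
    "events_frame",
    "events_from_frame",
]

# Defining class bounds (seconds): short pulses last at most 1 s, fanning
# at least 15 s.  Boundary values are accepted.
SRS_MAX_DURATION = 1.0
FRS_MIN_DURATION = 15.0


@dataclass
class DetectorConfig:
    """All detector thresholds, exposed and serialisable.

    ``threshold_k`` multiplies the rolling-median baseline of each band
    power trace; raising it reproduces the deliberately conservative
    behaviour of the original field converter (fewer false positives, more
    misses).  ``baseline_window_s`` is per band: it must comfortably exceed
    the longest event expected in that band, otherwise the baseline tracks
    the event itself (the fanning band therefore uses 120 s).
    """

    bands: dict[str, BandDef] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    threshold_k: float = 4.0
    hysteresis: float = 0.5
    baseline_window_s: dict[str, float] = field(
        default_factory=lambda: {"WRS_L": 30.0, "WRS_H": 5.0, "FRS": 120.0,
                                 "SRS": 5.0, "ENV_380_400": 5.0}
    )
    baseline_quantile: dict[str, float] = field(
        default_factory=lambda: {"FRS": 0.2}
    )
    merge_gap_s: float = 0.1
    srs_min_duration_s: float = 0.02
    srs_max_duration_s: float = SRS_MAX_DURATION
    frs_min_duration_s: float = FRS_MIN_DURATION
    frs_max_duration_s: float = float("inf")
    wrs_min_duration_s: float = 0.4
    wrs_max_duration_s: float = 10.0
    frs_regularity_min: float = 0.6
    wrs_concurrency_min: float = 0.3
    band_dominance_min: float = 0.4
    # genuine wing bursts carry a few % of a run's power (gated, at half the
    # abdomen amplitude); leakage phantoms carry orders of magnitude less
    wrs_wing_dominance_min: float = 0.01
    # wing activity inside a known low-band interval is confirmed against a
    # milder threshold than open-ended detection (k applies to searches, not
    # to a yes/no check at a fixed location)
    wing_confirm_k: float = 2.0
    bout_max_gap_s: float = 5.0
    meters_per_waggle: float = 75.0
    refine_rel_floor: dict[str, float] = field(
        default_factory=lambda: {"WRS_L": 0.02, "WRS_H": 0.02, "FRS": 1e-3,
                                 "SRS": 3e-4}
    )
    refine_noise_factor: float = 1.5
    count_presence_min: float = 0.6
    compute_fm_score: bool = False

    def __post_init__(self) -> None:
        if self.threshold_k <= 1:
            raise ParameterError("threshold_k must exceed 1")
        if not 0 < self.hysteresis <= 1:
            raise ParameterError("hysteresis must lie in (0, 1]")
        if self.meters_per_waggle <= 0:
            raise ParameterError("meters_per_waggle must be positive")
        for lo, hi, name in (
            (self.srs_min_duration_s, self.srs_max_duration_s, "SRS"),
            (self.frs_min_duration_s, self.frs_max_duration_s, "FRS"),
            (self.wrs_min_duration_s, self.wrs_max_duration_s, "WRS"),
        ):
            if not 0 < lo < hi:
                raise ParameterError(f"{name} duration bounds must be 0 < min < max")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {
            k: {"f_lo": b["f_lo"], "f_hi": b["f_hi"]} for k, b in d["bands"].items()
        }
        d["frs_max_duration_s"] = (
            None if np.isinf(self.frs_max_duration_s) else self.frs_max_duration_s
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {
                k: BandDef(k, v["f_lo"], v["f_hi"]) for k, v in d["bands"].items()
            }
        if d.get("frs_max_duration_s") is None:
            d["frs_max_duration_s"] = float("inf")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class CandidateInterval:
    """A supra-threshold interval of one band-power trace."""

    channel: int
    band: str
    t_start: float
    t_end: float
    peak_power: float
    mean_power: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ParameterError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SignalEvent:
    """One detected social signal."""

    label: str
    channel: int
    t_start: float
    t_end: float
    mean_power: float
    peak_power: float = 0.0
    n_waggles: Optional[int] = None
    regularity: Optional[float] = None
    distance_m: Optional[float] = None
    count_low_confidence: bool = False
    fm_score: Optional[float] = None

    def __post_init__(self) -> None:
        dur = self.duration
        if self.label == "SRS" and dur > SRS_MAX_DURATION + 1e-9:
            raise ParameterError(f"SRS events last at most 1 s, got {dur:.3f} s")
        if self.label == "FRS" and dur < FRS_MIN_DURATION - 1e-9:
            raise ParameterError(f"FRS events last at least 15 s, got {dur:.3f} s")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class DanceBout:
    """Consecutive waggle runs by (presumably) one dancer."""

    members: list[SignalEvent]
    t_start: float
    t_end: float
    total_waggles: int
    median_waggles: float
    distance_m: float


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _rolling_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window=max(window, 1), center=True, min_periods=1).quantile(
        q
    ).to_numpy()


def segment_band(
    trace: BandPowerTrace,
    cfg: DetectorConfig,
    channel: int = 0,
) -> list[CandidateInterval]:
    """Segment one band-power trace into candidate intervals.

    An interval opens when power exceeds ``k`` times the rolling-quantile
    baseline (median by default; the fanning band uses a lower quantile
    because its events are long relative to the baseline window) and closes
    when it falls below ``hysteresis`` times that threshold; intervals
    separated by less than the merge gap are merged.
    Interval edges are the outer extent of the active analysis windows
    (frame centre ± window/2); precise event edges are re-measured later on
    the waveform.
    """
    power = trace.power
    if power.size == 0:
        return []
    window_s = cfg.baseline_window_s.get(trace.band.name, 30.0)
    win_frames = max(1, int(round(window_s / trace.hop_s)))
    q = cfg.baseline_quantile.get(trace.band.name, 0.5)
    baseline = _rolling_quantile(power, win_frames, q)
    rise = cfg.threshold_k * baseline
    fall = cfg.hysteresis * rise

    runs: list[tuple[int, int]] = []
    open_at: Optional[int] = None
    for i in range(power.size):
        if open_at is None:
            if power[i] > rise[i]:
                open_at = i
        elif power[i] < fall[i]:
            runs.append((open_at, i - 1))
            open_at = None
    if open_at is not None:
        runs.append((open_at, power.size - 1))

    half = trace.window_s / 2.0
    intervals: list[list] = []
    for i0, i1 in runs:
        t0 = trace.times[i0] - half
        t1 = trace.times[i1] + half
        if intervals and t0 - intervals[-1][1] < cfg.merge_gap_s:
            intervals[-1][1] = t1
            intervals[-1][2] = max(intervals[-1][2], i0)
            intervals[-1][3] = i1
        else:
            intervals.append([t0, t1, i0, i1])

    out = []
    for t0, t1, i0, i1 in intervals:
        seg = power[i0 : i1 + 1]
        out.append(
            CandidateInterval(
                channel=channel,
                band=trace.band.name,
                t_start=max(t0, 0.0),
                t_end=t1,
                peak_power=float(seg.max()),
                mean_power=float(seg.mean()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Waveform-level edge refinement
# ---------------------------------------------------------------------------

#: Envelope smoothing (s) per band; roughly a couple of cycles of the lower
#: band edge, longer for the fanning band to bridge noise-induced dips in
#: long events.
_ENV_SMOOTH_S = {"WRS_L": 0.2, "WRS_H": 0.05, "FRS": 0.5, "SRS": 0.01}

#: Maximum dip below the envelope floor (s) bridged when growing the
#: supported run: destructive noise interference briefly notches the
#: envelope of a genuine event, and long events (fanning) must survive such
#: notches without being split.  Kept well below the inter-event gaps that
#: matter per band (e.g. the 5 s bout gap for waggle runs).
_ENV_DIP_TOL_S = {"WRS_L": 0.2, "WRS_H": 0.1, "FRS": 1.0, "SRS": 0.02}


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    win = min(win, x.size)  # numpy 'same' would otherwise grow the output
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def _refine_span(
    x: np.ndarray,
    sample_rate: float,
    band: BandDef,
    cand: CandidateInterval,
    cfg: DetectorConfig,
) -> Optional[tuple[float, float]]:
    """Re-measure a candidate's span on the band-passed waveform envelope.

    Returns refined (t_start, t_end) in recording time, or None if no
    supported span is found.  The envelope is |analytic signal| smoothed by
    a moving average of width ``w``; crossings of the floor are corrected by
    ``w/2`` per edge for the smoothing-induced widening.
    """
    w_s = _ENV_SMOOTH_S.get(band.name, 0.05)
    margin = max(4.0 * w_s, 1.0)
    pad = w_s + margin
    i0 = max(0, int((cand.t_start - pad) * sample_rate))
    i1 = min(x.size, int(np.ceil((cand.t_end + pad) * sample_rate)))
    if i1 - i0 < 16:
        return None
    seg = bandpass(x[i0:i1], sample_rate, band)
    env = np.abs(sps.hilbert(seg))
    win = max(1, int(round(w_s * sample_rate)))
    env = _moving_average(env, win)

    # noise floor from margins outside the candidate, kept one smoothing
    # width clear of its edges so event energy cannot spill into them
    gap = int(round(w_s * sample_rate))
    c0 = int(cand.t_start * sample_rate) - i0
    c1 = int(np.ceil(cand.t_end * sample_rate)) - i0
    outside = np.concatenate(
        [env[: max(c0 - gap, 0)], env[min(c1 + gap, env.size):]]
    )
    noise_med = float(np.median(outside)) if outside.size else 0.0
    peak = float(env.max())
    if peak <= 0:
        return None
    rel = cfg.refine_rel_floor.get(band.name, 1e-3)
    floor = max(rel * peak, cfg.refine_noise_factor * noise_med)

    above = env >= floor
    p = int(np.argmax(env))
    if not above[p]:
        return None
    idx = np.nonzero(above)[0]
    dip = max(1, int(round(_ENV_DIP_TOL_S.get(band.name, 0.1) * sample_rate)))
    breaks = np.nonzero(np.diff(idx) > dip)[0]
    group = int(np.searchsorted(breaks, np.searchsorted(idx, p), side="left"))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    lo = int(idx[starts[group]])
    hi = int(idx[ends[group]])
    half = win / 2.0
    t0 = (i0 + lo + half) / sample_rate
    t1 = (i0 + hi - half) / sample_rate
    if t1 <= t0:
        mid = (i0 + lo + i0 + hi) / 2.0 / sample_rate
        return (mid - 0.5 / sample_rate, mid + 0.5 / sample_rate)
    return (t0, t1)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _overlaps(a0: float, a1: float, spans: Sequence[tuple[float, float]]) -> bool:
    return any(a0 < b1 and b0 < a1 for b0, b1 in spans)


def _overlap_len(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _band_power_rates(
    seg: np.ndarray, sample_rate: float, bands: Sequence[BandDef]
) -> np.ndarray:
    """Per-band mean-square power rate of a segment (Hann periodogram)."""
    win = sps.windows.hann(seg.size, sym=False)
    spec = np.abs(np.fft.rfft(seg * win)) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / sample_rate)
    norm = np.sum(win**2) * seg.size
    return np.array(
        [
            float(spec[(freqs >= b.f_lo) & (freqs < b.f_hi)].sum()) / norm
            for b in bands
        ]
    )


def _band_dominance(
    x: np.ndarray,
    sample_rate: float,
    t_start: float,
    t_end: float,
    numerator_bands: Sequence[BandDef],
    cfg: DetectorConfig,
    margin_s: float = 2.0,
) -> float:
    """Share of the span's *excess* detection-band power in the defining bands.

    Signals are told apart by their characteristic frequencies, so an event
    must carry most of its above-noise power in its own band(s).  Per band,
    the power rate of the margins flanking the span estimates the local
    noise and is subtracted from the span's power rate; the ratio of the
    defining bands' excess to the total excess over all four detection bands
    rejects candidates born of spectral leakage from a strong signal in
    another band.  Subtracting the noise matters because ambient noise is
    strongly coloured (1/f): raw low-band noise power would otherwise
    swamp a modest in-band signal in a higher band.  When both margins
    exist, the per-band minimum is used, so an adjacent event contaminating
    one margin cannot cancel its own in-span power out of the excess.
    """
    names = ("WRS_L", "WRS_H", "FRS", "SRS")
    bands = [cfg.bands[n] for n in names]
    i0 = max(0, int(round(t_start * sample_rate)))
    i1 = min(x.size, int(round(t_end * sample_rate)))
    if i1 - i0 < 8:
        return 0.0
    span_rates = _band_power_rates(x[i0:i1], sample_rate, bands)

    m = int(round(margin_s * sample_rate))
    pieces = []
    if i0 > 8:
        pieces.append(x[max(0, i0 - m) : i0])
    if i1 < x.size - 8:
        pieces.append(x[i1 : min(x.size, i1 + m)])
    if pieces:
        noise_rates = np.min(
            [_band_power_rates(p, sample_rate, bands) for p in pieces], axis=0
        )
    else:
        noise_rates = np.zeros(len(bands))

    excess = np.maximum(span_rates - noise_rates, 0.0)
    total = excess.sum()
    if total <= 0:
        return 0.0
    idx = [names.index(b.name) for b in numerator_bands]
    return float(excess[idx].sum() / total)


def _wing_active_fraction(
    trace: BandPowerTrace, t_start: float, t_end: float, cfg: DetectorConfig
) -> float:
    """Fraction of a span's frames with confirmed wing-band activity."""
    window_s = cfg.baseline_window_s.get(trace.band.name, 5.0)
    win_frames = max(1, int(round(window_s / trace.hop_s)))
    baseline = _rolling_quantile(trace.power, win_frames, 0.5)
    in_span = (trace.times >= t_start) & (trace.times < t_end)
    if not in_span.any():
        return 0.0
    active = trace.power[in_span] > cfg.wing_confirm_k * baseline[in_span]
    return float(active.mean())


def classify(
    candidates: Sequence[CandidateInterval],
    rec: ESFRecording,
    cfg: DetectorConfig,
    traces: Optional[dict[tuple[int, str], BandPowerTrace]] = None,
) -> list[SignalEvent]:
    """Apply the band-and-duration rules to candidate intervals.

    Rule order is FRS > SRS > WRS; a span consumed by a higher-priority
    label removes overlapping candidates from the lower-priority pools, so
    the returned events never overlap within a channel.  Duration bounds at
    the class boundaries are inclusive (a pulse measured at exactly 1 s is a
    short pulse; fanning measured at exactly 15 s is fanning).

    ``traces`` may carry precomputed band-power traces keyed by
    ``(channel, band_name)``; the wing concurrency check needs the WRS_H
    trace and computes it on demand otherwise.
    """
    fs = rec.sample_rate
    events: list[SignalEvent] = []
    by_channel: dict[int, list[CandidateInterval]] = {}
    for cand in candidates:
        by_channel.setdefault(cand.channel, []).append(cand)
    if traces is None:
        traces = {}

    for ch, cands in sorted(by_channel.items()):
        x = rec.channel_float(ch)
        consumed: list[tuple[float, float]] = []
        pools = {name: [c for c in cands if c.band == name] for name in
                 ("FRS", "SRS", "WRS_L", "WRS_H")}

        # 1 — fanning: long, highly regular 90–120 Hz waves
        for cand in pools["FRS"]:
            span = _refine_span(x, fs, cfg.bands["FRS"], cand, cfg)
            if span is None:
                continue
            dur = span[1] - span[0]
            if not cfg.frs_min_duration_s <= dur <= cfg.frs_max_duration_s:
                continue
            if (
                _band_dominance(x, fs, span[0], span[1], [cfg.bands["FRS"]], cfg)
                < cfg.band_dominance_min
            ):
                continue
            s0, s1 = int(span[0] * fs), int(span[1] * fs)
            reg = regularity_index(x[s0:s1], fs, cfg.bands["FRS"])
            if reg < cfg.frs_regularity_min:
                continue
            events.append(
                SignalEvent(
                    label="FRS", channel=ch, t_start=span[0], t_end=span[1],
                    mean_power=cand.mean_power, peak_power=cand.peak_power,
                    regularity=reg,
                )
            )
            consumed.append(span)

        # 2 — short pulses: <= 1 s, fundamental above 350 Hz
        for cand in pools["SRS"]:
            span = _refine_span(x, fs, cfg.bands["SRS"], cand, cfg)
            if span is None or _overlaps(span[0], span[1], consumed):
                continue
            dur = span[1] - span[0]
            if not cfg.srs_min_duration_s <= dur <= cfg.srs_max_duration_s:
                continue
            if (
                _band_dominance(x, fs, span[0], span[1], [cfg.bands["SRS"]], cfg)
                < cfg.band_dominance_min
            ):
                continue
            events.append(
                SignalEvent(
                    label="SRS", channel=ch, t_start=span[0], t_end=span[1],
                    mean_power=cand.mean_power, peak_power=cand.peak_power,
                )
            )
            consumed.append(span)

        # 3 — waggle runs: low-band interval with concurrent wing activity.
        # Two wing checks: (a) the span must hold genuine wing-band excess
        # power — in very quiet recordings the mere spectral leakage of a
        # strong low-band signal crosses the wing band's detection
        # threshold, and such phantoms must not count as wing vibration;
        # (b) wing-band power must be elevated over its baseline during a
        # sufficient share of the interval ("partially synchronised").
        wing_key = (ch, "WRS_H")
        if pools["WRS_L"] and wing_key not in traces:
            params = analysis_params(cfg.bands["WRS_H"])
            traces[wing_key] = band_power(
                stft_spectrogram(x, fs, *params), cfg.bands["WRS_H"]
            )
        for cand in pools["WRS_L"]:
            span = _refine_span(x, fs, cfg.bands["WRS_L"], cand, cfg)
            if span is None or _overlaps(span[0], span[1], consumed):
                continue
            dur = span[1] - span[0]
            if not cfg.wrs_min_duration_s <= dur <= cfg.wrs_max_duration_s:
                continue
            if (
                _band_dominance(
                    x, fs, span[0], span[1],
                    [cfg.bands["WRS_L"], cfg.bands["WRS_H"]], cfg,
                )
                < cfg.band_dominance_min
            ):
                continue
            wing_share = _band_dominance(
                x, fs, span[0], span[1], [cfg.bands["WRS_H"]], cfg
            )
            if wing_share < cfg.wrs_wing_dominance_min:
                continue
            if (
                _wing_active_fraction(traces[wing_key], span[0], span[1], cfg)
                < cfg.wrs_concurrency_min
            ):
                continue
            event = SignalEvent(
                label="WRS", channel=ch, t_start=span[0], t_end=span[1],
                mean_power=cand.mean_power, peak_power=cand.peak_power,
            )
            count, low_conf = _count_waggles_span(x, fs, span[0], span[1], cfg)
            event.n_waggles = count
            event.count_low_confidence = low_conf
            event.distance_m = decode_distance(count, cfg)
            if cfg.compute_fm_score:
                event.fm_score = _wrs_fm_score(x, fs, span[0], span[1], cfg)
            events.append(event)
            consumed.append(span)

    events.sort(key=lambda e: (e.t_start, e.channel))
    return events


def detect_events(
    rec: ESFRecording,
    cfg: Optional[DetectorConfig] = None,
    channels: Optional[Sequence[int]] = None,
) -> list[SignalEvent]:
    """End-to-end detection on a recording (all six channels by default)."""
    if cfg is None:
        cfg = DetectorConfig()
    candidates: list[CandidateInterval] = []
    traces: dict[tuple[int, str], BandPowerTrace] = {}
    detection_bands = [cfg.bands[name] for name in ("WRS_L", "WRS_H", "FRS", "SRS")]
    for ch in (range(rec.N_CHANNELS) if channels is None else channels):
        x = rec.channel_float(ch)
        specs: dict[tuple[float, float], object] = {}
        for band in detection_bands:
            params = analysis_params(band)
            if params not in specs:
                specs[params] = stft_spectrogram(x, rec.sample_rate, *params)
            trace = band_power(specs[params], band)
            traces[(ch, band.name)] = trace
            candidates.extend(segment_band(trace, cfg, channel=ch))
    return classify(candidates, rec, cfg, traces=traces)


# ---------------------------------------------------------------------------
# Waggle counting and distance decoding
# ---------------------------------------------------------------------------


def _count_waggles_span(
    x: np.ndarray,
    sample_rate: float,
    t_start: float,
    t_end: float,
    cfg: DetectorConfig,
) -> tuple[int, bool]:
    band = cfg.bands["WRS_L"]
    i0 = max(0, int(round(t_start * sample_rate)))
    i1 = min(x.size, int(round(t_end * sample_rate)))
    if i1 - i0 < 8:
        return 0, True
    seg = x[i0:i1]
    filtered = bandpass(seg, sample_rate, band)
    # gate crossings on the local envelope so filter ring-down outside the
    # run (or a noise-only margin) contributes no cycles
    env = np.abs(sps.hilbert(filtered))
    win = max(1, int(round(0.1 * sample_rate)))
    env = _moving_average(env, win)
    active = env >= 0.25 * env.max() if env.max() > 0 else env > 0
    rising = int(np.sum((filtered[:-1] <= 0) & (filtered[1:] > 0) & active[:-1]))
    falling = int(np.sum((filtered[:-1] >= 0) & (filtered[1:] < 0) & active[:-1]))
    # each cycle contributes one rising and one falling crossing; averaging
    # the two halves the sensitivity to whether a boundary crossing resolved
    crossings = (rising + falling + 1) // 2

    # presence score: in-band share of low-frequency power; pink noise
    # spreads its power across the whole 1–50 Hz range, a waggle run
    # concentrates it in the 5–25 Hz band
    win = sps.windows.hann(seg.size, sym=False)
    spec = np.abs(np.fft.rfft(seg * win)) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / sample_rate)
    in_band = spec[(freqs >= band.f_lo) & (freqs < band.f_hi)].sum()
    low_total = spec[(freqs >= 1.0) & (freqs < 50.0)].sum()
    presence = in_band / low_total if low_total > 0 else 0.0
    return crossings, bool(presence < cfg.count_presence_min)


def count_waggles(
    rec: ESFRecording,
    event: SignalEvent | EventTruth,
    cfg: Optional[DetectorConfig] = None,
) -> int:
    """Count waggle cycles in a waggle-run event.

    The event span is band-passed in the low (abdomen) band with a
    zero-phase filter and positive-going zero crossings are counted — one
    per waggle cycle.  Counting on a span that carries no waggle signal is
    unstable; such calls are flagged on the event
    (``count_low_confidence``) when the in-band power share is low.
    """
    if cfg is None:
        cfg = DetectorConfig()
    if event.label != "WRS":
        raise UsageError(f"count_waggles applies to WRS events, not {event.label}")
    count, low_conf = _count_waggles_span(
        rec.channel_float(event.channel), rec.sample_rate,
        event.t_start, event.t_end, cfg,
    )
    if isinstance(event, SignalEvent):
        event.n_waggles = count
        event.count_low_confidence = low_conf
    return count


def decode_distance(n_waggles: int, cfg: Optional[DetectorConfig] = None) -> float:
    """Distance to the advertised food source: waggle count × 75 m.

    The number of waggle cycles per run scales with the distance to the
    indicated food source at roughly 75 m per waggle (Haldane–Spurway
    calibration); the factor is configurable.
    """
    if n_waggles < 0:
        raise UsageError("n_waggles must be non-negative")
    mpw = cfg.meters_per_waggle if cfg is not None else 75.0
    return float(n_waggles) * mpw


def _wrs_fm_score(
    x: np.ndarray, sample_rate: float, t_start: float, t_end: float,
    cfg: DetectorConfig,
) -> float:
    """Optional score: does the run's frequency rise, plateau, then fall?

    Instantaneous frequency is estimated from successive positive-going
    zero-crossing intervals of the band-passed waveform and correlated with
    a ramp–plateau–decay template.  Proposed as an additional labelling cue;
    off by default.
    """
    band = cfg.bands["WRS_L"]
    i0, i1 = int(t_start * sample_rate), int(t_end * sample_rate)
    filtered = bandpass(x[i0:i1], sample_rate, band)
    idx = np.nonzero((filtered[:-1] <= 0) & (filtered[1:] > 0))[0]
    if idx.size < 5:
        return 0.0
    freqs = sample_rate / np.diff(idx)
    n = freqs.size
    edge = max(1, int(round(0.1 * n)))
    template = np.ones(n)
    template[:edge] = np.linspace(0.0, 1.0, edge + 1)[:-1]
    template[n - edge:] = np.linspace(1.0, 0.0, edge + 1)[1:]
    f = freqs - freqs.mean()
    t = template - template.mean()
    denom = np.sqrt((f**2).sum() * (t**2).sum())
    return float((f * t).sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Bouts and channel fusion
# ---------------------------------------------------------------------------


def group_bouts(
    events: Sequence[SignalEvent], cfg: Optional[DetectorConfig] = None
) -> list[DanceBout]:
    """Group consecutive same-channel waggle runs into dance bouts.

    Runs on the same channel separated by less than the bout gap belong to
    one bout; the bout's decoded distance uses the median member waggle
    count (robust against single miscounted runs).
    """
    if cfg is None:
        cfg = DetectorConfig()
    wrs = sorted(
        (e for e in events if e.label == "WRS"), key=lambda e: (e.channel, e.t_start)
    )
    bouts: list[DanceBout] = []
    current: list[SignalEvent] = []

    def _close(members: list[SignalEvent]) -> None:
        counts = [m.n_waggles or 0 for m in members]
        med = float(np.median(counts))
        bouts.append(
            DanceBout(
                members=list(members),
                t_start=members[0].t_start,
                t_end=members[-1].t_end,
                total_waggles=int(sum(counts)),
                median_waggles=med,
                distance_m=med * cfg.meters_per_waggle,
            )
        )

    for e in wrs:
        if current and (
            e.channel != current[-1].channel
            or e.t_start - current[-1].t_end >= cfg.bout_max_gap_s
        ):
            _close(current)
            current = []
        current.append(e)
    if current:
        _close(current)
    bouts.sort(key=lambda b: b.t_start)
    return bouts


def fuse_channels(
    events: Sequence[SignalEvent], overlap_fraction: float = 0.5
) -> list[SignalEvent]:
    """Merge the same signal seen on several sensors into one event.

    Six sensors face one dance floor, so a strong dance can register on
    neighbouring channels.  Same-label events on different channels whose
    temporal overlap is at least ``overlap_fraction`` of the shorter one are
    merged transitively; the merged event keeps the span union and the
    features of the strongest (highest mean power) member.
    """
    events = list(events)
    n = len(events)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = events[i], events[j]
            if a.label != b.label or a.channel == b.channel:
                continue
            ov = _overlap_len(a.t_start, a.t_end, b.t_start, b.t_end)
            if ov >= overlap_fraction * min(a.duration, b.duration):
                parent[find(i)] = find(j)

    groups: dict[int, list[SignalEvent]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(events[i])
    merged: list[SignalEvent] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        strongest = max(members, key=lambda e: e.mean_power)
        fused = dataclasses.replace(
            strongest,
            t_start=min(e.t_start for e in members),
            t_end=max(e.t_end for e in members),
        )
        merged.append(fused)
    merged.sort(key=lambda e: (e.t_start, e.channel))
    return merged


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True


@dataclass
class EvaluationResult:
    per_class: dict[str, ClassMetrics]
    pooled: ClassMetrics

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, m in {**self.per_class, "pooled": self.pooled}.items():
            rows.append(
                {
                    "label": label, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                    "precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "precision_defined": m.precision_defined,
                }
            )
        return pd.DataFrame(rows)


def _metrics(tp: int, fp: int, fn: int) -> ClassMetrics:
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return ClassMetrics(tp, fp, fn, precision, recall, f1, precision_defined)


def evaluate(
    detected: Sequence[SignalEvent],
    truth: Sequence[EventTruth],
    min_overlap: float = 0.3,
    match_channel: bool = True,
) -> EvaluationResult:
    """Score detections against ground truth by interval matching.

    A detection matches a truth event when they share the label (and
    channel, by default) and their temporal overlap is at least
    ``min_overlap`` of the truth span; matching is greedy one-to-one by
    descending overlap.  Precision with no detections is reported as 0 and
    flagged undefined.
    """
    pairs = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            if d.label != t.label:
                continue
            if match_channel and d.channel != t.channel:
                continue
            ov = _overlap_len(d.t_start, d.t_end, t.t_start, t.t_end)
            if ov >= min_overlap * t.duration:
                pairs.append((ov, di, ti))
    pairs.sort(key=lambda p: -p[0])
    matched_d: set[int] = set()
    matched_t: set[int] = set()
    for _, di, ti in pairs:
        if di in matched_d or ti in matched_t:
            continue
        matched_d.add(di)
        matched_t.add(ti)

    labels = sorted({e.label for e in detected} | {t.label for t in truth})
    per_class = {}
    for label in labels:
        tp = sum(
            1 for ti in matched_t if truth[ti].label == label
        )
        fn = sum(1 for t in truth if t.label == label) - tp
        fp = sum(1 for i, d in enumerate(detected)
                 if d.label == label and i not in matched_d)
        per_class[label] = _metrics(tp, fp, fn)
    pooled = _metrics(
        len(matched_t), len(detected) - len(matched_d), len(truth) - len(matched_t)
    )
    return EvaluationResult(per_class=per_class, pooled=pooled)


def events_from_frame(df: pd.DataFrame) -> list[SignalEvent]:
    """Parse detected events back from their CSV/DataFrame form."""
    events = []
    for row in df.itertuples(index=False):
        def _opt(value, cast):
            if value == "" or (isinstance(value, float) and np.isnan(value)):
                return None
            return cast(value)

        events.append(
            SignalEvent(
                label=row.label,
                channel=int(row.channel),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                mean_power=float(row.mean_power),
                n_waggles=_opt(getattr(row, "n_waggles", ""), int),
                distance_m=_opt(getattr(row, "distance_m", ""), float),
                regularity=_opt(getattr(row, "regularity", ""), float),
            )
        )
    return events


def events_frame(events: Sequence[SignalEvent]) -> pd.DataFrame:
    """Detected events as a deterministic, CSV-ready DataFrame."""
    return pd.DataFrame(
        {
            "label": [e.label for e in events],
            "channel": [e.channel for e in events],
            "t_start": [round(e.t_start, 6) for e in events],
            "t_end": [round(e.t_end, 6) for e in events],
            "n_waggles": [e.n_waggles if e.n_waggles is not None else "" for e in events],
            "distance_m": [e.distance_m if e.distance_m is not None else "" for e in events],
            "mean_power": [f"{e.mean_power:.6e}" for e in events],
            "regularity": [
                f"{e.regularity:.4f}" if e.regularity is not None else ""
                for e in events
            ],
        }
    )
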