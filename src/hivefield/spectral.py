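"""Time–frequency primitives for ESF signal analysis.

Honeybee social signals occupy well-separated frequency bands: abdomen
waggling at 5–25 Hz with wing vibration at 190–230 Hz (waggle runs), short
pulses with fundamentals above 350 Hz, and highly regular 90–120 Hz fanning
waves.  Everything downstream (segmentation, classification) works on STFT
band-power traces computed here.

Analysis uses two time–frequency resolutions: the low band needs ~1 Hz
resolution (1.0 s Hann window, 0.25 s hop) to resolve a 5 Hz component,
while short pulses (<1 s) need fine time resolution (0.2 s window, 0.05 s
hop).  Spectrogram power is a one-sided power spectral density
(amplitude²/Hz), so band sums obey Parseval's identity per windowed frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "BandDef",
    "Spectrogram",
    "BandPowerTrace",
    "stft_spectrogram",
    "band_power",
    "bandpass",
    "regularity_index",
    "DEFAULT_BANDS",
    "ENVIRONMENT_BANDS",
    "analysis_params",
]


@dataclass(frozen=True)
class BandDef:
    """A named half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi})"
            )

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


#: Detection bands.  The short-pulse band is open-ended in principle
#: (">350 Hz"); 2400 Hz keeps it just below the Nyquist limit of the
#: 5 kHz ADC stream.  ENV_380_400 is the narrow band used for
#: environmental comparisons, kept separate from the detection band.
DEFAULT_BANDS: dict[str, BandDef] = {
    "WRS_L": BandDef("WRS_L", 5.0, 25.0),
    "WRS_H": BandDef("WRS_H", 190.0, 230.0),
    "FRS": BandDef("FRS", 90.0, 120.0),
    "SRS": BandDef("SRS", 350.0, 2400.0),
    "ENV_380_400": BandDef("ENV_380_400", 380.0, 400.0),
}

#: Bands used for weather/seasonal comparisons (the low band widens to
#: 5–30 Hz in that context).
ENVIRONMENT_BANDS: dict[str, BandDef] = {
    "ENV_5_30": BandDef("ENV_5_30", 5.0, 30.0),
    "WRS_H": DEFAULT_BANDS["WRS_H"],
    "ENV_380_400": DEFAULT_BANDS["ENV_380_400"],
}

#: (window_s, hop_s) for low-frequency vs high-frequency analysis.
LOW_RES = (1.0, 0.25)
HIGH_RES = (0.2, 0.05)


def analysis_params(band: BandDef) -> tuple[float, float]:
    """Window and hop (s) appropriate for a band: long windows below 30 Hz."""
    return LOW_RES if band.f_hi <= 30.0 else HIGH_RES


@dataclass
class Spectrogram:
    """Magnitude-squared STFT on a regular frame grid.

    ``power`` has shape (n_frames, n_bins) and holds a one-sided PSD in
    amplitude²/Hz; ``times`` are frame centres in seconds from the start of
    the signal; ``freqs`` are bin centres in Hz (DC bin retained).
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power must be (n_frames, n_bins)")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class BandPowerTrace:
    """Mean in-band PSD per STFT frame, on the source spectrogram's grid."""

    times: np.ndarray
    power: np.ndarray
    band: BandDef
    hop_s: float
    window_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.times.shape != self.power.shape:
            raise ValueError("times and power must align")


def stft_spectrogram(
    x: np.ndarray,
    sample_rate: float,
    window_s: float,
    hop_s: float,
) -> Spectrogram:
    """Short-time Fourier spectrogram with a Hann window.

    Frames are fully contained in the signal (no edge padding); a signal
    shorter than one window yields an empty spectrogram with 0 frames.
    Power is scaled as a one-sided PSD so that, per frame,
    ``sum(power) * df == sum((w * x_frame)**2) / sum(w**2)``.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(window_s * sample_rate))
    hop = int(round(hop_s * sample_rate))
    if nperseg < 8:
        raise ConfigurationError("window must span at least 8 samples")
    if not 0 < hop <= nperseg:
        raise ConfigurationError("need 0 < hop_s <= window_s")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sample_rate)
    if x.size < nperseg:
        return Spectrogram(
            times=np.empty(0),
            freqs=freqs,
            power=np.empty((0, freqs.size)),
            window_s=window_s,
            hop_s=hop_s,
        )
    win = sps.windows.hann(nperseg, sym=False)
    n_frames = 1 + (x.size - nperseg) // hop
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, nperseg)[starts]
    spec = np.fft.rfft(frames * win, axis=1)
    psd = (np.abs(spec) ** 2) / (sample_rate * np.sum(win**2))
    psd[:, 1:] *= 2.0
    if nperseg % 2 == 0:  # Nyquist bin is not duplicated in a one-sided PSD
        psd[:, -1] /= 2.0
    times = (starts + nperseg / 2) / sample_rate
    return Spectrogram(
        times=times, freqs=freqs, power=psd, window_s=window_s, hop_s=hop_s
    )


def band_power(spec: Spectrogram, band: BandDef) -> BandPowerTrace:
    """Per-frame mean PSD over the bins with ``f_lo <= f < f_hi``."""
    mask = (spec.freqs >= band.f_lo) & (spec.freqs < band.f_hi)
    if not mask.any():
        raise ConfigurationError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}) Hz contains no "
            f"spectrogram bins (bin spacing {spec.freqs[1] - spec.freqs[0]:.3g} Hz)"
            if spec.freqs.size > 1
            else f"band {band.name!r} contains no spectrogram bins"
        )
    power = spec.power[:, mask].mean(axis=1) if spec.n_frames else np.empty(0)
    return BandPowerTrace(
        times=spec.times,
        power=power,
        band=band,
        hop_s=spec.hop_s,
        window_s=spec.window_s,
    )


def bandpass(
    x: np.ndarray, sample_rate: float, band: BandDef, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward–backward filtering).

    Zero phase matters downstream: waggle cycles are counted from zero
    crossings of the filtered waveform, which must not be time-shifted.
    """
    nyq = sample_rate / 2.0
    if band.f_hi >= nyq:
        raise ConfigurationError(
            f"band {band.name!r} upper edge {band.f_hi} Hz reaches the "
            f"Nyquist frequency {nyq} Hz"
        )
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    try:
        sos = sps.butter(
            order, [band.f_lo, band.f_hi], btype="bandpass", fs=sample_rate,
            output="sos",
        )
    except ValueError as exc:
        raise ConfigurationError(f"cannot design band-pass: {exc}") from exc
    default_padlen = 3 * (2 * sos.shape[0] + 1 - 1) * 2
    padlen = min(default_padlen, x.size - 1)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _window_concentration(
    filtered: np.ndarray, sample_rate: float, band: BandDef
) -> float:
    win = sps.windows.hann(filtered.size, sym=False)
    spec = np.abs(np.fft.rfft(filtered * win)) ** 2
    freqs = np.fft.rfftfreq(filtered.size, d=1.0 / sample_rate)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    in_band = spec[mask]
    total = in_band.sum()
    if total <= 0:
        return 0.0
    peak = int(np.argmax(in_band))
    lo, hi = max(0, peak - 2), min(in_band.size, peak + 3)
    return float(in_band[lo:hi].sum() / total)


def regularity_index(
    segment: np.ndarray,
    sample_rate: float,
    band: BandDef,
    min_cycles: float = 20.0,
    analysis_window_s: float = 2.0,
) -> float:
    """Spectral concentration of a segment inside a band, in [0, 1].

    The segment is band-passed and split into Hann-windowed analysis
    windows of ``analysis_window_s`` (or the whole segment, if shorter);
    per window the index is the fraction of in-band power within the main
    lobe (±2 Rayleigh bins) of the dominant in-band peak, and the segment
    score is the mean over windows.  A jitter-free sinusoid scores close to
    1; broadband noise scores close to the main-lobe width over the band
    width.  Averaging over fixed-length windows keeps the score comparable
    across segment durations: a single full-length FFT would sharpen its
    Rayleigh resolution with segment length and penalise long, physically
    regular waves for their natural linewidth.  Used to quantify the
    "highly regular" character of fanning.
    """
    segment = np.asarray(segment, dtype=np.float64)
    duration = segment.size / sample_rate
    if duration * band.f_lo < min_cycles:
        raise InsufficientDataError(
            f"regularity index needs at least {min_cycles:.0f} cycles of "
            f"{band.f_lo} Hz; got {duration * band.f_lo:.1f}"
        )
    filtered = bandpass(segment, sample_rate, band)
    win_n = min(filtered.size, int(round(analysis_window_s * sample_rate)))
    n_win = filtered.size // win_n
    scores = [
        _window_concentration(
            filtered[i * win_n : (i + 1) * win_n], sample_rate, band
        )
        for i in range(n_win)
    ]
    return float(np.mean(scores))
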