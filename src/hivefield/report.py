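"""Aggregation, environment correlation and machine-readable run summaries.

Mirrors the field pipeline's daily report: hourly/daily event counts per
signal class, daily band-power means, telemetry extremes, entrance-activity
profiles, and rank correlations between ESF band strength and weather
variables (humidity, UV index).  Statistical plumbing — Spearman rank
correlation and Welch's t-test — comes from scipy; the substance here is the
aggregation and alignment conventions.

The summary is rendered as deterministic JSON (plus optional PNG plots via
the CLI) rather than a typeset document, so results are testable and
machine-consumable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _version
from .activity import PassageEvent, hourly_activity
from .errors import InsufficientDataError
from .formats import ESFRecording, TelemetrySeries, WeatherSeries
from .spectral import (
    ENVIRONMENT_BANDS,
    BandPowerTrace,
    analysis_params,
    band_power,
    stft_spectrogram,
)

__all__ = [
    "RunSummary",
    "hourly_event_counts",
    "daily_band_power",
    "correlate_environment",
    "seasonal_power_comparison",
    "summarize",
]


def hourly_event_counts(
    events: Sequence, bin_s: float = 3600.0, duration_s: Optional[float] = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Event counts per class per time bin (1 h and 2 h bins both supported).

    ``events`` may be detected events or ground-truth annotations (anything
    with ``label`` and ``t_start``).  Bins cover ``[t0, t0 + duration_s)``;
    if no duration is given the grid extends to the last event.  Counts are
    conserved: the table total equals ``len(events)`` for events inside the
    grid.
    """
    labels = sorted({e.label for e in events}) or []
    if duration_s is None:
        duration_s = max((e.t_start for e in events), default=0.0) + 1e-9
    n_bins = int(np.ceil(duration_s / bin_s)) if duration_s > 0 else 0
    edges = t0 + np.arange(n_bins + 1) * bin_s
    data = {"bin_start_s": edges[:-1] if n_bins else np.array([])}
    for label in labels:
        times = np.asarray([e.t_start for e in events if e.label == label])
        counts, _ = (
            np.histogram(times, bins=edges) if n_bins else (np.array([]), None)
        )
        data[label] = counts.astype(int)
    return pd.DataFrame(data)


def daily_band_power(
    traces: Mapping[str, BandPowerTrace],
    utc_start: float = 0.0,
) -> pd.DataFrame:
    """Daily per-band mean power: hourly means averaged within each UTC day.

    Hour-of-recording means are computed first and then averaged per UTC
    day, so a day recorded only in part weights each recorded hour equally.
    """
    frames = []
    for name, trace in traces.items():
        if trace.times.size == 0:
            continue
        abs_t = utc_start + trace.times
        df = pd.DataFrame({"power": trace.power})
        df["hour"] = (abs_t // 3600).astype(np.int64)
        df["day"] = (abs_t // 86400).astype(np.int64)
        hourly = df.groupby(["day", "hour"])["power"].mean().reset_index()
        daily = hourly.groupby("day")["power"].mean()
        frames.append(daily.rename(name))
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, axis=1)
    out.index.name = "day"
    return out.reset_index()


def correlate_environment(
    x_times: np.ndarray,
    x_values: np.ndarray,
    y_times: np.ndarray,
    y_values: np.ndarray,
    tolerance_s: float = 60.0,
) -> tuple[float, int]:
    """Spearman rank correlation of two time series after nearest alignment.

    Each x sample is paired with the nearest y sample within
    ``tolerance_s``; unmatched samples are dropped (no interpolation — ranks
    of interpolated values would be artefacts).  Returns the coefficient and
    the number of aligned pairs; fewer than 10 pairs is an error.
    """
    xf = pd.DataFrame({"t": np.asarray(x_times, float),
                       "x": np.asarray(x_values, float)}).sort_values("t")
    yf = pd.DataFrame({"t": np.asarray(y_times, float),
                       "y": np.asarray(y_values, float)}).sort_values("t")
    merged = pd.merge_asof(
        xf, yf, on="t", direction="nearest", tolerance=tolerance_s
    ).dropna()
    n = len(merged)
    if n < 10:
        raise InsufficientDataError(
            f"only {n} aligned pairs within {tolerance_s:.0f} s; need >= 10"
        )
    rho, _ = stats.spearmanr(merged["x"], merged["y"])
    return float(rho), int(n)


def seasonal_power_comparison(
    powers_a: np.ndarray, powers_b: np.ndarray
) -> tuple[float, float, float]:
    """Compare band powers between two periods (e.g. summer vs winter).

    Returns ``(percent_difference, t_statistic, p_value)`` where the percent
    difference is ``100 * (mean_a - mean_b) / mean_b`` — sample *b* is the
    reference denominator — and the test is Welch's unequal-variance
    two-sample t-test.
    """
    a = np.asarray(powers_a, dtype=float)
    b = np.asarray(powers_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(pct), float(t_stat), float(p)


@dataclass
class RunSummary:
    """Machine-readable summary of one monitoring run."""

    software_version: str
    config: dict
    event_counts_total: dict[str, int]
    event_counts_hourly: list[dict]
    event_counts_daily: list[dict]
    daily_band_power: list[dict]
    telemetry_daily: list[dict]
    activity_hourly: list[dict]
    correlations: list[dict]
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        """Deterministic JSON rendering (sorted keys, fixed float repr)."""
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2,
                          allow_nan=False)


def _telemetry_daily(tel: TelemetrySeries) -> list[dict]:
    df = tel.to_frame()
    df["day"] = (tel.timestamps // 86400).astype(np.int64)
    rows = []
    for day, grp in df.groupby("day"):
        row: dict = {"day": int(day), "n_records": int(len(grp))}
        for col in ("temp_in", "temp_out", "hum_in", "hum_out", "mcu_temp"):
            row[col] = {
                "min": round(float(grp[col].min()), 3),
                "mean": round(float(grp[col].mean()), 3),
                "max": round(float(grp[col].max()), 3),
            }
        row["hive_mass_kg"] = round(
            float(grp[["load_1", "load_2", "load_3"]].sum(axis=1).mean()), 3
        )
        rows.append(row)
    return rows


def summarize(
    recording: Optional[ESFRecording],
    events: Sequence,
    activity_events: Optional[Sequence[PassageEvent]] = None,
    activity_duration_s: Optional[float] = None,
    telemetry: Optional[TelemetrySeries] = None,
    weather: Optional[WeatherSeries] = None,
    config: Optional[dict] = None,
) -> RunSummary:
    """Aggregate one run into a deterministic :class:`RunSummary`.

    Any input may be omitted; the corresponding sections are empty.  When
    both a recording and weather are given, Spearman correlations between
    the environmental band powers and outdoor humidity / UV index are
    included (skipped with a flag when too few pairs align).
    """
    flags: list[str] = []
    counts_total = {}
    for e in events:
        counts_total[e.label] = counts_total.get(e.label, 0) + 1

    duration = recording.duration if recording is not None else None
    hourly = hourly_event_counts(events, 3600.0, duration_s=duration)
    daily = hourly_event_counts(events, 86400.0, duration_s=duration)

    band_rows: list[dict] = []
    corr_rows: list[dict] = []
    if recording is not None and recording.n_samples:
        utc0 = recording.meta.utc_start
        traces: dict[str, BandPowerTrace] = {}
        cache: dict[tuple[float, float], object] = {}
        x = recording.channel_float(0)
        for name, band in ENVIRONMENT_BANDS.items():
            params = analysis_params(band)
            if params not in cache:
                cache[params] = stft_spectrogram(x, recording.sample_rate, *params)
            spec = cache[params]
            if spec.n_frames:
                traces[name] = band_power(spec, band)
        dbp = daily_band_power(traces, utc_start=utc0)
        band_rows = dbp.round(9).to_dict(orient="records")
        if weather is not None and len(weather):
            for var in ("humidity", "uv_index"):
                for name, trace in traces.items():
                    try:
                        rho, n = correlate_environment(
                            utc0 + trace.times,
                            trace.power,
                            weather.timestamps,
                            getattr(weather, var),
                        )
                        rho = round(rho, 6)
                    except InsufficientDataError:
                        rho, n = None, 0
                        flags.append(f"correlation {var}~{name}: too few pairs")
                    corr_rows.append(
                        {"x": name, "y": var, "rho": rho, "n": n}
                    )

    telemetry_rows = _telemetry_daily(telemetry) if telemetry is not None else []
    activity_rows: list[dict] = []
    if activity_events is not None and activity_duration_s:
        activity_rows = hourly_activity(
            activity_events, activity_duration_s
        ).to_dict(orient="records")

    return RunSummary(
        software_version=_version,
        config=config or {},
        event_counts_total=counts_total,
        event_counts_hourly=hourly.to_dict(orient="records"),
        event_counts_daily=daily.to_dict(orient="records"),
        daily_band_power=band_rows,
        telemetry_daily=telemetry_rows,
        activity_hourly=activity_rows,
        correlations=corr_rows,
        flags=flags,
    )
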