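"""Recording containers and on-disk formats for hive monitoring streams.

A hive monitor produces three synchronous data streams:

* six electrostatic-field (ESF) channels digitised at 5,000 samples/s with
  24-bit resolution — the stream that carries honeybee social signals;
* two entrance-capacitance channels at 100 samples/s — the activity stream;
* telemetry every 120 s — in-hive and ambient temperature and humidity,
  three load cells, and MCU temperature.

All three are stored in one binary dialect: a fixed 64-byte header (magic,
format version, sample rate, channel count, UTC start, hive and hardware
identifiers) followed by a stream-specific payload.  ESF payloads are
channel-interleaved 24-bit two's-complement little-endian integers, matching
the ADC word size; activity payloads are interleaved 32-bit floats; telemetry
payloads are fixed little-endian float64 records.  The dialect is seekable
(fixed header, fixed frame size) and lossless.

Converters to interchange formats mirror the original field pipeline:
CSV chunks of at most 200 s of ESF data, and mono 16-bit PCM WAV export of a
single channel for manual inspection in audio software.
"""

from __future__ import annotations

import io
import struct
import wave
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator, Union

import numpy as np
import pandas as pd

from .errors import (
    CorruptionError,
    FormatError,
    SampleRangeError,
    SchemaError,
)

__all__ = [
    "HiveMetadata",
    "ESFRecording",
    "ActivityTrace",
    "TelemetrySeries",
    "WeatherSeries",
    "write_esf_binary",
    "read_esf_binary",
    "write_activity_binary",
    "read_activity_binary",
    "write_telemetry_binary",
    "read_telemetry_binary",
    "esf_to_csv",
    "esf_to_wav",
    "read_weather_table",
    "INT24_MIN",
    "INT24_MAX",
    "HEADER_SIZE",
    "CSV_DATE_FORMAT",
]

HEADER_SIZE = 64
FORMAT_VERSION = 1

#: ISO-8601 rendering of the CSV timestamp column
#: (pass as ``date_format`` to ``DataFrame.to_csv``).
CSV_DATE_FORMAT = "%Y-%m-%dT%H:%M:%S.%fZ"
MAGIC_ESF = b"ESF1"
MAGIC_ACT = b"ACT1"
MAGIC_TEL = b"TEL1"

INT24_MIN = -(1 << 23)
INT24_MAX = (1 << 23) - 1

# header: magic(4s) version(u8) sample_rate(u32) n_channels(u8)
#         utc_start(u64) hive_id(16s) hardware_id(16s) reserved(14x)
_HEADER_STRUCT = struct.Struct("<4sBIBQ16s16s14x")
assert _HEADER_STRUCT.size == HEADER_SIZE

_TEL_FIELDS = (
    "timestamp",
    "temp_in",
    "temp_out",
    "hum_in",
    "hum_out",
    "load_1",
    "load_2",
    "load_3",
    "mcu_temp",
)
_TEL_RECORD = struct.Struct("<%dd" % len(_TEL_FIELDS))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HiveMetadata:
    """Identity and clock anchor of one recording.

    Parameters
    ----------
    hive_id, hardware_id
        Opaque non-empty identifiers (hive and recording device); at most
        16 ASCII bytes each so they fit the fixed header.
    utc_start
        Recording start as Unix seconds (UTC).
    latitude, longitude
        Optional hive position in decimal degrees.
    """

    hive_id: str
    hardware_id: str
    utc_start: int = 0
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        for name in ("hive_id", "hardware_id"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"{name} must be non-empty")
            if len(value.encode("ascii", errors="strict")) > 16:
                raise ValueError(f"{name} must fit in 16 ASCII bytes: {value!r}")
        if self.utc_start < 0:
            raise ValueError("utc_start must be non-negative Unix seconds")


def _as_channel_matrix(channels, n_channels: int, dtype) -> np.ndarray:
    arr = np.asarray(channels)
    if arr.ndim != 2 or arr.shape[0] != n_channels:
        raise ValueError(
            f"expected {n_channels} equal-length channels, got shape {arr.shape}"
        )
    return np.ascontiguousarray(arr, dtype=dtype)


@dataclass
class ESFRecording:
    """Six aligned electrostatic-field channels in ADC counts.

    ``channels`` is a ``(6, n_samples)`` integer array; every sample must be
    representable in the 24-bit signed range of the acquisition ADC.
    """

    channels: np.ndarray
    sample_rate: float = 5000.0
    meta: HiveMetadata = field(
        default_factory=lambda: HiveMetadata("hive-0", "hw-0")
    )

    N_CHANNELS = 6

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.channels).dtype, np.integer):
            raise TypeError("ESF channels must be integer ADC counts")
        self.channels = _as_channel_matrix(self.channels, self.N_CHANNELS, np.int32)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = int(self.channels.min(initial=0)), int(self.channels.max(initial=0))
        if lo < INT24_MIN or hi > INT24_MAX:
            raise SampleRangeError(
                f"samples outside 24-bit signed range: min={lo}, max={hi}"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel_float(self, channel: int) -> np.ndarray:
        """One channel as float64 (for filtering / spectral analysis)."""
        return self.channels[channel].astype(np.float64)


@dataclass
class ActivityTrace:
    """Two entrance-capacitance channels, arbitrary capacitance units."""

    channels: np.ndarray
    sample_rate: float = 100.0
    meta: HiveMetadata = field(
        default_factory=lambda: HiveMetadata("hive-0", "hw-0")
    )

    N_CHANNELS = 2

    def __post_init__(self) -> None:
        self.channels = _as_channel_matrix(self.channels, self.N_CHANNELS, np.float32)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class TelemetrySeries:
    """Hive telemetry sampled nominally every 120 s, all day.

    Fields: in-hive and ambient temperature (°C), in-hive and ambient
    relative humidity (%), three load-cell masses (kg) and the recording
    device's MCU temperature (°C), each aligned with ``timestamps``
    (Unix seconds, strictly increasing).
    """

    timestamps: np.ndarray
    temp_in: np.ndarray
    temp_out: np.ndarray
    hum_in: np.ndarray
    hum_out: np.ndarray
    load_cells: np.ndarray  # (3, n) kg
    mcu_temp: np.ndarray
    meta: HiveMetadata = field(
        default_factory=lambda: HiveMetadata("hive-0", "hw-0")
    )

    NOMINAL_CADENCE_S = 120.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        for name in ("temp_in", "temp_out", "hum_in", "hum_out", "mcu_temp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.load_cells = _as_channel_matrix(self.load_cells, 3, np.float64)
        n = self.timestamps.size
        for name in ("temp_in", "temp_out", "hum_in", "hum_out", "mcu_temp"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match timestamps")
        if self.load_cells.shape[1] != n:
            raise ValueError("load_cells length does not match timestamps")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name in ("hum_in", "hum_out"):
            h = getattr(self, name)
            if h.size and (h.min() < 0 or h.max() > 100):
                raise ValueError(f"{name} must lie in [0, 100] %")

    def __len__(self) -> int:
        return self.timestamps.size

    def to_frame(self) -> pd.DataFrame:
        """Telemetry as a tidy DataFrame (one row per record)."""
        return pd.DataFrame(
            {
                "timestamp": pd.to_datetime(self.timestamps, unit="s", utc=True),
                "temp_in": self.temp_in,
                "temp_out": self.temp_out,
                "hum_in": self.hum_in,
                "hum_out": self.hum_out,
                "load_1": self.load_cells[0],
                "load_2": self.load_cells[1],
                "load_3": self.load_cells[2],
                "mcu_temp": self.mcu_temp,
            }
        )


@dataclass
class WeatherSeries:
    """Local weather observations (replacement for an online weather API)."""

    timestamps: np.ndarray  # Unix seconds, strictly increasing
    humidity: np.ndarray  # % relative humidity
    uv_index: np.ndarray  # dimensionless
    temperature: np.ndarray  # °C

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        for name in ("humidity", "uv_index", "temperature"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
            if getattr(self, name).size != self.timestamps.size:
                raise ValueError(f"{name} length does not match timestamps")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("weather timestamps must be strictly increasing")
        h = self.humidity
        if h.size and (h.min() < 0 or h.max() > 100):
            raise SchemaError("humidity must lie in [0, 100] %")

    def __len__(self) -> int:
        return self.timestamps.size


# ---------------------------------------------------------------------------
# Binary dialect
# ---------------------------------------------------------------------------


def _pack_header(
    magic: bytes, sample_rate: float, n_channels: int, meta: HiveMetadata
) -> bytes:
    return _HEADER_STRUCT.pack(
        magic,
        FORMAT_VERSION,
        int(round(sample_rate)),
        n_channels,
        int(meta.utc_start),
        meta.hive_id.encode("ascii").ljust(16, b"\x00"),
        meta.hardware_id.encode("ascii").ljust(16, b"\x00"),
    )


def _unpack_header(raw: bytes, expected_magic: bytes):
    if len(raw) < HEADER_SIZE:
        raise CorruptionError(
            f"stream ended inside the header at byte {len(raw)} (need {HEADER_SIZE})"
        )
    magic, version, sample_rate, n_channels, utc_start, hive, hw = (
        _HEADER_STRUCT.unpack(raw)
    )
    if magic != expected_magic:
        raise FormatError(
            f"bad magic {magic!r}; expected {expected_magic.decode()!r}"
        )
    if version != FORMAT_VERSION:
        raise FormatError(f"unsupported format version {version}")
    meta = HiveMetadata(
        hive_id=hive.rstrip(b"\x00").decode("ascii"),
        hardware_id=hw.rstrip(b"\x00").decode("ascii"),
        utc_start=utc_start,
    )
    return sample_rate, n_channels, meta


def _encode_int24(values: np.ndarray) -> bytes:
    """Pack int32 values (already range-checked) as 24-bit LE bytes."""
    as32 = np.ascontiguousarray(values, dtype="<i4")
    return as32.view(np.uint8).reshape(-1, 4)[:, :3].tobytes()


def _decode_int24(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    vals = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    vals -= (vals >= (1 << 23)) << 24
    return vals


def write_esf_binary(rec: ESFRecording, sink: BinaryIO) -> int:
    """Write an :class:`ESFRecording` in the binary dialect.

    The payload interleaves channels per sample frame (ch0..ch5, next
    sample, ...), each sample as a 24-bit little-endian two's-complement
    integer.  Returns the number of bytes written:
    ``64 + 3 * 6 * n_samples``.
    """
    lo, hi = int(rec.channels.min(initial=0)), int(rec.channels.max(initial=0))
    if lo < INT24_MIN or hi > INT24_MAX:
        raise SampleRangeError(
            f"samples outside 24-bit signed range: min={lo}, max={hi}"
        )
    header = _pack_header(MAGIC_ESF, rec.sample_rate, rec.N_CHANNELS, rec.meta)
    payload = _encode_int24(rec.channels.T.reshape(-1))
    sink.write(header)
    sink.write(payload)
    return len(header) + len(payload)


def read_esf_binary(source: BinaryIO) -> ESFRecording:
    """Read an ESF stream written by :func:`write_esf_binary` (bit-exact)."""
    raw = source.read()
    sample_rate, n_channels, meta = _unpack_header(raw[:HEADER_SIZE], MAGIC_ESF)
    payload = raw[HEADER_SIZE:]
    frame_size = 3 * n_channels
    if frame_size and len(payload) % frame_size:
        offset = HEADER_SIZE + len(payload) - (len(payload) % frame_size)
        raise CorruptionError(
            f"payload truncated mid-frame: {len(payload)} bytes is not a "
            f"multiple of the {frame_size}-byte frame; last whole frame ends "
            f"at byte {offset}"
        )
    flat = _decode_int24(payload)
    channels = flat.reshape(-1, n_channels).T
    return ESFRecording(channels=channels, sample_rate=sample_rate, meta=meta)


def write_activity_binary(trace: ActivityTrace, sink: BinaryIO) -> int:
    """Write an activity trace (2-channel interleaved float32 payload)."""
    header = _pack_header(MAGIC_ACT, trace.sample_rate, trace.N_CHANNELS, trace.meta)
    payload = np.ascontiguousarray(trace.channels.T, dtype="<f4").tobytes()
    sink.write(header)
    sink.write(payload)
    return len(header) + len(payload)


def read_activity_binary(source: BinaryIO) -> ActivityTrace:
    raw = source.read()
    sample_rate, n_channels, meta = _unpack_header(raw[:HEADER_SIZE], MAGIC_ACT)
    payload = raw[HEADER_SIZE:]
    frame_size = 4 * n_channels
    if frame_size and len(payload) % frame_size:
        offset = HEADER_SIZE + len(payload) - (len(payload) % frame_size)
        raise CorruptionError(
            f"payload truncated mid-frame; last whole frame ends at byte {offset}"
        )
    flat = np.frombuffer(payload, dtype="<f4")
    return ActivityTrace(
        channels=flat.reshape(-1, n_channels).T,
        sample_rate=sample_rate,
        meta=meta,
    )


def write_telemetry_binary(series: TelemetrySeries, sink: BinaryIO) -> int:
    """Write telemetry as fixed little-endian float64 records."""
    header = _pack_header(MAGIC_TEL, 0, len(_TEL_FIELDS), series.meta)
    cols = np.column_stack(
        [
            series.timestamps,
            series.temp_in,
            series.temp_out,
            series.hum_in,
            series.hum_out,
            series.load_cells[0],
            series.load_cells[1],
            series.load_cells[2],
            series.mcu_temp,
        ]
    )
    payload = np.ascontiguousarray(cols, dtype="<f8").tobytes()
    sink.write(header)
    sink.write(payload)
    return len(header) + len(payload)


def read_telemetry_binary(source: BinaryIO) -> TelemetrySeries:
    raw = source.read()
    _, n_fields, meta = _unpack_header(raw[:HEADER_SIZE], MAGIC_TEL)
    payload = raw[HEADER_SIZE:]
    if n_fields != len(_TEL_FIELDS):
        raise FormatError(f"unexpected telemetry field count {n_fields}")
    if _TEL_RECORD.size and len(payload) % _TEL_RECORD.size:
        offset = HEADER_SIZE + len(payload) - (len(payload) % _TEL_RECORD.size)
        raise CorruptionError(
            f"payload truncated mid-record; last whole record ends at byte {offset}"
        )
    cols = np.frombuffer(payload, dtype="<f8").reshape(-1, len(_TEL_FIELDS)).T
    return TelemetrySeries(
        timestamps=cols[0],
        temp_in=cols[1],
        temp_out=cols[2],
        hum_in=cols[3],
        hum_out=cols[4],
        load_cells=cols[5:8],
        mcu_temp=cols[8],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------


def esf_to_csv(
    rec: ESFRecording, chunk_seconds: float = 200.0
) -> Iterator[pd.DataFrame]:
    """Convert an ESF recording to tabular chunks of at most ``chunk_seconds``.

    Each chunk is a DataFrame with a UTC ``timestamp`` column (derived as
    ``utc_start + index / sample_rate``; rendered ISO-8601 when written with
    :data:`CSV_DATE_FORMAT`) and columns ``ch0``..``ch5``.  Concatenating
    all chunks reproduces the recording.  The 200 s default mirrors the
    field pipeline's per-file duration.
    """
    if chunk_seconds <= 0:
        raise ValueError("chunk_seconds must be positive")
    chunk_rows = int(round(chunk_seconds * rec.sample_rate))
    n = rec.n_samples
    for start in range(0, n, max(chunk_rows, 1)):
        stop = min(start + chunk_rows, n)
        idx = np.arange(start, stop)
        seconds = rec.meta.utc_start + idx / rec.sample_rate
        ts = pd.to_datetime((seconds * 1e9).round().astype(np.int64), utc=True)
        data = {"timestamp": ts}
        for ch in range(rec.N_CHANNELS):
            data[f"ch{ch}"] = rec.channels[ch, start:stop]
        yield pd.DataFrame(data)


def esf_to_wav(rec: ESFRecording, channel: int) -> bytes:
    """Export one ESF channel as a mono 16-bit PCM WAV payload.

    The channel is peak-normalised so that max ``|sample|`` maps to 0.95 of
    full scale; an all-zero channel exports as silence.  Intended for manual
    inspection of signal candidates in ordinary audio software.
    """
    if not 0 <= channel < rec.N_CHANNELS:
        raise IndexError(f"channel must be in 0..{rec.N_CHANNELS - 1}, got {channel}")
    x = rec.channel_float(channel)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 0:
        scaled = np.round(x / peak * 0.95 * 32767.0).astype("<i2")
    else:
        scaled = np.zeros(x.size, dtype="<i2")
    buf = io.BytesIO()
    with wave.open(buf, "wb") as wav:
        wav.setnchannels(1)
        wav.setsampwidth(2)
        wav.setframerate(int(round(rec.sample_rate)))
        wav.writeframes(scaled.tobytes())
    return buf.getvalue()


_WEATHER_COLUMNS = ("timestamp", "humidity", "uv_index", "temperature")


def read_weather_table(source: Union[str, "io.IOBase"]) -> WeatherSeries:
    """Read a local weather CSV into a validated, time-sorted series.

    The table must carry columns ``timestamp`` (ISO-8601 or Unix seconds),
    ``humidity`` (%), ``uv_index`` and ``temperature`` (°C).  Rows may be in
    any order; output is sorted by time.
    """
    df = pd.read_csv(source)
    missing = [c for c in _WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"weather table is missing columns: {missing}")
    raw_ts = df["timestamp"]
    if pd.api.types.is_numeric_dtype(raw_ts):
        seconds = raw_ts.astype(float)
    else:
        parsed = pd.to_datetime(raw_ts, utc=True, errors="coerce", format="mixed")
        bad = parsed.isna() & raw_ts.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"unparsable timestamp {raw_ts[bad.idxmax()]!r} on line {line}"
            )
        seconds = parsed.astype("int64") / 1e9
    order = np.argsort(seconds.to_numpy(), kind="stable")
    return WeatherSeries(
        timestamps=seconds.to_numpy()[order],
        humidity=df["humidity"].to_numpy(dtype=float)[order],
        uv_index=df["uv_index"].to_numpy(dtype=float)[order],
        temperature=df["temperature"].to_numpy(dtype=float)[order],
    )
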