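# hivefield

Detection and decoding of honeybee social signals from electrostatic-field
(ESF) hive recordings.

Honeybee bodies charge triboelectrically during flight and inside the
colony; their body movements therefore modulate an electrostatic field that
capacitive sensors inside the hive can pick up without disturbing the bees.
Three stereotypical social signals are separable in these recordings by
their characteristic frequencies and time courses:

| signal | behaviour | signature |
|---|---|---|
| **WRS** | waggle run (dance) | 5–25 Hz abdomen waggling (WRS_L) with partially synchronised 190–230 Hz wing vibration (WRS_H) |
| **SRS** | short pulses (begging/stop-signal contexts) | < 1 s, fundamental > 350 Hz plus harmonics |
| **FRS** | fanning (ventilation) | > 15 s of highly regular 90–120 Hz waves |

The number of waggle cycles in a run scales with the distance to the
advertised food source at roughly **75 m per waggle** (Haldane–Spurway
calibration), so counting cycles decodes the distance:
`d = n_waggles × 75 m`.

`hivefield` is the software side of such a monitor, built for desk-scale
development and validation:

* **`hivefield.simulate`** — a ground-truth generator for all three data
  streams of the monitor: 6-channel ESF at 5,000 S/s (24-bit), 2-channel
  entrance capacitance at 100 S/s, and 120 s-cadence telemetry with diurnal
  structure.  Signal models for all three classes, realistic noise
  (white + 1/f + mains hum + low-frequency crowd clutter), and scenarios
  that are fully deterministic under a seed.
* **`hivefield.formats`** — a binary recording dialect (one 64-byte header,
  three stream payloads), CSV conversion in 200 s chunks, WAV export for
  listening to candidate signals, and a local weather-table reader.
* **`hivefield.spectral`** — STFT band-power traces at two time–frequency
  resolutions, zero-phase band-pass filtering, and a regularity index for
  fanning.
* **`hivefield.detect`** — the detector: rolling-baseline segmentation of
  band-power traces, waveform-level edge refinement, rule-based
  classification (FRS > SRS > WRS priority), waggle counting by gated zero
  crossings, distance decoding, dance-bout grouping, cross-channel fusion,
  and precision/recall evaluation against ground truth.
* **`hivefield.activity`** — entrance passage counting and hourly activity
  profiles.
* **`hivefield.report`** — hourly/daily aggregation, Spearman correlation
  against weather variables, seasonal band-power comparison, and a
  deterministic JSON run summary.

## Worked example

```python
from hivefield import (
    DetectorConfig, NoiseSpec, Scenario, ScenarioEvent,
    WaggleRunSpec, SrsSpec, FanningSpec,
    render_scenario, detect_events, evaluate, group_bouts,
)

scenario = Scenario(
    duration=60.0,
    events=[
        ScenarioEvent(channel=0, t_start=5.0,
                      spec=WaggleRunSpec(waggle_freq=13.0, n_waggles=13)),
        ScenarioEvent(channel=0, t_start=8.0,
                      spec=WaggleRunSpec(waggle_freq=13.0, n_waggles=15)),
        ScenarioEvent(channel=1, t_start=12.0,
                      spec=SrsSpec(fundamental=450.0, duration=0.4)),
        ScenarioEvent(channel=2, t_start=20.0,
                      spec=FanningSpec(freq=105.0, duration=20.0)),
    ],
    noise=NoiseSpec(),  # white + 1/f + 50 Hz hum + crowd clutter
    seed=42,
)
recording, truth = render_scenario(scenario)

events = detect_events(recording, DetectorConfig())
for e in events:
    extra = ""
    if e.label == "WRS":
        extra = f"  waggles={e.n_waggles}  distance={e.distance_m:.0f} m"
    if e.label == "FRS":
        extra = f"  regularity={e.regularity:.2f}"
    print(f"{e.label}  ch{e.channel}  {e.t_start:7.2f}-{e.t_end:7.2f} s{extra}")

for bout in group_bouts(events):
    print(f"bout: {len(bout.members)} runs, median {bout.median_waggles:.0f} "
          f"waggles -> {bout.distance_m:.0f} m")

m = evaluate(events, truth).pooled
print(f"vs truth: precision={m.precision:.2f} recall={m.recall:.2f}")
```

prints

```
WRS  ch0     4.90-   6.04 s  waggles=13  distance=975 m
WRS  ch0     7.95-   9.24 s  waggles=16  distance=1200 m
SRS  ch1    12.04-  12.36 s
FRS  ch2    20.00-  40.00 s  regularity=1.00
bout: 2 runs, median 14 waggles -> 1088 m
vs truth: precision=1.00 recall=1.00
```

Both waggle runs are found with their spans and cycle counts (the second
run's count is off by one — cycle counting is accurate to ±1 on detected
spans), the 0.4 s pulse is labelled SRS, and the 20 s of perfectly regular
105 Hz fanning scores regularity 1.00.  The two runs, 2 s apart on one
channel, form a single dance bout whose distance is decoded from the median
count: 14 × 75 m ≈ 1088 m.

## Command line

The same pipeline is scriptable from a shell; see `examples/scenario.yaml`:

```bash
hivefield simulate examples/scenario.yaml -o run/ --telemetry-days 1
hivefield convert run/esf.bin -o run/csv --wav 0     # 200 s CSV chunks + WAV
hivefield detect run/esf.bin -o run/events.csv
hivefield evaluate run/events.csv run/truth.csv -o run/metrics.csv
hivefield report run/ --plots                        # summary.json + PNGs
```

Exit codes: 0 success, 1 usage error, 2 data error.

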