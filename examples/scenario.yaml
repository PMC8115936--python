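# A one-minute recording with one event of each class plus a dance bout.
# Render with:  hivefield simulate examples/scenario.yaml -o run/
duration: 60.0
seed: 42
sample_rate: 5000
noise:
  white_rms: 0.05
  pink_rms: 0.10
  mains_hz: 50.0
  mains_rms: 0.05
  crowd_rms: 0.05
meta:
  hive_id: example-hive
  hardware_id: example-hw
  utc_start: 1587362400   # 2020-04-20 06:00:00 UTC
events:
  - {kind: waggle, channel: 0, t_start: 5.0, waggle_freq: 13.0, n_waggles: 13}
  - {kind: waggle, channel: 0, t_start: 8.0, waggle_freq: 13.0, n_waggles: 15}
  - {kind: srs, channel: 1, t_start: 12.0, fundamental: 450.0, duration: 0.4}
  - {kind: fanning, channel: 2, t_start: 20.0, freq: 105.0, duration: 20.0, jitter: 0.0}
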