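# Methods

This note documents the signal models, the detector, the statistical
analyses and the numerical choices behind `hivefield`, in the spirit of a
model-description chapter: what is computed, under which assumptions, and
what passing the test suite does and does not show.

## 1. The measurement being modelled

A hive monitor digitises six electrostatic-field (ESF) channels at
5,000 samples/s with 24-bit resolution, two entrance-capacitance channels
at 100 samples/s, and telemetry (in-hive/ambient temperature and humidity,
three load cells, MCU temperature) every 120 s.  ESF and activity streams
are recorded during the operational window 06:00–23:59 UTC; telemetry runs
all day.  Charged bee bodies modulate the field as they move, so social
signals with stereotyped movement patterns leave stereotyped
time–frequency signatures.

Recordings are stored in a compact binary dialect: a 64-byte header
(magic `ESF1`/`ACT1`/`TEL1`, format version, sample rate, channel count,
UTC start, hive and hardware identifiers) followed by channel-interleaved
24-bit two's-complement little-endian samples (ESF), interleaved float32
(activity), or 9 × float64 records (telemetry; timestamp plus eight data
fields, so a non-uniform cadence survives a round trip).  The dialect is
lossless and seekable; round trips are bit-exact by construction and by
property test.  CSV conversion emits chunks of at most 200 s with
timestamps derived as `utc_start + index / sample_rate`; WAV export is
peak-normalised mono 16-bit PCM for listening to candidates in audio
software.

## 2. Signal models (the synthetic-data generator)

The generator is the package's evaluation surface: every event it renders
carries a ground-truth annotation, and a scenario (event list + noise +
seed) renders deterministically, bit-for-bit.

**Waggle run (WRS).**  The abdomen component is a phase-continuous
sinusoid making exactly `n_waggles` cycles.  Its instantaneous frequency
follows a ramp–plateau–decay profile: the first 10 % of cycles ramp up
from `(1 − fm_depth) · f` to the plateau `f = waggle_freq` (default 13 Hz,
bounds 5–25 Hz), the last 10 % decay back; `fm_depth` defaults to 0.2.
This realises the characteristic rise–plateau–fall of the waggle frequency
while keeping the cycle count exact, so run duration is derived:
`duration ≈ n_waggles / waggle_freq`, slightly longer with FM.  The wing
component is a phase-continuous oscillator at `wing_freq` (default 210 Hz,
bounds 190–230 Hz), amplitude-gated with a Hann bump over the central 60 %
of each selected cycle; a deterministic accumulator selects
`wing_sync_fraction` (default 0.7) of the cycles, realising the partial
synchronisation of wing bursts with abdomen waggling.  The wing amplitude
defaults to half the abdomen amplitude and can be set independently
(`wing_amplitude`), which the benchmark uses to control the wing band's
SNR separately.

**Short pulse (SRS).**  A Hann-windowed sum of a fundamental above 350 Hz
(default 450 Hz) and `n_harmonics` harmonics at 1/k amplitude, duration
strictly below 1 s.  The annotated span is the window support.

**Fanning (FRS).**  A near-sinusoid in 90–120 Hz lasting more than 15 s,
built from per-cycle periods `T_c = (1 + jitter · ε_c)/f` with ε standard
normal (clipped at ±2.5); `jitter` is the fractional cycle-period standard
deviation.  Zero jitter gives a perfect tone; period jitter j produces a
phase-diffusion linewidth of roughly `(2πj)² f / 4π` Hz, so j = 0.02 keeps
a 100 Hz wave within ~0.13 Hz — "highly regular" — while j ≥ 0.1 visibly
smears the line.  The benchmark uses j = 0.02.

**Noise.**  Four components, each normalised to a requested RMS:
white Gaussian; 1/f ("pink") noise shaped in the frequency domain to a
power-spectral slope of −1 (verified −1 ± 0.2 by periodogram regression);
a mains-hum sinusoid (default 50 Hz, the European grid); and crowd
clutter — a mean-removed random walk low-passed below 30 Hz — standing in
for the slow broadband signal of many bees moving near the sensors.
Defaults (white 0.05, pink 0.10, mains 0.05, crowd 0.05 in simulator
amplitude units) put a unit-amplitude event well above the floor; they are
conventions of this simulator, not field measurements.

**Band-local SNR.**  RMS of the event waveform inside its defining band
over its span, divided by the in-band noise RMS, in dB.  Waggle runs have
two defining bands and their two components are scaled independently.

**Entrance activity.**  Each passage adds a raised-cosine bump (default
width 0.3 s) to both capacitance channels, the second lagged 0.05 s (two
sensors in series along the tube); passages superpose linearly.
**Telemetry** holds in-hive temperature near the 35 °C brood set point
with small noise, drives ambient temperature and (anti-phase) humidity on
sinusoidal diurnal cycles peaking at 16:00 UTC, and adds noise throughout.

**The standard benchmark scenario** deals 50 events per class round-robin
over the six channels with 10–18 s random gaps (fanning then occupies
~28 % of a channel — sparse enough for rolling-baseline estimation, dense
enough to be busy), draws event parameters uniformly inside their class
bands (runs 10–16 Hz × 8–25 waggles; pulses 380–800 Hz × 0.2–0.8 s;
fanning 95–115 Hz × 16–24 s), and scales every event to 10 dB band-local
SNR in the default noise.

## 3. Time–frequency analysis

Spectrograms are magnitude-squared STFTs with a periodic Hann window, no
edge padding (a signal shorter than one window yields zero frames), and
one-sided PSD scaling, so per frame `sum(power)·df` equals the windowed
frame energy divided by the window energy (Parseval, tested to 1 %).  Two
resolutions serve different bands: 1.0 s window / 0.25 s hop below 30 Hz
(a 5 Hz component needs ~1 Hz resolution) and 0.2 s / 0.05 s above (a
sub-second pulse needs time resolution).  Band power is the per-frame mean
PSD over bins in the half-open band `[f_lo, f_hi)`; half-open edges make
adjacent bands partition without double counting.  Detection bands:
WRS_L 5–25, WRS_H 190–230, FRS 90–120, SRS 350–2400 Hz (the pulse band is
open-ended in principle; 2400 Hz keeps it under Nyquist).  Environmental
analyses use 5–30, 190–230 and 380–400 Hz.

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(zero phase), because waggle cycles are counted from zero crossings that
must not shift in time.

**Regularity index.**  The band-passed segment is split into 2 s analysis
windows; per window, the fraction of in-band power within ±2 Rayleigh bins
of the dominant peak; the score is the mean over windows.  Fixed-length
windows keep the score comparable across durations — a full-length FFT
would sharpen its resolution with segment length and penalise long,
physically regular waves for their natural linewidth.  Jitter-free fanning
scores ≈ 1.0, white noise ≈ 0.15–0.2, and the score decreases
monotonically in simulator jitter.

## 4. The detector

Per channel, four stages:

**(1) Segmentation.**  Each band-power trace is compared against
`k ×` a rolling-quantile baseline (k = 4, hysteresis 0.5 on the falling
edge; supra-threshold frame runs closer than 0.1 s merge).  The baseline
window must comfortably exceed the longest event expected in its band,
otherwise the baseline tracks the event and the hysteresis cuts it:
30 s for the low band, 5 s for WRS_H and SRS, 120 s for the fanning band.
The fanning band also uses the 0.2 quantile rather than the median: at
~30 % fanning occupancy a median still rides up over event-dense
stretches.  Raising `k` reproduces the deliberately conservative behaviour
of the original field software (fewer false positives, more misses).

**(2) Edge refinement.**  STFT frames smear event edges by up to one
window length, which is material against a 1 s duration bound.  Each
candidate's span is therefore re-measured on the waveform: band-pass,
amplitude envelope (|analytic signal|, smoothed by a per-band moving
average w: 0.2 s low band, 0.05 s wing, 0.5 s fanning, 0.01 s pulse), and
a floor equal to the larger of a per-band relative level (2 % of peak for
the narrow low-frequency bands, whose filters ring far longer below a
given relative level; 10⁻³ for fanning; 3·10⁻⁴ for the wide pulse band)
and 1.5 × the median envelope of flanking noise margins.  Margins are
offset from the candidate by one smoothing width and at least
max(4 w, 1 s) long, so event energy cannot spill into the noise estimate.
The supported run containing the envelope peak defines the span; dips
shorter than a per-band tolerance (1 s for fanning, else ≤ 0.2 s) are
bridged, since destructive noise interference briefly notches the envelope
of genuine events.  Crossings are corrected by w/2 per edge for the
smoothing-induced widening.

**(3) Classification**, in priority order FRS > SRS > WRS; a span consumed
by a higher-priority label removes overlapping candidates from the
remaining pools, so per-channel events never overlap.

* **FRS**: refined duration ≥ 15 s, fanning-band dominance, and
  regularity ≥ 0.6.
* **SRS**: refined duration in [0.02 s, 1 s] and pulse-band dominance.
* **WRS**: refined duration in [0.4, 10] s (covering ~3–30 waggles at
  5–25 Hz — not a biological constant, a clutter guard), combined
  low+wing dominance, a wing-band excess share of at least 1 % of the
  span's power, and confirmed wing concurrency: wing-band STFT power above
  2 × its rolling baseline on at least 30 % of the span's frames.
  Confirmation at a fixed location uses a milder threshold (2×) than
  open-ended detection (4×) because it carries no search-over-time burden;
  the 30 % floor is the "partially synchronised" criterion.

*Band dominance* is the share of the span's above-noise power, summed over
the four detection bands, that falls in the event's defining band(s); the
per-band noise rate is estimated from the smaller of the two flanking
margins.  The gate (threshold 0.4; 0.01 for the wing-presence variant)
rejects candidates born of spectral leakage: in a very quiet recording the
onset click of a strong fanning wave crosses the low band's threshold, and
wing-burst sidebands cross the pulse band's — real events carry their
power in their own band, leakage phantoms do not.  The noise subtraction
matters because ambient noise is strongly coloured: raw low-band noise
power would otherwise swamp a legitimate 10 dB fanning signal.

Duration bounds at the class boundaries are applied inclusively (exactly
1 s is a pulse, exactly 15 s is fanning): measured durations are
continuous estimates, and boundary-valued signals should resolve to the
printed class constants rather than fall into a measure-zero gap.
Emitted events satisfy the class bounds by construction (enforced in the
event type).

**(4) Decoding.**  Waggle cycles are counted on the zero-phase band-passed
span as `(rising + falling crossings + 1) // 2`, with crossings gated on
the amplitude envelope (≥ 25 % of peak) so filter ring-down and noisy
margins contribute no cycles; averaging both crossing polarities halves
the sensitivity to whether a boundary crossing resolves.  On clean runs
the count is exact for n = 3…30 (and ±1 on detected, slightly
over-extended spans).  Counting on a span without waggle signal is
meaningless; such calls are flagged (`count_low_confidence`) when the
5–25 Hz share of the span's 1–50 Hz power falls below 0.6 — pink noise
spreads its low-frequency power, a waggle run concentrates it.  Distance
is `n_waggles × 75 m` (configurable).  Consecutive same-channel runs with
gaps under 5 s form a dance bout whose distance uses the median member
count, robust to a single miscount.  An optional FM-profile score
(correlation of the run's zero-crossing frequency track with a
ramp–plateau–decay template) is computed only on request; it is a
candidate labelling improvement, not part of the rule set.

**Channel fusion.**  Six sensors face one dance floor, so one strong dance
can register on neighbouring channels.  `fuse_channels` merges same-label
events on different channels overlapping ≥ 50 % of the shorter one
(transitively), keeping the span union and the strongest channel's
features.  It is a separate operation, off the default path: scenarios
place independent events that may coincide across channels, and the field
configuration determines whether coincidence means duplication.

**Evaluation.**  Greedy one-to-one matching by descending overlap;
a detection matches a truth event with the same label (and channel, by
default) if their overlap is ≥ 30 % of the truth span.  Precision with no
detections is reported as 0 and flagged undefined.

## 5. Entrance activity and reporting

Passage counting averages the two capacitance channels, smooths with a
0.15 s moving average (≈ half the bump width), removes a 10 s rolling
median baseline, and picks peaks with prominence ≥ 5 × the noise MAD of
the *unsmoothed* detrended trace — prominence in correlated (smoothed)
noise reaches valley-to-peak excursions well above the smoothed amplitude
scale, so the raw-trace MAD is the right yardstick.  Hourly histograms
distinguish zero-count bins inside the recording from absent data outside
it.  Direction of travel is not resolved.

Reporting aggregates per-class event counts into 1 h/2 h and daily bins,
averages band power per hour then per UTC day, and computes Spearman rank
correlations between band-power traces and weather variables after
nearest-neighbour alignment within 60 s (no interpolation — ranks of
interpolated values are artefacts; fewer than 10 aligned pairs is an
error).  Seasonal comparisons report the percent difference of means,
`100 · (mean_a − mean_b)/mean_b` with sample *b* the reference, and
Welch's unequal-variance t-test.  Spearman and the t-test come from scipy;
they are named, standard analyses, not contributions of this package.
The run summary is deterministic JSON carrying the full configuration
snapshot and software version for provenance; plots are optional PNGs.

## 6. Problem sizes and defaults in the test suite

The suite exercises the pipeline at sizes a laptop handles in seconds:
the standard benchmark (150 events, ~10 min of 6-channel audio-rate
signal) runs in ~35 s; duration sweeps use 0.5 s steps over 5–30 s
(fanning) and 0.05 s steps over 0.1–2 s (pulses) in 40–120 s recordings
with near-negligible noise (white RMS 10⁻⁵ of event amplitude); the
waggle-count sweep covers n = 3…30 × 5 seeded repeats.  The acceptance
script re-derives the decoded distance of one waggle (75 m) and both
class-boundary constants (15 s, 1 s) from scratch with the same sweeps.

## 7. What the simulator does not emulate — and hence what tests show

The generator produces parametric, stationary-noise approximations.  It
does **not** model: electrostatics or sensor geometry (no amplitude decay
with distance, no inter-channel crosstalk except by explicit fusion
scenarios); non-stationary colony noise (thousands of bees produce
structured, diurnally varying clutter, not a fixed-RMS random walk);
signal-class ambiguity (buzzing runs, dorso-ventral abdominal vibrations
at 10–22 Hz, and grooming dances emanate low-band energy that field
recordings confound with waggle runs); overlapping same-channel events;
sensor artefacts (drift, saturation, contact loss); or dance direction.
Perfect precision/recall on the benchmark therefore bounds the method's
behaviour under its own assumptions — it does not predict field accuracy,
where human-validated classification of comparable recordings was
substantially conservative (field reports describe high false-negative
rates for waggle runs).  The detector's `k` is exposed precisely so the
conservative operating point can be reproduced.

## 8. Known limitations

* Duration measurement near class boundaries is accurate to roughly one
  envelope-smoothing width under noise; the boundary constants are exact
  only in the low-noise sweep regime.
* The rolling-baseline design assumes events are sparse at the
  baseline-window scale; above ~50 % band occupancy (continuous mass
  fanning) segmentation degrades — a global or adaptive-quantile baseline
  would be needed.
* Waggle counts on *detected* spans run +1 on occasion (span
  over-extension); bout-median decoding absorbs this.
* `correlate_environment` drops unmatched samples; with very sparse
  weather tables the effective n shrinks accordingly.
* The 24-bit quantisation is modelled by rounding at a fixed gain
  (2¹⁸ counts per unit amplitude); ADC non-linearity and dither are not.
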