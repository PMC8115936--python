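"""Shared fixtures: synthetic recordings assembled without the detector."""

from __future__ import annotations

import numpy as np
import pytest

from hivefield.formats import ESFRecording, HiveMetadata
from hivefield.simulate import ADC_GAIN

FS = 5000.0


@pytest.fixture
def meta():
    return HiveMetadata("test-hive", "test-hw", utc_start=1_587_362_400)


def embed_waveforms(
    placements, duration_s, noise_rms=1e-5, seed=0, meta_=None, fs=FS
):
    """Build a 6-channel recording from (channel, t_start, waveform) triples.

    Each channel gets independent tiny white noise so envelope floors and
    rolling baselines behave as on real data; amplitudes are in simulator
    units and quantised with the standard ADC gain.
    """
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = noise_rms * rng.standard_normal((6, n))
    for channel, t_start, wave in placements:
        i0 = int(round(t_start * fs))
        i1 = min(i0 + wave.size, n)
        x[channel, i0:i1] += wave[: i1 - i0]
    if meta_ is None:
        meta_ = HiveMetadata("test-hive", "test-hw", utc_start=1_587_362_400)
    return ESFRecording(
        channels=np.round(x * ADC_GAIN).astype(np.int32),
        sample_rate=fs,
        meta=meta_,
    )


@pytest.fixture
def embed():
    return embed_waveforms
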