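"""Shared fixtures: montages, schedules and small simulated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from fpvs import preprocess, synth
from fpvs.montage import make_montage


@pytest.fixture(scope="session")
def adult_montage():
    return make_montage("adult")


@pytest.fixture(scope="session")
def infant_montage():
    return make_montage("infant")


@pytest.fixture(scope="session")
def schedule():
    return synth.build_sequence_schedule(6, 6, 0.833, 34, 0.833)


@pytest.fixture(scope="session")
def clean_recording(schedule, adult_montage):
    """Noise-free single-sequence recording at 200 Hz with a 2-harmonic
    oddball (1.0 / 0.5 μV) and a 1-harmonic base response (2.0 μV),
    flat topography for exact amplitude checks."""
    flat = np.ones(adult_montage.n_channels)
    comps = [
        synth.SteadyStateComponent(1.0, [1.0, 0.5], topography=flat,
                                   name="oddball"),
        synth.SteadyStateComponent(6.0, [2.0], topography=flat, name="base"),
    ]
    rec, manifest = synth.simulate_recording(
        schedule, comps, synth.NoiseModel(), adult_montage,
        rate_hz=200.0, n_sequences=1, seed=0,
    )
    return rec, manifest


@pytest.fixture(scope="session")
def clean_segment(clean_recording):
    rec, _ = clean_recording
    return preprocess.crop_segments(rec, 36.0)[0]


@pytest.fixture(scope="session")
def noisy_segment(schedule, adult_montage):
    """One segment with pink noise and a known oddball, for operators that
    need realistic input."""
    comps = [synth.oddball_component(1.0, adult_montage),
             synth.base_component(2.0, adult_montage)]
    rec, manifest = synth.simulate_recording(
        schedule, comps, synth.NoiseModel(noise_scale=2.0), adult_montage,
        rate_hz=200.0, n_sequences=1, seed=42,
    )
    seg = preprocess.crop_segments(rec, 36.0)[0]
    return seg, manifest
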