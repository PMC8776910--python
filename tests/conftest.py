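"""Shared fixtures: synthetic fields and sequences reused across tests.

Field generation is the expensive step, so standard scenes are built once
per session and shared read-only; tests that mutate data build their own.
"""

from __future__ import annotations

import numpy as np
import pytest

from myofield.synth import (
    MotionSpec,
    SceneSpec,
    generate_contraction_sequence,
    generate_fluorescence_field,
)


@pytest.fixture(scope="session")
def clean_field():
    """Noiseless default TDP-style field: 8 myotubes, feeders, no aggregates."""
    spec = SceneSpec(seed=101, noise_sd=0.0, accumulation_fraction=0.0)
    return generate_fluorescence_field(spec)


@pytest.fixture(scope="session")
def accumulation_fields():
    """Five noiseless fields, 10 myotubes each, 30% accumulation-positive."""
    out = []
    for k in range(5):
        spec = SceneSpec(seed=200 + k, n_myotubes=10, accumulation_fraction=0.3,
                         marker_nuclear_fraction=0.7, noise_sd=0.0)
        out.append(generate_fluorescence_field(spec))
    return out


@pytest.fixture(scope="session")
def puncta_field():
    """Noiseless p62-style field with a 3% puncta area fraction."""
    spec = SceneSpec(seed=42, puncta_area_fraction=0.03, noise_sd=0.0)
    return generate_fluorescence_field(spec)


@pytest.fixture(scope="session")
def paced_sequence():
    """Noiseless 1 Hz contraction video at 10 fps, amplitude 3 px."""
    spec = MotionSpec(amplitude=3.0, frequency=1.0, frame_rate=10.0,
                      n_frames=20, noise_sd=0.0, seed=7)
    return generate_contraction_sequence(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
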