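"""Shared fixtures: one clean synthetic recording reused across test modules."""

import numpy as np
import pytest

from oscivar import SubjectSpec, synthesize_recording


@pytest.fixture(scope="session")
def asthma_spec() -> SubjectSpec:
    """Asthma-like subject with both intra-breath surcharges active."""
    return SubjectSpec(
        subject_id="A001",
        group="asthma",
        R_base=3.72,
        day_cv=0.14,
        breath_cv=0.05,
        early_insp_surcharge=0.15,
        exp_surcharge=0.25,
    )


@pytest.fixture(scope="session")
def clean_recording(asthma_spec):
    """Noiseless 2-minute recording at daily R = 3.9 (with breath noise)."""
    rng = np.random.default_rng(42)
    return synthesize_recording(
        asthma_spec, 3.9, rng, noise_sd_pressure=0.0, noise_sd_flow=0.0
    )


@pytest.fixture(scope="session")
def noiseless_recording():
    """Fully deterministic recording: no surcharges, no breath noise."""
    spec = SubjectSpec(
        subject_id="N001",
        group="healthy",
        R_base=3.0,
        day_cv=0.0,
        breath_cv=0.0,
    )
    rng = np.random.default_rng(0)
    return synthesize_recording(
        spec, 3.0, rng, noise_sd_pressure=0.0, noise_sd_flow=0.0
    )
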