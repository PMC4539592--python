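"""Shared fixtures: a small noiseless two-phase vesicle scene and the
method comparison computed on it once per session (curve fitting per
pixel is the expensive step)."""

import pytest
from hypothesis import HealthCheck, settings

import spectralgp as sg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def axis32() -> sg.WavelengthAxis:
    """The canonical detection axis: 32 channels of 8.9 nm from 415 nm."""
    return sg.WavelengthAxis(start_nm=415.0, width_nm=8.9, n_channels=32)


@pytest.fixture(scope="session")
def small_scene() -> sg.SyntheticScene:
    """Two-phase vesicle at desk scale (64x64, ~540 ring pixels)."""
    return sg.make_two_phase_vesicle(
        image_size=(64, 64), ring_radius=21.0, ring_thickness=4.0
    )


@pytest.fixture(scope="session")
def noiseless(small_scene):
    """(stack, truth) rendered without noise."""
    return sg.render_stack(small_scene, noise="none", seed=1)


@pytest.fixture(scope="session")
def noiseless_comparison(noiseless):
    """All three methods run on the noiseless scene with defaults."""
    stack, truth = noiseless
    config = sg.AnalysisConfig()
    return sg.compare_methods(
        stack, config, phase_labels=truth.phase_label
    )
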