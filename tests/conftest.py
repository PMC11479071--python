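"""Shared fixtures: small synthetic scenes rendered once per session."""

import numpy as np
import pytest
from hypothesis import settings

from pulsebeam import AcquisitionConfig, SceneParams, generate_rr_series, render_cube

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def short_cfg() -> AcquisitionConfig:
    """One-minute acquisition window; everything else at defaults."""
    return AcquisitionConfig(window_s=60.0)


@pytest.fixture(scope="session")
def clean_scene(short_cfg):
    """A noiseless, jitter-free one-minute scene with its ground truth."""
    params = SceneParams(seed=42, snr_db=None, phase_jitter_sd_rad=0.0, clutter_amp=0.2)
    truth = generate_rr_series(params, short_cfg.window_s)
    cube = render_cube(truth, params, short_cfg)
    return params, truth, cube


@pytest.fixture(scope="session")
def noisy_scene(short_cfg):
    """A one-minute scene at default SNR with frame-common phase jitter."""
    params = SceneParams(seed=7, snr_db=35.0, phase_jitter_sd_rad=0.02)
    truth = generate_rr_series(params, short_cfg.window_s)
    cube = render_cube(truth, params, short_cfg)
    return params, truth, cube


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
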