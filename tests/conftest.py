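"""Shared fixtures: radar config, calibrated threshold, canned scenes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import fmcw_vitals as fv
from fmcw_vitals import detect, preprocess

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def radar() -> fv.RadarConfig:
    return fv.RadarConfig()


@pytest.fixture(scope="session")
def background_profiles(radar):
    """Clutter-removed profiles of a 20-s empty-room recording."""
    scene = fv.Scenario(
        duration=20.0, segments=[(0.0, 20.0, "unmanned")],
        target_amplitude=0.0, seed=987)
    cube = fv.synthesize_if_cube(radar, scene)
    return preprocess.preprocess_cube(cube)


@pytest.fixture(scope="session")
def presence_threshold(background_profiles) -> float:
    return detect.calibrate_from_profiles(
        background_profiles, fv.ConfidenceConfig())


@pytest.fixture(scope="session")
def confidence_cfg(presence_threshold) -> fv.ConfidenceConfig:
    return dataclasses.replace(
        fv.ConfidenceConfig(), threshold=presence_threshold)


@pytest.fixture(scope="session")
def three_state_cube(radar) -> fv.IFFrameCube:
    """20 s empty room, 60 s stable sitting at 1 m, 20 s random motion."""
    scene = fv.Scenario(
        duration=100.0,
        segments=[(0.0, 20.0, "unmanned"), (20.0, 80.0, "stable"),
                  (80.0, 100.0, "motion")],
        seed=11)
    return fv.synthesize_if_cube(radar, scene)


def make_stable_cube(radar, duration=60.0, noise_sigma=0.0, seed=3,
                     **scenario_kwargs) -> fv.IFFrameCube:
    scene = fv.Scenario(
        duration=duration, segments=[(0.0, duration, "stable")],
        noise_sigma=noise_sigma, seed=seed, **scenario_kwargs)
    return fv.synthesize_if_cube(radar, scene)


@pytest.fixture(scope="session")
def stable_cube_noise_free(radar) -> fv.IFFrameCube:
    """30-s noise-free stable scene: respiration only, 1-mm amplitude."""
    return make_stable_cube(radar, duration=30.0, heart_amp=0.0)
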