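"""Shared fixtures: a small scaled synthetic cohort and its calibration
windows, generated once per session."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracles

from femg_xdyn.io_preprocess import (
    WindowingParams,
    compute_calibration_profile,
    normalize,
    segment_windows,
)
from femg_xdyn.model import ModelConfig, windows_to_arrays
from femg_xdyn.synth import SyntheticConfig, generate_cohort


def small_synth_config(**kw) -> SyntheticConfig:
    """Desk-scale generation conditions: 100 Hz sampling, short scenes.
    Burst rates/mixtures and physiology ranges stay at defaults."""
    base = dict(
        n_participants=4,
        sample_rate=100.0,
        scene_duration=40.0,
        baseline_duration=60.0,
        seed=42,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def tiny_model_config(**kw) -> ModelConfig:
    """A reduced architecture for fast unit tests."""
    base = dict(
        cnn_filters=(8, 16),
        tcn_filters=16,
        fc_hidden=16,
        rnn_hidden=12,
        max_epochs=6,
        patience=2,
        batch_size=32,
        lr=5e-3,
        n_val_participants=1,
        seed=3,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_synth_config())


@pytest.fixture(scope="session")
def calibration_windows(small_cohort):
    """(X, y, pids) calibration windows of the small cohort, normalized with
    per-participant estimated profiles; 1 s windows at 100 Hz."""
    windows = []
    for pid, calib in small_cohort.calibrations.items():
        profile = compute_calibration_profile(calib)
        windows.extend(segment_windows(normalize(calib, profile), WindowingParams(100)))
    return windows_to_arrays(windows)
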