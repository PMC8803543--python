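"""Shared fixtures: one small synthetic dataset reused across test modules."""

import numpy as np
import pytest

import statecomp as sc


@pytest.fixture(scope="session")
def small_config():
    return sc.SimConfig(n_subjects=3, duration_s=30.0, K_true=3, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """3 pseudo-subjects x 30 s at default gains, with ground truth."""
    return sc.generate_dataset(small_config)


@pytest.fixture(scope="session")
def micro_recs(small_dataset):
    """Microstate-arm preprocessing: reref -> band-pass -> 40 Hz maps."""
    recs, _ = small_dataset
    return [
        sc.moving_window_downsample(
            sc.bandpass(sc.rereference_average(r), 4.0, 30.0), 40.0
        )
        for r in recs
    ]


@pytest.fixture(scope="session")
def env_cat(small_dataset):
    """HMM-arm preprocessing: band-pass -> envelope -> 40 Hz -> normalize."""
    recs, _ = small_dataset
    envs = [
        sc.moving_window_downsample(
            sc.hilbert_envelope(sc.bandpass(r, 4.0, 30.0)), 40.0
        )
        for r in recs
    ]
    return sc.normalize_and_concatenate(envs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
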