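"""Shared fixtures: synthetic sessions reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from hippocoact import SynthConfig, generate_session


@pytest.fixture(scope="session")
def sleep_session():
    """240 s sleep-only session, 32 channels, default rates and amplitude."""
    cfg = SynthConfig(pre_sleep_s=240.0, n_channels=32, seed=11)
    lfp, spikes, ledger = generate_session(cfg)
    return cfg, lfp, spikes, ledger


@pytest.fixture(scope="session")
def laminar_session():
    """300 s, 64-channel laminar session with many DS events for CSD typing."""
    cfg = SynthConfig(
        pre_sleep_s=300.0, n_channels=64, ds_rate_hz=0.6, swr_rate_hz=0.2, seed=12
    )
    lfp, spikes, ledger = generate_session(cfg)
    return cfg, lfp, spikes, ledger


@pytest.fixture(scope="session")
def triplet_session():
    """Pre-sleep / exploration / post-sleep session with planted couplings."""
    cfg = SynthConfig(
        pre_sleep_s=180.0,
        exploration_s=180.0,
        post_sleep_s=180.0,
        n_channels=32,
        seed=13,
        coupling_spec=[(0, 1, "theta", 0.6), (2, 3, "ds_post", 0.6)],
    )
    lfp, spikes, ledger = generate_session(cfg)
    return cfg, lfp, spikes, ledger


def match_events(detected_t: np.ndarray, truth_t: np.ndarray, tol_s: float = 0.010):
    """(precision, recall) of detected peaks against planted peaks."""
    detected_t = np.asarray(detected_t, float)
    truth_t = np.asarray(truth_t, float)
    if len(detected_t) == 0 or len(truth_t) == 0:
        return 0.0, 0.0
    precision = np.mean([np.min(np.abs(truth_t - t)) < tol_s for t in detected_t])
    recall = np.mean([np.min(np.abs(detected_t - t)) < tol_s for t in truth_t])
    return float(precision), float(recall)
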