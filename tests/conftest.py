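"""Shared fixtures: session-scoped synthetic recordings reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from murisleep import load_preset, add_sleep_deprivation
from murisleep import scoring, spectral, synth


def full_chain(cfg):
    """simulate -> filter -> features -> calibrate -> score for one config."""
    hyp_true, _ = synth.simulate_hypnogram(cfg)
    eeg, emg = synth.simulate_signals(hyp_true, cfg)
    feats = spectral.epoch_features(
        spectral.highpass_eeg(eeg, cfg.fs_hz),
        spectral.bandpass_emg(emg, cfg.fs_hz),
        zt_start=cfg.zt_start,
        fs=cfg.fs_hz,
        epoch_s=cfg.epoch_s,
    )
    thr = scoring.calibrate_thresholds(feats)
    scored = scoring.score_epochs(feats, thr, zt_start=cfg.zt_start)
    return hyp_true, eeg, emg, feats, thr, scored


@pytest.fixture(scope="session")
def control_recording():
    """3-h control recording through the whole chain (truth + scored)."""
    cfg = load_preset("control_gfp", seed=42, days=0.125)
    return cfg, *full_chain(cfg)


@pytest.fixture(scope="session")
def sd_recordings():
    """Half-day (ZT0-12) baseline and deprivation-day recordings through the
    whole chain, for recovery/delta-rebound analyses."""
    base_cfg = load_preset("control_gfp", seed=7, days=0.5)
    test_cfg = add_sleep_deprivation(load_preset("control_gfp", seed=77, days=0.5))
    base = full_chain(base_cfg)
    test = full_chain(test_cfg)
    return base_cfg, base, test_cfg, test


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
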