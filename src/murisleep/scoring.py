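"""Automatic vigilance-state scoring from per-epoch features.

A reconstruction of the standard EMG-then-ratio decision tree: high EMG RMS
marks WAKE; among quiescent epochs a high theta:delta ratio marks REM and
the remainder is NREM.  The raw labels are then majority-smoothed, episodes
shorter than a minimum length are merged into their flanking state, and REM
directly following WAKE is relabelled NREM (REM is entered from NREM in
rodents).  Thresholds are calibrated per recording from the feature
distributions; an optional per-epoch override file substitutes for manual
confirmation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import NREM, REM, WAKE
from .hypnogram import Hypnogram, episodes, transitions  # noqa: F401 (re-export)

logger = logging.getLogger(__name__)


@dataclass
class ScoringThresholds:
    emg_wake_threshold: float  # uV
    ratio_rem_threshold: float  # dimensionless
    delta_nrem_floor: float | None = None  # unused by default
    smoothing_window_epochs: int = 3
    min_episode_epochs: int = 2

    def __post_init__(self) -> None:
        if self.emg_wake_threshold <= 0 or self.ratio_rem_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.smoothing_window_epochs < 1 or self.min_episode_epochs < 1:
            raise ValueError("windows must be >= 1")


def calibrate_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Derive scoring thresholds from >= 1 h of features.

    The EMG threshold sits at the deepest valley between the two dominant
    modes of log(emg_rms) (kernel density estimate); the REM threshold is
    the 90th percentile of the theta:delta ratio among low-EMG epochs.
    Degenerate distributions fall back to the 60th percentile / 2.0 with a
    logged warning.  Deterministic given the features.
    """
    if len(features) * 5.0 < 3600.0:
        raise ValueError("calibration needs at least 1 h of features")
    emg = features["emg_rms"].to_numpy(dtype=float)
    emg = emg[np.isfinite(emg) & (emg > 0)]
    log_emg = np.log(emg)

    emg_thr = None
    if np.ptp(log_emg) > 1e-6:
        kde = stats.gaussian_kde(log_emg)
        grid = np.linspace(log_emg.min(), log_emg.max(), 512)
        dens = kde(grid)
        # local maxima, two largest modes, deepest valley between them
        peaks = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
        if len(peaks) >= 2:
            top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
            valley = top2[0] + int(np.argmin(dens[top2[0] : top2[1] + 1]))
            emg_thr = float(np.exp(grid[valley]))
    if emg_thr is None:
        emg_thr = float(np.exp(np.percentile(log_emg, 60.0)))
        logger.warning("EMG distribution not bimodal; falling back to 60th percentile")

    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)
    low_emg = features["emg_rms"].to_numpy(dtype=float) <= emg_thr
    cand = ratio[low_emg & np.isfinite(ratio)]
    if len(cand) >= 10 and np.ptp(cand) > 1e-9:
        ratio_thr = float(np.percentile(cand, 90.0))
    else:
        ratio_thr = 2.0
        logger.warning("degenerate ratio distribution; falling back to 2.0")
    return ScoringThresholds(emg_wake_threshold=emg_thr, ratio_rem_threshold=ratio_thr)


def _majority_smooth(codes: np.ndarray, window: int) -> np.ndarray:
    """Centered majority vote; ties keep the incumbent label."""
    if window <= 1:
        return codes
    half = window // 2
    n = len(codes)
    counts = np.zeros((3, n), dtype=int)
    for off in range(-half, half + 1):
        shifted = np.roll(codes, -off)
        # edges: clamp instead of wrapping
        if off < 0:
            shifted[:-off] = codes[0]
        elif off > 0:
            shifted[-off:] = codes[-1]
        for c in range(3):
            counts[c] += shifted == c
    best = counts.max(axis=0)
    out = codes.copy()
    for c in range(3):
        wins = (counts[c] == best) & (counts[codes, np.arange(n)] < best)
        out[wins] = c
    return out


def _merge_short_episodes(states: np.ndarray, min_epochs: int) -> np.ndarray:
    """Relabel runs shorter than ``min_epochs`` with the preceding state
    (the following state for a short leading run), repeating to a fixed
    point."""
    states = states.copy()
    while True:
        eps = episodes(states)
        short = [e for e in eps if e.n_epochs < min_epochs]
        if not short or len(eps) == 1:
            return states
        changed = False
        for i, ep in enumerate(eps):
            if ep.n_epochs >= min_epochs:
                continue
            repl = eps[i - 1].state if i > 0 else eps[i + 1].state
            if repl != ep.state:
                states[ep.start_epoch : ep.start_epoch + ep.n_epochs] = repl
                changed = True
                break  # episode list is stale; recompute
        if not changed:
            return states


def score_epochs(
    features: pd.DataFrame, thresholds: ScoringThresholds, zt_start: float | None = None
) -> Hypnogram:
    """Classify each epoch as WAKE/NREM/REM and post-process.

    Rules: ``emg_rms > emg_wake_threshold`` => WAKE; else
    ``theta_delta_ratio > ratio_rem_threshold`` => REM; else NREM (with the
    optional absolute delta floor applied before the REM test).  Epochs with
    missing features are flagged and inherit the previous valid label.
    """
    emg = features["emg_rms"].to_numpy(dtype=float)
    ratio = features["theta_delta_ratio"].to_numpy(dtype=float)
    delta = features["delta"].to_numpy(dtype=float)
    n = len(features)
    missing = ~np.isfinite(emg) | ~np.isfinite(delta)

    codes = np.full(n, 1, dtype=np.int64)  # NREM default
    codes[emg > thresholds.emg_wake_threshold] = 0
    rem = (emg <= thresholds.emg_wake_threshold) & (ratio > thresholds.ratio_rem_threshold)
    if thresholds.delta_nrem_floor is not None:
        rem &= delta < thresholds.delta_nrem_floor
    codes[np.isfinite(ratio) & rem] = 2

    # missing epochs: carry the previous valid label (WAKE at the start)
    for i in np.flatnonzero(missing):
        codes[i] = codes[i - 1] if i > 0 else 0

    codes = _majority_smooth(codes, thresholds.smoothing_window_epochs)
    states = np.array([WAKE, NREM, REM], dtype=object)[codes]
    states = _merge_short_episodes(states, thresholds.min_episode_epochs)

    # REM cannot directly follow WAKE: relabel such episodes as NREM
    eps = episodes(states)
    for prev, cur in zip(eps[:-1], eps[1:]):
        if cur.state == REM and prev.state == WAKE:
            states[cur.start_epoch : cur.start_epoch + cur.n_epochs] = NREM

    if zt_start is None:
        zt_start = float(features["zt_h"].iloc[0]) if "zt_h" in features else 0.0
    return Hypnogram(states, epoch_s=5.0, zt_start=zt_start, flagged=missing)


def apply_overrides(hyp: Hypnogram, overrides: pd.DataFrame) -> Hypnogram:
    """Apply a manual-confirmation override table (epoch_index, state)."""
    states = hyp.states.copy()
    for _, row in overrides.iterrows():
        states[int(row["epoch_index"])] = str(row["state"])
    return Hypnogram(states, epoch_s=hyp.epoch_s, zt_start=hyp.zt_start, flagged=hyp.flagged)
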