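"""Sleep-deprivation accounting and delta-power rebound analysis.

"Total sleep" is NREM + REM throughout.  Baseline matching is always by
zeitgeber time: recovery and rebound metrics compare the test recording to
a baseline recording of the same animal at the same ZT, so diurnal
structure and global EEG amplitude cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import NREM, InterventionEvent
from .hypnogram import Hypnogram
from .spectral import SpectralSeries

#: minimum NREM epochs for a bin/window mean to be trusted
MIN_NREM_EPOCHS = 6


@dataclass
class RecoveryCurve:
    """Cumulative fraction of deprivation-lost sleep regained vs time.

    ``fraction`` is piecewise-constant between epoch boundaries, starts at
    0 and may exceed 1 or go negative.  ``recovery_rate_min_per_h`` is the
    least-squares slope of cumulative gained sleep (min) against time (h)
    over the curve's span.
    """

    time_h: np.ndarray
    fraction: np.ndarray
    debt_min: float
    recovery_rate_min_per_h: float

    def fraction_at(self, t_h: float) -> float:
        """Recovered fraction at ``t_h`` hours after deprivation end."""
        i = int(np.searchsorted(self.time_h, t_h, side="right")) - 1
        if i < 0:
            return 0.0
        return float(self.fraction[min(i, len(self.fraction) - 1)])


def _check_aligned(a: Hypnogram, b: Hypnogram) -> None:
    if a.epoch_s != b.epoch_s:
        raise ValueError("epoch lengths differ")
    if abs(a.zt_start - b.zt_start) > 1e-9:
        raise ValueError("recordings are not ZT-aligned")


def _folded_sleep_profile(baseline: Hypnogram) -> np.ndarray:
    """Baseline sleep propensity per ZT epoch: the sleep indicator averaged
    across all recorded days at each zeitgeber epoch.  A one-day baseline
    reduces to its plain sleep indicator; longer baselines average out
    day-to-day episode noise."""
    eph = baseline.epoch_s / 3600.0
    per_day = int(round(24.0 / eph))
    zt_ep = np.round(baseline.zt / eph).astype(int) % per_day
    sleep = baseline.is_sleep().astype(float)
    profile = np.full(per_day, np.nan)
    counts = np.bincount(zt_ep, minlength=per_day)
    sums = np.bincount(zt_ep, weights=sleep, minlength=per_day)
    with np.errstate(invalid="ignore"):
        profile[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return profile


def _baseline_profile_for(test: Hypnogram, baseline: Hypnogram) -> np.ndarray:
    """ZT-matched baseline sleep propensity for every test epoch."""
    eph = test.epoch_s / 3600.0
    per_day = int(round(24.0 / eph))
    profile = _folded_sleep_profile(baseline)
    zt_ep = np.round(test.zt / eph).astype(int) % per_day
    out = profile[zt_ep]
    if np.isnan(out).any():
        raise ValueError("baseline does not cover the required ZT range")
    return out


def sleep_debt(
    baseline: Hypnogram, test: Hypnogram, sd_window: tuple[float, float] = (0.0, 5.0)
) -> float:
    """Minutes of total sleep (NREM+REM) lost in ``sd_window`` (ZT hours,
    first test-recording day) relative to the ZT-matched baseline.

    The baseline may span several days; it is folded into a 24-h sleep
    propensity profile (per-ZT-epoch mean across days) before comparison.
    """
    _check_aligned(baseline, test)
    mask = test.window_mask(*sd_window)
    covered = mask.sum() * test.epoch_s / 3600.0
    if covered < (sd_window[1] - sd_window[0]) - test.epoch_s / 3600.0:
        raise ValueError("recording does not cover the deprivation window")
    epoch_min = test.epoch_s / 60.0
    base = _baseline_profile_for(test, baseline)
    base_sleep = float(base[mask].sum()) * epoch_min
    test_sleep = float(test.is_sleep()[mask].sum()) * epoch_min
    return base_sleep - test_sleep


def recovery_curve(
    baseline: Hypnogram,
    test: Hypnogram,
    sd_window: tuple[float, float] = (0.0, 5.0),
    horizon_h: float = 19.0,
) -> RecoveryCurve:
    """Cumulative recovered-sleep fraction after the deprivation window.

    fraction(t) = [cumulative test sleep - cumulative baseline sleep over
    (window end, window end + t]] / debt.
    """
    debt = sleep_debt(baseline, test, sd_window)
    if debt <= 0:
        raise ValueError(f"sleep debt is {debt:.1f} min; nothing to recover")
    _check_aligned(baseline, test)
    end_h = (sd_window[1] - test.zt_start) % 24.0
    epoch_h = test.epoch_s / 3600.0
    start_ep = int(round(end_h / epoch_h))
    stop_ep = min(len(test), start_ep + int(round(horizon_h / epoch_h)))
    if stop_ep <= start_ep:
        raise ValueError("no data after the deprivation window")
    epoch_min = test.epoch_s / 60.0
    base = _baseline_profile_for(test, baseline)
    gained = (
        test.is_sleep()[start_ep:stop_ep].astype(float) - base[start_ep:stop_ep]
    ).cumsum() * epoch_min
    time_h = (np.arange(1, stop_ep - start_ep + 1)) * epoch_h
    slope = float(np.polyfit(time_h, gained, 1)[0])
    return RecoveryCurve(
        time_h=time_h,
        fraction=gained / debt,
        debt_min=debt,
        recovery_rate_min_per_h=slope,
    )


def _nrem_delta_by_bin(
    feats: pd.DataFrame, hyp: Hypnogram, edges_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean NREM delta power and NREM epoch count per elapsed-time bin."""
    delta = feats["delta"].to_numpy(dtype=float)
    n = min(len(delta), len(hyp))
    nrem = (hyp.states[:n] == NREM) & ~hyp.flagged[:n] & np.isfinite(delta[:n])
    e = hyp.elapsed_h[:n]
    means = np.full(len(edges_h) - 1, np.nan)
    counts = np.zeros(len(edges_h) - 1, dtype=int)
    for i, (lo, hi) in enumerate(zip(edges_h[:-1], edges_h[1:])):
        m = nrem & (e >= lo) & (e < hi)
        counts[i] = int(m.sum())
        if counts[i]:
            means[i] = float(delta[:n][m].mean())
    return means, counts


def delta_timecourse(
    baseline_feats: pd.DataFrame,
    baseline_hyp: Hypnogram,
    test_feats: pd.DataFrame,
    test_hyp: Hypnogram,
    bin_h: float = 1.0,
) -> pd.DataFrame:
    """Hourly NREM delta power in the test recording against ZT-matched
    baseline, as a percentage ratio.

    Bins with fewer than 6 NREM epochs on either side are flagged
    ``low_confidence``; bins with no baseline NREM have an undefined ratio.
    """
    _check_aligned(baseline_hyp, test_hyp)
    dur = min(baseline_hyp.duration_h, test_hyp.duration_h)
    edges = np.arange(0.0, dur + 1e-9, bin_h)
    base_mean, base_n = _nrem_delta_by_bin(baseline_feats, baseline_hyp, edges)
    test_mean, test_n = _nrem_delta_by_bin(test_feats, test_hyp, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = 100.0 * test_mean / base_mean
    return pd.DataFrame(
        {
            "zt_bin_start": (baseline_hyp.zt_start + edges[:-1]) % 24.0,
            "elapsed_h": edges[:-1],
            "test_delta": test_mean,
            "baseline_delta": base_mean,
            "ratio_pct": ratio,
            "n_test_epochs": test_n,
            "n_baseline_epochs": base_n,
            "low_confidence": (test_n < MIN_NREM_EPOCHS) | (base_n < MIN_NREM_EPOCHS),
        }
    )


def first_hour_delta(
    baseline_feats: pd.DataFrame,
    baseline_hyp: Hypnogram,
    test_feats: pd.DataFrame,
    test_hyp: Hypnogram,
    sd_end_zt: float = 5.0,
) -> tuple[float, float, float]:
    """NREM delta in the first recovery hour vs ZT-matched baseline.

    The "first hour" is the first 1-h bin after deprivation end containing
    at least 6 NREM epochs in the test recording.  Returns
    (baseline_mean, test_mean, ratio).
    """
    _check_aligned(baseline_hyp, test_hyp)
    end_h = (sd_end_zt - test_hyp.zt_start) % 24.0
    dur = min(baseline_hyp.duration_h, test_hyp.duration_h)
    edges = np.arange(end_h, dur + 1e-9, 1.0)
    if len(edges) < 2:
        raise ValueError("no full hour after deprivation end")
    test_mean, test_n = _nrem_delta_by_bin(test_feats, test_hyp, edges)
    base_mean, base_n = _nrem_delta_by_bin(baseline_feats, baseline_hyp, edges)
    ok = np.flatnonzero((test_n >= MIN_NREM_EPOCHS) & (base_n >= MIN_NREM_EPOCHS))
    if len(ok) == 0:
        raise ValueError("insufficient NREM sleep for a first-hour comparison")
    i = int(ok[0])
    return float(base_mean[i]), float(test_mean[i]), float(test_mean[i] / base_mean[i])


@dataclass
class DrugDeltaResponse:
    """Evoked NREM-like delta-power time course after a drug event."""

    time_min: np.ndarray  # sliding-bin centers, minutes post-injection
    delta: np.ndarray  # mean NREM delta per bin (NaN where empty)
    ratio: np.ndarray  # delta / ZT-matched baseline NREM delta
    peak_time_min: float
    peak_ratio: float
    first30_spectrum: Optional[np.ndarray] = None


def drug_delta_response(
    features: pd.DataFrame,
    hyp: Hypnogram,
    event: InterventionEvent,
    baseline_feats: pd.DataFrame,
    baseline_hyp: Hypnogram,
    window_min: float = 5.0,
    step_min: float = 1.0,
    spectra: Optional[SpectralSeries] = None,
) -> DrugDeltaResponse:
    """Delta power in sliding bins after a drug injection.

    The reference is the mean NREM delta of the ZT-matched baseline
    recording over the event horizon.  ``peak_time_min`` is the bin-center
    of the maximum; bins with no scored NREM-like epochs are NaN and are
    excluded from the argmax.  If per-epoch ``spectra`` are supplied, the
    mean PSD over the first 30 min post-injection is attached.
    """
    _check_aligned(baseline_hyp, hyp)
    onset_h = (event.zt_onset - hyp.zt_start) % 24.0
    if onset_h >= hyp.duration_h:
        raise ValueError("event outside the recording")
    horizon_h = min(event.duration_h, hyp.duration_h - onset_h)
    if horizon_h <= 0:
        raise ValueError("no post-event data")

    delta = features["delta"].to_numpy(dtype=float)
    n = min(len(delta), len(hyp))
    nrem = (hyp.states[:n] == NREM) & ~hyp.flagged[:n] & np.isfinite(delta[:n])
    u_min = (hyp.elapsed_h[:n] - onset_h) * 60.0

    centers = np.arange(window_min / 2.0, horizon_h * 60.0 - window_min / 2.0 + 1e-9, step_min)
    means = np.full(len(centers), np.nan)
    for i, c in enumerate(centers):
        m = nrem & (u_min >= c - window_min / 2.0) & (u_min < c + window_min / 2.0)
        if m.any():
            means[i] = float(delta[:n][m].mean())

    # ZT-matched natural-NREM reference from the baseline recording
    bdelta = baseline_feats["delta"].to_numpy(dtype=float)
    nb = min(len(bdelta), len(baseline_hyp))
    b_nrem = (
        (baseline_hyp.states[:nb] == NREM)
        & ~baseline_hyp.flagged[:nb]
        & np.isfinite(bdelta[:nb])
    )
    b_window = (baseline_hyp.elapsed_h[:nb] >= onset_h) & (
        baseline_hyp.elapsed_h[:nb] < onset_h + horizon_h
    )
    ref_mask = b_nrem & b_window
    if ref_mask.sum() < MIN_NREM_EPOCHS:
        raise ValueError("baseline has insufficient NREM at the matched ZT")
    ref = float(bdelta[:nb][ref_mask].mean())

    valid = np.isfinite(means)
    if not valid.any():
        raise ValueError("no scored NREM-like epochs after the event")
    i_peak = int(np.flatnonzero(valid)[np.argmax(means[valid])])
    spectrum30 = None
    if spectra is not None:
        m30 = nrem & (u_min >= 0) & (u_min < 30.0)
        if m30.any():
            spectrum30 = spectra.psd[:n][m30].mean(axis=0)
    return DrugDeltaResponse(
        time_min=centers,
        delta=means,
        ratio=means / ref,
        peak_time_min=float(centers[i_peak]),
        peak_ratio=float(means[i_peak] / ref),
        first30_spectrum=spectrum30,
    )


def delta_rebound(
    features: pd.DataFrame,
    hyp: Hypnogram,
    event: InterventionEvent,
    baseline_feats: pd.DataFrame,
    baseline_hyp: Hypnogram,
    offset_h: float = 3.5,
    window_h: float = 1.0,
) -> float:
    """Mean NREM delta in a window starting ``offset_h`` after the event,
    as a percentage of ZT-matched baseline NREM delta."""
    _check_aligned(baseline_hyp, hyp)
    onset_h = (event.zt_onset - hyp.zt_start) % 24.0
    lo, hi = onset_h + offset_h, onset_h + offset_h + window_h
    edges = np.array([lo, hi])
    test_mean, test_n = _nrem_delta_by_bin(features, hyp, edges)
    base_mean, base_n = _nrem_delta_by_bin(baseline_feats, baseline_hyp, edges)
    if test_n[0] < MIN_NREM_EPOCHS or base_n[0] < MIN_NREM_EPOCHS:
        raise ValueError("insufficient NREM epochs in the rebound window")
    return float(100.0 * test_mean[0] / base_mean[0])
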