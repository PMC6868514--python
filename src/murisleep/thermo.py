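"""Core-body-temperature analyses: diurnal profiles, phase means, the
dark->light transition spike, and drug-induced hypothermia characterization.

Telemetry arrives at a 2-min cadence; all analyses are ZT-anchored
(ZT0 = lights on, lights off = ZT12-24).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import LIGHTS_OFF_ZT, InterventionEvent

logger = logging.getLogger(__name__)

PLAUSIBLE_RANGE_C = (15.0, 45.0)


@dataclass
class TemperatureSeries:
    """Timestamped core body temperature.

    ``elapsed_h`` are hours since recording start (strictly increasing,
    nominally 2-min cadence); ``zt_start`` anchors them to zeitgeber time.
    Samples outside the plausible range (15-45 C) are flagged, not dropped.
    """

    elapsed_h: np.ndarray
    temp_c: np.ndarray
    zt_start: float = 0.0
    implausible: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.elapsed_h = np.asarray(self.elapsed_h, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.elapsed_h.shape != self.temp_c.shape:
            raise ValueError("elapsed_h and temp_c must have the same shape")
        if len(self.elapsed_h) > 1 and not np.all(np.diff(self.elapsed_h) > 0):
            raise ValueError("timestamps must be strictly increasing")
        lo, hi = PLAUSIBLE_RANGE_C
        self.implausible = (self.temp_c <= lo) | (self.temp_c >= hi)
        n_bad = int(self.implausible.sum())
        if n_bad:
            logger.warning("%d temperature samples outside %s C", n_bad, PLAUSIBLE_RANGE_C)

    def __len__(self) -> int:
        return len(self.elapsed_h)

    @property
    def zt(self) -> np.ndarray:
        return (self.zt_start + self.elapsed_h) % 24.0

    @property
    def day(self) -> np.ndarray:
        return np.floor((self.zt_start + self.elapsed_h) / 24.0).astype(int)

    @property
    def lights_on(self) -> np.ndarray:
        return self.zt < LIGHTS_OFF_ZT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"zt_h": self.zt, "temp_c": self.temp_c})

    @classmethod
    def from_arrays(cls, elapsed_h, temp_c, zt_start=0.0) -> "TemperatureSeries":
        return cls(np.asarray(elapsed_h), np.asarray(temp_c), zt_start)


@dataclass
class HypothermiaReport:
    """Summary of a drug-induced hypothermia episode.

    ``recovery_time_min`` is the first post-nadir return to within 1 C of
    the pre-injection mean, or ``inf`` when the series never rewarms within
    the available data.
    """

    pre_injection_mean_c: float
    nadir_c: float
    time_to_nadir_min: float
    recovery_time_min: float
    area_below_baseline_c_h: float


def diurnal_profile(series: TemperatureSeries, bin_min: float = 30.0) -> pd.DataFrame:
    """Per-ZT-bin mean +/- SEM across days.

    Each day contributes one mean per bin; the profile is the across-day
    mean, so it is invariant to day-order permutation and its grand mean
    equals the series mean when days are complete.
    """
    if series.elapsed_h[-1] - series.elapsed_h[0] < 24.0 - 0.2:
        raise ValueError("diurnal profile needs at least one full day")
    gaps = np.diff(series.elapsed_h) * 60.0
    n_gaps = int((gaps > 10.0).sum())
    if n_gaps:
        logger.warning("%d gaps > 10 min in temperature series", n_gaps)
    bin_h = bin_min / 60.0
    df = pd.DataFrame(
        {
            "bin": np.floor(series.zt / bin_h).astype(int),
            "day": series.day,
            "temp": series.temp_c,
        }
    )
    per_day = df.groupby(["bin", "day"])["temp"].mean().reset_index()
    out = per_day.groupby("bin")["temp"].agg(["mean", "sem", "count"]).reset_index()
    out["zt_h"] = (out["bin"] + 0.5) * bin_h
    return out.rename(columns={"mean": "mean_c", "sem": "sem_c", "count": "n_days"})[
        ["zt_h", "mean_c", "sem_c", "n_days"]
    ]


def phase_means(series: TemperatureSeries) -> dict[str, float]:
    """Arithmetic means over lights-on, lights-off and all samples."""
    if series.elapsed_h[-1] - series.elapsed_h[0] < 24.0 - 0.2:
        raise ValueError("phase means need at least one full day")
    on = series.lights_on
    return {
        "lights_on_mean_c": float(series.temp_c[on].mean()),
        "lights_off_mean_c": float(series.temp_c[~on].mean()),
        "overall_mean_c": float(series.temp_c.mean()),
    }


def transition_spike(
    series: TemperatureSeries, center_zt: float = 24.0, window_min: float = 60.0
) -> float:
    """Mean temperature in a window centered on the lights-off -> lights-on
    transition minus the mean of the two flanking windows of equal width."""
    if series.elapsed_h[-1] - series.elapsed_h[0] < 48.0 - 0.2:
        raise ValueError("transition spike needs at least two days")
    half_h = window_min / 120.0
    # circular distance from the transition point
    d = (series.zt - center_zt + 12.0) % 24.0 - 12.0
    center = np.abs(d) <= half_h
    flank = (np.abs(d) > half_h) & (np.abs(d) <= 3 * half_h)
    return float(series.temp_c[center].mean() - series.temp_c[flank].mean())


def drug_response(
    series: TemperatureSeries, event: InterventionEvent
) -> HypothermiaReport:
    """Characterize the hypothermia following a drug event.

    Requires >= 1 h of pre-event and >= 4 h of post-event samples.  The
    nadir is the raw post-event minimum within the event horizon (no
    smoothing at the 2-min cadence).
    """
    onset = (event.zt_onset - series.zt_start) % 24.0
    t = series.elapsed_h
    if onset - t[0] < 1.0 - 1e-9 or t[-1] - onset < 4.0 - 1e-9:
        raise ValueError("need >=1 h pre-event and >=4 h post-event coverage")
    pre = (t >= onset - 1.0) & (t < onset)
    post = (t >= onset) & (t <= onset + event.duration_h)
    pre_mean = float(series.temp_c[pre].mean())
    post_t = t[post]
    post_temp = series.temp_c[post]
    i_nadir = int(np.argmin(post_temp))
    nadir = float(post_temp[i_nadir])
    time_to_nadir = float((post_t[i_nadir] - onset) * 60.0)
    if not (post_temp < pre_mean - 1.0).any():
        recovery = 0.0  # never left the baseline band
    else:
        after = post_temp[i_nadir:] >= pre_mean - 1.0
        if after.any():
            recovery = float((post_t[i_nadir + int(np.argmax(after))] - onset) * 60.0)
        else:
            recovery = math.inf
    deficit = np.clip(pre_mean - post_temp, 0, None)
    area = float(np.trapezoid(deficit, post_t))
    return HypothermiaReport(
        pre_injection_mean_c=pre_mean,
        nadir_c=nadir,
        time_to_nadir_min=time_to_nadir,
        recovery_time_min=recovery,
        area_below_baseline_c_h=area,
    )
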