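"""Quick-look figures: hypnogram raster, diurnal temperature profile,
recovery curve.  All return the matplotlib Axes for further styling."""

from __future__ import annotations

import numpy as np

from .hypnogram import STATE_CODES, Hypnogram
from .homeostasis import RecoveryCurve
from .thermo import TemperatureSeries, diurnal_profile


def plot_hypnogram(hyp: Hypnogram, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    codes = hyp.codes
    ax.step(hyp.elapsed_h, codes, where="post", lw=0.5)
    ax.set_yticks(list(STATE_CODES.values()), list(STATE_CODES.keys()))
    ax.set_xlabel("time (h)")
    return ax


def plot_diurnal_profile(series: TemperatureSeries, ax=None, **kwargs):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    prof = diurnal_profile(series, **kwargs)
    ax.errorbar(prof["zt_h"], prof["mean_c"], yerr=prof["sem_c"], fmt="-")
    ax.axvspan(12, 24, color="0.9", zorder=0)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("core temperature (°C)")
    return ax


def plot_recovery(curve: RecoveryCurve, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(curve.time_h, 100 * np.asarray(curve.fraction))
    ax.axhline(100, ls="--", c="0.5")
    ax.set_xlabel("time after deprivation end (h)")
    ax.set_ylabel("lost sleep recovered (%)")
    return ax
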