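"""Sleep-architecture summaries: time in state, episode statistics and
transition counts per light phase, state-conditioned spectra, and the group
comparison helpers (Welch/paired t tests with Holm-Bonferroni adjustment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import NREM, PHASES, STATES
from .hypnogram import Hypnogram, episodes, transitions
from .spectral import SpectralSeries


def _phase_labels(hyp: Hypnogram) -> np.ndarray:
    return np.where(hyp.lights_on, PHASES[0], PHASES[1])


def time_in_state(hyp: Hypnogram) -> pd.DataFrame:
    """Minutes per state per light phase; sums conserve the recording
    duration exactly (epochs are atomic)."""
    phase = _phase_labels(hyp)
    epoch_min = hyp.epoch_s / 60.0
    rows = []
    for ph in PHASES:
        for s in STATES:
            n = int(((hyp.states == s) & (phase == ph)).sum())
            rows.append({"phase": ph, "state": s, "total_minutes": n * epoch_min})
    return pd.DataFrame(rows)


def episode_stats(hyp: Hypnogram) -> pd.DataFrame:
    """Episode counts and mean durations (min) per state per phase; an
    episode straddling a phase boundary is attributed to the phase
    containing its onset."""
    phase = _phase_labels(hyp)
    epoch_min = hyp.epoch_s / 60.0
    eps = episodes(hyp)
    rows = []
    for ph in PHASES:
        for s in STATES:
            durs = [
                e.n_epochs for e in eps if e.state == s and phase[e.start_epoch] == ph
            ]
            rows.append(
                {
                    "phase": ph,
                    "state": s,
                    "episode_count": len(durs),
                    "mean_episode_duration_min": (
                        float(np.mean(durs)) * epoch_min if durs else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def transitions_by_phase(hyp: Hypnogram) -> pd.DataFrame:
    """Adjacent-epoch transition counts per ordered state pair per phase
    (the phase of the epoch being left)."""
    phase = _phase_labels(hyp)
    rows = []
    s = hyp.states
    for ph in PHASES:
        mask = phase[:-1] == ph
        change = mask & (s[:-1] != s[1:])
        for a in STATES:
            for b in STATES:
                if a == b:
                    continue
                n = int((change & (s[:-1] == a) & (s[1:] == b)).sum())
                rows.append({"phase": ph, "from": a, "to": b, "count": n})
    return pd.DataFrame(rows)


def state_spectra(hyp: Hypnogram, spectra: SpectralSeries) -> dict[str, np.ndarray]:
    """Bin-wise mean PSD per state; a state with no epochs maps to an
    all-NaN spectrum (flagged empty)."""
    if len(hyp) != spectra.n_epochs:
        raise ValueError("hypnogram and spectra differ in epoch count")
    valid = ~hyp.flagged
    out = {}
    for s in STATES:
        mask = (hyp.states == s) & valid
        if mask.any():
            out[s] = spectra.psd[mask].mean(axis=0)
        else:
            out[s] = np.full(spectra.psd.shape[1], np.nan)
    return out


def nrem_peak_frequency(hyp: Hypnogram, spectra: SpectralSeries) -> float:
    """Frequency-bin center maximizing the mean NREM PSD above the DC bin;
    ties break toward the lower frequency."""
    mean_psd = state_spectra(hyp, spectra)[NREM]
    if np.isnan(mean_psd).all():
        raise ValueError("no NREM epochs")
    return float(spectra.freqs[1 + int(np.argmax(mean_psd[1:]))])


def compare_groups(
    values_a, values_b, paired: bool = False
) -> tuple[float, float]:
    """Two-tailed t test between two groups of per-animal metric values:
    Welch's t for independent groups, a paired t otherwise.  Returns
    (statistic, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    if paired:
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of raw p-values
    (monotone, each >= its raw p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def compare_metric_family(
    group_a: dict[str, np.ndarray], group_b: dict[str, np.ndarray], paired: bool = False
) -> pd.DataFrame:
    """t test per metric plus Holm-Bonferroni adjustment over the family.

    ``group_a``/``group_b`` map metric name -> per-animal values.
    """
    names = list(group_a)
    if set(names) != set(group_b):
        raise ValueError("metric families differ between groups")
    rows = []
    for m in names:
        t, p = compare_groups(group_a[m], group_b[m], paired=paired)
        rows.append(
            {
                "metric": m,
                "mean_a": float(np.mean(group_a[m])),
                "sem_a": float(stats.sem(group_a[m])),
                "mean_b": float(np.mean(group_b[m])),
                "sem_b": float(stats.sem(group_b[m])),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_bonferroni(df["p"].to_numpy())
    return df
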