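"""Ground-truthed synthetic EEG/EMG/temperature recordings.

The generator draws a hypnogram from a semi-Markov chain (geometric episode
lengths with phase-specific means, successor states from configured
transition weights), overlays interventions (enforced wakefulness, a
sedative drug), then renders per-epoch EEG as a weighted sum of band-limited
noise components and EMG as state-scaled white noise, and core body
temperature as phase means + diurnal sinusoid + noise + event responses.

Everything is a pure function of (config, seed): per-stream generators are
derived as ``default_rng([seed, k])`` with a distinct ``k`` for the
hypnogram, the signals and the temperature series.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import optimize

from .config import (
    LIGHTS_OFF,
    LIGHTS_OFF_ZT,
    LIGHTS_ON,
    NREM,
    REM,
    STATES,
    WAKE,
    InterventionEvent,
    ScenarioConfig,
)
from .hypnogram import Episode, Hypnogram, episodes
from .thermo import TemperatureSeries

#: EEG synthesis bands (Hz): the broadband component spans the whole
#: physiological range so that band-weight fractions control the spectrum.
SYNTH_BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 10.0), "broadband": (0.5, 80.0)}


# ---------------------------------------------------------------------------
# embedded chain / expectation helpers
# ---------------------------------------------------------------------------

def transition_matrix(cfg: ScenarioConfig) -> np.ndarray:
    """Row-normalized successor probabilities of the embedded chain
    (order WAKE, NREM, REM; diagonal zero)."""
    P = np.zeros((3, 3))
    for i, s in enumerate(STATES):
        w = cfg.state_params[s].transition_weights
        for j, s2 in enumerate(STATES):
            P[i, j] = w.get(s2, 0.0)
        tot = P[i].sum()
        if tot <= 0:
            raise ValueError(f"{s}: zero-weight successor set")
        P[i] /= tot
    return P


def stationary_visit_frequencies(cfg: ScenarioConfig) -> np.ndarray:
    """Stationary distribution pi of the embedded (episode-level) chain."""
    P = transition_matrix(cfg)
    A = np.vstack([P.T - np.eye(3), np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0, None) / pi.sum()


def _mean_durations_s(cfg: ScenarioConfig, phase: str) -> np.ndarray:
    return np.array(
        [cfg.state_params[s].mean_episode_duration_s[phase] for s in STATES]
    )


def stationary_state_fractions(cfg: ScenarioConfig, phase: str) -> np.ndarray:
    """Expected long-run time fraction per state for one light phase:
    visit frequencies weighted by mean episode durations."""
    pi = stationary_visit_frequencies(cfg)
    m = _mean_durations_s(cfg, phase)
    w = pi * m
    return w / w.sum()


def _phase_at(zt: float) -> str:
    return LIGHTS_ON if (zt % 24.0) < LIGHTS_OFF_ZT else LIGHTS_OFF


def _sleep_fraction(cfg: ScenarioConfig, phase: str, boost: float = 1.0) -> float:
    """Quasi-stationary total-sleep fraction when WAKE episode means are
    divided by ``boost`` (floored at one epoch)."""
    pi = stationary_visit_frequencies(cfg)
    m = _mean_durations_s(cfg, phase).astype(float)
    m[0] = max(cfg.epoch_s, m[0] / boost)
    w = pi * m
    return (w[1] + w[2]) / w.sum()


def rebound_schedule(cfg: ScenarioConfig, event: InterventionEvent) -> dict:
    """Calibrated homeostatic response to a deprivation event.

    Solves (quasi-stationary approximation) for the initial WAKE-shortening
    factor B such that the expected cumulative extra sleep over the
    recovery horizon equals ``recovery_fraction_target`` times the expected
    sleep debt, and returns the expected recovery schedule used by the
    generator's feedback controller:

    ``{"B", "u_h" (hours since deprivation end), "expected_gained_min",
    "expected_debt_min"}``.

    When no target is configured, ``extra_sleep_propensity`` is taken as B.
    """
    rp = cfg.rebound_params
    grid_h = 1.0 / 60.0  # 1-min integration grid
    sd_end_zt = event.zt_onset + event.duration_h

    u_sd = np.arange(0, event.duration_h, grid_h)
    debt_h = sum(
        _sleep_fraction(cfg, _phase_at(event.zt_onset + ui)) * grid_h for ui in u_sd
    )
    if debt_h <= 0:
        raise ValueError("expected sleep debt is zero; nothing to recover")

    u = np.arange(0, rp.recovery_horizon_h, grid_h)
    phases = [_phase_at(sd_end_zt + ui) for ui in u]
    base = np.array([_sleep_fraction(cfg, ph) for ph in phases])

    def extra_curve(B: float) -> np.ndarray:
        b = 1.0 + (B - 1.0) * np.exp(-u / rp.decay_hours)
        boosted = np.array(
            [_sleep_fraction(cfg, ph, bi) for ph, bi in zip(phases, b)]
        )
        return np.cumsum(boosted - base) * grid_h

    def expected_fraction(B: float) -> float:
        return float(extra_curve(B)[-1] / debt_h)

    if rp.recovery_fraction_target is None:
        B = rp.extra_sleep_propensity or 1.0
    else:
        target = rp.recovery_fraction_target
        if expected_fraction(1.0) >= target:
            B = 1.0
        else:
            B_hi = 1e4
            if expected_fraction(B_hi) < target:
                raise ValueError(
                    f"recovery_fraction_target={target} unreachable within "
                    f"the {rp.recovery_horizon_h} h horizon for this "
                    "architecture"
                )
            B = float(
                optimize.brentq(lambda x: expected_fraction(x) - target, 1.0, B_hi)
            )
    return {
        "B": B,
        "u_h": u,
        "expected_gained_min": extra_curve(B) * 60.0,
        "expected_debt_min": debt_h * 60.0,
    }


def solve_rebound_boost(cfg: ScenarioConfig, event: InterventionEvent) -> float:
    """Initial WAKE-shortening factor B after a deprivation event (see
    :func:`rebound_schedule`)."""
    return rebound_schedule(cfg, event)["B"]


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

#: reference scale (minutes) converting schedule error into boost units
_FEEDBACK_REF_MIN = 180.0


def _event_windows(cfg: ScenarioConfig):
    """Forced-state windows, REM-suppression windows, sedation spans and
    deprivation rebounds, in epoch indices / elapsed hours."""
    eph = cfg.epoch_s / 3600.0
    forced, rem_off, sd_events, sedation_h = [], [], [], []
    for ev in cfg.events:
        onset_h = cfg.event_elapsed_h(ev)
        onset_ep = int(round(onset_h / eph))
        if ev.kind == "sleep_deprivation":
            end_ep = min(cfg.n_epochs, onset_ep + int(round(ev.duration_h / eph)))
            forced.append((onset_ep, end_ep, WAKE))
            sched = rebound_schedule(cfg, ev)
            sd_events.append((onset_h, onset_h + ev.duration_h, sched["B"]))
        else:
            dr = cfg.temperature_params.drug_response
            sed_h = ev.duration_h if dr is None else min(ev.duration_h, dr.sedation_min / 60.0)
            end_ep = min(cfg.n_epochs, onset_ep + int(round(sed_h / eph)))
            if ev.forced_state is not None:
                forced.append((onset_ep, end_ep, ev.forced_state))
                sedation_h.append((onset_h, onset_h + sed_h))
            if ev.rem_suppressed:
                horizon_ep = min(
                    cfg.n_epochs, onset_ep + int(round(ev.duration_h / eph))
                )
                rem_off.append((onset_ep, horizon_ep))
    forced.sort()
    return forced, rem_off, sd_events, sedation_h


def _build_controller(cfg: ScenarioConfig, sd_events, sedation_h) -> dict:
    """Standing homeostat: the cumulative expected-sleep schedule (minutes)
    on a 1-min grid over the whole recording.

    The schedule is the quasi-stationary sleep propensity per phase, zeroed
    during enforced wakefulness and drug sedation (the drug-induced
    NREM-like state is non-restorative and earns no sleep credit), and
    boosted along the calibrated open-loop recovery profile after each
    deprivation.  The generator's feedback steers realized sleep toward
    this schedule.
    """
    grid_h = 1.0 / 60.0
    grid = np.arange(0.0, cfg.days * 24.0 + grid_h / 2, grid_h)
    zt = (cfg.zt_start + grid) % 24.0
    f_on = _sleep_fraction(cfg, LIGHTS_ON)
    f_off = _sleep_fraction(cfg, LIGHTS_OFF)
    f = np.where(zt < LIGHTS_OFF_ZT, f_on, f_off)
    tau = cfg.rebound_params.decay_hours
    for start_h, end_h, B in sd_events:
        f[(grid >= start_h) & (grid < end_h)] = 0.0
        rec = grid >= end_h
        if B > 1.0 and rec.any():
            b_open = 1.0 + (B - 1.0) * np.exp(-(grid[rec] - end_h) / tau)
            phases = np.where(zt[rec] < LIGHTS_OFF_ZT, LIGHTS_ON, LIGHTS_OFF)
            f[rec] = [
                _sleep_fraction(cfg, ph, bi) for ph, bi in zip(phases, b_open)
            ]
    for start_h, end_h in sedation_h:
        f[(grid >= start_h) & (grid < end_h)] = 0.0
    cum_min = np.concatenate(([0.0], np.cumsum(f[:-1]) * grid_h * 60.0))
    return {
        "grid_h": grid,
        "cum_min": cum_min,
        "open": [(end_h, B) for _, end_h, B in sd_events],
        "sedation_h": sedation_h,
        "realized_min": 0.0,
    }


def _boost_at(elapsed_h: float, ctrl: dict, rp) -> float:
    """Closed-loop WAKE-shortening factor: open-loop rebound decay plus a
    two-sided feedback on the gap between scheduled and realized sleep
    (behind schedule -> shorter wake bouts; ahead -> sleep satiety)."""
    open_loop = 1.0
    for end_h, B in ctrl["open"]:
        if elapsed_h >= end_h:
            open_loop += (B - 1.0) * math.exp(-(elapsed_h - end_h) / rp.decay_hours)
    scheduled = float(np.interp(elapsed_h, ctrl["grid_h"], ctrl["cum_min"]))
    err = (scheduled - ctrl["realized_min"]) / _FEEDBACK_REF_MIN
    return max(0.25, open_loop + rp.feedback_gain * err)


def _track_sleep(ctrl: dict, cfg, t_ep: int, end_ep: int, state: str) -> None:
    """Accrue realized restorative-sleep minutes (drug sedation excluded)."""
    if state not in (NREM, REM):
        return
    eph = cfg.epoch_s / 3600.0
    lo_h, hi_h = t_ep * eph, end_ep * eph
    for s, e in ctrl["sedation_h"]:
        overlap = max(0.0, min(hi_h, e) - max(lo_h, s))
        hi_h -= overlap
    ctrl["realized_min"] += max(0.0, hi_h - lo_h) * 60.0


def simulate_hypnogram(
    cfg: ScenarioConfig,
) -> tuple[Hypnogram, list[Episode]]:
    """Draw a hypnogram from the configured semi-Markov architecture.

    Episode lengths are geometric in epochs with mean
    ``mean_episode_duration_s / epoch_s`` (phase of the episode onset);
    successors are drawn from the transition weights.  Deprivation events
    overwrite with WAKE; afterwards WAKE episode means are divided by an
    exponentially decaying boost calibrated to the configured recovery
    target.  Drug events force their NREM-like state for the sedation span
    and suppress REM for their whole horizon.

    Returns the hypnogram and its ground-truth episode list.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n_total = cfg.n_epochs
    eph = cfg.epoch_s / 3600.0
    forced, rem_off, sd_events, sedation_h = _event_windows(cfg)
    ctrl = _build_controller(cfg, sd_events, sedation_h)
    P = transition_matrix(cfg)

    states = np.empty(n_total, dtype=object)
    idx = {s: i for i, s in enumerate(STATES)}

    def forced_window_at(t: int):
        for s, e, st in forced:
            if s <= t < e:
                return e, st
        return None

    def next_forced_start(t: int) -> int:
        starts = [s for s, _, _ in forced if s > t]
        return min(starts) if starts else n_total

    def rem_suppressed_at(t: int) -> bool:
        return any(s <= t < e for s, e in rem_off)

    t = 0
    state = WAKE
    while t < n_total:
        elapsed = t * eph
        phase = _phase_at(cfg.zt_start + elapsed)
        win = forced_window_at(t)
        if win is not None:
            end, forced_state = win
            states[t:end] = forced_state
            _track_sleep(ctrl, cfg, t, end, forced_state)
            t = end
            state = forced_state
            continue
        m = cfg.state_params[state].mean_episode_duration_s[phase]
        if state == WAKE:
            m = max(cfg.epoch_s, m / _boost_at(elapsed, ctrl, cfg.rebound_params))
        n = int(rng.geometric(cfg.epoch_s / m))
        end = min(t + n, n_total, next_forced_start(t))
        states[t:end] = state
        _track_sleep(ctrl, cfg, t, end, state)
        t = end
        nxt = STATES[rng.choice(3, p=P[idx[state]])]
        if nxt == REM and rem_suppressed_at(t):
            nxt = NREM
        state = nxt

    hyp = Hypnogram(states, epoch_s=cfg.epoch_s, zt_start=cfg.zt_start)
    return hyp, episodes(hyp)


# ---------------------------------------------------------------------------
# EEG / EMG signals
# ---------------------------------------------------------------------------

#: biphasic decay of the evoked delta surge: a fast distribution-phase
#: component (the sharp decline right after the peak) and the slow tail
#: whose scale is the configurable ``delta_decay_min``
_DRUG_FAST_DECAY_FRAC = 0.3
_DRUG_FAST_DECAY_MIN = 18.0


def _drug_delta_envelope(dr, minutes: np.ndarray) -> np.ndarray:
    """Evoked NREM-like delta *power* ratio (vs natural NREM) at ``minutes``
    after injection: normalized rise times biphasic decay with its maximum
    of ``delta_peak_ratio`` exactly at ``delta_peak_min``."""
    m = dr.delta_peak_min
    a, tf, td = _DRUG_FAST_DECAY_FRAC, _DRUG_FAST_DECAY_MIN, dr.delta_decay_min

    def decay(t):
        return a * np.exp(-t / tf) + (1 - a) * np.exp(-t / td)

    # rise constant solved so argmax of (1 - e^(-t/tr)) * decay(t) is at m:
    # x e^-x / (1 - e^-x) = -m decay'(m)/decay(m), with x = m/tr
    g = float(decay(m))
    dg = -a / tf * math.exp(-m / tf) - (1 - a) / td * math.exp(-m / td)
    rhs = -m * dg / g
    if not 0 < rhs < 1:
        raise ValueError("delta envelope peak time incompatible with decay scales")
    x = optimize.brentq(
        lambda x: x * math.exp(-x) - rhs * (-math.expm1(-x)), 1e-9, 200.0
    )
    tr = m / x
    t = np.asarray(minutes, dtype=float)
    s = -np.expm1(-t / tr) * decay(t)
    return dr.delta_peak_ratio * s / (-math.expm1(-x) * g)


def _synth_band_noise(
    rng, n_ep: int, spe: int, fs: float, band: tuple[float, float], power: np.ndarray
) -> np.ndarray:
    """Per-epoch band-limited Gaussian noise with *exact* epoch power.

    Epochs are synthesized on the epoch's Fourier grid: complex-normal
    coefficients on the bins inside ``band``, rescaled so each epoch's
    variance equals ``power[epoch]`` exactly, then inverse-transformed.
    """
    freqs = np.fft.rfftfreq(spe, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1]) & (freqs > 0)
    nb = int(mask.sum())
    if nb == 0:
        raise ValueError(f"band {band} contains no epoch-grid bins")
    g = rng.standard_normal((n_ep, nb)) + 1j * rng.standard_normal((n_ep, nb))
    scale = np.sqrt(power * spe ** 2 / (2.0 * (np.abs(g) ** 2).sum(axis=1)))
    spec = np.zeros((n_ep, spe // 2 + 1), dtype=complex)
    spec[:, mask] = g * scale[:, None]
    return np.fft.irfft(spec, n=spe, axis=1)


def simulate_signals(
    hyp: Hypnogram, cfg: ScenarioConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render EEG and EMG traces (uV, ``cfg.fs_hz`` samples/s) for ``hyp``.

    Per epoch the EEG is the sum of delta-, theta- and broadband-limited
    noise components, each rescaled so its epoch power equals the state's
    band weight times the state's total power (``eeg_amplitude**2``).
    Post-deprivation NREM epochs carry a decaying delta power gain; drug
    events impose the evoked delta envelope, suppress the non-delta
    components with the concurrent temperature deficit, and are followed by
    a decaying rebound delta gain.  EMG is white noise at the state's RMS.
    """
    if abs(len(hyp) * hyp.epoch_s - cfg.n_epochs * cfg.epoch_s) > 1e-9 and len(hyp) != cfg.n_epochs:
        raise ValueError("hypnogram and config disagree on recording length")
    fs = cfg.fs_hz
    spe = int(round(cfg.epoch_s * fs))
    n_ep = len(hyp)
    n = n_ep * spe
    rng = np.random.default_rng([cfg.seed, 1])
    codes = hyp.codes
    elapsed_h = hyp.elapsed_h

    # per-epoch target power per band
    amp2 = np.array([cfg.state_params[s].eeg_amplitude ** 2 for s in STATES])
    weights = {
        b: np.array([cfg.state_params[s].eeg_band_weights[b] for s in STATES])
        for b in SYNTH_BANDS
    }
    wsum = sum(weights.values())
    target = {b: (weights[b] / wsum)[codes] * amp2[codes] for b in SYNTH_BANDS}

    nrem_mask = hyp.states == NREM
    # post-deprivation delta gain (power), decaying from delta_gain_post_sd
    rp = cfg.rebound_params
    for ev in cfg.events:
        if ev.kind != "sleep_deprivation" or rp.delta_gain_post_sd == 1.0:
            continue
        end_h = cfg.event_elapsed_h(ev) + ev.duration_h
        u = elapsed_h - end_h
        mask = nrem_mask & (u >= 0)
        target["delta"][mask] *= 1.0 + (rp.delta_gain_post_sd - 1.0) * np.exp(
            -u[mask] / rp.decay_hours
        )

    # drug events: evoked delta envelope, hypothermic suppression, rebound
    for ev in cfg.events:
        if ev.kind != "drug":
            continue
        dr = cfg.temperature_params.drug_response
        onset_h = cfg.event_elapsed_h(ev)
        if dr is not None:
            sed_h = min(ev.duration_h, dr.sedation_min / 60.0)
            u_min = (elapsed_h - onset_h) * 60.0
            sed = (u_min >= 0) & (u_min < sed_h * 60.0)
            if sed.any():
                nrem_delta = (weights["delta"] / wsum)[1] * amp2[1]
                target["delta"][sed] = nrem_delta * _drug_delta_envelope(
                    dr, u_min[sed]
                )
                # broadband/theta decline with the temperature deficit
                t_env = temperature_envelope(cfg, elapsed_h[sed])
                a = np.maximum(0.3, 1.0 + (t_env - 37.0) / 12.0)
                for b in ("theta", "broadband"):
                    target[b][sed] *= a ** 2
            reb = nrem_mask & (elapsed_h >= onset_h + sed_h)
            if dr.rebound_delta_gain != 1.0 and reb.any():
                u = elapsed_h[reb] - (onset_h + sed_h)
                target["delta"][reb] *= 1.0 + (dr.rebound_delta_gain - 1.0) * np.exp(
                    -u / dr.rebound_decay_h
                )

    eeg = np.zeros((n_ep, spe))
    for b, band in SYNTH_BANDS.items():
        lo, hi = band[0], min(band[1], 0.98 * fs / 2)
        eeg += _synth_band_noise(rng, n_ep, spe, fs, (lo, hi), target[b])
    eeg = eeg.ravel()

    emg_level = np.array([cfg.state_params[s].emg_rms_level for s in STATES])
    emg = rng.standard_normal(n) * np.repeat(emg_level[codes], spe)
    return eeg, emg


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

def _diurnal_baseline(cfg: ScenarioConfig, zt: np.ndarray) -> np.ndarray:
    tp = cfg.temperature_params
    zt = np.asarray(zt) % 24.0
    base = np.where(
        zt < LIGHTS_OFF_ZT, tp.mean_c[LIGHTS_ON], tp.mean_c[LIGHTS_OFF]
    ).astype(float)
    base += tp.diurnal_amplitude_c * np.sin(2 * np.pi * (zt - 12.0) / 24.0)
    # transient spike at the lights-off -> lights-on transition (ZT24)
    if tp.zt24_spike_c:
        half_h = tp.zt24_spike_window_min / 120.0
        dist = np.minimum(zt, 24.0 - zt)
        base = base + tp.zt24_spike_c * (dist <= half_h)
    return base


def temperature_envelope(cfg: ScenarioConfig, elapsed_h: np.ndarray) -> np.ndarray:
    """Noise-free temperature at ``elapsed_h`` hours from recording start:
    diurnal baseline plus any drug-induced hypothermia envelope."""
    elapsed_h = np.atleast_1d(np.asarray(elapsed_h, dtype=float))
    zt = (cfg.zt_start + elapsed_h) % 24.0
    temp = _diurnal_baseline(cfg, zt)
    dr = cfg.temperature_params.drug_response
    for ev in cfg.events:
        if ev.kind != "drug" or dr is None:
            continue
        onset = cfg.event_elapsed_h(ev)
        u = elapsed_h - onset
        in_ev = (u >= 0) & (u <= ev.duration_h)
        if not in_ev.any():
            continue
        t_pre = float(
            _diurnal_baseline(cfg, np.array([(cfg.zt_start + onset) % 24.0]))[0]
        )
        t2n = dr.time_to_nadir_min / 60.0
        uu = u[in_ev]
        descent = t_pre + (dr.nadir_c - t_pre) * (-np.expm1(-3 * uu / t2n)) / (
            -math.expm1(-3.0)
        )
        recovery = dr.nadir_c + dr.recovery_rate_c_per_h * (uu - t2n)
        env = np.where(uu <= t2n, descent, np.minimum(recovery, temp[in_ev]))
        temp[in_ev] = np.minimum(temp[in_ev], env)
    return temp


def simulate_temperature(
    hyp: Hypnogram, cfg: ScenarioConfig, cadence_min: float = 2.0
) -> TemperatureSeries:
    """Core-body-temperature series at a 2-min cadence over the span of
    ``hyp``: diurnal baseline + drug response + Gaussian noise."""
    rng = np.random.default_rng([cfg.seed, 2])
    step_h = cadence_min / 60.0
    elapsed = np.arange(0.0, hyp.duration_h, step_h)
    temp = temperature_envelope(cfg, elapsed)
    if cfg.temperature_params.noise_sd_c > 0:
        temp = temp + rng.normal(0, cfg.temperature_params.noise_sd_c, temp.shape)
    return TemperatureSeries(elapsed_h=elapsed, temp_c=temp, zt_start=cfg.zt_start)
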