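"""Generator contracts: forced events, determinism, stationary structure,
exact band powers, temperature envelopes."""

import numpy as np
import pytest

from murisleep import load_preset, add_sleep_deprivation
from murisleep.config import NREM, REM, STATES, WAKE, ScenarioConfig
from murisleep import synth, thermo


def _embedded_stationary(cfg):
    """Independent oracle: stationary distribution of the embedded chain by
    brute-force power iteration on the normalized weight matrix."""
    P = np.zeros((3, 3))
    for i, s in enumerate(STATES):
        w = cfg.state_params[s].transition_weights
        for j, s2 in enumerate(STATES):
            P[i, j] = w.get(s2, 0.0)
        P[i] /= P[i].sum()
    pi = np.full(3, 1 / 3)
    for _ in range(10_000):
        pi = pi @ P
    return pi / pi.sum()


def test_deprivation_window_is_all_wake():
    cfg = add_sleep_deprivation(load_preset("control_gfp", seed=2))
    hyp, _ = synth.simulate_hypnogram(cfg)
    window = hyp.zt < 5.0
    assert (hyp.states[window] == WAKE).all()
    assert hyp.is_sleep()[window].sum() == 0


def test_seed_determinism_of_all_simulators():
    cfg = load_preset("control_dex", seed=9)
    h1, e1 = synth.simulate_hypnogram(cfg)
    h2, e2 = synth.simulate_hypnogram(cfg)
    assert (h1.states == h2.states).all()
    assert e1 == e2
    s1 = synth.simulate_signals(h1, cfg)
    s2 = synth.simulate_signals(h2, cfg)
    assert np.array_equal(s1[0], s2[0]) and np.array_equal(s1[1], s2[1])
    t1 = synth.simulate_temperature(h1, cfg)
    t2 = synth.simulate_temperature(h2, cfg)
    assert np.array_equal(t1.temp_c, t2.temp_c)
    # a different seed changes the draw
    h3, _ = synth.simulate_hypnogram(load_preset("control_dex", seed=10))
    assert not (h1.states == h3.states).all()


def test_stationary_state_fractions_match_oracle():
    """10 simulated days: per-state time fractions within 3 SE of the
    semi-Markov stationary fractions (visit frequencies x mean durations)."""
    cfg = load_preset("control_gfp", seed=11, days=10.0)
    hyp, _ = synth.simulate_hypnogram(cfg)
    pi = _embedded_stationary(cfg)
    for phase, mask in (("lights_on", hyp.lights_on), ("lights_off", ~hyp.lights_on)):
        m = np.array(
            [cfg.state_params[s].mean_episode_duration_s[phase] for s in STATES]
        )
        expected = pi * m / (pi * m).sum()
        # SE from day-to-day scatter of the daily fractions
        day = np.floor(hyp.elapsed_h / 24.0).astype(int)
        for i, s in enumerate(STATES):
            daily = np.array(
                [
                    (hyp.states[(day == d) & mask] == s).mean()
                    for d in range(10)
                ]
            )
            se = daily.std(ddof=1) / np.sqrt(10)
            assert abs(daily.mean() - expected[i]) < 3 * max(se, 1e-3), (phase, s)


def test_mean_episode_durations_recover_configured_means():
    cfg = load_preset("control_gfp", seed=13, days=10.0)
    hyp, eps = synth.simulate_hypnogram(cfg)
    for s in STATES:
        durs = np.array(
            [
                e.n_epochs * cfg.epoch_s
                for e in eps
                if e.state == s and hyp.lights_on[e.start_epoch]
                and hyp.lights_on[min(e.start_epoch + e.n_epochs, len(hyp)) - 1]
            ]
        )
        m = cfg.state_params[s].mean_episode_duration_s["lights_on"]
        se = durs.std(ddof=1) / np.sqrt(len(durs))
        assert abs(durs.mean() - m) < 3 * se + 0.05 * m, s


def test_wake_never_transitions_directly_to_rem():
    cfg = load_preset("control_gfp", seed=17, days=3.0)
    hyp, _ = synth.simulate_hypnogram(cfg)
    pairs = set(zip(hyp.states[:-1], hyp.states[1:]))
    assert (WAKE, REM) not in pairs


def test_rem_suppressed_during_drug_event():
    cfg = load_preset("control_dex", seed=3)
    hyp, _ = synth.simulate_hypnogram(cfg)
    ev = cfg.events[0]
    onset = cfg.event_elapsed_h(ev)
    in_event = (hyp.elapsed_h >= onset) & (hyp.elapsed_h < onset + ev.duration_h)
    assert (hyp.states[in_event] != REM).all()
    # sedation span is the forced NREM-like state
    sed_h = cfg.temperature_params.drug_response.sedation_min / 60.0
    sed = (hyp.elapsed_h >= onset) & (hyp.elapsed_h < onset + sed_h)
    assert (hyp.states[sed] == NREM).all()


def test_epoch_band_powers_are_exact_by_construction():
    """Fourier-domain synthesis: per-epoch band powers equal their targets
    (rectangle-rule integration oracle on the plain epoch periodogram)."""
    cfg = load_preset("control_gfp", seed=21, days=1.0 / 24.0)
    hyp, _ = synth.simulate_hypnogram(cfg)
    eeg, _ = synth.simulate_signals(hyp, cfg)
    spe = int(cfg.epoch_s * cfg.fs_hz)
    x = eeg.reshape(len(hyp), spe)
    freqs = np.fft.rfftfreq(spe, 1 / cfg.fs_hz)
    power = np.abs(np.fft.rfft(x, axis=1)) ** 2 * 2 / spe ** 2
    delta_mask = (freqs >= 0.5) & (freqs < 4.0)
    for s in STATES:
        rows = hyp.states == s
        if rows.sum() < 10:
            continue
        sp = cfg.state_params[s]
        total = sp.eeg_amplitude ** 2
        wsum = sum(sp.eeg_band_weights.values())
        delta = power[rows][:, delta_mask].sum(axis=1).mean()
        target = sp.eeg_band_weights["delta"] / wsum * total
        # the delta band additionally receives the broadband component's
        # share; epoch-to-epoch cross-terms between overlapping components
        # average out over epochs
        bb = sp.eeg_band_weights["broadband"] / wsum * total
        assert delta == pytest.approx(target + bb * 3.5 / 79.5, rel=0.05)
        assert x[rows].var(axis=1).mean() == pytest.approx(total, rel=0.05)


def test_nrem_delta_exceeds_theta_and_emg_rms_matches():
    cfg = load_preset("control_gfp", seed=23, days=1.0 / 24.0)
    hyp, _ = synth.simulate_hypnogram(cfg)
    eeg, emg = synth.simulate_signals(hyp, cfg)
    spe = int(cfg.epoch_s * cfg.fs_hz)
    freqs = np.fft.rfftfreq(spe, 1 / cfg.fs_hz)
    nrem = np.flatnonzero(hyp.states == NREM)
    ep = eeg.reshape(len(hyp), spe)[nrem[0]]
    p = np.abs(np.fft.rfft(ep)) ** 2
    assert p[(freqs >= 0.5) & (freqs < 4)].sum() > p[(freqs >= 6) & (freqs < 10)].sum()
    wake = np.flatnonzero(hyp.states == WAKE)
    rms = np.sqrt((emg.reshape(len(hyp), spe)[wake] ** 2).mean(axis=1))
    level = cfg.state_params[WAKE].emg_rms_level
    assert np.all(np.abs(rms - level) < 0.10 * level)


def _flat_temp_config(preset="control_gfp", **kw):
    cfg = load_preset(preset, **kw)
    d = cfg.model_dump()
    d["temperature_params"]["noise_sd_c"] = 0.0
    d["temperature_params"]["diurnal_amplitude_c"] = 0.0
    return ScenarioConfig.model_validate(d)


def test_temperature_constant_at_phase_means_without_noise():
    cfg = _flat_temp_config(seed=1)
    hyp, _ = synth.simulate_hypnogram(cfg)
    t = synth.simulate_temperature(hyp, cfg)
    on = t.lights_on
    assert np.allclose(t.temp_c[on], 35.0)
    assert np.allclose(t.temp_c[~on], 36.0)


def test_zt24_spike_is_additive():
    cfg = _flat_temp_config(seed=1, days=2.0)
    d = cfg.model_dump()
    d["temperature_params"]["zt24_spike_c"] = 1.0
    cfg = ScenarioConfig.model_validate(d)
    hyp, _ = synth.simulate_hypnogram(cfg)
    t = synth.simulate_temperature(hyp, cfg)
    assert thermo.transition_spike(t) == pytest.approx(1.0, abs=0.05)


def test_drug_temperature_envelope_reaches_nadir():
    cfg = _flat_temp_config("control_dex", seed=1)
    hyp, _ = synth.simulate_hypnogram(cfg)
    t = synth.simulate_temperature(hyp, cfg)
    dr = cfg.temperature_params.drug_response
    assert t.temp_c.min() == pytest.approx(dr.nadir_c, abs=0.05)
    # analytic envelope minimum agrees
    env = synth.temperature_envelope(cfg, t.elapsed_h)
    assert np.array_equal(env, t.temp_c)
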