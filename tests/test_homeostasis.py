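"""Sleep-debt accounting, recovery curves, delta time courses and drug
responses, checked against hand-built hypnograms and generator truth."""

import numpy as np
import pandas as pd
import pytest

from murisleep.config import NREM, REM, WAKE, InterventionEvent
from murisleep.hypnogram import Hypnogram
from murisleep import homeostasis
from murisleep.homeostasis import (
    delta_rebound,
    delta_timecourse,
    drug_delta_response,
    first_hour_delta,
    recovery_curve,
    sleep_debt,
)

EP_H = 720  # 5-s epochs per hour


def day_hypnogram(pattern):
    """Build a 24-h hypnogram from (state, hours) blocks."""
    states = []
    for s, h in pattern:
        states.extend([s] * int(h * EP_H))
    assert len(states) == 24 * EP_H
    return Hypnogram(np.array(states, dtype=object))


def features_for(hyp, delta):
    n = len(hyp)
    delta = np.broadcast_to(np.asarray(delta, float), (n,)).copy()
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "zt_h": hyp.zt,
            "delta": delta,
            "theta": delta * 0.2,
            "theta_delta_ratio": np.full(n, 0.2),
            "emg_rms": np.full(n, 5.0),
            "total_power": delta * 1.8,
        }
    )


BASELINE = day_hypnogram(
    [(WAKE, 2.5), (NREM, 2.5), (WAKE, 2.5), (NREM, 2.5), (WAKE, 2), (NREM, 10), (WAKE, 2)]
)


def test_sleep_debt_examples():
    # all-WAKE during the window vs 150 min of baseline sleep
    base = day_hypnogram([(WAKE, 2.5), (NREM, 2.5), (WAKE, 19)])
    test = day_hypnogram([(WAKE, 24)])
    assert sleep_debt(base, test) == pytest.approx(150.0)
    assert sleep_debt(base, base) == 0.0
    # partial deprivation leaving 30 of 150 min
    test2 = day_hypnogram([(WAKE, 2.5), (NREM, 0.5), (WAKE, 21)])
    assert sleep_debt(base, test2) == pytest.approx(120.0)


def test_sleep_debt_requires_coverage():
    short = Hypnogram(np.array([WAKE] * (2 * EP_H), dtype=object))
    with pytest.raises(ValueError, match="cover"):
        sleep_debt(BASELINE, short)


def test_recovery_zero_when_test_tracks_baseline_after_window():
    test = day_hypnogram([(WAKE, 5), (NREM, 10 - 2.5 - 2.5), (WAKE, 2), (NREM, 10), (WAKE, 2)])
    # identical to baseline after ZT5 except the deprivation window
    base = day_hypnogram([(WAKE, 2.5), (NREM, 2.5), (NREM, 5), (WAKE, 2), (NREM, 10), (WAKE, 2)])
    curve = recovery_curve(base, test, (0.0, 5.0))
    assert curve.fraction[0] == pytest.approx(0.0, abs=1e-9)
    assert curve.fraction_at(19.0) == pytest.approx(0.0, abs=1e-9)
    assert curve.debt_min == pytest.approx(150.0)


def test_recovery_reaches_one_when_debt_repaid():
    # baseline: sleeps ZT0-5 then awake; test: awake ZT0-5 then sleeps 5 h
    base = day_hypnogram([(NREM, 5), (WAKE, 19)])
    test = day_hypnogram([(WAKE, 5), (NREM, 5), (WAKE, 14)])
    curve = recovery_curve(base, test, (0.0, 5.0))
    assert curve.fraction_at(5.0) == pytest.approx(1.0)
    assert curve.fraction_at(19.0) == pytest.approx(1.0)
    assert curve.recovery_rate_min_per_h > 0


def test_recovery_requires_positive_debt():
    with pytest.raises(ValueError, match="nothing to recover"):
        recovery_curve(BASELINE, BASELINE, (0.0, 5.0))


def test_recovery_invariant_to_shared_extra_sleep():
    """Adding identical sleep to baseline and test outside the deprivation
    and recovery windows leaves the curve unchanged."""
    base = day_hypnogram([(NREM, 5), (WAKE, 19)])
    test = day_hypnogram([(WAKE, 5), (NREM, 2.5), (WAKE, 16.5)])
    c1 = recovery_curve(base, test, (0.0, 5.0), horizon_h=10.0)
    # REM also counts as sleep: swap some NREM for REM on both sides
    base2 = day_hypnogram([(NREM, 2.5), (REM, 2.5), (WAKE, 19)])
    test2 = day_hypnogram([(WAKE, 5), (REM, 2.5), (WAKE, 16.5)])
    c2 = recovery_curve(base2, test2, (0.0, 5.0), horizon_h=10.0)
    assert np.allclose(c1.fraction, c2.fraction)


def test_multiday_baseline_folds_to_zt_profile():
    two_day = Hypnogram(
        np.concatenate([BASELINE.states, BASELINE.states]), epoch_s=5.0, zt_start=0.0
    )
    test = day_hypnogram([(WAKE, 24)])
    assert sleep_debt(two_day, test) == sleep_debt(BASELINE, test)


def test_delta_timecourse_ratio_scaling():
    base = BASELINE
    test = BASELINE
    f_base = features_for(base, 1000.0)
    tc = delta_timecourse(f_base, base, f_base, test)
    good = ~tc["low_confidence"]
    assert np.allclose(tc.loc[good, "ratio_pct"], 100.0)
    tc2 = delta_timecourse(f_base, base, features_for(test, 2000.0), test)
    assert np.allclose(tc2.loc[good, "ratio_pct"], 200.0)
    # hours with no NREM are flagged, not invented
    assert tc["low_confidence"].iloc[0]


def test_first_hour_delta_ratio():
    base, test = BASELINE, BASELINE
    f = features_for(base, 1000.0)
    b, t, r = first_hour_delta(f, base, f, test, sd_end_zt=5.0)
    assert r == pytest.approx(1.0)
    _, _, r15 = first_hour_delta(f, base, features_for(test, 1500.0), test, sd_end_zt=5.0)
    assert r15 == pytest.approx(1.5)


def test_post_deprivation_delta_rebound_decays(sd_recordings):
    """End to end on the control preset: first post-deprivation hour shows
    >100% NREM delta vs ZT-matched baseline, decaying afterwards
    (configured decaying delta gain is the oracle)."""
    from scipy import stats

    _, (bh_true, _, _, bfeats, _, bscored), _, (th_true, _, _, tfeats, _, tscored) = (
        sd_recordings
    )
    tc = delta_timecourse(bfeats, bscored, tfeats, tscored)
    good = tc[(tc["elapsed_h"] >= 5.0) & ~tc["low_confidence"]]
    assert good["ratio_pct"].iloc[0] > 100.0
    rho = stats.spearmanr(good["elapsed_h"], good["ratio_pct"]).statistic
    assert rho < 0
    b, t, r = first_hour_delta(bfeats, bscored, tfeats, tscored, sd_end_zt=5.0)
    assert 1.1 < r < 1.8  # configured initial power gain 1.5


DRUG = InterventionEvent(
    kind="drug", zt_onset=6.0, duration_h=5.0, forced_state=NREM, rem_suppressed=True
)


def test_drug_delta_response_null_and_envelope():
    base = BASELINE
    f = features_for(base, 1000.0)
    resp = drug_delta_response(f, base, DRUG, f, base)
    assert resp.peak_ratio == pytest.approx(1.0)

    # deterministic envelope with maximum at 11 min: argmax recovered exactly
    test = day_hypnogram([(WAKE, 6), (NREM, 6), (WAKE, 12)])
    u = (test.elapsed_h - 6.0) * 60.0
    env = np.where((u >= 0) & (u < 360), 1000 * (1 + np.exp(-((u - 11.0) ** 2) / 50.0)), 1000.0)
    resp = drug_delta_response(features_for(test, env), test, DRUG, f, base)
    assert resp.peak_time_min == pytest.approx(11.0, abs=0.5)


def test_delta_rebound_scaling():
    base = BASELINE
    test = day_hypnogram([(WAKE, 6), (NREM, 12), (WAKE, 6)])
    f_base = features_for(base, 1000.0)
    assert delta_rebound(f_base, test, DRUG, f_base, base) == pytest.approx(100.0)
    assert delta_rebound(
        features_for(test, 2000.0), test, DRUG, f_base, base
    ) == pytest.approx(200.0)


def test_delta_rebound_requires_nrem():
    awake = day_hypnogram([(WAKE, 24)])
    f = features_for(awake, 1000.0)
    with pytest.raises(ValueError, match="insufficient NREM"):
        delta_rebound(f, awake, DRUG, features_for(BASELINE, 1000.0), BASELINE)
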