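"""Filter contracts, PSD normalization (Parseval), band-power algebra and
feature assembly."""

import numpy as np
import pytest

from murisleep import spectral
from murisleep.spectral import (
    SpectralSeries,
    band_power,
    bandpass_emg,
    compute_psd,
    epoch_features,
    highpass_eeg,
)

FS = 200.0


def sine(freq, seconds=30.0, amp=1.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def butter4_net_gain(f, fc, kind):
    """Analytic oracle: squared-magnitude response of a 4th-order
    Butterworth applied forward-backward, |H|^2 with |H|^2 = 1/(1+x^8)."""
    x = (fc / f) if kind == "highpass" else (f / fc)
    single = 1.0 / (1.0 + x ** 8)
    return single ** 2  # power gain of one pass, applied twice -> amplitude**2 per pass


@pytest.mark.parametrize(
    "filt,freq,expect",
    [
        (highpass_eeg, 10.0, "pass"),
        (highpass_eeg, 0.05, "stop"),
        (bandpass_emg, 20.0, "pass"),
        (bandpass_emg, 60.0, "stop"),
        (bandpass_emg, 1.0, "stop"),
    ],
)
def test_filter_pass_and_stop_bands(filt, freq, expect):
    x = sine(freq, seconds=120.0)
    y = filt(x, FS)
    mid = slice(len(x) // 4, 3 * len(x) // 4)  # avoid edge transients
    amp = np.abs(y[mid]).max()
    if expect == "pass":
        assert amp == pytest.approx(1.0, rel=0.05)
    else:
        assert amp < (0.2 if freq < 1 else 0.5)


def test_highpass_stopband_matches_analytic_butterworth():
    """The net zero-phase response follows the squared 4th-order
    Butterworth magnitude (corner pre-warped to -3 dB at 0.5 Hz)."""
    fc = 0.5 * (np.sqrt(2.0) - 1.0) ** (1.0 / 8.0)
    for f in (0.2, 0.35, 0.5):
        x = sine(f, seconds=600.0)
        y = highpass_eeg(x, FS)
        mid = slice(len(x) // 3, 2 * len(x) // 3)
        measured = (np.abs(y[mid]).max()) ** 2
        # net amplitude gain is the single-pass power gain (applied twice)
        expected = butter4_net_gain(f, fc, "highpass")
        assert measured == pytest.approx(expected, rel=0.15), f


def test_corner_attenuation_is_3db():
    for filt, f in [(highpass_eeg, 0.5), (bandpass_emg, 5.0), (bandpass_emg, 45.0)]:
        x = sine(f, seconds=600.0)
        y = filt(x, FS)
        mid = slice(len(x) // 3, 2 * len(x) // 3)
        db = 20 * np.log10(np.abs(y[mid]).max())
        assert db == pytest.approx(-3.0, abs=0.5), (filt.__name__, f)


def test_dc_input_killed_by_highpass():
    y = highpass_eeg(np.full(4000, 3.0), FS)
    assert np.abs(y[1000:-1000]).max() < 1e-6


def test_too_short_trace_raises():
    with pytest.raises(ValueError, match="warm-up"):
        highpass_eeg(np.ones(10), FS)
    with pytest.raises(ValueError):
        highpass_eeg(np.array([1.0, np.nan, 2.0] * 100), FS)


def test_psd_bin_width_and_sine_concentration():
    spec = compute_psd(sine(2.0, seconds=5.0))
    assert spec.df_hz == pytest.approx(200 / 512)
    k = int(np.argmin(np.abs(spec.freqs - 2.0)))
    total = spec.psd[0].sum()
    # Hann leakage spreads a non-bin-centered tone into adjacent bins
    assert spec.psd[0][k - 1 : k + 2].sum() / total > 0.90
    assert spec.psd[0][k] == spec.psd[0].max()


def test_psd_flat_for_white_noise(rng):
    x = rng.standard_normal(int(10_000 * FS * 5 / 5))  # 10k epochs worth? keep 2k
    x = x[: 2000 * 1000]
    spec = compute_psd(x)
    mean_psd = spec.psd.mean(axis=0)
    band = (spec.freqs >= 1.0) & (spec.freqs <= 90.0)
    assert mean_psd[band].max() / mean_psd[band].min() < 1.5


def test_parseval_identity_and_variance_agreement(rng):
    # deterministic multi-tone epoch: integrated PSD within 5% of variance
    x = sine(3.0, 5.0) + 0.5 * sine(11.0, 5.0) + 0.2 * sine(37.0, 5.0)
    spec = compute_psd(x)
    assert spec.psd[0].sum() * spec.df_hz == pytest.approx(x.var(), rel=0.05)
    # white noise: exact identity against the Hann-weighted mean square
    y = rng.standard_normal(50 * 1000)
    spec = compute_psd(y)
    win = np.asarray(np.hanning(513)[:512])  # periodic Hann, as used internally
    seg = y.reshape(50, 1000)
    wms = 0.5 * (
        ((seg[:, :512] * win) ** 2).sum(axis=1) + ((seg[:, 488:] * win) ** 2).sum(axis=1)
    ) / (win ** 2).sum()
    assert np.allclose(spec.psd.sum(axis=1) * spec.df_hz, wms, rtol=1e-9)
    # and the epoch-averaged estimate matches plain variance within 5%
    assert spec.psd.sum(axis=1).mean() * spec.df_hz == pytest.approx(
        y.var(), rel=0.05
    )


def test_band_power_partition_additivity(rng):
    spec = compute_psd(rng.standard_normal(10 * 1000))
    total = band_power(spec, 0.0, 100.0)
    parts = (
        band_power(spec, 0.0, 0.5)
        + band_power(spec, 0.5, 4.0)
        + band_power(spec, 4.0, 100.0)
    )
    assert np.allclose(parts, total, rtol=1e-12)


def test_band_power_rejects_bad_bands(rng):
    spec = compute_psd(rng.standard_normal(1000))
    with pytest.raises(ValueError):
        band_power(spec, 4.0, 0.5)
    with pytest.raises(ValueError, match="no frequency bins"):
        band_power(spec, 0.01, 0.1)


def test_white_noise_delta_fraction_matches_flat_psd(rng):
    """Flat-PSD oracle: delta share of 0-100 Hz equals the delta bins'
    bandwidth share, ~3.5/100."""
    spec = compute_psd(rng.standard_normal(2000 * 1000))
    delta = band_power(spec, 0.5, 4.0).mean()
    total = band_power(spec, 0.0, 100.0).mean()
    n_delta_bins = ((spec.freqs >= 0.5) & (spec.freqs < 4.0)).sum()
    assert n_delta_bins == 9
    assert delta / total == pytest.approx(9 * spec.df_hz / 100.0, rel=0.03)
    assert delta / total == pytest.approx(3.5 / 100.0, rel=0.05)


def test_sine_delta_band_dominates():
    spec = compute_psd(sine(2.0, 5.0))
    assert band_power(spec, 0.5, 4.0)[0] / band_power(spec, 0.0, 100.0)[0] > 0.90


def test_epoch_features_constants_and_ratio():
    # constant EMG (filter-bypass mode): RMS equals the constant
    eeg = sine(8.0, seconds=10.0)
    emg = np.full_like(eeg, 2.5)
    feats = epoch_features(eeg, emg)
    assert np.allclose(feats["emg_rms"], 2.5)
    # pure 8 Hz EEG: theta dominated
    assert (feats["theta_delta_ratio"] > 5).all()
    assert len(feats) == 2


def test_epoch_features_scaling_and_shift(rng):
    x = rng.standard_normal(10 * 1000)
    m = rng.standard_normal(10 * 1000)
    f1 = epoch_features(x, m)
    f2 = epoch_features(3.0 * x, -2.0 * m)
    assert np.allclose(f2["delta"], 9.0 * f1["delta"])
    assert np.allclose(f2["total_power"], 9.0 * f1["total_power"])
    assert np.allclose(f2["emg_rms"], 2.0 * f1["emg_rms"])
    assert np.allclose(f2["theta_delta_ratio"], f1["theta_delta_ratio"])
    # shifting by whole epochs shifts features correspondingly
    f3 = epoch_features(np.roll(x, 2 * 1000), np.roll(m, 2 * 1000))
    assert np.allclose(
        f3["delta"].to_numpy()[2:], f1["delta"].to_numpy()[:-2]
    )


def test_length_mismatch_rejected(rng):
    with pytest.raises(ValueError, match="differ in length"):
        epoch_features(rng.standard_normal(2000), rng.standard_normal(1000))


def test_nrem_ratio_below_rem_ratio_on_synthetic_epochs(control_recording):
    """Configured band weights are the oracle: NREM epochs must show a lower
    theta:delta ratio than REM epochs."""
    cfg, hyp_true, _, _, feats, _, _ = control_recording
    nrem = feats["theta_delta_ratio"][hyp_true.states == "NREM"]
    rem = feats["theta_delta_ratio"][hyp_true.states == "REM"]
    if len(rem) == 0:
        pytest.skip("no REM epochs drawn in this fixture")
    assert nrem.median() < rem.median()
    assert nrem.quantile(0.99) < rem.quantile(0.01)
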