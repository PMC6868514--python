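"""Per-epoch spectral features from raw EEG/EMG.

The processing chain mirrors standard rodent polysomnography practice:
the EEG is high-pass filtered at 0.5 Hz (-3 dB), the EMG band-pass filtered
5-45 Hz (-3 dB), both with zero-phase 4th-order Butterworth filters; power
spectra use 512-sample FFT windows inside each 5-s (1000-sample at 200 Hz)
epoch, giving a 0.390625 Hz bin width; delta is 0.5-4 Hz, theta 6-10 Hz,
and the EMG is summarized by its RMS per 5-s bin.

Filter corners are pre-warped so that the *net* forward-backward response
is -3 dB at the stated edge frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, signal

logger = logging.getLogger(__name__)

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 10.0)

#: single-pass corner shift so that |H|^4 = 1/2 at the nominal edge for a
#: 4th-order Butterworth applied forward-backward: x = (sqrt(2)-1)^(1/8)
_FILTFILT_CORNER_FACTOR = (np.sqrt(2.0) - 1.0) ** (1.0 / 8.0)


@dataclass
class SpectralSeries:
    """Per-epoch one-sided PSD (uV^2/Hz) over bins of width fs/nfft."""

    psd: np.ndarray  # (n_epochs, n_bins)
    freqs: np.ndarray  # bin centers, Hz

    @property
    def df_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_epochs(self) -> int:
        return self.psd.shape[0]


def _apply_sos(sos: np.ndarray, trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    # default filtfilt padding; shorter traces cannot be filtered cleanly
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(trace) <= padlen:
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than the filter "
            f"warm-up ({padlen} samples)"
        )
    return signal.sosfiltfilt(sos, trace)


def highpass_eeg(trace: np.ndarray, fs: float = 200.0, corner_hz: float = 0.5) -> np.ndarray:
    """Zero-phase 0.5 Hz high-pass (-3 dB at the corner after the
    forward-backward pass)."""
    sos = signal.butter(
        4, corner_hz * _FILTFILT_CORNER_FACTOR, btype="highpass", fs=fs, output="sos"
    )
    return _apply_sos(sos, trace)


@lru_cache(maxsize=8)
def _emg_bandpass_sos(fs: float, lo: float, hi: float):
    """4th-order Butterworth band-pass whose corners are solved numerically
    so the *net* forward-backward response is -3 dB at (lo, hi)."""

    def net_db(lo_d: float, hi_d: float, f: float) -> float:
        sos = signal.butter(4, [lo_d, hi_d], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=np.array([f]), fs=fs)
        return 40.0 * np.log10(np.abs(h[0]))

    lo_d = lo * _FILTFILT_CORNER_FACTOR
    hi_d = hi / _FILTFILT_CORNER_FACTOR
    for _ in range(3):  # edges are weakly coupled; a few sweeps suffice
        lo_d = optimize.brentq(lambda c: net_db(c, hi_d, lo) + 3.0, 0.3 * lo, lo)
        hi_d = optimize.brentq(
            lambda c: net_db(lo_d, c, hi) + 3.0, hi, min(2.0 * hi, 0.99 * fs / 2)
        )
    return signal.butter(4, [lo_d, hi_d], btype="bandpass", fs=fs, output="sos")


def bandpass_emg(
    trace: np.ndarray, fs: float = 200.0, band: tuple[float, float] = (5.0, 45.0)
) -> np.ndarray:
    """Zero-phase 5-45 Hz band-pass (-3 dB corners after the
    forward-backward pass)."""
    return _apply_sos(_emg_bandpass_sos(fs, band[0], band[1]), trace)


def filter_magnitude_db(kind: str, freqs_hz, fs: float = 200.0) -> np.ndarray:
    """Net (forward-backward) magnitude response in dB of the packaged EEG
    high-pass or EMG band-pass at ``freqs_hz`` — the analytic oracle for the
    filter contracts."""
    if kind == "eeg":
        sos = signal.butter(
            4, 0.5 * _FILTFILT_CORNER_FACTOR, btype="highpass", fs=fs, output="sos"
        )
    elif kind == "emg":
        sos = _emg_bandpass_sos(fs, 5.0, 45.0)
    else:
        raise ValueError("kind must be 'eeg' or 'emg'")
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=fs)
    return 40.0 * np.log10(np.abs(h) + 1e-300)  # 2x20: applied twice


def compute_psd(
    trace: np.ndarray,
    fs: float = 200.0,
    epoch_s: float = 5.0,
    fft_size: int = 512,
) -> SpectralSeries:
    """Per-epoch PSD from Hann-tapered ``fft_size``-sample periodograms.

    Each epoch (``epoch_s * fs`` samples) is covered by two segments, at
    offset 0 and flush with the epoch end (0 and 488 for 1000-sample
    epochs), whose one-sided periodograms are averaged.  Normalization is
    the usual density convention: ``sum(psd) * df`` equals the Hann-weighted
    mean square of the segments (Parseval).  A partial trailing epoch is
    dropped with a logged count.
    """
    trace = np.asarray(trace, dtype=float)
    spe = int(round(epoch_s * fs))
    if len(trace) < spe:
        raise ValueError("trace shorter than one epoch")
    n_ep = len(trace) // spe
    dropped = len(trace) - n_ep * spe
    if dropped:
        logger.info("dropping partial trailing epoch (%d samples)", dropped)
    x = trace[: n_ep * spe].reshape(n_ep, spe)

    if fft_size > spe:
        raise ValueError("fft_size larger than the epoch")
    offsets = [0] if fft_size == spe else [0, spe - fft_size]
    win = signal.windows.hann(fft_size, sym=False)
    scale = 2.0 / (fs * (win ** 2).sum())
    n_bins = fft_size // 2 + 1

    psd = np.zeros((n_ep, n_bins))
    for off in offsets:
        seg = x[:, off : off + fft_size] * win
        spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2 * scale
        spec[:, 0] /= 2.0
        spec[:, -1] /= 2.0
        psd += spec
    psd /= len(offsets)
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / fs)
    return SpectralSeries(psd=psd, freqs=freqs)


def band_power(spectrum: SpectralSeries | np.ndarray, lo_hz: float, hi_hz: float,
               freqs: np.ndarray | None = None, df_hz: float | None = None) -> np.ndarray:
    """Integrated power over bins whose centers lie in [lo_hz, hi_hz).

    Contiguous bands therefore partition the spectrum exactly.  Accepts a
    :class:`SpectralSeries` or a raw PSD array plus its bin centers.
    """
    if isinstance(spectrum, SpectralSeries):
        psd, freqs, df = spectrum.psd, spectrum.freqs, spectrum.df_hz
    else:
        if freqs is None:
            raise ValueError("freqs required for raw PSD arrays")
        psd = np.asarray(spectrum)
        df = df_hz if df_hz is not None else float(freqs[1] - freqs[0])
    nyq = freqs[-1]
    if not (0 <= lo_hz < hi_hz <= nyq + 1e-9):
        raise ValueError(f"band [{lo_hz}, {hi_hz}) outside [0, {nyq}]")
    mask = (freqs >= lo_hz) & (freqs < hi_hz)
    if hi_hz >= nyq - 1e-9:
        mask[-1] = True  # a band reaching Nyquist includes the Nyquist bin
    if not mask.any():
        raise ValueError(f"band [{lo_hz}, {hi_hz}) contains no frequency bins")
    return np.asarray(psd)[..., mask].sum(axis=-1) * df


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    zt_start: float = 0.0,
    fs: float = 200.0,
    epoch_s: float = 5.0,
) -> pd.DataFrame:
    """Assemble per-epoch features from *filtered* EEG and EMG traces.

    Returns a DataFrame with columns ``epoch_index, zt_h, delta, theta,
    theta_delta_ratio, emg_rms, total_power``.  The ratio is NaN where
    delta power is exactly zero (flagged, excluded from downstream means).
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if len(eeg) != len(emg):
        raise ValueError("EEG and EMG traces differ in length")
    spec = compute_psd(eeg, fs=fs, epoch_s=epoch_s)
    delta = band_power(spec, *DELTA_BAND)
    theta = band_power(spec, *THETA_BAND)
    total = band_power(spec, 0.0, spec.freqs[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.where(delta > 0, delta, 1.0), np.nan)
    spe = int(round(epoch_s * fs))
    n_ep = spec.n_epochs
    emg_rms = np.sqrt(
        (emg[: n_ep * spe].reshape(n_ep, spe) ** 2).mean(axis=1)
    )
    zt = (zt_start + np.arange(n_ep) * epoch_s / 3600.0) % 24.0
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_ep),
            "zt_h": zt,
            "delta": delta,
            "theta": theta,
            "theta_delta_ratio": ratio,
            "emg_rms": emg_rms,
            "total_power": total,
        }
    )
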