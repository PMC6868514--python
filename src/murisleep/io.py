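"""File I/O and the end-to-end pipeline.

Formats: EDF (16-bit) for raw EEG/EMG, CSV (comma, '.' decimal, UTF-8,
header row) for features, hypnograms, temperature and reports.  Every CSV
carries ``#``-prefixed provenance header lines (tool version, seed, preset).
EDF files are written by a minimal built-in writer and read back through
:mod:`mne`.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .hypnogram import Hypnogram

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CSV with provenance
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path, provenance: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# murisleep {__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trace_csv(trace: np.ndarray, path, fs_hz: float, provenance=None) -> None:
    """Two-column raw-signal CSV: time_s, value_uV."""
    t = np.arange(len(trace)) / fs_hz
    write_csv(
        pd.DataFrame({"time_s": t, "value_uV": trace}),
        path,
        {**(provenance or {}), "fs_hz": fs_hz},
    )


def read_trace_csv(path, expect_fs_hz: Optional[float] = None) -> tuple[np.ndarray, float]:
    df = read_csv(path)
    for col in ("time_s", "value_uV"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} is missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace CSV too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    if expect_fs_hz is not None and abs(fs - expect_fs_hz) > 0.01 * expect_fs_hz:
        raise ValueError(
            f"sampling rate {fs:.3f} Hz does not match expected {expect_fs_hz} Hz"
        )
    return df["value_uV"].to_numpy(dtype=float), fs


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    signals: dict[str, np.ndarray],
    fs_hz: float,
    physical_dim: str = "uV",
    start: Optional[_dt.datetime] = None,
) -> None:
    """Write channels to a 16-bit EDF file (1-s data records).

    The physical range is the per-channel data range, so the quantization
    step is ``range / 65535``.  Traces must share a length that is a whole
    number of seconds.
    """
    fs = int(round(fs_hz))
    if abs(fs - fs_hz) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    labels = list(signals)
    n = {len(v) for v in signals.values()}
    if len(n) != 1:
        raise ValueError("all channels must have the same length")
    n = n.pop()
    if n % fs:
        raise ValueError("trace length must be a whole number of seconds")
    n_rec = n // fs
    ns = len(labels)
    start = start or _dt.datetime(2000, 1, 1)

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field("1", 8),
            _edf_field(ns, 4),
        ]
    )

    pmins, pmaxs, scaled = [], [], []
    for lab in labels:
        x = np.asarray(signals[lab], dtype=float)
        pmin, pmax = float(x.min()), float(x.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        # EDF stores physical limits in 8 ascii chars; round outward
        pmin, pmax = float(f"{pmin:.6g}"[:8]), float(f"{pmax:.6g}"[:8])
        pmin = min(pmin, float(x.min()))
        pmax = max(pmax, float(x.max()))
        dig = np.round(
            (x - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        ).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled.append(dig.reshape(n_rec, fs))

    def sig_fields(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += sig_fields(labels, 16)
    header += sig_fields([""] * ns, 80)
    header += sig_fields([physical_dim] * ns, 8)
    header += sig_fields([f"{p:.6g}"[:8] for p in pmins], 8)
    header += sig_fields([f"{p:.6g}"[:8] for p in pmaxs], 8)
    header += sig_fields([-32768] * ns, 8)
    header += sig_fields([32767] * ns, 8)
    header += sig_fields([""] * ns, 80)
    header += sig_fields([fs] * ns, 8)
    header += sig_fields([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in scaled:
                fh.write(ch[r].tobytes())


def read_edf(path, expect_fs_hz: Optional[float] = None) -> tuple[dict[str, np.ndarray], float]:
    """Read an EDF file via mne; returns channel -> trace (uV) and the
    sampling rate.  Raises on a sampling-rate mismatch (no resampling)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expect_fs_hz is not None and abs(fs - expect_fs_hz) > 1e-6:
        raise ValueError(f"EDF sampling rate {fs} != expected {expect_fs_hz}")
    data = raw.get_data() * 1e6  # mne returns volts for uV channels
    return {name: data[i] for i, name in enumerate(raw.ch_names)}, fs


def read_signals(path, fmt: Optional[str] = None, expect_fs_hz: Optional[float] = None):
    """Load raw traces from EDF or two-column CSV.

    Returns ``(channels: dict[str, array], fs_hz)``; CSV files contribute a
    single channel named after the file stem.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return read_edf(path, expect_fs_hz)
    if fmt == "csv":
        trace, fs = read_trace_csv(path, expect_fs_hz)
        return {path.stem: trace}, fs
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# hypnogram / temperature CSV
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hyp: Hypnogram, path, provenance=None) -> None:
    write_csv(hyp.to_frame(), path, provenance)


def read_hypnogram_csv(path, epoch_s: float = 5.0) -> Hypnogram:
    return Hypnogram.from_frame(read_csv(path), epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: ScenarioConfig | str | Path,
    out_dir,
    preset_name: str = "custom",
    write_raw_edf: bool = False,
) -> Path:
    """simulate -> features -> score -> analyze -> report for one scenario.

    When the scenario contains events, a matched event-free baseline of the
    same scenario (same seed) is simulated and the deprivation/drug
    comparisons are run against it.  Outputs are deterministic given the
    config seed; the run log records preset, seed, thresholds and version.
    """
    from . import architecture, homeostasis, scoring, spectral, synth, thermo

    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"preset": preset_name, "seed": config.seed}
    log: dict = {"preset": preset_name, "seed": config.seed, "version": __version__}

    def process(cfg: ScenarioConfig, tag: str):
        hyp_true, _ = synth.simulate_hypnogram(cfg)
        eeg, emg = synth.simulate_signals(hyp_true, cfg)
        temp = synth.simulate_temperature(hyp_true, cfg)
        feats = spectral.epoch_features(
            spectral.highpass_eeg(eeg, cfg.fs_hz),
            spectral.bandpass_emg(emg, cfg.fs_hz),
            zt_start=cfg.zt_start,
            fs=cfg.fs_hz,
            epoch_s=cfg.epoch_s,
        )
        thr = scoring.calibrate_thresholds(feats)
        hyp = scoring.score_epochs(feats, thr, zt_start=cfg.zt_start)
        write_csv(feats, out / f"features_{tag}.csv", prov)
        write_hypnogram_csv(hyp, out / f"hypnogram_{tag}.csv", prov)
        write_hypnogram_csv(hyp_true, out / f"hypnogram_truth_{tag}.csv", prov)
        write_csv(temp.to_frame(), out / f"temperature_{tag}.csv", prov)
        if write_raw_edf:
            write_edf(out / f"raw_{tag}.edf", {"EEG": eeg, "EMG": emg}, cfg.fs_hz)
        log[f"thresholds_{tag}"] = {
            "emg_wake_threshold": thr.emg_wake_threshold,
            "ratio_rem_threshold": thr.ratio_rem_threshold,
        }
        return hyp, feats, temp

    try:
        hyp, feats, temp = process(config, "test")
        summary: dict = {}

        write_csv(architecture.time_in_state(hyp), out / "time_in_state.csv", prov)
        write_csv(architecture.episode_stats(hyp), out / "episode_stats.csv", prov)
        write_csv(
            architecture.transitions_by_phase(hyp), out / "transitions.csv", prov
        )
        if temp.elapsed_h[-1] - temp.elapsed_h[0] >= 24.0:
            summary["temperature"] = thermo.phase_means(temp)

        if config.events:
            base_cfg = config.model_copy(update={"events": []})
            base_cfg = ScenarioConfig.model_validate(base_cfg.model_dump())
            bhyp, bfeats, btemp = process(base_cfg, "baseline")
            for ev in config.events:
                if ev.kind == "sleep_deprivation":
                    window = (ev.zt_onset, ev.zt_onset + ev.duration_h)
                    curve = homeostasis.recovery_curve(bhyp, hyp, window)
                    write_csv(
                        pd.DataFrame(
                            {"t_h": curve.time_h, "fraction": curve.fraction}
                        ),
                        out / "recovery.csv",
                        prov,
                    )
                    tc = homeostasis.delta_timecourse(bfeats, bhyp, feats, hyp)
                    write_csv(tc, out / "delta_timecourse.csv", prov)
                    summary["sleep_deprivation"] = {
                        "debt_min": curve.debt_min,
                        "recovered_fraction_19h": curve.fraction_at(19.0),
                        "recovery_rate_min_per_h": curve.recovery_rate_min_per_h,
                    }
                elif ev.kind == "drug":
                    resp = homeostasis.drug_delta_response(feats, hyp, ev, bfeats, bhyp)
                    write_csv(
                        pd.DataFrame(
                            {
                                "t_min": resp.time_min,
                                "delta": resp.delta,
                                "ratio": resp.ratio,
                            }
                        ),
                        out / "drug_delta_response.csv",
                        prov,
                    )
                    report = thermo.drug_response(temp, ev)
                    summary["drug"] = {
                        "peak_time_min": resp.peak_time_min,
                        "peak_ratio": resp.peak_ratio,
                        "nadir_c": report.nadir_c,
                        "time_to_nadir_min": report.time_to_nadir_min,
                        "recovery_time_min": report.recovery_time_min,
                    }
                    try:
                        summary["drug"]["rebound_pct_3p5h"] = homeostasis.delta_rebound(
                            feats, hyp, ev, bfeats, bhyp
                        )
                    except ValueError as exc:
                        logger.info("delta rebound unavailable: %s", exc)
    except Exception as exc:  # pragma: no cover - stage naming only
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    log["summary"] = summary
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return out


def directory_checksum(path) -> str:
    """SHA-256 over the sorted file names and contents of a report directory
    (used by determinism checks)."""
    h = hashlib.sha256()
    for p in sorted(Path(path).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
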