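"""Hypnogram container: per-epoch vigilance-state labels anchored to ZT."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .config import LIGHTS_OFF_ZT, NREM, REM, STATES, WAKE

#: integer codes used internally; order fixed for transition matrices
STATE_CODES = {WAKE: 0, NREM: 1, REM: 2}
CODE_STATES = np.array(STATES)


class Episode(NamedTuple):
    state: str
    start_epoch: int
    n_epochs: int


@dataclass
class Hypnogram:
    """Sequence of per-epoch state labels with zeitgeber anchoring.

    Parameters
    ----------
    states : array of str
        One label per epoch, each in {"WAKE", "NREM", "REM"}.
    epoch_s : float
        Epoch length in seconds (5 s throughout this package).
    zt_start : float
        Zeitgeber time (hours, ZT0 = lights on) of the first epoch's onset.
    flagged : bool array, optional
        Epochs excluded from downstream averaging (e.g. missing features).
    """

    states: np.ndarray
    epoch_s: float = 5.0
    zt_start: float = 0.0
    flagged: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels {bad}")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.states), dtype=bool)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def codes(self) -> np.ndarray:
        return np.array([STATE_CODES[s] for s in self.states], dtype=np.int8)

    @property
    def duration_h(self) -> float:
        return len(self) * self.epoch_s / 3600.0

    @property
    def elapsed_h(self) -> np.ndarray:
        """Hours since recording start at each epoch onset."""
        return np.arange(len(self)) * self.epoch_s / 3600.0

    @property
    def zt(self) -> np.ndarray:
        """Zeitgeber time (hours in [0, 24)) at each epoch onset."""
        return (self.zt_start + self.elapsed_h) % 24.0

    @property
    def lights_on(self) -> np.ndarray:
        """True for epochs in the lights-on phase (ZT0-12)."""
        return self.zt < LIGHTS_OFF_ZT

    def window_mask(self, zt_lo: float, zt_hi: float, day: int = 0) -> np.ndarray:
        """Epochs whose onset falls in [zt_lo, zt_hi) on recording-day ``day``
        (day 0 starts at the first epoch; the window is located by ZT)."""
        abs_h = self.zt_start + self.elapsed_h
        lo = zt_lo + 24.0 * day
        lo += 24.0 * np.ceil(max(0.0, (self.zt_start - lo)) / 24.0)
        hi = lo + (zt_hi - zt_lo)
        return (abs_h >= lo) & (abs_h < hi)

    def elapsed_mask(self, lo_h: float, hi_h: float) -> np.ndarray:
        e = self.elapsed_h
        return (e >= lo_h) & (e < hi_h)

    def is_sleep(self) -> np.ndarray:
        return (self.states == NREM) | (self.states == REM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "zt_h": self.zt,
                "state": self.states,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch_s: float = 5.0) -> "Hypnogram":
        zt0 = float(df["zt_h"].iloc[0]) if len(df) else 0.0
        return cls(df["state"].to_numpy(dtype=object), epoch_s=epoch_s, zt_start=zt0)


def episodes(hyp: Hypnogram | Iterable[str]) -> list[Episode]:
    """Maximal runs of identical labels; concatenating them reconstructs the
    hypnogram exactly."""
    states = hyp.states if isinstance(hyp, Hypnogram) else np.asarray(list(hyp), dtype=object)
    if len(states) == 0:
        raise ValueError("empty hypnogram")
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(states)]))
    return [Episode(states[s], int(s), int(e - s)) for s, e in zip(starts, ends)]


def transitions(hyp: Hypnogram | Iterable[str]) -> pd.DataFrame:
    """3x3 matrix of adjacent-epoch state changes (rows: from, cols: to);
    the diagonal is zero and the total equals ``len(episodes) - 1``."""
    states = hyp.states if isinstance(hyp, Hypnogram) else np.asarray(list(hyp), dtype=object)
    if len(states) == 0:
        raise ValueError("empty hypnogram")
    codes = np.array([STATE_CODES[s] for s in states])
    mat = np.zeros((3, 3), dtype=int)
    prev, nxt = codes[:-1], codes[1:]
    mask = prev != nxt
    np.add.at(mat, (prev[mask], nxt[mask]), 1)
    return pd.DataFrame(mat, index=list(STATES), columns=list(STATES))
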