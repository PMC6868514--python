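"""Scenario configuration for synthetic sleep recordings.

A :class:`ScenarioConfig` fully parameterizes one simulated experiment:
the semi-Markov sleep architecture (per-state, per-light-phase episode
durations and transition weights), the state-conditioned EEG/EMG spectra,
interventions (enforced wakefulness, a sedative drug), the homeostatic
rebound that follows them, and the core-body-temperature model.

Four presets ship with the package:

``control_gfp``
    Intact animal: consolidated sleep, ~80% recovery of deprivation-lost
    sleep over 19 h, 35.5 °C mean core temperature.
``lesion_dgal``
    Preoptic-galanin-lesion phenotype: fragmented sleep, blunted rebound
    (~22% recovery), chronically elevated temperature (37 °C mean) with a
    larger diurnal range and a transient spike at the dark->light transition.
``control_dex`` / ``lesion_dex``
    The corresponding dexmedetomidine experiments: a 6-h window starting at
    ZT18 with an i.p. injection at ZT19 that forces an NREM-like state,
    suppresses REM, evokes a delta-power surge and (in controls) sustained
    hypothermia to ~25 °C followed by a delta rebound in natural NREM sleep.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES = (WAKE, NREM, REM)

LIGHTS_ON = "lights_on"
LIGHTS_OFF = "lights_off"
PHASES = (LIGHTS_ON, LIGHTS_OFF)

#: ZT hour at which lights switch off (lights on spans [0, 12)).
LIGHTS_OFF_ZT = 12.0


class StateParams(BaseModel):
    """Per-state architecture and signal parameters."""

    mean_episode_duration_s: dict[str, float]
    transition_weights: dict[str, float]
    eeg_band_weights: dict[str, float]
    eeg_amplitude: float = Field(gt=0, description="target epoch EEG RMS, uV")
    emg_rms_level: float = Field(gt=0, description="EMG white-noise RMS, uV")

    @model_validator(mode="after")
    def _check(self) -> "StateParams":
        if set(self.mean_episode_duration_s) != set(PHASES):
            raise ValueError(f"mean_episode_duration_s needs phases {PHASES}")
        weights = self.transition_weights
        if any(w < 0 for w in weights.values()):
            raise ValueError("transition weights must be nonnegative")
        if sum(weights.values()) <= 0:
            raise ValueError("transition weights must not all be zero")
        if set(self.eeg_band_weights) != {"delta", "theta", "broadband"}:
            raise ValueError("eeg_band_weights needs delta/theta/broadband")
        if any(w < 0 for w in self.eeg_band_weights.values()):
            raise ValueError("band weights must be nonnegative")
        return self


class DrugResponse(BaseModel):
    """Pharmacodynamic envelope of a sedative (dexmedetomidine-like) event.

    Temperature: roughly exponential descent from the pre-injection level to
    ``nadir_c`` over ``time_to_nadir_min``, then linear rewarming at
    ``recovery_rate_c_per_h`` until the undisturbed diurnal baseline is met.
    EEG: delta power in the drug-induced NREM-like state follows a
    rise-and-decay envelope peaking at ``delta_peak_min`` minutes at
    ``delta_peak_ratio`` times natural NREM delta, decaying with time
    constant ``delta_decay_min``.  After ``sedation_min`` the animal resumes
    natural sleep; NREM delta is then boosted by ``rebound_delta_gain``
    decaying over ``rebound_decay_h`` (the post-sedation delta rebound).
    """

    nadir_c: float
    time_to_nadir_min: float = Field(gt=0)
    recovery_rate_c_per_h: float = Field(gt=0)
    delta_peak_min: float = Field(gt=0)
    delta_peak_ratio: float = Field(1.0, gt=0)
    delta_decay_min: float = Field(120.0, gt=0)
    sedation_min: float = Field(180.0, ge=0)
    rebound_delta_gain: float = Field(1.0, ge=0)
    rebound_decay_h: float = Field(2.0, gt=0)


class TemperatureParams(BaseModel):
    mean_c: dict[str, float]
    diurnal_amplitude_c: float = Field(ge=0)
    noise_sd_c: float = Field(ge=0)
    zt24_spike_c: float = Field(0.0, ge=0)
    zt24_spike_window_min: float = Field(60.0, gt=0)
    drug_response: Optional[DrugResponse] = None

    @model_validator(mode="after")
    def _check(self) -> "TemperatureParams":
        if set(self.mean_c) != set(PHASES):
            raise ValueError(f"mean_c needs phases {PHASES}")
        return self


class ReboundParams(BaseModel):
    """Post-deprivation homeostatic response.

    The sleep-propensity boost shortens WAKE episodes by a factor
    ``b(t) = 1 + (B - 1) exp(-t / decay_hours)`` after deprivation ends.
    If ``recovery_fraction_target`` is set, B is solved numerically so the
    expected fraction of lost sleep recovered 19 h after deprivation end
    equals the target; otherwise ``extra_sleep_propensity`` is used as B
    directly.  ``delta_gain_post_sd`` is the initial NREM delta *power* gain,
    decaying with the same time constant.
    """

    delta_gain_post_sd: float = Field(1.0, ge=0)
    decay_hours: float = Field(3.5, gt=0)
    extra_sleep_propensity: Optional[float] = Field(None, ge=1.0)
    recovery_fraction_target: Optional[float] = None
    recovery_horizon_h: float = Field(19.0, gt=0)
    #: homeostatic feedback gain: gain * (scheduled - realized gained
    #: sleep)/debt is added to the WAKE-shortening factor, so recovery
    #: discharges in proportion to sleep actually obtained.
    feedback_gain: float = Field(10.0, ge=0)


class InterventionEvent(BaseModel):
    kind: Literal["sleep_deprivation", "drug"]
    zt_onset: float = Field(ge=0)
    duration_h: float = Field(gt=0)
    forced_state: Optional[str] = None
    rem_suppressed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "InterventionEvent":
        if self.kind == "sleep_deprivation":
            # enforced wakefulness is WAKE by definition
            self.forced_state = WAKE
        if self.forced_state is not None and self.forced_state not in STATES:
            raise ValueError(f"forced_state must be one of {STATES}")
        return self


class ScenarioConfig(BaseModel):
    epoch_s: float = Field(5.0, gt=0)
    fs_hz: float = Field(200.0, gt=0)
    zt_start: float = Field(0.0, ge=0, lt=24)
    days: float = Field(1.0, gt=0)
    state_params: dict[str, StateParams]
    rebound_params: ReboundParams = ReboundParams()
    events: list[InterventionEvent] = []
    temperature_params: TemperatureParams
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if set(self.state_params) != set(STATES):
            raise ValueError(f"state_params needs all of {STATES}")
        for name, sp in self.state_params.items():
            for phase, m in sp.mean_episode_duration_s.items():
                if m < self.epoch_s:
                    raise ValueError(
                        f"{name}/{phase}: mean episode duration {m}s "
                        f"< epoch length {self.epoch_s}s"
                    )
            unknown = set(sp.transition_weights) - set(STATES)
            if unknown:
                raise ValueError(f"{name}: unknown successor states {unknown}")
            if sp.transition_weights.get(name, 0) != 0:
                raise ValueError(f"{name}: self-transition weight must be 0")
        # REM entry only from NREM: WAKE->REM is structurally forbidden
        if self.state_params[WAKE].transition_weights.get(REM, 0) != 0:
            raise ValueError("WAKE->REM transitions are not allowed")
        total_h = self.days * 24.0
        for ev in self.events:
            onset_h = self._elapsed_h(ev.zt_onset)
            if onset_h is None or onset_h >= total_h:
                raise ValueError(
                    f"event at ZT{ev.zt_onset} outside the simulated timeline"
                )
        return self

    def _elapsed_h(self, zt: float) -> Optional[float]:
        """Hours from recording start to the first occurrence of ZT ``zt``."""
        delta = (zt - self.zt_start) % 24.0
        if delta >= self.days * 24.0:
            return None
        return delta

    # -- convenience ------------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return int(round(self.days * 24 * 3600 / self.epoch_s))

    def event_elapsed_h(self, ev: InterventionEvent) -> float:
        out = self._elapsed_h(ev.zt_onset)
        if out is None:  # pragma: no cover - blocked by validator
            raise ValueError("event outside timeline")
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


PRESETS = ("control_gfp", "lesion_dgal", "control_dex", "lesion_dex")


def load_preset(name: str, **overrides) -> ScenarioConfig:
    """Load a packaged scenario preset, optionally overriding top-level fields
    (e.g. ``seed=3, days=5``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = importlib.resources.files("murisleep.presets") / f"{name}.yaml"
    cfg = ScenarioConfig.model_validate(yaml.safe_load(ref.read_text()))
    if overrides:
        cfg = cfg.model_copy(update=overrides)
        cfg = ScenarioConfig.model_validate(cfg.model_dump())
    return cfg


def add_sleep_deprivation(
    cfg: ScenarioConfig, zt_onset: float = 0.0, duration_h: float = 5.0
) -> ScenarioConfig:
    """Return a copy of ``cfg`` with an enforced-wakefulness event added
    (default: the 5-h deprivation protocol starting at ZT0)."""
    ev = InterventionEvent(
        kind="sleep_deprivation", zt_onset=zt_onset, duration_h=duration_h
    )
    out = cfg.model_copy(update={"events": list(cfg.events) + [ev]})
    return ScenarioConfig.model_validate(out.model_dump())
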