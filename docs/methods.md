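# Methods

`murisleep` analyses mouse polysomnography: EEG/EMG at 200 Hz scored in 5-s
epochs into WAKE, NREM and REM sleep, plus core body temperature telemetry
at a 2-min cadence, on a 12:12 light/dark cycle (zeitgeber time ZT0 =
lights on, lights off = ZT12–24). Because no public recordings accompany
the phenotypes the package targets, it ships a ground-truthed synthetic
generator whose presets encode two animal groups — an intact control and a
preoptic-galanin-lesion phenotype — under three protocols: undisturbed
baseline, 5-h enforced wakefulness from ZT0, and an i.p. dexmedetomidine
injection at ZT19. All group-level numbers the package reports are
parameter-recovery results: the generator's configured truth pushed through
the full signal → features → scoring → metrics chain.

## Synthetic generator

### Sleep architecture

The hypnogram is a semi-Markov chain. Episode lengths are geometric in
epochs with mean `mean_episode_duration_s / epoch_s`, the discrete analogue
of an exponential duration floored at one epoch; the geometric law keeps
the configured mean exact, so the stationary time fraction of each state is
exactly `pi_s * m_s / sum(pi * m)`, with `pi` the stationary distribution of
the embedded transition chain — the oracle used by the tests. Successor
states are drawn from per-state transition weights; WAKE→REM is
structurally forbidden (rodent REM is entered from NREM). Episode means are
phase-specific (taken at episode onset); defaults give the control animal
roughly 55% sleep in lights-on and 24% in lights-off (≈10 h sleep/day),
with dark-phase wake bouts of 10 min, and give the lesion preset the
fragmentation phenotype (dark-phase WAKE 4 min / NREM 1.5 min bouts, more
and shorter episodes, more sleep in the dark phase) while leaving REM
bouts (60 s) untouched. REM is kept near 10% of sleep so that the
percentile-based REM threshold calibration (below) remains valid.

### Deprivation and homeostatic recovery

A deprivation event overwrites its window with WAKE. Afterwards WAKE
episode means are divided by a boost
`b(u) = 1 + (B − 1) e^(−u/tau) + g·e(u)`:

* the open-loop part decays with `decay_hours` (default 3.5 h); its initial
  magnitude `B` is solved numerically (Brent) so that, in a quasi-stationary
  approximation, the expected extra sleep over the 19-h recovery horizon
  equals `recovery_fraction_target` times the expected sleep debt;
* the feedback part `g·e(u)` (gain `feedback_gain`, default 10) tracks the
  error `e(u)` between that calibrated expected recovery schedule and the
  sleep actually obtained, normalized by the expected debt. It is
  two-sided: an animal behind schedule falls asleep faster, one ahead of
  schedule stays awake longer.

The feedback term exists because sleep homeostasis is a regulated process:
a purely open-loop boost leaves the 19-h recovered fraction with a
per-realization SD of ~24 percentage points under this architecture,
whereas real within-animal designs produce far tighter group means. With
feedback the generator meets its contract — expected recovered fraction
equals the target — with a per-seed SD of ~11 points. Presets encode 80%
(control) and 22% (lesion) targets.

Post-deprivation NREM epochs also carry a delta *power* gain decaying with
the same time constant (`delta_gain_post_sd`, control 1.5, lesion 1.15),
which is what the delta-power time-course analyses measure.

### EEG/EMG synthesis

Per epoch the EEG (µV) is the sum of three band-limited Gaussian noise
components — delta 0.5–4 Hz, theta 6–10 Hz, broadband 0.5–80 Hz —
synthesized directly on the epoch's Fourier grid with complex-normal
coefficients rescaled so each component's epoch power *exactly* equals its
state band weight times the state total power (`eeg_amplitude²`). This
gives exact control of band-power fractions with no filter spillover.
Defaults: NREM delta/theta/broadband weights 0.55/0.10/0.35 at 60 µV RMS;
WAKE 0.15/0.35/0.50 at 40 µV; REM 0.08/0.55/0.37 at 45 µV. EMG is white
noise at the state RMS (WAKE 30, NREM 6, REM 4 µV).

A drug event forces the NREM-like state for `sedation_min` and suppresses
REM for its whole horizon. During sedation the delta-power target follows a
rise-and-decay envelope `(1 − e^(−t/tau_r)) e^(−t/tau_d)` normalized to peak
at `delta_peak_ratio` × natural NREM delta exactly at `delta_peak_min`
(the rise constant is solved from the peak time; decay `delta_decay_min`),
while the theta and broadband targets are multiplied by the squared
temperature coupling factor `max(0.3, 1 + (T − 37)/12)` — the broadband
power decline that accompanies the evolving hypothermia. The coupling is
applied only inside the sedation window: the evoked delta envelope and the
post-sedation rebound gain (`rebound_delta_gain`, control 1.4 decaying over
2 h; lesion 1.0) are parameterized directly as the observable delta-power
course, net of temperature, because no quantitative amplitude–temperature
law is available and the drug analyses are defined on the delta
observable itself.

### Temperature

Temperature = phase mean + diurnal sinusoid (peak mid-dark) + Gaussian
noise (SD 0.15 °C) + an optional rectangular spike at the dark→light
transition (lesion: +1 °C over 60 min, the ZT24 spike) + the drug response:
exponential descent from the pre-injection baseline to `nadir_c`
(exactly reached at `time_to_nadir_min`), then linear rewarming at
`recovery_rate_c_per_h` capped at the diurnal baseline. Presets: control
35 °C lights-on / 36 °C lights-off (overall 35.5 °C), lesion 36/38
(overall 37 °C); control dexmedetomidine nadir 25 °C reached over 2 h with
1 °C/h rewarming (hypothermia outlasting 4 h), lesion nadir 31 °C at
45 min with 3 °C/h rewarming (truncated hypothermia). The published
descriptions of the descent give both "2 h" and "75 min"; the presets use
2 h and expose `time_to_nadir_min`.

### What the generator does not emulate

No artifacts or electrode noise, no 1/f spectral background, no
state-transition spectra (epochs are conditionally stationary), no
circadian modulation of NREM delta power in baseline, no individual-animal
random effects. Passing parameter-recovery tests therefore demonstrates
that the analysis chain is correct and unbiased under the stated
statistical structure, not that the scorer would reach 95% agreement on
real recordings.

## Analysis chain

* **Filtering.** EEG high-pass 0.5 Hz, EMG band-pass 5–45 Hz; 4th-order
  Butterworth applied forward–backward (zero phase). Corners are
  pre-warped by `(sqrt(2)−1)^(1/8)` so the *net* two-pass response is −3 dB
  at the stated edges.
* **Spectra.** Per 5-s epoch (1000 samples), two Hann-tapered 512-sample
  segments at offsets 0 and 488, one-sided periodograms averaged, density
  normalization (integrated PSD = Hann-weighted mean square; Parseval).
  Bin width 200/512 = 0.390625 Hz. Band power sums bins whose centers lie
  in `[lo, hi)` — contiguous bands partition the spectrum; a band reaching
  Nyquist includes the Nyquist bin; the DC bin is never part of delta.
  A partial trailing epoch is dropped with a logged count.
* **Features.** Delta (0.5–4 Hz) and theta (6–10 Hz) power, theta:delta
  ratio (NaN-flagged when delta = 0), EMG RMS per 5-s bin on the band-passed
  EMG.
* **Scoring.** EMG RMS above threshold ⇒ WAKE; else ratio above threshold ⇒
  REM; else NREM. Thresholds are calibrated per recording: the EMG
  threshold at the deepest KDE valley between the two dominant modes of
  log EMG RMS (fallback 60th percentile), the REM threshold at the 90th
  percentile of the ratio among low-EMG epochs (fallback 2.0). Labels are
  then majority-smoothed (window 3, ties keep the incumbent), episodes
  shorter than 2 epochs are merged into the preceding state (the following
  state at the recording start), and REM directly after WAKE is relabelled
  NREM. The published scorer is unpublished; this decision tree uses
  exactly the features the original pipeline computed. An optional
  per-epoch override table substitutes for manual confirmation. The
  absolute-delta floor ships disabled.
* **Architecture.** Time in state, episode counts/durations and transition
  counts per light phase (straddling episodes attributed by onset; counts
  then conserve exactly), state-conditioned mean spectra, NREM peak
  frequency (argmax above DC, ties toward lower frequency).
* **Homeostasis.** Total sleep = NREM + REM. The baseline recording is
  folded into a 24-h per-ZT-epoch sleep-propensity profile (mean across
  days); debt = folded-baseline minus test sleep over the deprivation
  window; the recovery curve cumulates (test − folded baseline) sleep after
  the window, normalized by debt, with the recovery rate as the
  least-squares slope of gained minutes vs hours over the 19-h horizon
  (one admissible reading; the source protocol does not define the rate).
  Analyses use 5-day baselines, matching the 5-day continuous recordings
  of the underlying protocol. Delta time courses compare NREM-only delta
  per hour bin to ZT-matched baseline (bins with <6 NREM epochs flagged);
  the drug response uses 5-min sliding bins, peak time = bin-center argmax,
  reference = baseline NREM delta over the matched ZT horizon; the delta
  rebound is the 1-h window 3.5 h post-injection vs ZT-matched baseline.
  Hypothermia-induced amplitude decline is deliberately not corrected for.
* **Temperature metrics.** Diurnal profile (30-min ZT bins, mean ± SEM
  across days), phase means, transition spike (60-min window at ZT24 minus
  equal flanking windows), hypothermia report (pre-injection 1-h mean,
  raw-sample nadir and its latency, recovery = first post-nadir return to
  within 1 °C of the pre mean — ∞ if never, 0 if the band is never left —
  and the temperature deficit area).
* **Statistics.** Welch's t (the unpaired default), paired t, Holm–
  Bonferroni step-down over metric families (via statsmodels). ANOVA is
  out of scope; the comparisons the package reproduces are two-group.

## Problem sizes and tolerances

Acceptance-style checks simulate 5–6 seeds of the relevant protocol
(1-day test recordings with 5-day baselines for recovery accounting; 6-h
recordings for the drug protocol), sized so the whole suite runs in a few
minutes on one CPU. Scoring agreement is ≥99% on noiseless, well-separated
feature sets and ≥90% end-to-end at default noise; Parseval holds exactly
against the windowed mean square and within 5% against plain epoch
variance for deterministic signals and epoch-averaged noise (a single
white-noise epoch's plain variance fluctuates by ~4% SD around the
windowed estimate, so the 5% form is only asserted where it is an
identity). The type-I error of the Welch test is checked at 10⁴ null
replicates (0.05 ± 0.01).

## Known limitations

* The scorer is a reconstruction; its thresholds are calibrated from the
  data, not fitted to human scoring.
* The quasi-stationary calibration of the rebound boost is exact only when
  episode durations are short relative to the boost decay; with the
  default parameters the residual bias is ≲2 percentage points.
* The REM threshold rule (90th percentile) degrades when REM exceeds
  ~10–15% of sleep, and misscored REM epochs slightly dilute scored-NREM
  delta means in baselines.
* EDF export uses a minimal built-in 16-bit writer (1-s records, physical
  range = data range); files are readable by mne and similar tools but
  carry no patient/transducer metadata.
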