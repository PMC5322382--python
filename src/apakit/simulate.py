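"""Synthetic trial generation and the real-time acquisition loop.

Two tasks are emulated, each with ground truth for parameter-recovery
testing:

* **supine leg raise** (in-scanner task): three 32 Hz force channels.  The
  left (support) sensor shows the anticipatory loading bump — a smooth rise
  beginning at the APA onset, a plateau while the right leg is airborne, and
  a return to baseline after the relax command.  The right (moving) sensor
  loses most of its load at lift; the touch channel fires when the foot
  reaches the restraining bar.
* **upright step initiation**: medio-lateral platform force (synthesized at
  1000 Hz, band-limited with a 100 Hz low-pass to emulate the platform's
  analog filter) with a biphasic APA deflection, plus a 200 Hz
  antero-posterior ankle-marker trace following a sigmoid step displacement.

External support (knee pad supine, walker upright) suppresses the APA: the
simulated APA amplitude is scaled by ``1 - suppression_factor`` in the
supported condition.

The acquisition loop reproduces the control box's online trigger: the moving
leg's force falling below (calibration mean − 20 SD) raises a ``trigger``
event, and the relax command follows 500 ms later.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .types import (EventTable, ForceTrace, MarkerTrace, TrialRecording,
                    ValidationError)

CONDITIONS = ("supported", "unsupported")

#: go-cue → APA latency jitter bounds (s); a plausible reaction-time band,
#: a free simulator parameter
LATENCY_RANGE = (0.150, 0.400)

SCANNER_RATE_HZ = 32.0
STEP_FORCE_RATE_HZ = 1000.0
STEP_FORCE_CUTOFF_HZ = 100.0
MARKER_RATE_HZ = 200.0


def smoothstep(t: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """C1 ramp: 0 before ``onset``, 1 after ``onset + rise``."""
    x = np.clip((t - onset) / rise, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class SupineTrialParams:
    """Supine leg-raise generator parameters (forces in N, times in s)."""

    baseline_left: float = 40.0
    baseline_right: float = 40.0
    # unsupported APA amplitude defaults to the load the support leg takes
    # over from the lifted leg (lift_drop_fraction * baseline_right)
    apa_amplitude: float = 36.0
    apa_lead: float = 0.25          # APA onset → leg-lift onset
    lift_drop_fraction: float = 0.9
    ramp_tau: float = 0.06          # APA rise completes in 3*ramp_tau
    noise_sd: float = 0.2
    condition: str = "unsupported"
    suppression_factor: float = 0.5
    seed: int = 0
    rate_hz: float = SCANNER_RATE_HZ

    def __post_init__(self):
        if self.apa_amplitude < 0 or self.baseline_left < 0:
            raise ValidationError("amplitudes must be >= 0")
        if not self.apa_lead > 0:
            raise ValidationError("apa_lead must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.suppression_factor <= 1:
            raise ValidationError("suppression_factor must be in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass
class StepTrialParams:
    """Upright step-initiation generator parameters."""

    fml_amplitude: float = 20.0     # peak medio-lateral APA force (N)
    apa_lead: float = 0.25          # APA onset → step (foot-off) onset
    fml_phase_s: float = 0.30       # duration of each F_ml lobe
    step_sigmoid_scale: float = 0.15  # marker rise completes in 3*scale
    marker_excursion: float = 300.0  # mm
    noise_sd_force: float = 0.1
    noise_sd_marker: float = 0.2
    condition: str = "unsupported"
    suppression_factor: float = 0.5
    seed: int = 0
    force_rate_hz: float = STEP_FORCE_RATE_HZ
    marker_rate_hz: float = MARKER_RATE_HZ

    def __post_init__(self):
        if self.fml_amplitude < 0 or self.marker_excursion < 0:
            raise ValidationError("amplitudes must be >= 0")
        if not self.apa_lead > 0:
            raise ValidationError("apa_lead must be > 0")
        if min(self.noise_sd_force, self.noise_sd_marker) < 0:
            raise ValidationError("noise SDs must be >= 0")
        if not 0 <= self.suppression_factor <= 1:
            raise ValidationError("suppression_factor must be in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass
class GroundTruth:
    """Simulator truth echoed per trial, for parameter-recovery tests."""

    true_apa_onset: float
    true_move_onset: float      # leg-lift (supine) or step (upright) onset
    apa_amplitude_effective: float
    condition: str
    trial_index: int = 0


def _effective_amplitude(amplitude, condition, suppression) -> float:
    if condition == "supported":
        return amplitude * (1.0 - suppression)
    return amplitude


def _trial_timing(schedule_slice: EventTable):
    """Cross/prepare/go onsets and go max-duration for one trial."""
    f = schedule_slice.frame
    out = {}
    for typ in ("cross", "prepare_circle", "go_circle"):
        rows = f[f["trial_type"] == typ]
        if rows.empty:
            raise ValidationError(f"schedule slice lacks a {typ} event")
        out[typ] = (float(rows["onset"].iloc[0]),
                    float(rows["duration"].iloc[0]))
    return out


def simulate_supine_trial(params: SupineTrialParams,
                          schedule_slice: EventTable
                          ) -> tuple[TrialRecording, GroundTruth]:
    """One supine leg-raise trial: 32 Hz left/right/touch channels.

    The left (support) force rises smoothly from its baseline starting at
    the APA onset (go cue + jittered latency), the right force drops by
    ``lift_drop_fraction`` at lift onset (= APA onset + ``apa_lead``), and
    both return to baseline after the relax command (lift + 500 ms).
    """
    rate = params.rate_hz
    if params.apa_lead < 2.0 / rate:
        raise ValidationError(
            "apa_lead shorter than 2 sample periods is undetectable")
    rng = np.random.default_rng(params.seed)
    timing = _trial_timing(schedule_slice)
    t_cross, _ = timing["cross"]
    t_go, go_max = timing["go_circle"]

    t0 = t_cross
    n = int(round((t_go + go_max - t_cross) * rate))
    t = t0 + np.arange(n) / rate

    latency = rng.uniform(*LATENCY_RANGE)
    apa_onset = t_go + latency
    lift_onset = apa_onset + params.apa_lead
    relax_time = lift_onset + 0.5
    amp = _effective_amplitude(params.apa_amplitude, params.condition,
                               params.suppression_factor)

    rise = smoothstep(t, apa_onset, 3.0 * params.ramp_tau)
    release = smoothstep(t, relax_time, 0.3)
    left = params.baseline_left + amp * rise * (1.0 - release)

    drop = smoothstep(t, lift_onset, 0.10)
    right = params.baseline_right * (
        1.0 - params.lift_drop_fraction * drop * (1.0 - release))

    touch_time = lift_onset + 0.15   # transit to the restraining bar
    touch = (t >= touch_time).astype(float) * (1.0 - release)

    if params.noise_sd > 0:
        left = left + rng.normal(0, params.noise_sd, n)
        right = right + rng.normal(0, params.noise_sd, n)

    events = schedule_slice.frame.copy()
    trial_index = int(events["trial_index"].iloc[0])
    rec = TrialRecording(
        traces={"left_foot": ForceTrace(left, rate, "left_foot", t0),
                "right_foot": ForceTrace(right, rate, "right_foot", t0),
                "touch": ForceTrace(touch, rate, "touch", t0, units="bool")},
        events=EventTable(events), trial_index=trial_index)
    truth = GroundTruth(true_apa_onset=apa_onset, true_move_onset=lift_onset,
                        apa_amplitude_effective=amp,
                        condition=params.condition, trial_index=trial_index)
    return rec, truth


def _biphasic(t: np.ndarray, onset: float, amp: float,
              phase: float) -> np.ndarray:
    """Toward-then-away medio-lateral deflection: a full-amplitude sine lobe
    followed by a half-amplitude opposite lobe, zero elsewhere."""
    w = (t - onset) / phase
    out = np.zeros_like(t)
    m1 = (w >= 0) & (w < 1)
    out[m1] = amp * np.sin(np.pi * w[m1])
    m2 = (w >= 1) & (w < 2)
    out[m2] = -0.5 * amp * np.sin(np.pi * (w[m2] - 1.0))
    return out


def simulate_step_trial(params: StepTrialParams,
                        schedule_slice: EventTable
                        ) -> tuple[TrialRecording, GroundTruth]:
    """One upright step-initiation trial: F_ml force + ankle-marker traces.

    The medio-lateral force shows a biphasic APA deflection beginning at the
    APA onset; the marker's antero-posterior displacement follows a sigmoid
    of amplitude ``marker_excursion`` beginning at the step onset.  The force
    channel is band-limited with a zero-phase Butterworth low-pass at 100 Hz
    to emulate the platform's analog anti-aliasing filter.
    """
    frate, mrate = params.force_rate_hz, params.marker_rate_hz
    if params.apa_lead < 2.0 / mrate:
        raise ValidationError(
            "apa_lead shorter than 2 sample periods is undetectable")
    rng = np.random.default_rng(params.seed)
    timing = _trial_timing(schedule_slice)
    t_cross, _ = timing["cross"]
    t_go, go_max = timing["go_circle"]

    t0 = t_cross
    nf = int(round((t_go + go_max - t_cross) * frate))
    tf = t0 + np.arange(nf) / frate
    nm = int(round((t_go + go_max - t_cross) * mrate))
    tm = t0 + np.arange(nm) / mrate

    latency = rng.uniform(*LATENCY_RANGE)
    apa_onset = t_go + latency
    step_onset = apa_onset + params.apa_lead
    amp = _effective_amplitude(params.fml_amplitude, params.condition,
                               params.suppression_factor)

    fml = _biphasic(tf, apa_onset, amp, params.fml_phase_s)
    if params.noise_sd_force > 0:
        fml = fml + rng.normal(0, params.noise_sd_force, nf)
    sos = signal.butter(4, STEP_FORCE_CUTOFF_HZ, btype="low", fs=frate,
                        output="sos")
    fml = signal.sosfiltfilt(sos, fml)

    marker = params.marker_excursion * smoothstep(
        tm, step_onset, 3.0 * params.step_sigmoid_scale)
    if params.noise_sd_marker > 0:
        marker = marker + rng.normal(0, params.noise_sd_marker, nm)

    events = schedule_slice.frame.copy()
    trial_index = int(events["trial_index"].iloc[0])
    rec = TrialRecording(
        traces={"f_ml": ForceTrace(fml, frate, "f_ml", t0)},
        marker=MarkerTrace(marker, mrate, t0),
        events=EventTable(events), trial_index=trial_index)
    truth = GroundTruth(true_apa_onset=apa_onset, true_move_onset=step_onset,
                        apa_amplitude_effective=amp,
                        condition=params.condition, trial_index=trial_index)
    return rec, truth


def simulate_run(task: str, params, schedule,
                 n_trials: int | None = None) -> tuple[list, list]:
    """Simulate every trial of a schedule; per-trial seeds derive from
    ``params.seed`` so a run is reproducible end to end."""
    sim = {"supine": simulate_supine_trial,
           "step": simulate_step_trial}.get(task)
    if sim is None:
        raise ValidationError(f"unknown task {task!r}")
    n = schedule.n_trials if n_trials is None else min(n_trials,
                                                       schedule.n_trials)
    seeds = np.random.SeedSequence(params.seed).generate_state(n)
    recs, truths = [], []
    for trial in range(n):
        p = replace(params, seed=int(seeds[trial] % (2 ** 31)))
        rec, truth = sim(p, schedule.events.for_trial(trial))
        recs.append(rec)
        truths.append(truth)
    return recs, truths


# ---------------------------------------------------------------------------
# real-time trigger emulation

def run_acquisition_loop(recording: TrialRecording,
                         calibration_window: tuple[float, float],
                         k_sd: float = 20.0,
                         sd_floor_frac: float = 0.005,
                         relax_delay: float = 0.500) -> EventTable:
    """Replay the control box's online trigger rule on a recorded trial.

    The moving-leg (right foot) force is calibrated over
    ``calibration_window`` (mean m, SD s, with s floored at
    ``sd_floor_frac * |m|`` so a noiseless calibration cannot make the
    threshold unreachable).  Scanning sample by sample after the go cue, the
    first value below ``m - k_sd * s`` raises a ``trigger`` event; the
    ``relax_cmd`` event follows ``relax_delay`` (500 ms) later.  No crossing
    before the go stimulus's maximum duration yields an empty table.
    """
    trace = recording.traces.get("right_foot")
    if trace is None:
        raise ValidationError("recording lacks a right_foot (moving leg) trace")
    cal = trace.slice_window(*calibration_window)
    if cal.size < 5:
        raise ValidationError("calibration window must contain >= 5 samples")
    m = float(np.mean(cal))
    s = float(np.std(cal, ddof=1))
    s = max(s, sd_floor_frac * abs(m))
    threshold = m - k_sd * s

    go = recording.events.of_type("go_circle")
    t_go = float(go["onset"].iloc[0])
    go_max = float(go["duration"].iloc[0])

    times = trace.times
    trigger_time = None
    for value, tt in zip(trace.samples, times):   # genuine online scan
        if tt < t_go or tt >= t_go + go_max:
            continue
        if value < threshold:
            trigger_time = float(tt)
            break
    if trigger_time is None:
        return EventTable()
    return EventTable.from_rows([
        (trigger_time, 0.0, "trigger", recording.trial_index),
        (trigger_time + relax_delay, 0.0, "relax_cmd",
         recording.trial_index)])


def offline_trigger_scan(recording: TrialRecording,
                         calibration_window: tuple[float, float],
                         k_sd: float = 20.0,
                         sd_floor_frac: float = 0.005) -> float | None:
    """Vectorized full-trace threshold search with the same calibration rule;
    the offline counterpart the online loop must agree with exactly."""
    trace = recording.traces["right_foot"]
    cal = trace.slice_window(*calibration_window)
    if cal.size < 5:
        raise ValidationError("calibration window must contain >= 5 samples")
    m = float(np.mean(cal))
    s = max(float(np.std(cal, ddof=1)), sd_floor_frac * abs(m))
    go = recording.events.of_type("go_circle")
    t_go = float(go["onset"].iloc[0])
    go_max = float(go["duration"].iloc[0])
    t = trace.times
    mask = (t >= t_go) & (t < t_go + go_max) & (trace.samples < m - k_sd * s)
    idx = np.flatnonzero(mask)
    return float(t[idx[0]]) if idx.size else None
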