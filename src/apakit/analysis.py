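"""APA onset detection and quantification.

Onsets are threshold crossings relative to a quiescent baseline: a signal is
"on" at the first time it stays beyond mean ± k·SD of its baseline window
for a debounce run of consecutive samples.  Two task-specific pipelines are
built on this primitive:

* **step initiation** — APA onset on the medio-lateral force (2 SD above
  baseline), step onset on the ankle marker's antero-posterior displacement
  (2 SD above baseline); amplitude is the peak |F_ml − baseline mean| inside
  the APA interval, normalized by foot length (N/cm).
* **supine leg raise** — APA onset on the left (support) sensor (2 SD above
  baseline), leg-lift onset on the right (moving) sensor (2 SD below
  baseline); force magnitude is the support-force integral between the two
  onsets as a percentage of the whole trial-window integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import signal

from .types import (ForceTrace, MarkerTrace, TrialRecording, TrialWindow,
                    ValidationError)

Trace = Union[ForceTrace, MarkerTrace]

def default_hold(rate_hz: float) -> int:
    """Debounce run length for threshold crossings.

    A single sample above 2 SD occurs by chance in ~2.3% of Gaussian noise
    samples, so a 1-sample rule produces false onsets in a sizeable fraction
    of trials at any rate.  Two consecutive samples (62 ms) suffice at the
    32 Hz scanner rate; high-rate platform/marker signals use at least 10 ms
    of samples because band-limited noise is correlated over several sample
    periods.
    """
    return 2 if rate_hz <= 64 else max(3, int(round(0.010 * rate_hz)))


def baseline_stats(trace: Trace, window: tuple[float, float]
                   ) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) of a trace over ``[start, end)``."""
    vals = trace.slice_window(*window)
    if vals.size < 5:
        raise ValidationError(
            f"baseline window {window} holds {vals.size} samples (< 5)")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def detect_crossing(trace: Trace, window: tuple[float, float],
                    mean: float, sd: float, k_sd: float = 2.0,
                    direction: str = "above",
                    hold: Optional[int] = None) -> Optional[float]:
    """First time in ``window`` the signal stays beyond mean ± k·SD for
    ``hold`` consecutive samples; ``None`` if it never does."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if direction not in ("above", "below"):
        raise ValidationError(f"direction must be above/below, got {direction!r}")
    if hold is None:
        hold = default_hold(trace.rate_hz)
    if hold < 1:
        raise ValidationError("hold must be >= 1")
    t = trace.times
    in_win = (t >= window[0]) & (t < window[1])
    if direction == "above":
        beyond = trace.samples > mean + k_sd * sd
    else:
        beyond = trace.samples < mean - k_sd * sd
    ok = beyond & in_win
    if hold > 1:
        # run of `hold` consecutive samples, all inside the window
        kernel = np.ones(hold, dtype=int)
        runs = np.convolve(ok.astype(int), kernel, mode="valid") == hold
        idx = np.flatnonzero(runs)
    else:
        idx = np.flatnonzero(ok)
    return float(t[idx[0]]) if idx.size else None


def lowpass_filter(trace: Trace, cutoff_hz: float = 10.0,
                   order: int = 4) -> Trace:
    """Zero-phase (forward-backward) Butterworth low-pass, so band-limiting
    does not delay onsets."""
    nyq = trace.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.rate_hz,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    if isinstance(trace, MarkerTrace):
        return MarkerTrace(filtered, trace.rate_hz, trace.t0)
    return ForceTrace(filtered, trace.rate_hz, trace.channel, trace.t0,
                      trace.units)


@dataclass
class StepAPAResult:
    """Per-trial step-initiation measures (invalid trials are flagged, never
    silently dropped)."""

    valid: bool
    apa_onset: Optional[float] = None
    step_onset: Optional[float] = None
    apa_interval: Optional[float] = None      # step_onset − apa_onset
    fml_amplitude_norm: Optional[float] = None  # N/cm
    fml_amplitude: Optional[float] = None       # N, before normalization
    reason: Optional[str] = None
    trial_index: int = 0


@dataclass
class ScannerAPAResult:
    """Per-trial supine (in-scanner) measures."""

    valid: bool
    apa_onset: Optional[float] = None
    leglift_onset: Optional[float] = None
    apa_interval: Optional[float] = None
    force_magnitude_pct: Optional[float] = None  # % of whole-curve integral
    peak_amplitude: Optional[float] = None       # N above baseline mean
    reason: Optional[str] = None
    trial_index: int = 0


def compute_step_apa(fml: ForceTrace, marker: MarkerTrace,
                     windows: TrialWindow, foot_length_cm: float,
                     k_sd: float = 2.0,
                     hold: Optional[int] = None,
                     trial_index: int = 0) -> StepAPAResult:
    """Quantify one step-initiation trial.

    APA onset: F_ml exceeds baseline mean + 2 SD.  Step onset: marker AP
    displacement exceeds its baseline mean + 2 SD.  Amplitude: peak
    |F_ml − baseline mean| within [apa_onset, step_onset], divided by foot
    length (N/cm).
    """
    if not foot_length_cm > 0:
        raise ValidationError("foot_length_cm must be > 0")
    f_mean, f_sd = baseline_stats(fml, windows.baseline)
    m_mean, m_sd = baseline_stats(marker, windows.baseline)

    apa_onset = detect_crossing(fml, windows.movement, f_mean, f_sd, k_sd,
                                "above", hold)
    if apa_onset is None:
        return StepAPAResult(valid=False, reason="no APA onset crossing",
                             trial_index=trial_index)
    step_onset = detect_crossing(marker, windows.movement, m_mean, m_sd,
                                 k_sd, "above", hold)
    if step_onset is None:
        return StepAPAResult(valid=False, apa_onset=apa_onset,
                             reason="no step onset crossing",
                             trial_index=trial_index)
    if step_onset <= apa_onset:
        return StepAPAResult(valid=False, apa_onset=apa_onset,
                             step_onset=step_onset,
                             reason="step onset precedes APA onset",
                             trial_index=trial_index)
    seg = fml.slice_window(apa_onset, step_onset)
    amp = float(np.max(np.abs(seg - f_mean)))
    return StepAPAResult(valid=True, apa_onset=apa_onset,
                         step_onset=step_onset,
                         apa_interval=step_onset - apa_onset,
                         fml_amplitude=amp,
                         fml_amplitude_norm=amp / foot_length_cm,
                         trial_index=trial_index)


def _integral(trace: ForceTrace, start: float, end: float) -> float:
    """Trapezoidal integral over [start, end], endpoint-exact: window edges
    falling between samples are linearly interpolated so a constant trace c
    integrates to exactly c*(end − start)."""
    t = trace.times
    y = trace.samples
    start = max(start, float(t[0]))
    end = min(end, float(t[-1]))
    if end <= start:
        raise ValidationError(f"empty integration window [{start}, {end})")
    inner = (t > start) & (t < end)
    ts = np.concatenate([[start], t[inner], [end]])
    ys = np.concatenate([[np.interp(start, t, y)], y[inner],
                         [np.interp(end, t, y)]])
    return float(np.trapezoid(ys, ts))


def compute_scanner_apa(left: ForceTrace, right: ForceTrace,
                        windows: TrialWindow, k_sd: float = 2.0,
                        hold: Optional[int] = None,
                        trial_index: int = 0) -> ScannerAPAResult:
    """Quantify one supine leg-raise trial.

    APA onset: left (support) force above baseline mean + 2 SD.  Leg-lift
    onset: right (moving) force below baseline mean − 2 SD.  Magnitude: the
    trapezoidal integral of the left force over [APA onset, lift onset]
    divided by its integral over the whole movement window, × 100.
    """
    l_mean, l_sd = baseline_stats(left, windows.baseline)
    r_mean, r_sd = baseline_stats(right, windows.baseline)

    apa_onset = detect_crossing(left, windows.movement, l_mean, l_sd, k_sd,
                                "above", hold)
    if apa_onset is None:
        return ScannerAPAResult(valid=False, reason="no APA onset crossing",
                                trial_index=trial_index)
    lift_onset = detect_crossing(right, windows.movement, r_mean, r_sd, k_sd,
                                 "below", hold)
    if lift_onset is None:
        return ScannerAPAResult(valid=False, apa_onset=apa_onset,
                                reason="no leg-lift crossing",
                                trial_index=trial_index)
    if lift_onset <= apa_onset:
        return ScannerAPAResult(valid=False, apa_onset=apa_onset,
                                leglift_onset=lift_onset,
                                reason="lift onset precedes APA onset",
                                trial_index=trial_index)
    pct = force_magnitude_pct(left, (apa_onset, lift_onset),
                              windows.movement)
    mov = left.slice_window(*windows.movement)
    peak = float(np.max(mov) - l_mean)
    return ScannerAPAResult(valid=True, apa_onset=apa_onset,
                            leglift_onset=lift_onset,
                            apa_interval=lift_onset - apa_onset,
                            force_magnitude_pct=pct,
                            peak_amplitude=peak, trial_index=trial_index)


def force_magnitude_pct(left: ForceTrace, apa_interval: tuple[float, float],
                        curve_window: tuple[float, float]) -> float:
    """Support-force integral over the APA interval as a percentage of the
    whole-curve integral.

    The APA interval is clipped into the curve window, so for a nonnegative
    trace the numerator integrates a sub-interval of the denominator and the
    result is bounded in [0, 100]; multiplying the trace by any positive
    constant leaves it unchanged.
    """
    whole = _integral(left, *curve_window)
    if whole <= 0:
        raise ValidationError("whole-curve integral must be > 0")
    a = max(apa_interval[0], curve_window[0])
    b = min(apa_interval[1], curve_window[1])
    return 100.0 * _integral(left, a, b) / whole


# ---------------------------------------------------------------------------
# per-recording drivers

def trial_windows_from_events(recording: TrialRecording) -> TrialWindow:
    """Default analysis windows from the trial's cue events: baseline is the
    instructed relax phase (cross onset → prepare onset); the movement window
    runs from the go cue (no response can precede the imperative stimulus)
    to the end of the trace."""
    f = recording.events.frame
    cross = f[f["trial_type"] == "cross"]
    prep = f[f["trial_type"] == "prepare_circle"]
    go = f[f["trial_type"] == "go_circle"]
    if cross.empty or prep.empty or go.empty:
        raise ValidationError("recording lacks cross/prepare/go events")
    t_cross = float(cross["onset"].iloc[0])
    t_prep = float(prep["onset"].iloc[0])
    t_go = float(go["onset"].iloc[0])
    any_trace = recording.marker or next(iter(recording.traces.values()))
    t_end = float(any_trace.times[-1])
    for tr in recording.traces.values():
        t_end = min(t_end, float(tr.times[-1]))
    if not t_cross < t_prep <= t_go < t_end:
        raise ValidationError("cue events out of order for this trace")
    return TrialWindow(baseline=(t_cross, t_prep), movement=(t_go, t_end))


def analyze_step_recording(recording: TrialRecording, foot_length_cm: float,
                           windows: Optional[TrialWindow] = None,
                           **kw) -> StepAPAResult:
    if windows is None:
        windows = trial_windows_from_events(recording)
    if recording.marker is None:
        raise ValidationError("step analysis requires a marker trace")
    return compute_step_apa(recording.traces["f_ml"], recording.marker,
                            windows, foot_length_cm,
                            trial_index=recording.trial_index, **kw)


def analyze_scanner_recording(recording: TrialRecording,
                              windows: Optional[TrialWindow] = None,
                              **kw) -> ScannerAPAResult:
    if windows is None:
        windows = trial_windows_from_events(recording)
    return compute_scanner_apa(recording.traces["left_foot"],
                               recording.traces["right_foot"], windows,
                               trial_index=recording.trial_index, **kw)
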