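"""Core domain types for APA force recordings.

All times are seconds from run start; windows are closed-open ``[start, end)``.
Force traces are uniformly sampled (a rate and a time origin, no per-sample
timestamps); marker traces carry antero-posterior displacement in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: channel tags the force logger knows about
FORCE_CHANNELS = ("left_foot", "right_foot", "touch", "f_ml")

#: event labels the paradigm and the acquisition loop may emit
TRIAL_TYPES = ("cross", "prepare_circle", "go_circle", "relax_cmd", "trigger",
               "touch_bar")

EVENT_COLUMNS = ("onset", "duration", "trial_type", "trial_index")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class ForceTrace:
    """Uniformly sampled single-channel force series.

    Parameters
    ----------
    samples : array of force values (N, or raw sensor units per ``units``).
    rate_hz : sampling frequency, > 0.
    channel : one of :data:`FORCE_CHANNELS`.
    t0 : time of the first sample, seconds from run start.
    """

    samples: np.ndarray
    rate_hz: float
    channel: str
    t0: float = 0.0
    units: str = "N"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be > 0")
        if self.channel not in FORCE_CHANNELS:
            raise ValidationError(f"unknown channel tag {self.channel!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate_hz

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate_hz

    def slice_window(self, start: float, end: float) -> np.ndarray:
        """Samples whose timestamps fall in ``[start, end)``."""
        t = self.times
        return self.samples[(t >= start) & (t < end)]


@dataclass
class MarkerTrace:
    """Antero-posterior marker displacement (mm), uniformly sampled."""

    displacement: np.ndarray
    rate_hz: float = 200.0
    t0: float = 0.0

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 1 or self.displacement.size == 0:
            raise ValidationError("displacement must be a non-empty 1-D array")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.displacement.size) / self.rate_hz

    @property
    def samples(self) -> np.ndarray:  # uniform access alongside ForceTrace
        return self.displacement

    def slice_window(self, start: float, end: float) -> np.ndarray:
        t = self.times
        return self.displacement[(t >= start) & (t < end)]


class EventTable:
    """Ordered stimulus/response events: (onset s, duration s, type, trial).

    Wraps a DataFrame with columns ``onset, duration, trial_type,
    trial_index``; onsets must be non-decreasing and durations non-negative.
    """

    def __init__(self, frame: Optional[pd.DataFrame] = None):
        if frame is None:
            frame = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                                  zip(EVENT_COLUMNS,
                                      (float, float, str, int))})
        frame = frame.reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        frame = frame[list(EVENT_COLUMNS)].astype(
            {"onset": float, "duration": float, "trial_type": str,
             "trial_index": int}, errors="raise") if len(frame) else frame
        if len(frame):
            if (frame["duration"].to_numpy() < 0).any():
                raise ValidationError("negative event duration")
            onsets = frame["onset"].to_numpy()
            if (np.diff(onsets) < 0).any():
                raise ValidationError("event onsets must be non-decreasing")
            bad = set(frame["trial_type"]) - set(TRIAL_TYPES)
            if bad:
                raise ValidationError(f"unknown trial_type values {sorted(bad)}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def of_type(self, trial_type: str) -> pd.DataFrame:
        return self.frame[self.frame["trial_type"] == trial_type]

    def for_trial(self, trial_index: int) -> "EventTable":
        return EventTable(self.frame[self.frame["trial_index"] == trial_index])

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        """Build from an iterable of (onset, duration, trial_type, trial_index)."""
        return cls(pd.DataFrame(list(rows), columns=list(EVENT_COLUMNS)))


@dataclass
class MotionSeries:
    """Per-volume rigid-body motion estimates: 3 rotations (rad) + 3
    translations (mm); column order in source files is declared by a dialect
    tag (``rotations_first`` is the common convention)."""

    rotations: np.ndarray    # (n_volumes, 3) rad
    translations: np.ndarray  # (n_volumes, 3) mm
    dialect: str = "rotations_first"

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        for name, arr in (("rotations", self.rotations),
                          ("translations", self.translations)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{name} must have shape (n, 3)")
            if not np.isfinite(arr).all():
                raise ValidationError(f"non-finite values in {name}")
        if self.rotations.shape[0] != self.translations.shape[0]:
            raise ValidationError("rotation/translation row counts differ")

    @property
    def n_volumes(self) -> int:
        return self.rotations.shape[0]


@dataclass
class TrialWindow:
    """Baseline and movement analysis windows, seconds, ``[start, end)``."""

    baseline: tuple[float, float]
    movement: tuple[float, float]

    def __post_init__(self):
        b0, b1 = self.baseline
        m0, m1 = self.movement
        if not (b0 < b1 and m0 < m1):
            raise ValidationError("windows must be non-empty")
        if b1 > m0:
            raise ValidationError("baseline window must precede movement window")


@dataclass
class TrialRecording:
    """Synchronized traces + events for one trial (plus marker if present)."""

    traces: dict[str, ForceTrace]
    events: EventTable
    marker: Optional[MarkerTrace] = None
    trial_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, tr in self.traces.items():
            if name != tr.channel:
                raise ValidationError(
                    f"trace keyed {name!r} carries channel tag {tr.channel!r}")

    def go_cue_time(self) -> float:
        go = self.events.of_type("go_circle")
        if go.empty:
            raise ValidationError("recording has no go_circle event")
        return float(go["onset"].iloc[0])


# ---------------------------------------------------------------------------
# demographics

SUBJECT_NUMERIC = ("age", "weight_kg", "height_m")
SUBJECT_OPTIONAL_NUMERIC = ("disease_duration_y", "updrs_motor", "dled_mg",
                            "foot_length_cm")


class SubjectTable:
    """Per-subject demographics/clinical rows.

    Required columns: ``id, age, sex, weight_kg, height_m``; optional:
    ``disease_duration_y, updrs_motor, dled_mg, side_affected,
    foot_length_cm``.  ``foot_length_cm`` must be > 0 wherever amplitude
    normalization is later requested.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        required = ("id", "age", "sex", "weight_kg", "height_m")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"demographics missing columns {missing}")
        for col in SUBJECT_NUMERIC:
            vals = pd.to_numeric(frame[col], errors="coerce")
            if len(frame) and vals.isna().any():
                raise ValidationError(f"non-numeric value in column {col!r}")
            frame[col] = vals
        for col in SUBJECT_OPTIONAL_NUMERIC:
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                if ((~frame[col].isna()) & vals.isna()).any():
                    raise ValidationError(f"non-numeric value in column {col!r}")
                frame[col] = vals
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def foot_length(self, subject_id) -> float:
        row = self.frame[self.frame["id"] == subject_id]
        if row.empty:
            raise ValidationError(f"unknown subject id {subject_id!r}")
        if "foot_length_cm" not in row.columns or row["foot_length_cm"].isna().all():
            raise ValidationError(
                f"subject {subject_id!r} has no foot_length_cm; required for "
                "amplitude normalization")
        fl = float(row["foot_length_cm"].iloc[0])
        if not fl > 0:
            raise ValidationError("foot_length_cm must be > 0 for normalization")
        return fl
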