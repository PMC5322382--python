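"""Readers and writers for every file the toolkit touches.

The FMS run log is a self-describing, diff-friendly text format (the control
box of the original device stored plain text; this is a clean-room layout):

.. code-block:: text

    # fms-log 1
    # trial 0
    # block rate_hz=32 t0=0.000 channels=left_foot,right_foot,touch
    50.1 49.8 0
    ...
    # marker rate_hz=200 t0=0.000
    0.012
    ...
    # events
    onset	duration	trial_type	trial_index
    0.000	6.500	cross	0
    # end

Channels sampled together share a ``# block`` tick table (the scanner task is
a single 3-channel 32 Hz block); signals at other rates get their own block.
Forces are serialized with 6 significant digits and times at 1 ms resolution,
so a write→read round trip is exact at the declared precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (EVENT_COLUMNS, EventTable, ForceTrace, MarkerTrace,
                    MotionSeries, ParseError, SubjectTable, TrialRecording,
                    ValidationError)

FORMAT_VERSION = 1

_PathLike = Union[str, Path]


def _fmt_force(x: float) -> str:
    return f"{x:.6g}"


def _fmt_time(x: float) -> str:
    return f"{x:.3f}"   # 1 ms resolution


# ---------------------------------------------------------------------------
# FMS run log

def write_fms_log(recordings, path: _PathLike) -> None:
    """Write a run (sequence of :class:`TrialRecording`) to an FMS log file."""
    if isinstance(recordings, TrialRecording):
        recordings = [recordings]
    lines = [f"# fms-log {FORMAT_VERSION}"]
    for rec in recordings:
        lines.append(f"# trial {rec.trial_index}")
        # group channels into rate-homogeneous blocks, stable channel order
        by_rate: dict[tuple[float, float], list[str]] = {}
        for name, tr in rec.traces.items():
            by_rate.setdefault((tr.rate_hz, tr.t0), []).append(name)
        for (rate, t0), chans in by_rate.items():
            n = {len(rec.traces[c].samples) for c in chans}
            if len(n) != 1:
                raise ValidationError(
                    f"channels {chans} share a rate but differ in length")
            lines.append(f"# block rate_hz={_fmt_force(rate)} t0={_fmt_time(t0)} "
                         f"channels={','.join(chans)}")
            cols = [rec.traces[c].samples for c in chans]
            for row in zip(*cols):
                lines.append(" ".join(_fmt_force(v) for v in row))
        if rec.marker is not None:
            m = rec.marker
            lines.append(f"# marker rate_hz={_fmt_force(m.rate_hz)} "
                         f"t0={_fmt_time(m.t0)}")
            lines.extend(_fmt_force(v) for v in m.displacement)
        lines.append("# events")
        lines.append("\t".join(EVENT_COLUMNS))
        for _, row in rec.events.frame.iterrows():
            lines.append("\t".join([_fmt_time(row["onset"]),
                                    _fmt_time(row["duration"]),
                                    str(row["trial_type"]),
                                    str(int(row["trial_index"]))]))
        lines.append("# end")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_kv(tokens, lineno):
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise ParseError(f"malformed header token {tok!r}", lineno)
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def read_fms_log(path: _PathLike) -> list[TrialRecording]:
    """Read an FMS run log; inverse of :func:`write_fms_log`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# fms-log"):
        raise ParseError("missing 'fms-log' header", 1)
    recordings: list[TrialRecording] = []
    i, n = 1, len(lines)

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("# trial "):
            raise ParseError(f"expected '# trial', got {line!r}", i + 1)
        trial_index = int(line.split()[2])
        i += 1
        traces: dict[str, ForceTrace] = {}
        marker = None
        events = EventTable()
        while i < n:
            line = lines[i].strip()
            if line == "# end":
                i += 1
                break
            if line.startswith("# block "):
                kv = _parse_kv(line.split()[2:], i + 1)
                chans = kv["channels"].split(",")
                rate, t0 = float(kv["rate_hz"]), float(kv["t0"])
                i += 1
                rows = []
                while i < n and not lines[i].startswith("#"):
                    vals = lines[i].split()
                    if len(vals) != len(chans):
                        raise ParseError(
                            f"expected {len(chans)} values, got {len(vals)}",
                            i + 1)
                    try:
                        rows.append([float(v) for v in vals])
                    except ValueError:
                        raise ParseError(f"non-numeric sample {lines[i]!r}",
                                         i + 1) from None
                    i += 1
                arr = np.array(rows, dtype=float)
                if arr.size == 0:
                    raise ParseError("empty sample block", i)
                for j, c in enumerate(chans):
                    try:
                        traces[c] = ForceTrace(arr[:, j], rate, c, t0)
                    except ValidationError as e:
                        raise ParseError(str(e), i) from None
            elif line.startswith("# marker "):
                kv = _parse_kv(line.split()[2:], i + 1)
                rate, t0 = float(kv["rate_hz"]), float(kv["t0"])
                i += 1
                vals = []
                while i < n and not lines[i].startswith("#"):
                    try:
                        vals.append(float(lines[i]))
                    except ValueError:
                        raise ParseError(
                            f"non-numeric marker sample {lines[i]!r}",
                            i + 1) from None
                    i += 1
                marker = MarkerTrace(np.array(vals), rate, t0)
            elif line == "# events":
                i += 1
                if i >= n or lines[i].split("\t") != list(EVENT_COLUMNS):
                    raise ParseError("malformed events header", i + 1)
                i += 1
                rows = []
                while i < n and not lines[i].startswith("#"):
                    fields = lines[i].split("\t")
                    if len(fields) != 4:
                        raise ParseError(
                            f"expected 4 event fields, got {len(fields)}",
                            i + 1)
                    rows.append((float(fields[0]), float(fields[1]),
                                 fields[2], int(fields[3])))
                    i += 1
                try:
                    events = EventTable.from_rows(rows)
                except ValidationError as e:
                    raise ParseError(str(e), i) from None
            else:
                raise ParseError(f"unexpected line {line!r}", i + 1)
        recordings.append(TrialRecording(traces=traces, events=events,
                                         marker=marker,
                                         trial_index=trial_index))
    return recordings


# ---------------------------------------------------------------------------
# events TSV (BIDS-events-like)

def write_events(events: EventTable, path: _PathLike) -> None:
    events.frame.to_csv(path, sep="\t", index=False,
                        float_format="%.3f")


def read_events(path: _PathLike) -> EventTable:
    """Read a tab-separated events file (onset, duration, trial_type,
    trial_index); onset ordering and non-negative durations are enforced."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse events file: {e}") from None
    try:
        return EventTable(frame)
    except ValidationError:
        raise


# ---------------------------------------------------------------------------
# rigid-body motion parameters

def read_motion_params(path: _PathLike,
                       dialect: str = "rotations_first") -> MotionSeries:
    """Read whitespace-separated 6-column motion-parameter text.

    ``dialect`` declares the column order: ``rotations_first`` (3 rotations
    in rad then 3 translations in mm, the common convention) or
    ``translations_first``.
    """
    if dialect not in ("rotations_first", "translations_first"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = line.split()
        if len(vals) != 6:
            raise ParseError(f"expected 6 columns, got {len(vals)}", lineno)
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise ParseError(f"non-numeric value in {line!r}", lineno) from None
    arr = np.array(rows, dtype=float).reshape(-1, 6)
    if dialect == "rotations_first":
        rot, trans = arr[:, :3], arr[:, 3:]
    else:
        trans, rot = arr[:, :3], arr[:, 3:]
    return MotionSeries(rotations=rot, translations=trans, dialect=dialect)


# ---------------------------------------------------------------------------
# demographics

def read_demographics(path: _PathLike) -> SubjectTable:
    """Read a subject demographics/clinical CSV (header required)."""
    frame = pd.read_csv(path)
    return SubjectTable(frame)


def load_pd_cohort() -> SubjectTable:
    """The eight-patient Parkinson's disease cohort profile shipped with the
    package (age, weight, height, disease duration, UPDRS motor score, daily
    levodopa-equivalent dose, most-affected side)."""
    from importlib.resources import files
    data = files("apakit").joinpath("data/pd_cohort.csv").read_text()
    return SubjectTable(pd.read_csv(_io.StringIO(data)))
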