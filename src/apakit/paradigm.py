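"""Event-related stimulus scheduling with Poisson-grid durations.

Each trial shows three stimuli: a cross (relax; its duration is the
inter-stimulus interval, 5.5–8.5 s), a prepare circle (1–3 s) and a go circle
(up to 5 s — at acquisition time the go stimulus ends when the force under
the moving leg drops, so its scheduled duration is the 5 s maximum).
Durations are randomized on a 0.5 s grid with truncated-Poisson weights,
which jitters stimulus timing to decorrelate the regressors of the
event-related hemodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import EventTable, ValidationError

CUE_MAPPINGS = ("open_is_prepare", "closed_is_prepare")


@dataclass
class ParadigmConfig:
    """Run-level schedule parameters (defaults match the published task)."""

    n_trials: int = 30
    prepare_range: tuple[float, float] = (1.0, 3.0)
    go_max: float = 5.0
    isi_range: tuple[float, float] = (5.5, 8.5)
    grid_step: float = 0.5
    poisson_rate: float = 1.5
    cue_mapping: str = "open_is_prepare"
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.prepare_range, self.isi_range):
            if not lo < hi:
                raise ValidationError("duration ranges must be well-ordered")
            k = (hi - lo) / self.grid_step
            if abs(k - round(k)) > 1e-9:
                raise ValidationError("grid_step must divide range width")
        if not self.poisson_rate > 0:
            raise ValidationError("poisson_rate must be > 0")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.cue_mapping not in CUE_MAPPINGS:
            raise ValidationError(f"unknown cue_mapping {self.cue_mapping!r}")


@dataclass
class ParadigmSchedule:
    """Ordered cross/prepare/go events for one run."""

    events: EventTable
    config: ParadigmConfig
    total_duration: float = field(init=False)

    def __post_init__(self):
        f = self.events.frame
        self.total_duration = float((f["onset"] + f["duration"]).max())

    @property
    def n_trials(self) -> int:
        return int(self.events.frame["trial_index"].max()) + 1


def grid_values(duration_range: tuple[float, float],
                grid_step: float) -> np.ndarray:
    lo, hi = duration_range
    k = int(round((hi - lo) / grid_step))
    return lo + grid_step * np.arange(k + 1)


def truncated_poisson_pmf(k: int, lam: float) -> np.ndarray:
    """Poisson(λ) pmf renormalized to the support {0..k}."""
    if k < 0:
        raise ValidationError("empty grid")
    p = stats.poisson.pmf(np.arange(k + 1), lam)
    return p / p.sum()


def sample_grid_duration(duration_range: tuple[float, float],
                         grid_step: float, lam: float,
                         rng: np.random.Generator) -> float:
    """Draw ``range_min + step*j`` with j ~ Poisson(λ) truncated to the grid."""
    vals = grid_values(duration_range, grid_step)
    if vals.size == 0:
        raise ValidationError("empty grid")
    pmf = truncated_poisson_pmf(vals.size - 1, lam)
    return float(rng.choice(vals, p=pmf))


def build_schedule(config: ParadigmConfig) -> ParadigmSchedule:
    """Deterministic (seeded) 30-trial cross→prepare→go schedule.

    The go event is scheduled at its 5 s maximum; its realized duration is an
    acquisition-time outcome (force drop under the moving leg), not a
    schedule property.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    isi_grid = grid_values(config.isi_range, config.grid_step)
    prep_grid = grid_values(config.prepare_range, config.grid_step)
    isi = rng.choice(isi_grid, size=n,
                     p=truncated_poisson_pmf(isi_grid.size - 1,
                                             config.poisson_rate))
    prep = rng.choice(prep_grid, size=n,
                      p=truncated_poisson_pmf(prep_grid.size - 1,
                                              config.poisson_rate))
    trial_len = isi + prep + config.go_max
    starts = np.concatenate([[0.0], np.cumsum(trial_len)[:-1]])

    onsets = np.empty(3 * n)
    durations = np.empty(3 * n)
    onsets[0::3] = starts
    onsets[1::3] = starts + isi
    onsets[2::3] = starts + isi + prep
    durations[0::3] = isi
    durations[1::3] = prep
    durations[2::3] = config.go_max
    frame = pd.DataFrame({
        "onset": onsets, "duration": durations,
        "trial_type": np.tile(["cross", "prepare_circle", "go_circle"], n),
        "trial_index": np.repeat(np.arange(n), 3)})
    return ParadigmSchedule(events=EventTable(frame), config=config)


def counterbalance(subject_ids, seed: int = 0) -> dict:
    """Assign cue mappings as evenly as possible across subjects.

    Half the subjects see the open circle as the prepare cue and half the
    closed circle (the extra subject of an odd group goes to
    ``open_is_prepare``).  Deterministic given the seed.
    """
    ids = list(subject_ids)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    n_open = (len(ids) + 1) // 2
    mapping = {}
    for pos, idx in enumerate(order):
        mapping[ids[idx]] = (CUE_MAPPINGS[0] if pos < n_open
                             else CUE_MAPPINGS[1])
    return mapping


def counterbalance_conditions(subject_ids, seed: int = 0) -> dict:
    """Even-split assignment of condition order (supported-first vs
    unsupported-first) across subjects, same rule as cue counterbalancing."""
    ids = list(subject_ids)
    rng = np.random.default_rng(seed + 1)
    order = list(rng.permutation(len(ids)))
    n_first = (len(ids) + 1) // 2
    return {ids[idx]: ("supported_first" if pos < n_first
                       else "unsupported_first")
            for pos, idx in enumerate(order)}


def schedule_summary(schedule: ParadigmSchedule) -> str:
    f = schedule.events.frame
    lines = [f"trials: {schedule.n_trials}",
             f"total planned duration: {schedule.total_duration:.1f} s"]
    for typ in ("cross", "prepare_circle", "go_circle"):
        d = f[f["trial_type"] == typ]["duration"]
        lines.append(f"{typ}: mean {d.mean():.2f} s, "
                     f"range {d.min():.1f}-{d.max():.1f} s")
    return "\n".join(lines)
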