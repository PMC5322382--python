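"""Head-motion quality control from rigid-body motion parameters.

"Displacement" here is the Euclidean norm of the three translation
components relative to a reference volume (rotations, if present, are
reported but excluded from the criterion).  A run passes QC when the maximum
per-volume displacement stays under 1 mm — the conventional bound below
which residual motion does not bias activation inference at a 3 mm voxel
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MotionSeries, ValidationError

PASS_THRESHOLD_MM = 1.0


@dataclass
class MotionSummary:
    mean_abs_displacement: float       # mm
    max_abs_displacement: float        # mm
    per_volume_displacement: np.ndarray
    pass_1mm: bool
    reference: str = "first"


def mean_displacement(motion: MotionSeries,
                      reference: str = "first") -> MotionSummary:
    """Per-volume translation magnitude relative to a reference volume.

    ``reference`` is ``first`` (default) or ``middle``.  The mean and max of
    the per-volume displacements summarize the run; ``pass_1mm`` is true iff
    the max stays under 1 mm.
    """
    if motion.n_volumes < 2:
        raise ValidationError("motion QC needs >= 2 volumes")
    if reference == "first":
        ref = motion.translations[0]
    elif reference == "middle":
        ref = motion.translations[motion.n_volumes // 2]
    else:
        raise ValidationError(f"reference must be first/middle, got {reference!r}")
    disp = np.linalg.norm(motion.translations - ref, axis=1)
    mx = float(disp.max())
    return MotionSummary(mean_abs_displacement=float(disp.mean()),
                         max_abs_displacement=mx,
                         per_volume_displacement=disp,
                         pass_1mm=bool(mx < PASS_THRESHOLD_MM),
                         reference=reference)


def frame_displacement(motion: MotionSeries) -> np.ndarray:
    """Frame-to-frame translation magnitudes (the alternative convention;
    reported alongside, not used for the criterion)."""
    return np.linalg.norm(np.diff(motion.translations, axis=0), axis=1)


def qc_report(summaries: dict) -> pd.DataFrame:
    """Group-level motion table: per group/condition mean, SE and range of
    the mean absolute displacement, plus the pass rate — the shape of a
    Results-paragraph head-motion statement.

    ``summaries`` maps a group label to a list of :class:`MotionSummary`.
    """
    if not summaries or all(len(v) == 0 for v in summaries.values()):
        raise ValidationError("qc_report needs at least one summary")
    rows = []
    for group, items in summaries.items():
        if not items:
            raise ValidationError(f"group {group!r} has no summaries")
        vals = np.array([s.mean_abs_displacement for s in items])
        se = (float(np.std(vals, ddof=1)) / np.sqrt(len(vals))
              if len(vals) > 1 else 0.0)
        rows.append({"group": group, "n": len(vals),
                     "mean_mm": float(vals.mean()), "se_mm": se,
                     "min_mm": float(vals.min()), "max_mm": float(vals.max()),
                     "pass_rate": float(np.mean([s.pass_1mm for s in items]))})
    return pd.DataFrame(rows)


def format_qc_report(report: pd.DataFrame) -> str:
    lines = []
    for _, r in report.iterrows():
        lines.append(
            f"{r['group']}: mean displacement {r['mean_mm']:.2f} mm "
            f"(SE = {r['se_mm']:.2f}, range: {r['min_mm']:.2f}-"
            f"{r['max_mm']:.2f}), {r['pass_rate']:.0%} of runs < 1 mm")
    return "\n".join(lines)
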