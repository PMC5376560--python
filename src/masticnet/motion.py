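"""Head-motion quality control.

A subject's motion trace holds six rigid-body parameters over time
(translations in mm, rotations in degrees).  Movement is summarised by the
mean frame-to-frame displacement -- the Euclidean norm of the difference
between consecutive (tx, ty, tz) vectors, and analogously for rotations --
and subjects whose *maximal* displacement reaches 1.5 mm or 1.5 degrees are
excluded (the limit is strict: exactly 1.5 fails).  Only differences between
frames matter, so the indices are invariant to a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as _stats

__all__ = [
    "MotionTrace",
    "MotionSummary",
    "mean_displacement",
    "check_exclusion",
    "compare_group_motion",
]


@dataclass(frozen=True)
class MotionTrace:
    """timepoints x 6 matrix: tx, ty, tz (mm), rx, ry, rz (deg)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 6:
            raise ValueError(f"motion trace must be timepoints x 6, got {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 timepoints")
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite motion parameters")
        data = data.copy()
        data.setflags(write=False)
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class MotionSummary:
    mean_translation_mm: float
    mean_rotation_deg: float
    max_translation_mm: float
    max_rotation_deg: float
    excluded: bool

    def __post_init__(self) -> None:
        if self.max_translation_mm < self.mean_translation_mm - 1e-12:
            raise ValueError("max translation below mean translation")
        if self.max_rotation_deg < self.mean_rotation_deg - 1e-12:
            raise ValueError("max rotation below mean rotation")


def _frame_displacements(trace: MotionTrace) -> tuple[np.ndarray, np.ndarray]:
    diffs = np.diff(trace.data, axis=0)
    trans = np.linalg.norm(diffs[:, :3], axis=1)
    rot = np.linalg.norm(diffs[:, 3:], axis=1)
    return trans, rot


def mean_displacement(trace: MotionTrace) -> tuple[float, float]:
    """Mean frame-to-frame displacement: (translation mm, rotation deg)."""
    trans, rot = _frame_displacements(trace)
    return float(trans.mean()), float(rot.mean())


def check_exclusion(
    trace: MotionTrace, trans_limit: float = 1.5, rot_limit: float = 1.5
) -> MotionSummary:
    """Summarise motion and flag subjects at or beyond the displacement limits."""
    if trans_limit <= 0 or rot_limit <= 0:
        raise ValueError("exclusion limits must be positive")
    trans, rot = _frame_displacements(trace)
    max_t, max_r = float(trans.max()), float(rot.max())
    return MotionSummary(
        mean_translation_mm=float(trans.mean()),
        mean_rotation_deg=float(rot.mean()),
        max_translation_mm=max_t,
        max_rotation_deg=max_r,
        excluded=bool(max_t >= trans_limit or max_r >= rot_limit),
    )


def compare_group_motion(
    summaries_a, summaries_b, modality: str = "translation", mode: str = "welch"
):
    """Two-tailed two-sample t test on mean-displacement indices.

    ``modality`` selects ``"translation"`` (mm) or ``"rotation"`` (deg).
    Returns ``(t, df, p_two_tailed)``.
    """
    if modality not in ("translation", "rotation"):
        raise ValueError("modality must be 'translation' or 'rotation'")
    attr = "mean_translation_mm" if modality == "translation" else "mean_rotation_deg"
    a = np.array([getattr(s, attr) for s in summaries_a], dtype=float)
    b = np.array([getattr(s, attr) for s in summaries_b], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    return _stats.two_sample_t(a, b, mode=mode)
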