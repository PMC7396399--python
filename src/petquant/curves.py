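"""Core data containers and curve utilities.

Time is expressed in minutes everywhere inside the package; readers convert
from whatever unit the file header declares.  Activity concentrations are
stored decay-corrected to injection time (the convention of dynamic PET
time-activity curves); dosimetry re-applies physical decay explicitly where
the physics requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "F18_HALF_LIFE_MIN",
    "TimeActivityCurve",
    "BloodSampleSeries",
    "FrameSchedule",
    "StudyRecord",
    "trapezoid_auc",
    "apply_physical_decay",
    "remove_physical_decay",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

BLOOD_KINDS = ("whole_blood", "plasma", "parent_fraction")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed, decay-corrected activity concentration for one region or organ.

    Parameters
    ----------
    region_id : str
        Region / organ label.
    frame_start, frame_end : array-like, minutes
        Frame boundaries.  Frames must be sorted, non-overlapping and
        strictly positive in duration.
    conc : array-like, kBq·cm⁻³
        Decay-corrected activity concentration per frame.
    """

    region_id: str
    frame_start: np.ndarray
    frame_end: np.ndarray
    conc: np.ndarray

    def __post_init__(self):
        fs = _as_float_array(self.frame_start, "frame_start")
        fe = _as_float_array(self.frame_end, "frame_end")
        c = _as_float_array(self.conc, "conc")
        if not (len(fs) == len(fe) == len(c)) or len(fs) < 1:
            raise ValueError("frame_start, frame_end, conc must share length >= 1")
        if np.any(fe <= fs):
            bad = int(np.nonzero(fe <= fs)[0][0])
            raise ValueError(f"frame_end <= frame_start at frame {bad}")
        if np.any(fs[1:] < fe[:-1] - 1e-9):
            bad = int(np.nonzero(fs[1:] < fe[:-1] - 1e-9)[0][0]) + 1
            raise ValueError(f"frames overlap or are unsorted at frame {bad}")
        object.__setattr__(self, "frame_start", fs)
        object.__setattr__(self, "frame_end", fe)
        object.__setattr__(self, "conc", c)

    @property
    def frame_mid(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def frame_duration(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def n_frames(self) -> int:
        return len(self.conc)

    def truncated(self, duration_min: float) -> "TimeActivityCurve":
        """Keep only frames ending at or before ``duration_min``."""
        keep = self.frame_end <= duration_min + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frames end before {duration_min} min")
        return TimeActivityCurve(
            self.region_id, self.frame_start[keep], self.frame_end[keep], self.conc[keep]
        )

    def auc(self, t0: float, t1: float) -> float:
        """Trapezoidal AUC over [t0, t1] on the frame mid-time samples."""
        return trapezoid_auc(self.frame_mid, self.conc, t0, t1)

    def with_conc(self, conc) -> "TimeActivityCurve":
        return TimeActivityCurve(self.region_id, self.frame_start, self.frame_end, conc)


@dataclass(frozen=True)
class BloodSampleSeries:
    """Discrete arterial samples: whole blood, plasma, or parent fraction."""

    t: np.ndarray
    value: np.ndarray
    kind: str

    def __post_init__(self):
        t = _as_float_array(self.t, "t")
        v = _as_float_array(self.value, "value")
        if len(t) != len(v) or len(t) < 1:
            raise ValueError("t and value must share length >= 1")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be >= 0 and strictly increasing")
        if self.kind not in BLOOD_KINDS:
            raise ValueError(f"kind must be one of {BLOOD_KINDS}, got {self.kind!r}")
        if self.kind == "parent_fraction" and (np.any(v < 0) or np.any(v > 1)):
            raise ValueError("parent_fraction values must lie in [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)

    def auc(self, t0: float, t1: float) -> float:
        return trapezoid_auc(self.t, self.value, t0, t1)


@dataclass(frozen=True)
class FrameSchedule:
    """A dynamic acquisition frame schedule given as frame durations (minutes)."""

    durations: np.ndarray

    def __post_init__(self):
        d = _as_float_array(self.durations, "durations")
        if len(d) < 1 or np.any(d <= 0):
            raise ValueError("durations must be positive")
        object.__setattr__(self, "durations", d)

    @classmethod
    def default_brain(cls) -> "FrameSchedule":
        """123-min brain schedule: 20 s × 9, 1 min × 3, 3 min × 5, 6 min × 17."""
        d = [1.0 / 3] * 9 + [1.0] * 3 + [3.0] * 5 + [6.0] * 17
        return cls(np.array(d))

    @property
    def frame_start(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])

    @property
    def frame_end(self) -> np.ndarray:
        return np.cumsum(self.durations)

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.durations

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.durations))

    @property
    def n_frames(self) -> int:
        return len(self.durations)


@dataclass
class StudyRecord:
    """One subject-session: TACs, blood data, dose and ancillary measurements."""

    subject_id: str
    session: str  # "test" or "retest"
    injected_dose_mbq: float
    tacs: Mapping[str, TimeActivityCurve] = field(default_factory=dict)
    blood: Mapping[str, BloodSampleSeries] = field(default_factory=dict)
    body_weight_kg: Optional[float] = None
    f_p: Optional[float] = None

    def __post_init__(self):
        if self.session not in ("test", "retest"):
            raise ValueError("session must be 'test' or 'retest'")
        if not self.injected_dose_mbq > 0:
            raise ValueError("injected_dose_mbq must be > 0")


def trapezoid_auc(t: Sequence[float], v: Sequence[float], t0: float, t1: float) -> float:
    """Trapezoidal integral of sampled series (t, v) over [t0, t1].

    The endpoints are linearly interpolated; extrapolation beyond the sampled
    support is refused.
    """
    t = _as_float_array(t, "t")
    v = _as_float_array(v, "v")
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError(
            f"[{t0}, {t1}] outside sampled support [{t[0]}, {t[-1]}]; no extrapolation"
        )
    grid = np.unique(np.concatenate([t[(t > t0) & (t < t1)], [t0, t1]]))
    vals = np.interp(grid, t, v)
    return float(np.trapezoid(vals, grid))


def apply_physical_decay(t, value, half_life_min: float = F18_HALF_LIFE_MIN):
    """Convert decay-corrected values back to physical activity.

    value(t) -> value(t) · exp(−ln2 · t / half_life).
    """
    if not half_life_min > 0:
        raise ValueError("half_life_min must be > 0")
    t = np.asarray(t, dtype=float)
    return np.asarray(value, dtype=float) * np.exp(-np.log(2.0) * t / half_life_min)


def remove_physical_decay(t, value, half_life_min: float = F18_HALF_LIFE_MIN):
    """Inverse of :func:`apply_physical_decay` (decay-correct a physical series)."""
    if not half_life_min > 0:
        raise ValueError("half_life_min must be > 0")
    t = np.asarray(t, dtype=float)
    return np.asarray(value, dtype=float) * np.exp(np.log(2.0) * t / half_life_min)
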