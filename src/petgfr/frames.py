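"""Acquisition frame schedules and frame-sampled curves.

Dynamic PET data are reconstructed into contiguous time frames of varying
duration (short frames during the bolus passage, longer ones later).  Every
curve in this package — arterial input, plasma input, cortical and urine
time-activity curves — is sampled on such a schedule, with the frame value
interpreted as the frame-average concentration plotted/fitted at the frame
mid-time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrameSchedule", "SampledCurve", "make_frame_schedule"]


class ValidationError(ValueError):
    """Raised when domain-type invariants are violated."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    starts : array of float
        Frame start times in seconds.
    durations : array of float
        Frame durations in seconds, strictly positive.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.shape != durations.shape or starts.ndim != 1:
            raise ValidationError("starts and durations must be 1-d and equal length")
        if np.any(durations <= 0):
            raise ValidationError("frame durations must be positive")
        if starts.size > 1:
            if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
                raise ValidationError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in seconds (start + duration/2), strictly increasing."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """Total scan duration in seconds."""
        return float(self.durations.sum())

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.durations, other.durations)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.starts.tobytes(), self.durations.tobytes()))


def make_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a schedule from (count, duration-seconds) groups laid out from t = 0.

    ``[(24, 5), (18, 10), (10, 30), (20, 60)]`` is the 72-frame, 30-min
    clinical protocol used throughout this package.
    """
    starts: list[float] = []
    durations: list[float] = []
    t = 0.0
    for count, duration in spec:
        if count < 0:
            raise ValidationError(f"frame count must be >= 0, got {count}")
        if duration <= 0:
            raise ValidationError(f"frame duration must be > 0, got {duration}")
        for _ in range(int(count)):
            starts.append(t)
            durations.append(float(duration))
            t += duration
    return FrameSchedule(np.array(starts), np.array(durations))


#: The clinical 30-min dynamic acquisition protocol: 24x5 s, 18x10 s, 10x30 s, 20x60 s.
DEFAULT_SCHEDULE_SPEC: list[tuple[int, float]] = [(24, 5), (18, 10), (10, 30), (20, 60)]


@dataclass(frozen=True)
class SampledCurve:
    """A curve sampled on a frame schedule (frame-average value per frame)."""

    schedule: FrameSchedule
    values: np.ndarray
    units: str = "kBq/ml"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValidationError(
                f"curve has {values.size} values for {self.schedule.n_frames} frames"
            )

    @property
    def mid_times(self) -> np.ndarray:
        return self.schedule.mid_times

    def scaled(self, factor: float) -> "SampledCurve":
        return SampledCurve(self.schedule, self.values * factor, self.units)

    def with_values(self, values: np.ndarray) -> "SampledCurve":
        return SampledCurve(self.schedule, values, self.units)


def require_same_schedule(*curves: SampledCurve) -> FrameSchedule:
    """Return the common schedule or raise if the curves disagree."""
    schedule = curves[0].schedule
    for c in curves[1:]:
        if c.schedule != schedule:
            raise ValidationError("curves are sampled on different frame schedules")
    return schedule
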