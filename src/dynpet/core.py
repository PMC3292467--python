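"""Core measurement objects: acquisition frame schedules and time-activity curves.

All file I/O is in seconds and Bq/mL; kinetic computations elsewhere in the
package work in minutes.  Tissue density is taken as 1 g/mL, so Bq/mL and
Bq/g are used interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "default_schedule",
    "SECONDS_PER_MINUTE",
]

SECONDS_PER_MINUTE = 60.0

#: CSV column names for TAC files.
TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "activity_bq_per_ml")


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: start times and durations in seconds.

    Frames must be non-overlapping, strictly ordered, and of positive
    duration.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.ndim != 1:
            raise ValueError("frame arrays must be one-dimensional")
        if start.size != dur.size:
            raise ValueError("start and duration arrays must have equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ValueError("frame times must be finite")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[:-1] + dur[:-1] > start[1:] + 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / SECONDS_PER_MINUTE

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / SECONDS_PER_MINUTE

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / SECONDS_PER_MINUTE

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / SECONDS_PER_MINUTE

    @property
    def total_span_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return bool(
            np.array_equal(self.start_s, other.start_s)
            and np.array_equal(self.duration_s, other.duration_s)
        )


def default_schedule() -> FrameSchedule:
    """The default 28-frame, 60-minute dynamic acquisition.

    Ten 30 s frames, five 60 s frames, five 120 s frames, and eight 300 s
    frames, covering [0, 3600] s contiguously; the final frame spans the
    55-60 min window.
    """
    durations = np.concatenate(
        [
            np.full(10, 30.0),
            np.full(5, 60.0),
            np.full(5, 120.0),
            np.full(8, 300.0),
        ]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(start_s=starts, duration_s=durations)


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration (Bq/mL) or SUV on a frame schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    units: str = "Bq/ml"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TAC values must be one-dimensional")
        if self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC has {self.values.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, units: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            schedule=self.schedule,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                TAC_COLUMNS[0]: self.schedule.start_s,
                TAC_COLUMNS[1]: self.schedule.duration_s,
                TAC_COLUMNS[2]: self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        missing = [c for c in TAC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TAC CSV {path} is missing columns: {missing}")
        schedule = FrameSchedule(
            start_s=df[TAC_COLUMNS[0]].to_numpy(float),
            duration_s=df[TAC_COLUMNS[1]].to_numpy(float),
        )
        return cls(schedule=schedule, values=df[TAC_COLUMNS[2]].to_numpy(float))
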