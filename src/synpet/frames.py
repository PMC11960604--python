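"""Frame timing, time-activity curves, window averaging and integral operators.

Dynamic PET data arrive as a sequence of emission frames of varying
duration.  Everything downstream — kinetic fits, Logan plots, SUVR
windows — is clocked by the frame schedule, so this module owns the two
basic containers (:class:`FrameSchedule`, :class:`TimeActivityCurve`) and
the handful of operators every model consumes.

Internal time unit is **minutes**; sidecar files use seconds and are
converted at the boundary.  Kinetic rate constants are conventionally
quoted per minute, so keeping minutes internally avoids unit juggling in
the model code.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "parse_frame_schedule",
    "window_average",
    "cumulative_integral",
    "volume_weighted_mean",
]


class ScheduleError(ValueError):
    """Raised for malformed or inconsistent frame schedules."""


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition timing, in seconds from injection.

    Parameters
    ----------
    starts:
        Frame start times (s).  Must begin at 0 and be non-decreasing.
    durations:
        Frame durations (s), all positive.
    truncated:
        Set when the schedule is a deliberately shortened acquisition
        (subjects who left the scanner early); contiguity is still
        required, the flag only records provenance.
    """

    starts: np.ndarray
    durations: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or durations.shape != starts.shape:
            raise ScheduleError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ScheduleError("schedule must contain at least one frame")
        if durations.min() <= 0:
            raise ScheduleError("all frame durations must be positive")
        if starts[0] != 0:
            raise ScheduleError(f"first frame must start at 0 s, got {starts[0]}")
        if np.any(np.diff(starts) < 0):
            raise ScheduleError("frame starts must be non-decreasing")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise ScheduleError("frames must be contiguous (start[i+1] == start[i] + duration[i])")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def total_seconds(self) -> float:
        return float(self.starts[-1] + self.durations[-1])

    @property
    def total_minutes(self) -> float:
        return self.total_seconds / 60.0

    def mid_times(self) -> np.ndarray:
        """Frame midpoints in minutes: ``(start + duration/2) / 60``."""
        return (self.starts + self.durations / 2.0) / 60.0

    def frame_edges_minutes(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) of every frame, in minutes."""
        return self.starts / 60.0, (self.starts + self.durations) / 60.0

    def duration_weights(self) -> np.ndarray:
        """Default frame weights, proportional to duration (longer frames
        average more counts and carry lower variance)."""
        w = self.durations / self.durations.sum()
        return w * len(self)  # mean weight 1, convenient for SSE scales

    def truncate(self, n_frames: int) -> "FrameSchedule":
        """Drop trailing frames (incomplete acquisitions)."""
        if not 1 <= n_frames <= len(self):
            raise ScheduleError(f"cannot truncate schedule of {len(self)} frames to {n_frames}")
        return FrameSchedule(self.starts[:n_frames].copy(),
                             self.durations[:n_frames].copy(),
                             truncated=n_frames < len(self))

    def format(self) -> str:
        """Compact ``countxduration`` text form; inverse of
        :func:`parse_frame_schedule`."""
        tokens: list[str] = []
        durs = self.durations
        i = 0
        while i < len(durs):
            j = i
            while j < len(durs) and durs[j] == durs[i]:
                j += 1
            tokens.append(f"{j - i}x{durs[i]:g}")
            i = j
        return ",".join(tokens)

    # ---- sidecar I/O -------------------------------------------------
    def to_sidecar(self, path) -> None:
        """Write a frame-timing sidecar (JSON or TSV by extension)."""
        path = str(path)
        if path.endswith(".json"):
            with open(path, "w") as fh:
                json.dump({"frame_starts_s": self.starts.tolist(),
                           "frame_durations_s": self.durations.tolist()}, fh, indent=1)
        else:
            pd.DataFrame({"frame_index": np.arange(len(self)),
                          "start_s": self.starts,
                          "duration_s": self.durations}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_sidecar(cls, path) -> "FrameSchedule":
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                d = json.load(fh)
            return cls(np.asarray(d["frame_starts_s"], float),
                       np.asarray(d["frame_durations_s"], float))
        df = pd.read_csv(path, sep="\t").sort_values("frame_index")
        return cls(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


# The 90-min, 35-frame dynamic acquisition used throughout the examples
# and the synthetic cohort.
DEFAULT_SCHEDULE_SPEC = "4x15,8x30,9x60,2x180,10x300,2x600"

_TOKEN_RE = re.compile(r"^(\d+)x(\d+(?:\.\d+)?)$")


def parse_frame_schedule(spec: str) -> FrameSchedule:
    """Parse a compact ``countxduration_s`` schedule description.

    ``"4x15,8x30,9x60,2x180,10x300,2x600"`` describes the standard
    90-minute, 35-frame dynamic acquisition: 4 frames of 15 s, 8 of
    30 s, and so on, contiguous from injection.

    Raises
    ------
    ScheduleError
        Naming the offending token if any token is malformed or
        non-positive.
    """
    durations: list[float] = []
    for token in str(spec).split(","):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ScheduleError(f"malformed schedule token {token!r} (expected countxduration)")
        count, dur = int(m.group(1)), float(m.group(2))
        if count <= 0 or dur <= 0:
            raise ScheduleError(f"schedule token {token!r} must have positive count and duration")
        durations.extend([dur] * count)
    durations_arr = np.asarray(durations, float)
    starts = np.concatenate([[0.0], np.cumsum(durations_arr)[:-1]])
    return FrameSchedule(starts, durations_arr)


def default_schedule() -> FrameSchedule:
    """The 35-frame / 90-min acquisition schedule."""
    return parse_frame_schedule(DEFAULT_SCHEDULE_SPEC)


@dataclass
class TimeActivityCurve:
    """Activity concentration versus frame mid-time for one region or voxel.

    ``mid_times`` are minutes post-injection; ``values`` are activity
    concentrations in arbitrary (but consistent) units, e.g. kBq/mL.
    Optional nonnegative per-frame ``weights`` feed weighted least
    squares; when absent, callers default to duration-proportional
    weights derived from the schedule.
    """

    mid_times: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None
    schedule: FrameSchedule | None = None
    voxel_count: int | None = None
    volume_mm3: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.mid_times = np.asarray(self.mid_times, float)
        self.values = np.asarray(self.values, float)
        if self.mid_times.shape != self.values.shape:
            raise ValueError("mid_times and values must have the same length")
        if self.mid_times.size and np.any(np.diff(self.mid_times) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must match values in length")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, values, **kw) -> "TimeActivityCurve":
        return cls(schedule.mid_times(), np.asarray(values, float),
                   schedule=schedule, **kw)

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.mid_times.copy(), self.values * factor,
                                 None if self.weights is None else self.weights.copy(),
                                 self.schedule, self.voxel_count, self.volume_mm3, self.name)

    def effective_weights(self) -> np.ndarray:
        """Frame weights for least squares: explicit weights if set,
        otherwise duration-proportional from the schedule, otherwise
        uniform."""
        if self.weights is not None:
            return self.weights
        if self.schedule is not None:
            return self.schedule.duration_weights()
        return np.ones_like(self.values)


def _window_frame_mask(mid_times: np.ndarray, window) -> np.ndarray:
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError(f"window end must exceed start, got [{t0}, {t1}]")
    return (mid_times >= t0) & (mid_times <= t1)


def window_average(tac: TimeActivityCurve, window, durations=None):
    """Duration-weighted mean activity over frames whose *midpoint* lies
    in ``window = [t0, t1]`` (minutes).

    Midpoint membership matches late-window conventions: on the standard
    35-frame schedule the [70, 90] window captures exactly the two
    600-s frames (mid-times 75 and 85 min).
    """
    mask = _window_frame_mask(tac.mid_times, window)
    if not mask.any():
        raise ValueError(
            f"no frame mid-time falls in window {list(window)}; "
            f"available mid-times (min): {np.round(tac.mid_times, 3).tolist()}")
    if durations is None:
        if tac.schedule is not None:
            durations = tac.schedule.durations
        else:
            durations = np.ones_like(tac.values)
    durations = np.asarray(durations, float)
    w = durations[mask]
    return float(np.sum(tac.values[mask] * w) / np.sum(w))


def window_average_image(frames_4d: np.ndarray, schedule: FrameSchedule, window) -> np.ndarray:
    """Duration-weighted mean frame image over a time window (minutes)."""
    mask = _window_frame_mask(schedule.mid_times(), window)
    if not mask.any():
        raise ValueError(
            f"no frame mid-time falls in window {list(window)}; "
            f"available mid-times (min): {np.round(schedule.mid_times(), 3).tolist()}")
    w = schedule.durations[mask]
    return np.tensordot(frames_4d[..., mask], w, axes=([-1], [0])) / w.sum()


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Per-frame running integral ``int_0^t C dtau`` (min * activity).

    Trapezoid rule over the frame mid-times, with an initial segment
    from (0, 0) to the first midpoint — activity is zero at injection.
    """
    if len(tac) < 1:
        raise ValueError("cumulative_integral requires at least one frame")
    t = np.concatenate([[0.0], tac.mid_times])
    v = np.concatenate([[0.0], tac.values])
    increments = np.diff(t) * (v[:-1] + v[1:]) / 2.0
    return np.cumsum(increments)


def volume_weighted_mean(values, volumes) -> float:
    """Volume-weighted regional average: ``sum(value*volume)/sum(volume)``.

    Used for composite ROIs such as the temporal meta-ROI (entorhinal,
    amygdala, parahippocampal, fusiform, inferior temporal, middle
    temporal), where larger regions should dominate the composite.
    """
    values = np.asarray(values, float)
    volumes = np.asarray(volumes, float)
    if values.size == 0:
        raise ValueError("volume_weighted_mean of an empty region set")
    if values.shape != volumes.shape:
        raise ValueError("values and volumes must align")
    if np.any(volumes <= 0):
        raise ValueError("all ROI volumes must be positive")
    return float(np.sum(values * volumes) / np.sum(volumes))
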