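"""Freezing-behavior scoring from frame-wise activity traces.

The input is a per-frame activity score exported by a video-tracking
system.  Frames at or below a user-set threshold are classified as
inactive; percent freezing is computed over sequential fixed-length
epochs (default 10 s); freezing bouts are maximal inactive runs of at
least ``min_bout_s`` seconds (default 2 s), computed from the unbinned
frame mask rather than from epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from deltapet.errors import InputError

__all__ = [
    "ActivityTrace",
    "FreezingConfig",
    "FreezingResult",
    "score_inactivity",
    "epoch_percent_freezing",
    "detect_bouts",
    "window_mean",
    "pre_post_change",
    "score_trace",
]


@dataclass(frozen=True)
class ActivityTrace:
    """Frame-wise activity scores for one subject and session.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    session : str
        Session label (e.g. ``"F1"``, ``"F2"``, ``"F3"``).
    time_s : ndarray
        Per-frame timestamps in seconds, strictly increasing and
        uniformly spaced (within ``1e-6 / frame_rate``).
    activity_score : ndarray
        Non-negative per-frame activity score, arbitrary units.
    frame_rate : float
        Frames per second.
    """

    subject_id: str
    session: str
    time_s: np.ndarray
    activity_score: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        time_s = np.asarray(self.time_s, dtype=float)
        score = np.asarray(self.activity_score, dtype=float)
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "activity_score", score)
        if time_s.ndim != 1 or score.ndim != 1 or time_s.size != score.size:
            raise InputError("time_s and activity_score must be 1-D and equal length")
        if time_s.size == 0:
            raise InputError("empty trace")
        if self.frame_rate <= 0:
            raise InputError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not np.all(np.isfinite(score)):
            raise InputError("activity scores must be finite")
        if time_s.size > 1:
            dt = np.diff(time_s)
            if np.any(dt <= 0):
                raise InputError("time_s must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-6 / self.frame_rate + 1e-9):
                raise InputError("frame spacing inconsistent with frame_rate")

    @property
    def n_frames(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id: str, session: str,
                   frame_rate: float | None = None) -> "ActivityTrace":
        """Build a trace from a CSV-style table with columns
        ``frame_index, time_s, activity_score``."""
        time_s = frame["time_s"].to_numpy(dtype=float)
        if frame_rate is None:
            if len(time_s) < 2:
                raise InputError("cannot infer frame_rate from a single frame")
            frame_rate = 1.0 / float(np.median(np.diff(time_s)))
        return cls(subject_id=subject_id, session=session, time_s=time_s,
                   activity_score=frame["activity_score"].to_numpy(dtype=float),
                   frame_rate=float(frame_rate))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_index": np.arange(self.n_frames),
            "time_s": self.time_s,
            "activity_score": self.activity_score,
        })


@dataclass(frozen=True)
class FreezingConfig:
    """Scoring parameters.

    ``inactive_at_threshold`` controls the tie rule: by default a frame
    whose score equals the threshold exactly counts as inactive.
    """

    activity_threshold: float = 0.1
    epoch_s: float = 10.0
    min_bout_s: float = 2.0
    pre_window: tuple[float, float] | None = None
    post_window: tuple[float, float] | None = None
    inactive_at_threshold: bool = True

    def __post_init__(self) -> None:
        if self.activity_threshold < 0:
            raise InputError("activity_threshold must be >= 0")
        if self.epoch_s <= 0:
            raise InputError("epoch_s must be > 0")
        if self.min_bout_s <= 0:
            raise InputError("min_bout_s must be > 0")


@dataclass
class FreezingResult:
    """Per-subject scoring output."""

    subject_id: str
    session: str
    inactive: np.ndarray
    epoch_percent: np.ndarray
    partial_epoch_percent: float | None
    bouts: list[tuple[float, float]]
    window_means: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "session": self.session,
            "epoch_percent": [float(v) for v in self.epoch_percent],
            "partial_epoch_percent": self.partial_epoch_percent,
            "bouts": [{"start_s": s, "duration_s": d} for s, d in self.bouts],
            "window_means": self.window_means,
        }


def score_inactivity(trace: ActivityTrace, cfg: FreezingConfig) -> np.ndarray:
    """Boolean inactivity mask: one flag per frame.

    A frame is inactive iff its score is below the threshold (or equal,
    under the default tie rule).
    """
    if cfg.inactive_at_threshold:
        return trace.activity_score <= cfg.activity_threshold
    return trace.activity_score < cfg.activity_threshold


def epoch_percent_freezing(inactive: np.ndarray, frame_rate: float,
                           epoch_s: float = 10.0) -> tuple[np.ndarray, float | None]:
    """Percent of inactive frames per sequential complete epoch.

    Returns ``(epoch_percent, partial)`` where ``partial`` is the
    percentage over the trailing incomplete epoch (``None`` if the trace
    divides evenly).  Partial epochs are excluded from group averages.
    """
    if frame_rate <= 0:
        raise InputError("frame_rate must be > 0")
    inactive = np.asarray(inactive, dtype=bool)
    if inactive.size == 0:
        raise InputError("empty inactivity mask")
    frames_per_epoch = int(round(frame_rate * epoch_s))
    if frames_per_epoch < 1:
        raise InputError("epoch shorter than one frame")
    n_complete = inactive.size // frames_per_epoch
    head = inactive[: n_complete * frames_per_epoch].reshape(n_complete, frames_per_epoch)
    percent = 100.0 * head.mean(axis=1) if n_complete else np.empty(0)
    tail = inactive[n_complete * frames_per_epoch:]
    partial = 100.0 * float(tail.mean()) if tail.size else None
    return percent, partial


def detect_bouts(inactive: np.ndarray, frame_rate: float,
                 min_bout_s: float = 2.0) -> list[tuple[float, float]]:
    """Freezing bouts: maximal inactive runs of at least ``min_bout_s``.

    Returns ``(start_s, duration_s)`` tuples in temporal order, computed
    from the unbinned frame mask.
    """
    if frame_rate <= 0:
        raise InputError("frame_rate must be > 0")
    inactive = np.asarray(inactive, dtype=bool)
    if inactive.size == 0:
        raise InputError("empty inactivity mask")
    padded = np.concatenate(([False], inactive, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    bouts = []
    for s, e in zip(starts, ends):
        duration = (e - s) / frame_rate
        if duration >= min_bout_s - 1e-12:
            bouts.append((s / frame_rate, duration))
    return bouts


def _complete_epochs_in_window(n_epochs: int, epoch_s: float,
                               window: tuple[float, float]) -> np.ndarray:
    start_s, end_s = window
    idx = np.arange(n_epochs)
    e_start = idx * epoch_s
    e_end = (idx + 1) * epoch_s
    return idx[(e_start >= start_s - 1e-9) & (e_end <= end_s + 1e-9)]


def window_mean(epoch_percent: np.ndarray, window: tuple[float, float],
                epoch_s: float = 10.0) -> float:
    """Unweighted mean of the epochs lying fully inside ``window``."""
    epoch_percent = np.asarray(epoch_percent, dtype=float)
    idx = _complete_epochs_in_window(epoch_percent.size, epoch_s, window)
    if idx.size == 0:
        raise InputError(f"window {window} contains no complete epoch")
    return float(epoch_percent[idx].mean())


def pre_post_change(epoch_percent: np.ndarray, pre_window: tuple[float, float],
                    post_window: tuple[float, float], epoch_s: float = 10.0) -> float:
    """Change in percent freezing: post-window mean minus pre-window mean."""
    return window_mean(epoch_percent, post_window, epoch_s) - window_mean(
        epoch_percent, pre_window, epoch_s)


def score_trace(trace: ActivityTrace, cfg: FreezingConfig) -> FreezingResult:
    """Full per-subject scoring: mask, epochs, bouts and window means."""
    inactive = score_inactivity(trace, cfg)
    percent, partial = epoch_percent_freezing(inactive, trace.frame_rate, cfg.epoch_s)
    bouts = detect_bouts(inactive, trace.frame_rate, cfg.min_bout_s)
    windows: dict[str, float] = {}
    if cfg.pre_window is not None:
        windows["pre"] = window_mean(percent, cfg.pre_window, cfg.epoch_s)
    if cfg.post_window is not None:
        windows["post"] = window_mean(percent, cfg.post_window, cfg.epoch_s)
    if "pre" in windows and "post" in windows:
        windows["change"] = windows["post"] - windows["pre"]
    return FreezingResult(subject_id=trace.subject_id, session=trace.session,
                          inactive=inactive, epoch_percent=percent,
                          partial_epoch_percent=partial, bouts=bouts,
                          window_means=windows)
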