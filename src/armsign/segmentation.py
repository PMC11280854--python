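"""Sign start/end detection on continuous two-armband streams.

Detection rules
---------------
* EMG: motion iff the absolute frame-to-frame change on any of the 8
  channels is >= ``emg_threshold`` (default 40 on the device's
  [-127, 128] integer scale).
* IMU: motion iff the absolute value of the mean of the three wrap-aware
  Euler-angle changes (roll, pitch, yaw) is > ``imu_threshold`` degrees
  (default 20).  The literal "mean of the changes" lets opposite-sign angle
  changes cancel; set ``imu_mean_of_abs=True`` for the mean-of-absolute
  variant.
* A segment opens at the first frame (either sensor, either arm) whose
  predicate fires and closes once no predicate on any stream has fired for
  ``pause_ms`` of wall time (at 200 Hz and a 60 ms pause this is 12
  consecutive quiet EMG frames).  Segments shorter than ``min_record_s``
  are discarded with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .kinematics import Quaternion, angular_difference, quaternion_to_euler
from .synth import (
    EMG_FS,
    IMU_FS,
    ArmbandStream,
    EmgFrame,
    ImuFrame,
    Session,
    TwoArmRecording,
)

__all__ = [
    "SegmenterConfig",
    "Segment",
    "emg_motion",
    "imu_motion",
    "segment_stream",
    "min_duration_filter",
    "quiet_frames_to_close",
    "segments_to_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmenterConfig:
    """Motion-detector thresholds and timing settings.

    Defaults mirror the reference interface: EMG change 40, IMU mean Euler
    change 20 degrees, 60 ms movement pause, 0.4 s minimum record time.
    """

    emg_threshold: int = 40
    imu_threshold: float = 20.0
    pause_ms: float = 60.0
    min_record_s: float = 0.4
    imu_mean_of_abs: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.emg_threshold <= 256):
            raise ValueError("emg_threshold must be in [0, 256]")
        if not (0 <= self.imu_threshold <= 360):
            raise ValueError("imu_threshold must be in [0, 360] degrees")
        if not (20 <= self.pause_ms <= 1000):
            raise ValueError("pause_ms must be in [20, 1000]")
        if self.min_record_s < 0:
            raise ValueError("min_record_s must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SegmenterConfig":
        known = {"emg_threshold", "imu_threshold", "pause_ms", "min_record_s", "imu_mean_of_abs"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown segmenter config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class Segment:
    """Half-open [start_t, end_t) window with per-channel sample slices."""

    start_t: float
    end_t: float
    trigger_source: str  # "emg" | "imu" | "both"
    channels: dict[tuple[str, str], tuple[float, np.ndarray]]
    closed_by_pause: bool = True
    label: Optional[str] = None

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t

    def channel_arrays(self) -> dict[tuple[str, str], tuple[float, np.ndarray]]:
        return self.channels


def quiet_frames_to_close(config: SegmenterConfig, fs: float = EMG_FS) -> int:
    """Consecutive quiet frames at rate ``fs`` needed to end a sign.

    With the 60 ms default pause on the 200 Hz EMG stream this is exactly 12
    frames of 5 ms each.
    """
    return int(round(config.pause_ms / 1000.0 * fs))


def emg_motion(
    prev: Union[EmgFrame, np.ndarray],
    curr: Union[EmgFrame, np.ndarray],
    threshold: float,
) -> bool:
    """True iff any of the 8 channels changed by at least ``threshold``."""
    p = prev.values if isinstance(prev, EmgFrame) else np.asarray(prev)
    c = curr.values if isinstance(curr, EmgFrame) else np.asarray(curr)
    if p.shape != c.shape:
        raise ValueError("frames must share the channel layout")
    return bool(np.max(np.abs(c.astype(float) - p.astype(float))) >= threshold)


def imu_motion(
    prev: ImuFrame,
    curr: ImuFrame,
    threshold_deg: float,
    mean_of_abs: bool = False,
) -> bool:
    """True iff the mean wrap-aware Euler-angle change exceeds ``threshold_deg``."""
    e0 = quaternion_to_euler(prev.orientation)
    e1 = quaternion_to_euler(curr.orientation)
    deltas = [
        angular_difference(e0.roll, e1.roll),
        angular_difference(e0.pitch, e1.pitch),
        angular_difference(e0.yaw, e1.yaw),
    ]
    if mean_of_abs:
        value = sum(abs(d) for d in deltas) / 3.0
    else:
        value = abs(sum(deltas) / 3.0)
    return value > threshold_deg


def _euler_series(quat: np.ndarray) -> np.ndarray:
    out = np.empty((len(quat), 3))
    for i, row in enumerate(quat):
        e = quaternion_to_euler(Quaternion(*row))
        out[i] = e.as_tuple()
    return out


def _imu_motion_flags(quat: np.ndarray, config: SegmenterConfig) -> np.ndarray:
    """Vector of predicate values for frames 1..m-1 (vs previous frame)."""
    if len(quat) < 2:
        return np.zeros(0, dtype=bool)
    eul = _euler_series(quat)
    d = eul[1:] - eul[:-1]
    d = np.mod(d + 180.0, 360.0) - 180.0
    d[d == -180.0] = 180.0
    if config.imu_mean_of_abs:
        value = np.mean(np.abs(d), axis=1)
    else:
        value = np.abs(np.mean(d, axis=1))
    return value > config.imu_threshold


def _emg_motion_flags(emg: np.ndarray, threshold: float) -> np.ndarray:
    if len(emg) < 2:
        return np.zeros(0, dtype=bool)
    diffs = np.abs(np.diff(emg.astype(float), axis=0))
    return np.max(diffs, axis=1) >= threshold


def segment_stream(
    session: Union[Session, tuple[ArmbandStream, ArmbandStream]],
    config: Optional[SegmenterConfig] = None,
) -> list[Segment]:
    """Detect sign segments in a pair of continuous armband streams.

    Causal single pass: predicates are evaluated per stream at its own rate;
    the pause clock is wall time and requires every sensor on both arms to
    stay quiet for the full window.  A segment still open at end of stream
    is closed there with ``closed_by_pause=False``.
    """
    config = config or SegmenterConfig()
    if isinstance(session, Session):
        left, right = session.left, session.right
    else:
        left, right = session

    # (t, is_motion, source) events for every frame-to-frame comparison
    events: list[tuple[float, bool, str]] = []
    for arm in (left, right):
        for t in (arm.emg_t, arm.imu_t):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("misordered timestamps in input stream")
        eflags = _emg_motion_flags(arm.emg, config.emg_threshold)
        for i, flag in enumerate(eflags):
            events.append((float(arm.emg_t[i + 1]), bool(flag), "emg"))
        iflags = _imu_motion_flags(arm.quat, config)
        for i, flag in enumerate(iflags):
            events.append((float(arm.imu_t[i + 1]), bool(flag), "imu"))
    # at equal timestamps process motion before quiet so a motion frame
    # arriving exactly at the pause boundary extends the segment
    events.sort(key=lambda e: (e[0], not e[1]))

    pause_s = config.pause_ms / 1000.0
    emg_dt = 1.0 / EMG_FS
    raw: list[tuple[float, float, str, bool]] = []
    open_start: Optional[float] = None
    open_prev_t: Optional[float] = None
    last_motion_t: Optional[float] = None
    sources: set[str] = set()

    def close(end_motion_t: float, by_pause: bool) -> None:
        nonlocal open_start, last_motion_t, sources
        src = "both" if len(sources) == 2 else next(iter(sources))
        raw.append((open_start, end_motion_t + emg_dt, src, by_pause))
        open_start = None
        last_motion_t = None
        sources = set()

    for t, motion, source in events:
        if motion:
            if open_start is None:
                # motion detected comparing this frame to the previous one on
                # its stream; the segment starts at that previous frame
                dt = emg_dt if source == "emg" else 1.0 / IMU_FS
                open_start = t - dt
            last_motion_t = t
            sources.add(source)
        elif open_start is not None and t - last_motion_t >= pause_s - 1e-12:
            close(last_motion_t, by_pause=True)
    if open_start is not None:
        close(last_motion_t, by_pause=False)

    kept: list[Segment] = []
    all_channels = TwoArmRecording(left=left, right=right).channel_arrays()
    for start_t, end_t, src, by_pause in raw:
        seg_channels = {}
        for key, (fs, x) in all_channels.items():
            arm_obj = left if key[0] == "left" else right
            t_arr = arm_obj.emg_t if key[1].startswith("emg") else arm_obj.imu_t
            mask = (t_arr >= start_t - 1e-12) & (t_arr < end_t - 1e-12)
            seg_channels[key] = (fs, x[mask])
        kept.append(Segment(start_t, end_t, src, seg_channels, closed_by_pause=by_pause))
    return min_duration_filter(kept, config.min_record_s)


def min_duration_filter(segments: Sequence[Segment], min_record_s: float) -> list[Segment]:
    """Drop segments shorter than the minimum record time (with a warning)."""
    out = []
    for seg in segments:
        if seg.duration >= min_record_s - 1e-12:
            out.append(seg)
        else:
            logger.warning(
                "discarding %.3f s segment at t=%.3f (< min_record_s=%.3f)",
                seg.duration,
                seg.start_t,
                min_record_s,
            )
    return out


def segments_to_tsv(segments: Sequence[Segment]) -> str:
    """BED-like TSV dump: start_s, end_s, trigger_source, label."""
    lines = ["start_s\tend_s\ttrigger_source\tlabel"]
    for seg in segments:
        lines.append(
            f"{seg.start_t:.6f}\t{seg.end_t:.6f}\t{seg.trigger_source}\t{seg.label or '.'}"
        )
    return "\n".join(lines) + "\n"
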