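"""Seeded synthetic two-armband sessions emulating the wearable device.

Device model: per armband, 8 EMG channels sampled at 200 Hz as integers in
[-127, 128], and an IMU at 50 Hz providing 10 values per frame (3-axis
accelerometer in g, 3-axis gyroscope in rad/s, 4-component orientation
quaternion).  A 1-second two-armband recording therefore holds
``2 * (8*200 + 10*50) = 4200`` raw scalar samples.

Generative model
----------------
EMG: per-channel nonnegative activation envelope (plateau + 1-3 Gaussian
bumps, with 10 ms linear on/off ramps) multiplying a sinusoidal carrier,
plus envelope-gated Gaussian noise scaled by ``noise_level``; rounded and
clipped to the integer range.  At ``noise_level=0`` the output is fully
determined by the template (no dependence on the seed).

IMU: orientation follows a slerp through seeded waypoint rotations that
start and end at identity; gyroscope is the finite-difference body-frame
angular velocity of that trajectory; accelerometer is gravity rotated into
the sensor frame plus small noise.

Sessions place signs sequentially with quiet rest gaps (constant EMG,
frozen orientation) so the segmenter can be exercised end to end against
the returned ground-truth annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .dataset import Dictionary, SignDataset
from .kinematics import EulerAngles, Quaternion, euler_to_quaternion

__all__ = [
    "EMG_FS",
    "IMU_FS",
    "N_EMG_CHANNELS",
    "EMG_MIN",
    "EMG_MAX",
    "EmgFrame",
    "ImuFrame",
    "ArmbandStream",
    "TwoArmRecording",
    "SignTemplate",
    "Session",
    "SegmentAnnotation",
    "make_sign_templates",
    "synthesize_recording",
    "synthesize_session",
    "synthesize_dataset",
]

EMG_FS = 200.0
IMU_FS = 50.0
N_EMG_CHANNELS = 8
EMG_MIN = -127
EMG_MAX = 128

_RAMP_S = 0.010  # envelope on/off ramp
_EMG_NOISE_STD = 20.0
_SPEED_RANGE = (0.8, 1.25)


@dataclass(frozen=True)
class EmgFrame:
    """One 5 ms EMG frame: 8 integer channel values in [-127, 128]."""

    t: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (N_EMG_CHANNELS,):
            raise ValueError("EMG frame must hold exactly 8 channel values")
        if v.min() < EMG_MIN or v.max() > EMG_MAX:
            raise ValueError("EMG values outside [-127, 128]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ImuFrame:
    """One 20 ms IMU frame: accel (g), gyro (rad/s), unit orientation quaternion."""

    t: float
    accel: np.ndarray
    gyro: np.ndarray
    orientation: Quaternion

    def __post_init__(self) -> None:
        a = np.asarray(self.accel, dtype=float)
        g = np.asarray(self.gyro, dtype=float)
        if a.shape != (3,) or g.shape != (3,):
            raise ValueError("accel and gyro must be 3-vectors")
        object.__setattr__(self, "accel", a)
        object.__setattr__(self, "gyro", g)


@dataclass
class ArmbandStream:
    """Time-aligned EMG (200 Hz) and IMU (50 Hz) buffers for one armband.

    EMG is an ``(n, 8)`` integer array, IMU arrays are ``(m, 3/3/4)`` with the
    quaternion stored as ``(w, x, y, z)`` rows.
    """

    device_id: str  # "left" | "right"
    emg_t: np.ndarray
    emg: np.ndarray
    imu_t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        if self.device_id not in ("left", "right"):
            raise ValueError("device_id must be 'left' or 'right'")
        self.emg_t = np.asarray(self.emg_t, dtype=float)
        self.emg = np.asarray(self.emg)
        self.imu_t = np.asarray(self.imu_t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.emg.shape != (len(self.emg_t), N_EMG_CHANNELS):
            raise ValueError("EMG buffer shape mismatch")
        if not (len(self.imu_t) == len(self.accel) == len(self.gyro) == len(self.quat)):
            raise ValueError("IMU buffer length mismatch")
        for t in (self.emg_t, self.imu_t):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_emg(self) -> int:
        return len(self.emg_t)

    @property
    def n_imu(self) -> int:
        return len(self.imu_t)

    def emg_frames(self) -> Iterator[EmgFrame]:
        for t, row in zip(self.emg_t, self.emg):
            yield EmgFrame(float(t), row)

    def imu_frames(self) -> Iterator[ImuFrame]:
        for t, a, g, q in zip(self.imu_t, self.accel, self.gyro, self.quat):
            yield ImuFrame(float(t), a, g, Quaternion(*q))

    @property
    def raw_scalar_count(self) -> int:
        return self.n_emg * N_EMG_CHANNELS + self.n_imu * 10


@dataclass
class TwoArmRecording:
    """One labelled sign recording from both armbands."""

    left: ArmbandStream
    right: ArmbandStream
    label: Optional[str] = None
    repetition: Optional[int] = None

    @property
    def duration(self) -> float:
        return max(
            self.left.emg_t[-1] + 1.0 / EMG_FS if self.left.n_emg else 0.0,
            self.left.imu_t[-1] + 1.0 / IMU_FS if self.left.n_imu else 0.0,
        )

    @property
    def raw_scalar_count(self) -> int:
        return self.left.raw_scalar_count + self.right.raw_scalar_count

    def channel_arrays(self) -> dict[tuple[str, str], tuple[float, np.ndarray]]:
        """Map of (device, channel) -> (sampling rate, 1-D samples).

        Channel names: ``emg0..emg7``, ``acc_x/y/z``, ``gyro_x/y/z``,
        ``quat_w/x/y/z`` — the layout every downstream stage keys on.
        """
        out: dict[tuple[str, str], tuple[float, np.ndarray]] = {}
        for arm in (self.left, self.right):
            d = arm.device_id
            for c in range(N_EMG_CHANNELS):
                out[(d, f"emg{c}")] = (EMG_FS, arm.emg[:, c].astype(float))
            for i, ax in enumerate("xyz"):
                out[(d, f"acc_{ax}")] = (IMU_FS, arm.accel[:, i])
            for i, ax in enumerate("xyz"):
                out[(d, f"gyro_{ax}")] = (IMU_FS, arm.gyro[:, i])
            for i, comp in enumerate("wxyz"):
                out[(d, f"quat_{comp}")] = (IMU_FS, arm.quat[:, i])
        return out


@dataclass(frozen=True)
class SegmentAnnotation:
    """Ground-truth [start, end) window of one sign within a session."""

    start_t: float
    end_t: float
    word: str


@dataclass
class Session:
    """Continuous two-armband streams with ground-truth sign annotations."""

    left: ArmbandStream
    right: ArmbandStream
    annotations: list[SegmentAnnotation]


@dataclass
class _EmgChannelParams:
    plateau: float
    carrier_hz: float
    phase: float
    bumps: list[tuple[float, float, float]]  # (center_frac, width_frac, amplitude)


@dataclass
class SignTemplate:
    """Seeded per-sign generator parameters (16 EMG channels + 2 arm trajectories)."""

    word: str
    duration_s: float
    emg_channels: list[_EmgChannelParams]  # 8 left then 8 right
    waypoints_left: list[EulerAngles]  # identity-bracketed
    waypoints_right: list[EulerAngles]

    def __post_init__(self) -> None:
        if self.duration_s < 0.4:
            raise ValueError("nominal duration must be >= minimum record time (0.4 s)")
        if len(self.emg_channels) != 2 * N_EMG_CHANNELS:
            raise ValueError("need 16 EMG channel parameter sets")
        for ch in self.emg_channels:
            if ch.plateau < 0 or any(b[2] < 0 for b in ch.bumps):
                raise ValueError("envelopes must be nonnegative")

    def to_params(self) -> dict:
        """Serializable parameter dump (used for distinctness checks and JSON)."""
        return {
            "word": self.word,
            "duration_s": self.duration_s,
            "emg_channels": [
                {
                    "plateau": ch.plateau,
                    "carrier_hz": ch.carrier_hz,
                    "phase": ch.phase,
                    "bumps": [list(b) for b in ch.bumps],
                }
                for ch in self.emg_channels
            ],
            "waypoints_left": [list(e.as_tuple()) for e in self.waypoints_left],
            "waypoints_right": [list(e.as_tuple()) for e in self.waypoints_right],
        }


def _draw_template(word: str, rng: np.random.Generator) -> SignTemplate:
    duration = float(rng.uniform(0.8, 1.4))
    channels: list[_EmgChannelParams] = []
    for c in range(2 * N_EMG_CHANNELS):
        n_bumps = int(rng.integers(1, 4))
        bumps = [
            (
                float(rng.uniform(0.15, 0.85)),
                float(rng.uniform(0.05, 0.20)),
                float(rng.uniform(0.0, 35.0)),
            )
            for _ in range(n_bumps)
        ]
        # channel 0 of each arm gets phase 0 so the carrier delta is maximal at
        # sign onset and the EMG predicate fires within the first frames
        phase = 0.0 if c % N_EMG_CHANNELS == 0 else float(rng.uniform(0.0, 2 * math.pi))
        channels.append(
            _EmgChannelParams(
                plateau=float(rng.uniform(55.0, 95.0)),
                carrier_hz=float(rng.uniform(30.0, 55.0)),
                phase=phase,
                bumps=bumps,
            )
        )

    def draw_waypoints() -> list[EulerAngles]:
        n_mid = int(rng.integers(1, 3))
        mid = [
            EulerAngles(
                float(rng.uniform(-60, 60)),
                float(rng.uniform(-45, 45)),
                float(rng.uniform(-60, 60)),
            )
            for _ in range(n_mid)
        ]
        ident = EulerAngles(0.0, 0.0, 0.0)
        return [ident, *mid, ident]

    return SignTemplate(word, duration, channels, draw_waypoints(), draw_waypoints())


def make_sign_templates(n_signs: int, seed: int, words: Optional[Sequence[str]] = None) -> list[SignTemplate]:
    """Draw ``n_signs`` distinct seeded sign templates.

    Words default to ``sign000, sign001, ...``; pass ``words`` to attach a
    real dictionary.
    """
    if n_signs < 1:
        raise ValueError("n_signs must be >= 1")
    if words is not None and len(words) != n_signs:
        raise ValueError("words must match n_signs")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_signs):
        word = words[i] if words is not None else f"sign{i:03d}"
        out.append(_draw_template(word, rng))
    return out


def _envelope(ch: _EmgChannelParams, frac: np.ndarray, duration: float) -> np.ndarray:
    env = np.full_like(frac, ch.plateau)
    for center, width, amp in ch.bumps:
        env = env + amp * np.exp(-0.5 * ((frac - center) / width) ** 2)
    t = frac * duration
    ramp = np.minimum(1.0, np.minimum(t / _RAMP_S, (duration - t) / _RAMP_S))
    return env * np.clip(ramp, 0.0, 1.0)


def _slerp_trajectory(waypoints: list[EulerAngles], frac: np.ndarray) -> Rotation:
    quats = [euler_to_quaternion(e) for e in waypoints]
    xyzw = np.array([[q.x, q.y, q.z, q.w] for q in quats])
    times = np.linspace(0.0, 1.0, len(waypoints))
    slerp = Slerp(times, Rotation.from_quat(xyzw))
    return slerp(np.clip(frac, 0.0, 1.0))


def _render_arm(
    template: SignTemplate,
    arm: str,
    duration: float,
    noise_level: float,
    rng: np.random.Generator,
    n_emg: int,
    n_imu: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render one arm's raw buffers for one sign of the given duration."""
    lo = 0 if arm == "left" else N_EMG_CHANNELS
    t_emg = np.arange(n_emg) / EMG_FS
    frac_emg = t_emg / duration
    emg = np.empty((n_emg, N_EMG_CHANNELS))
    for c in range(N_EMG_CHANNELS):
        ch = template.emg_channels[lo + c]
        env = _envelope(ch, frac_emg, duration)
        carrier = np.sin(2 * math.pi * ch.carrier_hz * t_emg + ch.phase)
        noise = rng.standard_normal(n_emg)
        emg[:, c] = env * carrier + noise_level * (env / ch.plateau) * _EMG_NOISE_STD * noise
    emg = np.clip(np.rint(emg), EMG_MIN, EMG_MAX).astype(np.int16)

    t_imu = np.arange(n_imu) / IMU_FS
    waypoints = template.waypoints_left if arm == "left" else template.waypoints_right
    if noise_level > 0:
        jitter = Rotation.from_rotvec(
            noise_level * np.radians(8.0) * rng.standard_normal((len(waypoints) - 2, 3))
        )
        mids = [
            Rotation.from_quat(_xyzw(euler_to_quaternion(e))) * j
            for e, j in zip(waypoints[1:-1], jitter)
        ]
        rots = _compose_waypoints(waypoints, mids)
    else:
        rots = None
    frac_imu = t_imu / duration
    if rots is None:
        traj = _slerp_trajectory(waypoints, frac_imu)
    else:
        times = np.linspace(0.0, 1.0, len(waypoints))
        traj = Slerp(times, rots)(np.clip(frac_imu, 0.0, 1.0))

    quat_xyzw = traj.as_quat()
    quat = np.column_stack([quat_xyzw[:, 3], quat_xyzw[:, :3]])
    # keep a consistent hemisphere so per-component time series are smooth
    flips = np.sign(np.sum(quat[1:] * quat[:-1], axis=1))
    flips[flips == 0] = 1.0
    quat[1:] *= np.cumprod(flips)[:, None]

    gyro = np.zeros((n_imu, 3))
    if n_imu > 1:
        rel = traj[:-1].inv() * traj[1:]
        gyro[:-1] = rel.as_rotvec() * IMU_FS
        gyro[-1] = gyro[-2]
    accel = traj.inv().apply(np.array([0.0, 0.0, 1.0]))
    accel = accel + noise_level * 0.05 * rng.standard_normal((n_imu, 3))
    return emg, accel, gyro, quat


def _xyzw(q: Quaternion) -> np.ndarray:
    return np.array([q.x, q.y, q.z, q.w])


def _compose_waypoints(waypoints: list[EulerAngles], mids: list[Rotation]) -> Rotation:
    ident = Rotation.identity()
    seq = [ident] + mids + [ident]
    return Rotation.concatenate(seq)


def synthesize_recording(
    template: SignTemplate,
    speed_factor: float = 1.0,
    noise_level: float = 0.0,
    seed: int = 0,
) -> TwoArmRecording:
    """Render one sign as a standalone two-armband recording.

    ``speed_factor`` time-warps the template (duration = nominal / factor);
    ``noise_level`` scales every stochastic term, so 0 gives a fully
    template-determined output regardless of the seed.
    """
    if not (speed_factor > 0):
        raise ValueError("speed_factor must be positive")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    duration = template.duration_s / speed_factor
    n_emg = int(round(EMG_FS * duration))
    n_imu = int(round(IMU_FS * duration))
    rng = np.random.default_rng(seed)
    arms = {}
    for arm in ("left", "right"):
        emg, accel, gyro, quat = _render_arm(template, arm, duration, noise_level, rng, n_emg, n_imu)
        arms[arm] = ArmbandStream(
            device_id=arm,
            emg_t=np.arange(n_emg) / EMG_FS,
            emg=emg,
            imu_t=np.arange(n_imu) / IMU_FS,
            accel=accel,
            gyro=gyro,
            quat=quat,
        )
    return TwoArmRecording(left=arms["left"], right=arms["right"], label=template.word)


def synthesize_session(
    templates: Sequence[SignTemplate],
    reps: int,
    rest_ms: float = 400.0,
    config: Optional[dict] = None,
    seed: int = 0,
    noise_level: float = 0.25,
) -> Session:
    """Concatenate signs with quiet rest gaps into continuous paired streams.

    ``config`` may carry ``pause_ms`` (the segmenter pause to be used
    downstream); ``rest_ms`` must exceed it so rests are segmentable.
    Rest-gap EMG is exactly constant (zero frame-to-frame delta) and the
    orientation is frozen, so no motion predicate can fire between signs.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pause_ms = float((config or {}).get("pause_ms", 60.0))
    if rest_ms <= pause_ms:
        raise ValueError(f"rest_ms ({rest_ms}) must exceed the segmenter pause ({pause_ms} ms)")
    rng = np.random.default_rng(seed)
    imu_dt = 1.0 / IMU_FS
    rest_n_imu = max(1, int(round(rest_ms / 1000.0 * IMU_FS)))

    emg_chunks = {"left": [], "right": []}
    accel_chunks = {"left": [], "right": []}
    gyro_chunks = {"left": [], "right": []}
    quat_chunks = {"left": [], "right": []}
    annotations: list[SegmentAnnotation] = []

    ident = np.array([1.0, 0.0, 0.0, 0.0])

    def append_rest(n_imu_frames: int) -> None:
        n_emg_frames = 4 * n_imu_frames
        for arm in ("left", "right"):
            emg_chunks[arm].append(np.zeros((n_emg_frames, N_EMG_CHANNELS), dtype=np.int16))
            accel_chunks[arm].append(np.tile(np.array([0.0, 0.0, 1.0]), (n_imu_frames, 1)))
            gyro_chunks[arm].append(np.zeros((n_imu_frames, 3)))
            quat_chunks[arm].append(np.tile(ident, (n_imu_frames, 1)))

    t_cursor = 0.0
    append_rest(rest_n_imu)
    t_cursor += rest_n_imu * imu_dt

    for _ in range(reps):
        for template in templates:
            speed = float(rng.uniform(*_SPEED_RANGE))
            duration = template.duration_s / speed
            n_imu = max(1, int(round(IMU_FS * duration)))
            duration = n_imu * imu_dt  # quantize so both rates stay aligned
            n_emg = 4 * n_imu
            sign_seed = int(rng.integers(0, 2**31))
            sign_rng = np.random.default_rng(sign_seed)
            for arm in ("left", "right"):
                emg, accel, gyro, quat = _render_arm(
                    template, arm, duration, noise_level, sign_rng, n_emg, n_imu
                )
                emg_chunks[arm].append(emg)
                accel_chunks[arm].append(accel)
                gyro_chunks[arm].append(gyro)
                quat_chunks[arm].append(quat)
            annotations.append(SegmentAnnotation(t_cursor, t_cursor + duration, template.word))
            t_cursor += duration
            append_rest(rest_n_imu)
            t_cursor += rest_n_imu * imu_dt

    arms = {}
    for arm in ("left", "right"):
        emg = np.concatenate(emg_chunks[arm])
        n_emg = len(emg)
        n_imu = sum(len(c) for c in quat_chunks[arm])
        arms[arm] = ArmbandStream(
            device_id=arm,
            emg_t=np.arange(n_emg) / EMG_FS,
            emg=emg,
            imu_t=np.arange(n_imu) / IMU_FS,
            accel=np.concatenate(accel_chunks[arm]),
            gyro=np.concatenate(gyro_chunks[arm]),
            quat=np.concatenate(quat_chunks[arm]),
        )
    return Session(left=arms["left"], right=arms["right"], annotations=annotations)


def synthesize_dataset(
    n_signs: int,
    reps: int,
    noise_level: float = 0.25,
    seed: int = 0,
    words: Optional[Sequence[str]] = None,
    speed_range: tuple[float, float] = _SPEED_RANGE,
) -> SignDataset:
    """Balanced labelled dataset: ``n_signs * reps`` standalone recordings.

    Per-recording speed factors are drawn uniformly from ``speed_range``
    (default 0.8-1.25) to emulate natural signing-speed variation.
    """
    if n_signs < 1 or reps < 1:
        raise ValueError("n_signs and reps must be >= 1")
    templates = make_sign_templates(n_signs, seed, words=words)
    rng = np.random.default_rng(seed + 1)
    recordings: list[TwoArmRecording] = []
    for template in templates:
        for rep in range(reps):
            speed = float(rng.uniform(*speed_range))
            rec_seed = int(rng.integers(0, 2**31))
            rec = synthesize_recording(template, speed_factor=speed, noise_level=noise_level, seed=rec_seed)
            rec.repetition = rep
            recordings.append(rec)
    return SignDataset(
        dictionary=Dictionary([t.word for t in templates]),
        recordings=recordings,
    )
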