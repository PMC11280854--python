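"""Orientation math: Euler/quaternion conversions and wrap-aware angle differences.

Convention
----------
Euler angles are intrinsic yaw-pitch-roll (Z-Y-X): roll ``alpha`` about x,
pitch ``beta`` about y, yaw ``gamma`` about z, all in **degrees**.  The
quaternion composition implemented by :func:`euler_to_quaternion` is

    q_w = cos(a/2)cos(b/2)cos(g/2) + sin(a/2)sin(b/2)sin(g/2)
    q_x = sin(a/2)cos(b/2)cos(g/2) - cos(a/2)sin(b/2)sin(g/2)
    q_y = cos(a/2)sin(b/2)cos(g/2) + sin(a/2)cos(b/2)sin(g/2)
    q_z = cos(a/2)cos(b/2)sin(g/2) - sin(a/2)sin(b/2)cos(g/2)

which is the standard aerospace (Tait-Bryan) sign pattern.  Angles are kept
in degrees everywhere outside the trig calls because the motion-detector
threshold is configured in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Quaternion",
    "EulerAngles",
    "euler_to_quaternion",
    "quaternion_to_euler",
    "angular_difference",
]

_GIMBAL_EPS = 1e-6


@dataclass(frozen=True)
class Quaternion:
    """Unit quaternion (w, x, y, z); (1, 0, 0, 0) is the identity rotation."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.w, self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError("quaternion components must be finite")

    @property
    def norm(self) -> float:
        return math.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize a zero-norm quaternion")
        return Quaternion(self.w / n, self.x / n, self.y / n, self.z / n)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w, self.x, self.y, self.z)


@dataclass(frozen=True)
class EulerAngles:
    """Roll/pitch/yaw in degrees.

    Canonical ranges: roll in (-180, 180], pitch in [-90, 90],
    yaw in (-180, 180].
    """

    roll: float
    pitch: float
    yaw: float

    def __post_init__(self) -> None:
        for a in (self.roll, self.pitch, self.yaw):
            if not math.isfinite(a):
                raise ValueError("Euler angles must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.roll, self.pitch, self.yaw)


def euler_to_quaternion(e: EulerAngles) -> Quaternion:
    """Convert intrinsic Z-Y-X Euler angles (degrees) to a unit quaternion."""
    ha = math.radians(e.roll) / 2.0
    hb = math.radians(e.pitch) / 2.0
    hg = math.radians(e.yaw) / 2.0
    ca, sa = math.cos(ha), math.sin(ha)
    cb, sb = math.cos(hb), math.sin(hb)
    cg, sg = math.cos(hg), math.sin(hg)
    q = Quaternion(
        w=ca * cb * cg + sa * sb * sg,
        x=sa * cb * cg - ca * sb * sg,
        y=ca * sb * cg + sa * cb * sg,
        z=ca * cb * sg - sa * sb * cg,
    )
    return q.normalized()


def quaternion_to_euler(q: Quaternion) -> EulerAngles:
    """Invert :func:`euler_to_quaternion`, returning canonical angles in degrees.

    At gimbal lock (|sin(pitch)| within 1e-6 of 1) roll is set to 0 and yaw
    absorbs the remaining rotation about the vertical axis.
    """
    q = q.normalized()
    w, x, y, z = q.w, q.x, q.y, q.z
    sin_pitch = 2.0 * (w * y - x * z)
    if abs(sin_pitch) >= 1.0 - _GIMBAL_EPS:
        pitch = math.copysign(90.0, sin_pitch)
        roll = 0.0
        if sin_pitch > 0:
            yaw = math.degrees(2.0 * math.atan2(-x, w))
        else:
            yaw = math.degrees(2.0 * math.atan2(x, w))
    else:
        pitch = math.degrees(math.asin(sin_pitch))
        roll = math.degrees(math.atan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y)))
        yaw = math.degrees(math.atan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z)))
    return EulerAngles(_canonical_half_open(roll), pitch, _canonical_half_open(yaw))


def _canonical_half_open(angle_deg: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    a = math.fmod(angle_deg, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def angular_difference(a: float, b: float) -> float:
    """Signed shortest angular distance from ``a`` to ``b``, in (-180, 180].

    The antipodal tie (|b - a| = 180 mod 360) resolves to +180 because the
    range is half-open.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("angles must be finite")
    return _canonical_half_open(b - a)
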