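"""Denavit-Hartenberg model and forward kinematics of the 6-DOF arm chain.

The chain runs from the sternoclavicular joint (point O, the base) through
the clavicle to the glenohumeral joint (point S), down the upper arm to the
humeroulnar joint (point E) and along the forearm to the wrist centre
(point EE, the end effector).  Six revolute joints articulate it:

========  =============================================  ==================
joint     anatomical meaning                             chain location
========  =============================================  ==================
theta_1   horizontal rotation of the clavicle            base (point O)
theta_2   vertical rotation of the clavicle              base (point O)
theta_3   shoulder roll                                  shoulder (point S)
theta_4   shoulder pitch (abduction/adduction driver)    shoulder (point S)
theta_5   shoulder yaw / humeral axial rotation          shoulder (point S)
theta_6   elbow flexion/extension                        elbow (point E)
========  =============================================  ==================

Only three link constants are non-zero: the clavicle length ``l2`` (link
length of joint 2), the upper-arm length ``d5`` (link offset of joint 5) and
the forearm length ``l6`` (link length of joint 6).  The classic (distal)
Denavit-Hartenberg convention is used throughout; angles are radians and
lengths millimetres.

Base frame convention: origin at point O, +X lateral toward the instrumented
arm, +Z superior (gravity-up), +Y completing a right-handed frame.  This
makes the anatomical branch rules of the inverse kinematics (``Xc > 0``,
``Zc > 0``) literal coordinate-sign tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "DHRow",
    "DH_TABLE",
    "ArmGeometry",
    "link_length",
    "dh_transform",
    "forward_kinematics",
    "FKChain",
    "rotation_of",
    "position_of",
    "rigid_inverse",
    "assert_rotation",
    "wrap_angle",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class DHRow:
    """One row of the Denavit-Hartenberg table.

    ``link_offset_d`` and ``link_length_l`` are either a number (millimetres)
    or the name of an :class:`ArmGeometry` attribute (``"l2"``, ``"d5"``,
    ``"l6"``) resolved at evaluation time.  ``link_angle_theta`` is the joint
    variable and therefore not stored here.
    """

    joint_index: int
    link_offset_d: float | str
    link_length_l: float | str
    link_twist_a: float

    def resolve(self, geometry: "ArmGeometry") -> tuple[float, float]:
        """Return numeric (d, l) for this row under ``geometry``."""
        d = getattr(geometry, self.link_offset_d) if isinstance(self.link_offset_d, str) else self.link_offset_d
        l = getattr(geometry, self.link_length_l) if isinstance(self.link_length_l, str) else self.link_length_l
        return float(d), float(l)


#: The six rows of the arm chain.  Offsets are all zero except d5 on joint 5;
#: lengths all zero except l2 on joint 2 and l6 on joint 6; twists alternate
#: (-pi/2, pi/2, -pi/2, pi/2, -pi/2, 0).
DH_TABLE: tuple[DHRow, ...] = (
    DHRow(1, 0.0, 0.0, -_HALF_PI),
    DHRow(2, 0.0, "l2", _HALF_PI),
    DHRow(3, 0.0, 0.0, -_HALF_PI),
    DHRow(4, 0.0, 0.0, _HALF_PI),
    DHRow(5, "d5", 0.0, -_HALF_PI),
    DHRow(6, 0.0, "l6", 0.0),
)


@dataclass(frozen=True)
class ArmGeometry:
    """The three non-zero link constants of the chain, in millimetres.

    Parameters
    ----------
    l2 : float
        Clavicle length (sternoclavicular to glenohumeral joint), > 0.
    d5 : float
        Upper-arm length (glenohumeral to humeroulnar joint), > 0.
    l6 : float
        Forearm length (humeroulnar joint to wrist centre), > 0.
    """

    l2: float
    d5: float
    l6: float

    def __post_init__(self):
        for name in ("l2", "d5", "l6"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name}_mm must be a finite positive length, got {v!r}")

    @property
    def reach(self) -> float:
        """Maximum distance from the base to the end effector."""
        return self.l2 + self.d5 + self.l6

    def elbow_reachable(self, oe: float) -> bool:
        """Whether an elbow at distance ``oe`` from the base closes the
        triangle O-S-E, i.e. ``| oe - d5 | <= l2 <= oe + d5``."""
        return abs(oe - self.d5) <= self.l2 <= oe + self.d5

    @classmethod
    def from_config(cls, path: str | Path) -> "ArmGeometry":
        """Load geometry from a JSON or YAML file with keys l2_mm/d5_mm/l6_mm."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidInputError(f"geometry file {path} does not contain a mapping")
        try:
            return cls(l2=float(data["l2_mm"]), d5=float(data["d5_mm"]), l6=float(data["l6_mm"]))
        except KeyError as exc:
            raise InvalidInputError(f"geometry file {path} is missing key {exc}") from None


def link_length(point_a: Sequence[float], point_b: Sequence[float]) -> float:
    """Euclidean distance between two 3-D points (the link-length formula).

    Segment lengths that vary between subjects (clavicle, humerus, radius)
    are measured as straight-line distances between the estimated joint
    centres and then enter the kinematics as constants.
    """
    a = np.asarray(point_a, dtype=float)
    b = np.asarray(point_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise InvalidInputError("link_length expects two 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("link_length received non-finite coordinates")
    return float(np.linalg.norm(a - b))


def dh_transform(row: DHRow, theta: float, geometry: ArmGeometry) -> np.ndarray:
    """The 4x4 homogeneous transform of one joint in the classic DH form.

    ``[[Ct, -St*Ca,  St*Sa, l*Ct],
       [St,  Ct*Ca, -Ct*Sa, l*St],
       [ 0,     Sa,     Ca,    d],
       [ 0,      0,      0,    1]]``
    """
    if not any(row is r or row == r for r in DH_TABLE):
        raise InvalidInputError(f"unknown DH row (joint index {getattr(row, 'joint_index', '?')})")
    d, l = row.resolve(geometry)
    ct, st = math.cos(theta), math.sin(theta)
    ca, sa = math.cos(row.link_twist_a), math.sin(row.link_twist_a)
    # snap the twist cosines/sines to exact 0/+-1 (twists are multiples of pi/2)
    ca, sa = round(ca), round(sa)
    return np.array(
        [
            [ct, -st * ca, st * sa, l * ct],
            [st, ct * ca, -ct * sa, l * st],
            [0.0, sa, ca, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


@dataclass(frozen=True)
class FKChain:
    """Cumulative transforms T01..T06 of one configuration.

    ``transforms[k]`` is T0(k+1).  Named accessors return the anatomical
    points: the shoulder S is the position of T02, the elbow E the position
    of T05 and the end effector EE the position of T06.
    """

    transforms: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.transforms) != 6:
            raise InvalidInputError("FKChain expects six cumulative transforms")

    def T(self, k: int) -> np.ndarray:
        """Cumulative transform T0k, k = 1..6."""
        if not 1 <= k <= 6:
            raise InvalidInputError("k must be in 1..6")
        return self.transforms[k - 1]

    @property
    def shoulder(self) -> np.ndarray:
        return position_of(self.T(2))

    @property
    def elbow(self) -> np.ndarray:
        return position_of(self.T(5))

    @property
    def end_effector(self) -> np.ndarray:
        return position_of(self.T(6))

    @property
    def pose(self) -> np.ndarray:
        """The end-effector homogeneous transform T06."""
        return self.T(6)


def forward_kinematics(geometry: ArmGeometry, joints: Sequence[float]) -> FKChain:
    """Forward kinematics: all cumulative products T01..T06.

    ``joints`` holds the six joint angles theta_1..theta_6 in radians.
    """
    th = np.asarray(joints, dtype=float)
    if th.shape != (6,):
        raise InvalidInputError("joints must be six angles")
    if not np.all(np.isfinite(th)):
        raise InvalidInputError("joint angles must be finite")
    acc = np.eye(4)
    out = []
    for row, theta in zip(DH_TABLE, th):
        acc = acc @ dh_transform(row, float(theta), geometry)
        out.append(acc)
    return FKChain(tuple(out))


# --- small rigid-transform helpers -----------------------------------------

def rotation_of(T: np.ndarray) -> np.ndarray:
    return np.asarray(T)[:3, :3]


def position_of(T: np.ndarray) -> np.ndarray:
    return np.asarray(T)[:3, 3]


def rigid_inverse(T: np.ndarray) -> np.ndarray:
    """Inverse of a rigid transform computed as (R^T, -R^T p)."""
    R = rotation_of(T)
    p = position_of(T)
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ p
    return out


def assert_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    """Raise if ``R`` is not orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise InvalidInputError("rotation must be a finite 3x3 matrix")
    if np.max(np.abs(R.T @ R - np.eye(3))) > tol or abs(np.linalg.det(R) - 1.0) > tol:
        raise InvalidInputError("matrix is not a proper rotation within tolerance")


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(-a + math.pi, 2.0 * math.pi)
    out = -(w - math.pi)
    return out if out.ndim else float(out)
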