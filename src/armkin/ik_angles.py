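"""Stage 2 of the inverse kinematics: closed-form joint angles theta_1..theta_6.

With the shoulder centre S and elbow centre E known (stage 1), the six
joint angles follow sequentially by equating elements of partial-chain
transforms with the measured end-effector transform:

* theta_1 = atan2(Yc, Xc) and theta_2 = atan2(-Zc, C1*Xc + S1*Yc) come
  straight from the spherical coordinates of S (``Xc = l2*C2*C1``,
  ``Yc = l2*C2*S1``, ``Zc = -l2*S2``).
* theta_3 compares the position columns of ``T02^-1 * T06`` with the
  remaining chain, via the intermediates
  ``a = C1*C2*Px + C2*S1*Py - S2*Pz - l2``, ``b = -S1*Px + C1*Py``,
  ``c = C1*C2*R11 + C2*S1*R21 - S2*R31``, ``d = -S1*R11 + C1*R21``:
  ``theta_3 = atan2(b - l6*d, a - l6*c)``.
* theta_4 compares elements (1,3) and (2,3) of ``T03^-1 * T06``:
  ``P = -C4*S5`` and ``Q = -S4*S5``, so ``atan2(Q, P)`` equals theta_4 only
  up to a pi shift whose sign depends on sign(S5).
* theta_5 compares elements (2,1) and (1,1) of ``T04^-1 * T06``
  (= ``S5*C6`` and ``C5*C6``), valid up to pi when ``C6 < 0``.
* theta_6 compares elements (2,1) and (1,1) of ``T05^-1 * T06``
  (= ``S6`` and ``C6``), which is exact with no ambiguity.

The pi-ambiguities of theta_4 and theta_5 are resolved by enumerating the
candidate branch combinations and keeping the one whose forward kinematics
best reproduces the measured pose (:func:`solve_all`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .arm_model import (
    DH_TABLE,
    ArmGeometry,
    dh_transform,
    forward_kinematics,
    rigid_inverse,
    rotation_of,
    wrap_angle,
)
from .errors import InconsistentPoseError, SingularConfigurationError
from .ik_position import (
    EndEffectorPose,
    PositionSolution,
    elbow_from_end_effector,
    perpendicularity_residual,
    solve_shoulder_position,
)

__all__ = [
    "AngleSolution",
    "theta_1_2",
    "theta_3",
    "theta_4",
    "theta_5",
    "theta_6",
    "solve_all",
    "pose_residual",
    "intermediate_identities",
]

#: mm of position error equivalent to 1 rad of rotation error in the
#: branch-selection residual
_ROT_WEIGHT = 100.0


@dataclass
class AngleSolution:
    """Accepted joint angles with branch notes and the pose residual."""

    joints: np.ndarray  # six angles, radians, each in (-pi, pi]
    branch_flags: dict = field(default_factory=dict)
    fk_residual: float = math.nan
    position: PositionSolution | None = None


def _partial_transform(geometry: ArmGeometry, thetas) -> np.ndarray:
    """Cumulative transform T0k for the first ``len(thetas)`` joints."""
    T = np.eye(4)
    for row, th in zip(DH_TABLE, thetas):
        T = T @ dh_transform(row, float(th), geometry)
    return T


def theta_1_2(shoulder: np.ndarray, l2: float) -> tuple[float, float]:
    """Clavicle angles from the shoulder centre.

    ``theta_1 = atan2(Yc, Xc)``; ``theta_2 = atan2(-Zc, C1*Xc + S1*Yc)``.
    Undefined when the shoulder lies on the base z-axis.
    """
    xc, yc, zc = np.asarray(shoulder, dtype=float).reshape(3)
    if math.hypot(xc, yc) < 1e-9 * l2:
        raise SingularConfigurationError(
            "shoulder lies on the base z-axis; theta_1 is undefined"
        )
    th1 = math.atan2(yc, xc)
    th2 = math.atan2(-zc, math.cos(th1) * xc + math.sin(th1) * yc)
    return wrap_angle(th1), wrap_angle(th2)


def _abcd(pose: EndEffectorPose, th1: float, th2: float, l2: float):
    c1, s1 = math.cos(th1), math.sin(th1)
    c2, s2 = math.cos(th2), math.sin(th2)
    px, py, pz = pose.position
    r11, r21, r31 = pose.rotation[:, 0]
    a = c1 * c2 * px + c2 * s1 * py - s2 * pz - l2
    b = -s1 * px + c1 * py
    c = c1 * c2 * r11 + c2 * s1 * r21 - s2 * r31
    d = -s1 * r11 + c1 * r21
    return a, b, c, d


def theta_3(pose: EndEffectorPose, th1: float, th2: float, geometry: ArmGeometry) -> float:
    """Shoulder roll: ``atan2(b - l6*d, a - l6*c)``.

    The pair ``(a - l6*c, b - l6*d)`` is the elbow position expressed in
    frame 2; it vanishes when the elbow lies on the axis of joint 3
    (sin(theta_4) = 0), where the roll is indeterminate.
    """
    a, b, c, d = _abcd(pose, th1, th2, geometry.l2)
    y = b - geometry.l6 * d
    x = a - geometry.l6 * c
    if math.hypot(x, y) < 1e-9 * geometry.d5:
        raise SingularConfigurationError(
            "elbow lies on the joint-3 axis (sin theta_4 ~ 0); theta_3 is indeterminate"
        )
    return wrap_angle(math.atan2(y, x))


def theta_4(pose: EndEffectorPose, th1: float, th2: float, th3: float, geometry: ArmGeometry) -> float:
    """Shoulder pitch from ``atan2(Q, P)`` with ``P = -C4*S5``, ``Q = -S4*S5``.

    Returns theta_4 directly when sin(theta_5) < 0 and theta_4 +- pi when
    sin(theta_5) > 0; :func:`solve_all` resolves the shift.  Both arguments
    vanish at the wrist singularity sin(theta_5) = 0.
    """
    M = rigid_inverse(_partial_transform(geometry, (th1, th2, th3))) @ pose.as_matrix()
    P = M[0, 2]
    Q = M[1, 2]
    if math.hypot(P, Q) < 1e-8:
        raise SingularConfigurationError(
            "wrist singularity (sin theta_5 ~ 0): theta_4 is indeterminate"
        )
    return wrap_angle(math.atan2(Q, P))


def theta_5(
    pose: EndEffectorPose,
    th1: float,
    th2: float,
    th3: float,
    th4: float,
    geometry: ArmGeometry,
) -> float:
    """Humeral axial rotation from the ``(S5*C6, C5*C6)`` element pair of
    ``T04^-1 * T06``; valid up to pi when cos(theta_6) < 0, degenerate when
    cos(theta_6) ~ 0."""
    M = rigid_inverse(_partial_transform(geometry, (th1, th2, th3, th4))) @ pose.as_matrix()
    y = M[1, 0]  # S5*C6
    x = M[0, 0]  # C5*C6
    if math.hypot(x, y) < 1e-8:
        raise SingularConfigurationError(
            "cos(theta_6) ~ 0 makes the theta_5 element pair degenerate"
        )
    return wrap_angle(math.atan2(y, x))


def theta_6(
    pose: EndEffectorPose,
    th1: float,
    th2: float,
    th3: float,
    th4: float,
    th5: float,
    geometry: ArmGeometry,
) -> float:
    """Elbow flexion from the exact ``(S6, C6)`` element pair of ``T05^-1 * T06``."""
    M = rigid_inverse(_partial_transform(geometry, (th1, th2, th3, th4, th5))) @ pose.as_matrix()
    return wrap_angle(math.atan2(M[1, 0], M[0, 0]))


def pose_residual(T_a: np.ndarray, T_b: np.ndarray, rot_weight: float = _ROT_WEIGHT) -> float:
    """Mixed pose distance: position error (mm) + weighted geodesic rotation
    angle (rad).  Used to rank branch candidates."""
    dp = float(np.linalg.norm(T_a[:3, 3] - T_b[:3, 3]))
    Rrel = rotation_of(T_a).T @ rotation_of(T_b)
    c = (np.trace(Rrel) - 1.0) / 2.0
    # atan2 form of the geodesic angle: full precision near zero, where
    # acos((tr-1)/2) would bottom out at ~1e-8 rad
    s = 0.5 * math.sqrt(
        (Rrel[2, 1] - Rrel[1, 2]) ** 2
        + (Rrel[0, 2] - Rrel[2, 0]) ** 2
        + (Rrel[1, 0] - Rrel[0, 1]) ** 2
    )
    ang = math.atan2(s, c)
    return dp + rot_weight * ang


def solve_all(
    pose: EndEffectorPose,
    geometry: ArmGeometry,
    residual_tol: float = 1e-6,
    reference_shoulder: np.ndarray | None = None,
) -> AngleSolution:
    """Full closed-form inverse kinematics with branch resolution.

    Runs the stage-1 position solve (``reference_shoulder`` disambiguates
    the rare pose with two anatomically feasible shoulder placements, e.g.
    the previous frame of a trajectory), extracts theta_1..theta_3, then
    enumerates the <= 4 branch combinations from the theta_4 and theta_5
    pi-ambiguities.  Each candidate is pushed through the forward model and
    the one minimizing the pose residual is returned; for exact (noise-free)
    input the winning residual is ~machine precision.

    Raises :class:`InconsistentPoseError` when no candidate reproduces the
    pose within ``residual_tol``; measured (noisy) data needs a loosened
    ``residual_tol``.
    """
    elbow = elbow_from_end_effector(pose, geometry.l6)
    psol = solve_shoulder_position(pose, elbow, geometry, reference_shoulder=reference_shoulder)
    th1, th2 = theta_1_2(psol.shoulder, geometry.l2)
    th3 = theta_3(pose, th1, th2, geometry)
    th4_raw = theta_4(pose, th1, th2, th3, geometry)

    target = pose.as_matrix()
    best: AngleSolution | None = None
    for d4 in (0.0, math.pi):
        th4 = wrap_angle(th4_raw + d4)
        try:
            th5_raw = theta_5(pose, th1, th2, th3, th4, geometry)
            th5_flag = None
        except SingularConfigurationError:
            # cos(theta_6) ~ 0: fall back to the unambiguous (-M[0,2], M[1,2])
            # element pair (= sin theta_5, cos theta_5) of T04^-1 * T06
            M = rigid_inverse(_partial_transform(geometry, (th1, th2, th3, th4))) @ target
            th5_raw = wrap_angle(math.atan2(-M[0, 2], M[1, 2]))
            th5_flag = "theta5_from_unambiguous_pair"
        for d5 in (0.0, math.pi) if th5_flag is None else (0.0,):
            th5 = wrap_angle(th5_raw + d5)
            th6 = theta_6(pose, th1, th2, th3, th4, th5, geometry)
            joints = np.array([th1, th2, th3, th4, th5, th6])
            res = pose_residual(forward_kinematics(geometry, joints).pose, target)
            if best is None or res < best.fk_residual:
                flags = {"theta4_shift": d4 != 0.0, "theta5_shift": d5 != 0.0}
                if th5_flag:
                    flags["theta5_note"] = th5_flag
                best = AngleSolution(joints=joints, branch_flags=flags, fk_residual=res, position=psol)
    assert best is not None
    if best.fk_residual > residual_tol:
        raise InconsistentPoseError(
            f"no branch candidate reproduces the pose (best residual "
            f"{best.fk_residual:.3e} > {residual_tol:.1e}); the pose is not "
            "consistent with the rigid-chain model"
        )
    return best


def intermediate_identities(
    pose: EndEffectorPose, joints: np.ndarray, geometry: ArmGeometry
) -> dict[str, float]:
    """Residuals of every intermediate identity at a recovered joint vector.

    All residuals are dimensionless (lengths normalized by the relevant
    link) and vanish to machine precision when ``pose`` is exactly the
    forward kinematics of ``joints``.  Keys name the constraint:

    - ``es_perp``: (S - E) . z_EE = 0, normalized by l2
    - ``sphere``: |S|^2 - l2^2, normalized by l2^2
    - ``clavicle_xy``: C1*Xc + S1*Yc - l2*C2, normalized by l2
    - ``clavicle_z``: -Zc - l2*S2, normalized by l2
    - ``elbow_frame2_y`` / ``elbow_frame2_x``: l6*C6*S5 = -a*S3 + b*C3 and
      C6*S5 = -c*S3 + d*C3 (frame-2 position/direction comparisons)
    - ``t36_P`` / ``t36_Q``: elements (1,3), (2,3) of T03^-1*T06 vs
      -C4*S5, -S4*S5
    - ``t46_S5C6`` / ``t46_C5C6``: elements (2,1), (1,1) of T04^-1*T06 vs
      S5*C6, C5*C6
    - ``t56_C6`` / ``t56_S6``: elements (1,1), (2,1) of T05^-1*T06 vs C6, S6
    - ``s6c6_unit``: S6^2 + C6^2 - 1 from the measured elements
    """
    th = np.asarray(joints, dtype=float).reshape(6)
    th1, th2, th3, th4, th5, th6 = th
    l2, d5, l6 = geometry.l2, geometry.d5, geometry.l6
    chain = forward_kinematics(geometry, th)
    S = chain.shoulder
    E = elbow_from_end_effector(pose, l6)
    target = pose.as_matrix()

    out: dict[str, float] = {}
    out["es_perp"] = abs(perpendicularity_residual(pose, S, E)) / l2
    out["sphere"] = abs(float(S @ S) - l2**2) / l2**2
    c1, s1 = math.cos(th1), math.sin(th1)
    c2, s2 = math.cos(th2), math.sin(th2)
    xc, yc, zc = S
    out["clavicle_xy"] = abs(c1 * xc + s1 * yc - l2 * c2) / l2
    out["clavicle_z"] = abs(-zc - l2 * s2) / l2
    a, b, c, d = _abcd(pose, th1, th2, l2)
    s3, c3 = math.sin(th3), math.cos(th3)
    s4, c4 = math.sin(th4), math.cos(th4)
    s5, c5 = math.sin(th5), math.cos(th5)
    s6, c6 = math.sin(th6), math.cos(th6)
    out["elbow_frame2_y"] = abs(l6 * c6 * s5 - (-a * s3 + b * c3)) / l6
    out["elbow_frame2_x"] = abs(c6 * s5 - (-c * s3 + d * c3))
    M3 = rigid_inverse(_partial_transform(geometry, th[:3])) @ target
    out["t36_P"] = abs(M3[0, 2] - (-c4 * s5))
    out["t36_Q"] = abs(M3[1, 2] - (-s4 * s5))
    M4 = rigid_inverse(_partial_transform(geometry, th[:4])) @ target
    out["t46_S5C6"] = abs(M4[1, 0] - s5 * c6)
    out["t46_C5C6"] = abs(M4[0, 0] - c5 * c6)
    M5 = rigid_inverse(_partial_transform(geometry, th[:5])) @ target
    out["t56_C6"] = abs(M5[0, 0] - c6)
    out["t56_S6"] = abs(M5[1, 0] - s6)
    out["s6c6_unit"] = abs(M5[0, 0] ** 2 + M5[1, 0] ** 2 - 1.0)
    return out
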