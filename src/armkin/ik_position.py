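"""Stage 1 of the inverse kinematics: elbow and shoulder centre positions.

Given only the measured end-effector pose (position ``P`` and rotation
``R`` of the wrist frame) and the three link constants, the elbow centre E
and the shoulder centre S are reconstructed geometrically:

1.  The forearm lies along the end-effector x-axis, so
    ``E = P - l6 * R[:, 0]``.
2.  The upper arm E-S is perpendicular to the end-effector z-axis
    (a structural property of the chain), giving one plane through S:
    ``R13*Xc + R23*Yc + R33*Zc = alpha`` with ``alpha = R13*Xe + R23*Ye + R33*Ze``.
3.  The interior angle theta_0 of triangle O-S-E at E follows from the law
    of cosines, giving a second plane:
    ``Xe*Xc + Ye*Yc + Ze*Zc = beta`` with
    ``beta = |OE|^2 - d5*|OE|*cos(theta_0) = (|OE|^2 - d5^2 + l2^2) / 2``.
4.  S also lies on the sphere of radius ``l2`` about the base O:
    ``Xc^2 + Yc^2 + Zc^2 = l2^2``.

The two planes intersect in a line which pierces the sphere in at most two
points — a quadratic in ``Zc``.  Anatomy selects the root: in the normal
state the clavicle points upward-oblique (``Zc > 0``, larger root) and the
shoulder sits lateral to the sternoclavicular origin (``Xc > 0``).  A
configuration where no root satisfies both rules corresponds to a shoulder
dislocation and is reported as an :class:`~armkin.errors.AnatomicalViolationError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arm_model import ArmGeometry, assert_rotation
from .errors import (
    AnatomicalViolationError,
    DegenerateConfigurationError,
    InvalidInputError,
    UnreachableTargetError,
)

__all__ = [
    "EndEffectorPose",
    "PositionSolution",
    "elbow_from_end_effector",
    "cos_theta0",
    "shoulder_plane_coefficients",
    "solve_shoulder_position",
    "perpendicularity_residual",
]


@dataclass(frozen=True)
class EndEffectorPose:
    """Measured wrist pose: position (mm) and direction-cosine matrix."""

    position: np.ndarray
    rotation: np.ndarray
    #: orthonormality tolerance; measured data is noisier than synthetic
    tol: float = 1e-6

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float).reshape(3)
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise InvalidInputError("pose rotation must be 3x3")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(R))):
            raise InvalidInputError("pose contains non-finite values")
        assert_rotation(R, self.tol)
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "rotation", R)

    @classmethod
    def from_matrix(cls, T: np.ndarray, tol: float = 1e-6) -> "EndEffectorPose":
        T = np.asarray(T, dtype=float)
        return cls(position=T[:3, 3].copy(), rotation=T[:3, :3].copy(), tol=tol)

    def as_matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.position
        return T


@dataclass
class PositionSolution:
    """Output of the stage-1 solve, with every intermediate for diagnostics."""

    elbow: np.ndarray
    shoulder: np.ndarray
    cos_theta0: float
    alpha: float
    beta: float
    plane1: tuple[float, float, float]  # (p1, q1, r1): p1*Yc + q1*Zc = r1
    plane2: tuple[float, float, float]  # (p2, q2, r2): p2*Xc + q2*Zc = r2
    root_candidates: tuple[float, float]  # the two Zc roots, ascending
    diagnostics: dict = field(default_factory=dict)


def elbow_from_end_effector(pose: EndEffectorPose, l6: float) -> np.ndarray:
    """Elbow centre from the wrist pose: ``E = P - l6 * (R11, R21, R31)``.

    The forearm of length ``l6`` extends along the end-effector x-axis, so
    walking back from the wrist recovers the humeroulnar joint centre.
    """
    if not (math.isfinite(l6) and l6 >= 0):
        raise InvalidInputError(f"l6 must be a finite non-negative length, got {l6!r}")
    return pose.position - l6 * pose.rotation[:, 0]


def cos_theta0(elbow: np.ndarray, geometry: ArmGeometry, tol: float = 1e-9) -> float:
    """Cosine of the interior angle at E in triangle O-S-E (law of cosines).

    ``cos(theta_0) = (d5^2 + |OE|^2 - l2^2) / (2 * d5 * |OE|)``.

    Raises :class:`UnreachableTargetError` when the triangle inequality is
    violated beyond ``tol`` (the elbow cannot be at that distance from the
    base for any shoulder placement).
    """
    e = np.asarray(elbow, dtype=float).reshape(3)
    oe = float(np.linalg.norm(e))
    if oe <= 0.0:
        raise InvalidInputError("elbow coincides with the base; |OE| must be > 0")
    c = (geometry.d5**2 + oe**2 - geometry.l2**2) / (2.0 * geometry.d5 * oe)
    if abs(c) > 1.0 + tol:
        raise UnreachableTargetError(
            f"|cos(theta_0)| = {abs(c):.6f} > 1: elbow distance {oe:.2f} mm breaks "
            f"triangle O-S-E (l2 = {geometry.l2}, d5 = {geometry.d5})"
        )
    return min(1.0, max(-1.0, c))


def _alpha_beta(pose: EndEffectorPose, elbow: np.ndarray, geometry: ArmGeometry) -> tuple[float, float, float]:
    e = np.asarray(elbow, dtype=float).reshape(3)
    rz = pose.rotation[:, 2]
    alpha = float(rz @ e)
    c0 = cos_theta0(e, geometry)
    oe2 = float(e @ e)
    beta = oe2 - geometry.d5 * math.sqrt(oe2) * c0  # == (|OE|^2 - d5^2 + l2^2) / 2
    return alpha, beta, c0


def shoulder_plane_coefficients(
    pose: EndEffectorPose,
    elbow: np.ndarray,
    alpha: float,
    beta: float,
    eps_scale: float = 1e-6,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Reduce the two shoulder planes to the eliminated two-variable forms.

    Plane A: ``R13*Xc + R23*Yc + R33*Zc = alpha`` (perpendicularity of E-S to
    the wrist z-axis).  Plane B: ``Xe*Xc + Ye*Yc + Ze*Zc = beta`` (law of
    cosines in triangle O-S-E).  Eliminating ``Xc`` with pivot ``Xe`` yields
    ``p1*Yc + q1*Zc = r1``; eliminating ``Yc`` with pivot ``Ye`` yields
    ``p2*Xc + q2*Zc = r2``:

    ``p1 = R23 - (Ye/Xe)*R13``, ``q1 = R33 - (Ze/Xe)*R13``, ``r1 = alpha - (R13/Xe)*beta``
    ``p2 = R13 - (Xe/Ye)*R23``, ``q2 = R33 - (Ze/Ye)*R23``, ``r2 = alpha - (R23/Ye)*beta``

    The division by ``Xe`` (resp. ``Ye``) assumes that pivot is away from
    zero.  When it is not, the elimination is re-pivoted: the row with the
    largest normalized coefficient of the variable being eliminated is used
    as the pivot row instead, which yields an equally valid plane through
    the same intersection line.  Only when neither row constrains the
    variable at all is the construction degenerate.
    """
    e = np.asarray(elbow, dtype=float).reshape(3)
    xe, ye, ze = e
    r13, r23, r33 = pose.rotation[:, 2]
    scale = max(1.0, float(np.linalg.norm(e)))
    eps = eps_scale * scale

    row_a = np.array([r13, r23, r33, alpha])  # unit-normal plane (z-axis perpendicularity)
    row_b = np.array([xe, ye, ze, beta])      # law-of-cosines plane, normal = E

    if abs(xe) >= eps and abs(ye) >= eps:
        p1 = r23 - (ye / xe) * r13
        q1 = r33 - (ze / xe) * r13
        r1 = alpha - (r13 / xe) * beta
        p2 = r13 - (xe / ye) * r23
        q2 = r33 - (ze / ye) * r23
        r2 = alpha - (r23 / ye) * beta
        return (p1, q1, r1), (p2, q2, r2)

    def eliminate(var: int) -> tuple[float, float, float]:
        na = float(np.linalg.norm(row_a[:3]))
        nb = float(np.linalg.norm(row_b[:3]))
        ma = abs(row_a[var]) / na if na else 0.0
        mb = abs(row_b[var]) / nb if nb else 0.0
        if max(ma, mb) < eps_scale:
            raise DegenerateConfigurationError(
                "neither plane constrains the variable being eliminated; the reduced "
                "plane coefficients are ill-conditioned"
            )
        pivot, other = (row_b, row_a) if mb >= ma else (row_a, row_b)
        red = other - (other[var] / pivot[var]) * pivot
        keep = [i for i in (0, 1, 2) if i != var]
        return float(red[keep[0]]), float(red[keep[1]]), float(red[3])

    plane1 = eliminate(0)  # drops Xc -> p1*Yc + q1*Zc = r1
    plane2_yz = eliminate(1)  # drops Yc -> p2*Xc + q2*Zc = r2
    return plane1, plane2_yz


def _affine_xy_of_zc(pose: EndEffectorPose, elbow: np.ndarray, alpha: float, beta: float):
    """Express (Xc, Yc) as affine functions of Zc from the two planes.

    Solves the 2x2 system ``[[R13, R23], [Xe, Ye]] @ (Xc, Yc) =
    (alpha - R33*Zc, beta - Ze*Zc)`` symbolically in ``Zc``.  Equivalent to
    the pivot elimination of :func:`shoulder_plane_coefficients` but valid
    whenever the 2x2 determinant is non-zero, regardless of which elbow
    coordinate vanishes.
    """
    e = np.asarray(elbow, dtype=float).reshape(3)
    xe, ye, ze = e
    r13, r23, r33 = pose.rotation[:, 2]
    M = np.array([[r13, r23], [xe, ye]])
    det = float(np.linalg.det(M))
    scale = max(1.0, float(np.linalg.norm(e)))
    if abs(det) < 1e-12 * scale:
        raise DegenerateConfigurationError(
            "the two shoulder planes project to parallel lines in the XY plane; "
            "Xc and Yc cannot be eliminated in favour of Zc"
        )
    Minv = np.array([[ye, -r23], [-xe, r13]]) / det
    const = Minv @ np.array([alpha, beta])
    slope = Minv @ np.array([-r33, -ze])
    # Xc = const[0] + slope[0]*Zc ; Yc = const[1] + slope[1]*Zc
    return const, slope


def solve_shoulder_position(
    pose: EndEffectorPose,
    elbow: np.ndarray,
    geometry: ArmGeometry,
    disc_tol_scale: float = 1e-8,
    reference_shoulder: np.ndarray | None = None,
) -> PositionSolution:
    """Solve for the shoulder centre on the plane-plane-sphere intersection.

    Substituting the two plane constraints into the sphere
    ``Xc^2 + Yc^2 + Zc^2 = l2^2`` yields a quadratic in ``Zc``; in the
    pivot form its coefficients are
    ``(q1^2/p1^2 + q2^2/p2^2 + 1) Zc^2 - 2 (q1 r1/p1^2 + q2 r2/p2^2) Zc +
    (r1^2/p1^2 + r2^2/p2^2) = l2^2``.

    Both roots are exact stage-1 solutions (each satisfies ``|OS| = l2``,
    ``|ES| = d5`` and the wrist-axis perpendicularity), so the anatomical
    sign rules do the selecting: a root is *feasible* only if the clavicle
    points upward-oblique (``Zc > 0``) and the shoulder sits lateral to the
    sternoclavicular origin (``Xc > 0``).  If no root is feasible the
    configuration is a shoulder dislocation
    (:class:`AnatomicalViolationError`).  If exactly one is feasible — the
    regime the method is designed for — it is selected.  If both are
    feasible the pose is genuinely ambiguous; ``reference_shoulder`` (e.g.
    the previous frame of a trajectory) breaks the tie by proximity, and
    without a reference the less-elevated root (smaller ``Zc``) is chosen
    as the anatomically normal clavicle posture, with the ambiguity
    recorded in the diagnostics.
    """
    e = np.asarray(elbow, dtype=float).reshape(3)
    alpha, beta, c0 = _alpha_beta(pose, e, geometry)
    const, slope = _affine_xy_of_zc(pose, e, alpha, beta)

    # quadratic A*Zc^2 + B*Zc + C = 0 from |S|^2 = l2^2
    A = float(slope @ slope) + 1.0
    B = 2.0 * float(const @ slope)
    C = float(const @ const) - geometry.l2**2
    disc = B * B - 4.0 * A * C
    l2sq = geometry.l2**2
    if disc < 0.0:
        if disc > -disc_tol_scale * l2sq * A:
            disc = 0.0  # tangency within numerical tolerance
        else:
            raise UnreachableTargetError(
                f"negative discriminant ({disc:.3e}): the shoulder sphere does not "
                "meet the plane-plane intersection line"
            )
    sq = math.sqrt(disc)
    zc_lo = (-B - sq) / (2.0 * A)
    zc_hi = (-B + sq) / (2.0 * A)

    rz = pose.rotation[:, 2]
    l2 = geometry.l2

    def back_sub(zc: float) -> np.ndarray:
        xy = const + slope * zc
        s = np.array([xy[0], xy[1], zc])
        # Newton polish on the exact constraint system; the quadratic route
        # loses up to half the working precision near root tangency.
        for _ in range(3):
            F = np.array([rz @ s - alpha, e @ s - beta, s @ s - l2 * l2])
            J = np.vstack([rz, e, 2.0 * s])
            try:
                step = np.linalg.solve(J, F)
            except np.linalg.LinAlgError:
                break
            s = s - step
            if float(np.abs(F).max()) < 1e-12 * l2:
                break
        return s

    # pivot-form plane coefficients, kept for diagnostics when well-conditioned
    try:
        plane1, plane2 = shoulder_plane_coefficients(pose, e, alpha, beta)
    except DegenerateConfigurationError:
        plane1 = plane2 = (math.nan, math.nan, math.nan)

    candidates = [back_sub(zc_lo), back_sub(zc_hi)]
    feasible = [s for s in candidates if s[2] > 0.0 and s[0] > 0.0]
    diagnostics = {
        "zc_roots": (zc_lo, zc_hi),
        "n_feasible": len(feasible),
        "ambiguous": len(feasible) == 2,
        "violation": False,
    }
    if not feasible:
        diagnostics["violation"] = True
        raise AnatomicalViolationError(
            "anatomical branch rules violated (shoulder dislocation): neither root "
            f"satisfies Zc > 0 and Xc > 0 (candidates {candidates[0].round(2)}, "
            f"{candidates[1].round(2)})",
            diagnostics=diagnostics,
        )
    if len(feasible) == 1:
        selected = feasible[0]
        diagnostics["selected_by"] = "sign_rules"
    elif reference_shoulder is not None:
        ref = np.asarray(reference_shoulder, dtype=float).reshape(3)
        selected = min(feasible, key=lambda s: float(np.linalg.norm(s - ref)))
        diagnostics["selected_by"] = "continuity"
    else:
        selected = min(feasible, key=lambda s: s[2])
        diagnostics["selected_by"] = "least_elevation"
    return PositionSolution(
        elbow=e,
        shoulder=selected,
        cos_theta0=c0,
        alpha=alpha,
        beta=beta,
        plane1=plane1,
        plane2=plane2,
        root_candidates=(zc_lo, zc_hi),
        diagnostics=diagnostics,
    )


def perpendicularity_residual(pose: EndEffectorPose, shoulder: np.ndarray, elbow: np.ndarray) -> float:
    """Residual of the structural constraint (S - E) . z_EE = 0, in mm.

    Exactly zero for poses produced by the forward model; for measured
    marker data it quantifies how far the arm deviates from the rigid-chain
    assumption and is reported as a diagnostic, not enforced.
    """
    es = np.asarray(shoulder, dtype=float) - np.asarray(elbow, dtype=float)
    return float(es @ pose.rotation[:, 2])
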