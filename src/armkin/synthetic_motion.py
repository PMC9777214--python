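"""Synthetic ground-truth motions and marker trajectories.

Every pipeline stage is testable without captured data: smooth periodic
joint-angle profiles emulating the two rehabilitation exercises (10
repetitions each, per the measurement protocol) are pushed through the
forward model, markers are placed at body-fixed offsets around the joint
centres, and optional isotropic Gaussian noise emulates optical
motion-capture jitter.

Each repetition is a raised-cosine excursion from the joint's rest offset
to offset + amplitude and back, so the velocity is zero at every cycle
endpoint — the property that makes per-cycle segmentation of real
repetitions unambiguous.  Default amplitudes follow the measured
average ROM pattern of each exercise; default offsets keep every sampled
configuration inside the anatomically valid branch of the inverse
kinematics (shoulder above the horizontal plane through the base,
Zc > 0, and lateral to it, Xc > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .arm_model import ArmGeometry, forward_kinematics
from .errors import InvalidInputError
from .motion_pipeline import (
    AngleTrajectory,
    MarkerFrameSeries,
    ROMRecord,
    records_from_csv,
)

__all__ = [
    "MotionProfileSpec",
    "DEFAULT_GEOMETRY",
    "generate_joint_profiles",
    "synthesize_markers",
    "simulate",
    "make_table_fixtures",
    "is_branch_unambiguous",
    "sample_branch_valid_joints",
]

#: Plausible adult segment lengths, mm (clavicle, upper arm, forearm).
DEFAULT_GEOMETRY = ArmGeometry(l2=180.0, d5=300.0, l6=260.0)

# Default per-joint signed amplitudes (deg) follow each exercise's average
# ROM pattern; offsets (deg) keep the whole excursion branch-valid
# (theta_2 < 0 throughout => Zc > 0; |theta_1|, |theta_2| < 90 => Xc > 0)
# and away from the sin(theta_4) = 0 / sin(theta_5) = 0 singularities.
_DEFAULTS = {
    "abduction_adduction": {
        "amplitude": (24.0, -15.0, 39.0, 129.0, 57.0, 23.0),
        "offset": (-12.0, -8.0, -20.0, 12.0, 12.0, 15.0),
    },
    "external_internal": {
        "amplitude": (4.0, -3.0, 8.0, 8.0, 109.0, 24.0),
        "offset": (-2.0, -10.0, 10.0, 25.0, 15.0, 12.0),
    },
}


@dataclass(frozen=True)
class MotionProfileSpec:
    """Parameters of one synthetic recording.

    Angles in degrees, lengths in millimetres.  ``amplitude`` entries are
    signed (the excursion direction); the configured ROM of joint k is
    ``|amplitude[k]|``.  ``phase`` shifts each joint's raised-cosine by a
    fraction of a cycle.  ``amplitude_jitter_sd`` scales every repetition's
    whole pattern so that the dominant joint's per-cycle amplitude has the
    given SD, emulating inter-repetition variability.  ``base_position``
    places the SC joint in the capture volume and ``base_yaw_deg`` rotates
    the subject about the vertical, both of which the pipeline's base-frame
    normalization must undo.
    """

    motion: str = "abduction_adduction"
    n_reps: int = 10
    sample_rate: float = 50.0  # Hz
    cycle_duration: float = 2.0  # s per repetition
    amplitude: tuple[float, ...] | None = None  # deg, signed; None -> motion default
    offset: tuple[float, ...] | None = None  # deg; None -> motion default
    phase: tuple[float, ...] = (0.0,) * 6  # fraction of a cycle
    amplitude_jitter_sd: float = 2.0  # deg, on the dominant joint
    marker_noise_sd: float = 0.5  # mm, isotropic
    base_position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, world
    base_yaw_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.motion not in _DEFAULTS:
            raise InvalidInputError(f"unknown motion {self.motion!r}")
        if self.n_reps < 1:
            raise InvalidInputError("n_reps must be >= 1")
        if self.sample_rate <= 0 or self.cycle_duration <= 0:
            raise InvalidInputError("sample_rate and cycle_duration must be > 0")
        if self.amplitude_jitter_sd < 0 or self.marker_noise_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")
        for name in ("amplitude", "offset"):
            v = getattr(self, name)
            if v is not None and len(v) != 6:
                raise InvalidInputError(f"{name} must have six entries")
        if len(self.phase) != 6:
            raise InvalidInputError("phase must have six entries")

    @property
    def amplitudes_deg(self) -> np.ndarray:
        a = self.amplitude if self.amplitude is not None else _DEFAULTS[self.motion]["amplitude"]
        return np.asarray(a, dtype=float)

    @property
    def offsets_deg(self) -> np.ndarray:
        o = self.offset if self.offset is not None else _DEFAULTS[self.motion]["offset"]
        return np.asarray(o, dtype=float)


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """C1-smooth bump: 0 at u = 0 and 1, peak 1 at u = 0.5."""
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * u))


def generate_joint_profiles(spec: MotionProfileSpec) -> AngleTrajectory:
    """Ground-truth joint-angle trajectory for one synthetic recording.

    Per repetition j, joint k follows
    ``offset_k + amplitude_k * f_j * rc(u + phase_k)`` where ``rc`` is the
    raised cosine over the cycle fraction ``u`` and ``f_j`` is the
    repetition's common jitter factor.  Every sampled configuration is
    checked against the anatomical branch rules; a spec that leaves them is
    rejected with the index of the first violating sample.
    """
    rng = np.random.default_rng([spec.seed, 0])
    amp = spec.amplitudes_deg
    off = spec.offsets_deg
    dom = int(np.argmax(np.abs(amp)))
    n_per = int(round(spec.sample_rate * spec.cycle_duration))
    if n_per < 4:
        raise InvalidInputError("fewer than 4 samples per cycle; raise sample_rate")
    n = spec.n_reps * n_per + 1
    t = np.arange(n) / spec.sample_rate
    factors = np.ones(spec.n_reps)
    if spec.amplitude_jitter_sd > 0:
        rel = spec.amplitude_jitter_sd / max(abs(amp[dom]), 1e-9)
        factors = 1.0 + rng.normal(0.0, rel, size=spec.n_reps)
        factors = np.clip(factors, 0.1, None)
    theta = np.empty((n, 6))
    cycle_idx = np.minimum((np.arange(n) // n_per), spec.n_reps - 1)
    u = (np.arange(n) % n_per) / n_per
    u[-1] = 1.0  # closing sample of the last repetition
    for k in range(6):
        bump = _raised_cosine(np.mod(u + spec.phase[k], 1.0))
        theta[:, k] = off[k] + amp[k] * factors[cycle_idx] * bump
    theta = np.radians(theta)

    s2 = np.sin(theta[:, 1])
    zc_ok = s2 < 0  # Zc = -l2*sin(theta_2) > 0
    xc_ok = (np.cos(theta[:, 1]) * np.cos(theta[:, 0])) > 0  # Xc = l2*C2*C1 > 0
    bad = np.flatnonzero(~(zc_ok & xc_ok))
    if bad.size:
        i = int(bad[0])
        raise InvalidInputError(
            f"spec leaves the anatomically valid branch at sample {i} "
            f"(t = {t[i]:.3f} s, theta_1 = {math.degrees(theta[i, 0]):.1f} deg, "
            f"theta_2 = {math.degrees(theta[i, 1]):.1f} deg); adjust offsets/amplitudes"
        )
    qc = [{"frame": i, "flag": "ok", "truth": True} for i in range(n)]
    return AngleTrajectory(time=t, theta=theta, qc=qc)


# Body-fixed marker offsets (mm).  The three shoulder offsets sum to zero so
# their centroid is exactly the glenohumeral centre; the elbow and wrist
# pairs are symmetric about their joint centres.
_SHOULDER_OFFSETS = np.array([[50.0, 0.0, 20.0], [-25.0, 43.0, 20.0], [-25.0, -43.0, -40.0]])
_ELBOW_OFFSET = np.array([0.0, 35.0, 0.0])
_WRIST_OFFSET = np.array([0.0, 25.0, 0.0])


def synthesize_markers(
    truth: AngleTrajectory,
    geometry: ArmGeometry,
    spec: MotionProfileSpec,
) -> MarkerFrameSeries:
    """Marker trajectories from a ground-truth joint trajectory.

    Per frame the forward model places the joint centres; the SC marker
    sits exactly at the base, the three shoulder markers at clavicle-fixed
    offsets whose centroid is the shoulder centre, and the elbow/wrist
    pairs symmetrically about their centres on the upper-arm and forearm
    frames.  The whole scene is then moved to ``spec.base_position`` and
    yawed by ``spec.base_yaw_deg``, and isotropic Gaussian noise of SD
    ``spec.marker_noise_sd`` is added to every coordinate.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = len(truth)
    yaw = math.radians(spec.base_yaw_deg)
    Rw = np.array(
        [[math.cos(yaw), -math.sin(yaw), 0.0], [math.sin(yaw), math.cos(yaw), 0.0], [0.0, 0.0, 1.0]]
    )
    p0 = np.asarray(spec.base_position, dtype=float)

    out = {lab: np.empty((n, 3)) for lab in ("SC", "SH1", "SH2", "SH3", "EL1", "EL2", "WR1", "WR2")}
    for i in range(n):
        chain = forward_kinematics(geometry, truth.theta[i])
        R02 = chain.T(2)[:3, :3]
        R04 = chain.T(4)[:3, :3]
        R06 = chain.T(6)[:3, :3]
        S, E, EE = chain.shoulder, chain.elbow, chain.end_effector

        def place(p_base: np.ndarray) -> np.ndarray:
            return p0 + Rw @ p_base

        out["SC"][i] = place(np.zeros(3))
        for j in range(3):
            out[f"SH{j + 1}"][i] = place(S + R02 @ _SHOULDER_OFFSETS[j])
        out["EL1"][i] = place(E + R04 @ _ELBOW_OFFSET)
        out["EL2"][i] = place(E - R04 @ _ELBOW_OFFSET)
        out["WR1"][i] = place(EE + R06 @ _WRIST_OFFSET)
        out["WR2"][i] = place(EE - R06 @ _WRIST_OFFSET)
    if spec.marker_noise_sd > 0:
        for lab in out:
            out[lab] = out[lab] + rng.normal(0.0, spec.marker_noise_sd, size=(n, 3))
    return MarkerFrameSeries(time=truth.time.copy(), markers=out)


def simulate(
    spec: MotionProfileSpec, geometry: ArmGeometry = DEFAULT_GEOMETRY
) -> tuple[MarkerFrameSeries, AngleTrajectory]:
    """Generate one synthetic recording: (markers, ground-truth angles)."""
    truth = generate_joint_profiles(spec)
    return synthesize_markers(truth, geometry, spec), truth


def is_branch_unambiguous(
    joints: np.ndarray, geometry: ArmGeometry, root_separation_min: float = 1.0
) -> bool:
    """Whether the anatomical sign rules single out this configuration's
    shoulder among the two stage-1 solutions.

    Pure geometry, independent of the inverse-kinematics code path: the two
    stage-1 solutions are the intersections of the sphere ``|S| = l2`` with
    the line through the true shoulder S directed along
    ``cross(z_EE, E)`` (both shoulder planes contain S and have normals
    z_EE and E).  The mirror solution is ``S - 2 (S . d) d`` for the unit
    line direction ``d``.  The configuration is unambiguous when the true S
    satisfies ``Zc > 0`` and ``Xc > 0``, the mirror does not, and the two
    are at least ``root_separation_min`` mm apart (away from tangency,
    where the solutions coalesce and the split of S around the O-E axis is
    ill-conditioned).
    """
    chain = forward_kinematics(geometry, joints)
    S = chain.shoulder
    E = chain.elbow
    rz = chain.pose[:3, 2]
    d = np.cross(rz, E)
    nd = float(np.linalg.norm(d))
    if nd < 1e-9:
        return False
    d = d / nd
    mirror = S - 2.0 * float(S @ d) * d
    if np.linalg.norm(mirror - S) < root_separation_min:
        return False
    s_ok = S[2] > 0.0 and S[0] > 0.0
    m_ok = mirror[2] > 0.0 and mirror[0] > 0.0
    return bool(s_ok and not m_ok)


def sample_branch_valid_joints(
    rng: np.random.Generator,
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
    singularity_margin: float = 0.1,
) -> np.ndarray:
    """One random reachable joint vector on which the closed-form inverse
    kinematics is well-posed.

    Rejection sampling over physiological-ish ranges: theta_1 in (-75, 75)
    deg, theta_2 in (-80, -10) deg (clavicle upward-oblique, so Zc > 0 and
    Xc > 0), the rest unrestricted except margins ``singularity_margin`` on
    |sin theta_4|, |sin theta_5| and |cos theta_6| (the wrist/roll
    singularities and the theta_5-pair degeneracy), plus the
    :func:`is_branch_unambiguous` shoulder-selection test.
    """
    while True:
        th = np.radians(
            [
                rng.uniform(-75.0, 75.0),
                rng.uniform(-80.0, -10.0),
                rng.uniform(-179.0, 179.0),
                rng.uniform(-179.0, 179.0),
                rng.uniform(-179.0, 179.0),
                rng.uniform(-179.0, 179.0),
            ]
        )
        if abs(math.sin(th[3])) < singularity_margin:
            continue
        if abs(math.sin(th[4])) < singularity_margin:
            continue
        if abs(math.cos(th[5])) < singularity_margin:
            continue
        if not is_branch_unambiguous(th, geometry):
            continue
        return th


def make_table_fixtures() -> dict[str, list[ROMRecord]]:
    """The bundled per-subject ROM values of the two measured exercises.

    Returns a mapping motion -> ten :class:`ROMRecord` (five male, five
    female subjects), exactly as printed in the study tables; used by the
    cohort-statistics reproduction tests.
    """
    out: dict[str, list[ROMRecord]] = {}
    for motion in ("abduction_adduction", "external_internal"):
        ref = resources.files("armkin.data") / f"rom_{motion}.csv"
        with resources.as_file(ref) as path:
            out[motion] = records_from_csv(path)
    return out
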