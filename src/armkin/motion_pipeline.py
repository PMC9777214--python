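"""Marker trajectories -> joint angles -> range of motion -> cohort statistics.

The measurement pipeline mirrors a typical optical motion-capture protocol
for the shoulder: reflective markers on the sternoclavicular joint (SC),
three around the shoulder (SH1..SH3, centroid at the glenohumeral centre),
two at the elbow (EL1, EL2) and two at the wrist (WR1, WR2).  Per frame the
joint centres are estimated from the marker clusters, an end-effector frame
is built at the wrist, the closed-form inverse kinematics recovers the six
joint angles, and the per-joint range of motion (ROM) is summarized over
the repetitions of the exercise.  Sex-stratified cohort statistics (mean,
population SD, SEM) aggregate the per-subject ROM values.

Composite ROM conventions: abduction/adduction is dominated by the clavicle
vertical angle plus shoulder pitch (theta_2 + theta_4); external/internal
rotation by the humeral axial rotation alone (theta_5).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arm_model import ArmGeometry, link_length
from .errors import (
    AnatomicalViolationError,
    DegenerateConfigurationError,
    InconsistentPoseError,
    InvalidInputError,
    SingularConfigurationError,
    TrajectoryQualityError,
    UnreachableTargetError,
)
from .ik_angles import solve_all
from .ik_position import EndEffectorPose, perpendicularity_residual

__all__ = [
    "MARKER_LABELS",
    "MarkerFrameSeries",
    "JointCenterSeries",
    "AngleTrajectory",
    "ROMRecord",
    "CohortTable",
    "read_marker_csv",
    "lowpass_markers",
    "estimate_joint_centers",
    "geometry_from_centers",
    "build_end_effector_poses",
    "angles_over_time",
    "compute_rom",
    "composite_rom",
    "cohort_stats",
    "round_half_away",
    "THETA_COLUMNS",
]

MARKER_LABELS = ("SC", "SH1", "SH2", "SH3", "EL1", "EL2", "WR1", "WR2")
THETA_COLUMNS = tuple(f"theta{i}" for i in range(1, 7))

MOTIONS = ("abduction_adduction", "external_internal")


@dataclass
class MarkerFrameSeries:
    """Timestamped labelled marker positions (mm, capture-world frame)."""

    time: np.ndarray  # (n,), seconds, strictly increasing
    markers: dict[str, np.ndarray]  # label -> (n, 3)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise InvalidInputError("time must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        missing = [lab for lab in MARKER_LABELS if lab not in self.markers]
        if missing:
            raise InvalidInputError(f"missing marker labels: {missing}")
        for lab, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(t), 3):
                raise InvalidInputError(f"marker {lab} must have shape (n, 3)")
            self.markers[lab] = arr
        self.time = t

    def __len__(self) -> int:
        return len(self.time)

    @property
    def gap_mask(self) -> np.ndarray:
        """True where any marker coordinate is missing (NaN) in a frame."""
        bad = np.zeros(len(self), dtype=bool)
        for arr in self.markers.values():
            bad |= ~np.all(np.isfinite(arr), axis=1)
        return bad

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time": self.time}
        for lab in MARKER_LABELS:
            for j, ax in enumerate("xyz"):
                cols[f"{lab}_{ax}"] = self.markers[lab][:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_marker_csv(path: str | Path, label_map: dict[str, str] | None = None) -> MarkerFrameSeries:
    """Read a wide motion-capture CSV export (one x/y/z column triple per
    marker, leading ``time`` column, millimetres).

    ``label_map`` maps the canonical labels to the names used in the file,
    e.g. ``{"SC": "Clavicle"}`` when the export used different marker names.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise InvalidInputError(f"{path}: marker CSV must have a 'time' column")
    label_map = label_map or {}
    markers = {}
    for lab in MARKER_LABELS:
        src = label_map.get(lab, lab)
        cols = [f"{src}_{ax}" for ax in "xyz"]
        if not all(c in df.columns for c in cols):
            raise InvalidInputError(f"{path}: missing columns for marker {lab} ({cols})")
        markers[lab] = df[cols].to_numpy(dtype=float)
    return MarkerFrameSeries(time=df["time"].to_numpy(dtype=float), markers=markers)


def lowpass_markers(
    frames: MarkerFrameSeries, cutoff_hz: float, order: int = 4
) -> MarkerFrameSeries:
    """Zero-phase Butterworth low-pass of every marker coordinate.

    Standard pre-processing for optical capture data: the exercises studied
    here have a repetition fundamental around 0.5 Hz, so a cutoff of ~3 Hz
    (six harmonics) removes most sensor jitter while leaving the movement
    waveform intact.  Requires gap-free data (filter NaNs would spread);
    frames with gaps raise :class:`InvalidInputError`.
    """
    from scipy.signal import butter, filtfilt

    if cutoff_hz <= 0:
        raise InvalidInputError("cutoff_hz must be > 0")
    fs = 1.0 / float(np.median(np.diff(frames.time)))
    if cutoff_hz >= fs / 2:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {fs / 2:.1f} Hz"
        )
    if np.any(frames.gap_mask):
        raise InvalidInputError("low-pass filtering requires gap-free marker data")
    if len(frames) < 8 * (order + 1):
        raise InvalidInputError("too few frames to filter at this order")
    b, a = butter(order, cutoff_hz / (fs / 2.0))
    out = {lab: filtfilt(b, a, arr, axis=0) for lab, arr in frames.markers.items()}
    return MarkerFrameSeries(time=frames.time.copy(), markers=out)


@dataclass
class JointCenterSeries:
    """Per-frame joint centres in the base frame anchored at the SC joint.

    The base origin O is the SC marker (so O = 0 by construction after the
    per-frame translation); orientation comes from a calibration window:
    +X is the horizontal projection of the mean O->S direction over the
    first ``calibration_seconds`` of the recording, +Z is capture-world up,
    +Y completes the right-handed frame.
    """

    time: np.ndarray
    shoulder: np.ndarray  # (n, 3) S_meas
    elbow: np.ndarray  # (n, 3) E_meas
    end_effector: np.ndarray  # (n, 3) EE
    gap: np.ndarray  # (n,) bool
    world_to_base: np.ndarray  # (3, 3)

    def __len__(self) -> int:
        return len(self.time)


def estimate_joint_centers(
    frames: MarkerFrameSeries, calibration_seconds: float = 1.0
) -> JointCenterSeries:
    """Joint centres from marker clusters, re-expressed in the base frame.

    O = SC marker; S = centroid of the three shoulder markers; E = midpoint
    of the elbow pair; EE = midpoint of the wrist pair.  Frames with any
    missing marker are flagged and carried as NaN centres.
    """
    n = len(frames)
    gap = frames.gap_mask
    sc = frames.markers["SC"]
    s_w = (frames.markers["SH1"] + frames.markers["SH2"] + frames.markers["SH3"]) / 3.0
    e_w = (frames.markers["EL1"] + frames.markers["EL2"]) / 2.0
    ee_w = (frames.markers["WR1"] + frames.markers["WR2"]) / 2.0

    # calibration window for the base-frame yaw
    calib = (frames.time <= frames.time[0] + calibration_seconds) & ~gap
    if not np.any(calib):
        raise InvalidInputError("no valid frames inside the calibration window")
    mean_os = np.nanmean(s_w[calib] - sc[calib], axis=0)
    horiz = np.array([mean_os[0], mean_os[1], 0.0])
    nh = np.linalg.norm(horiz)
    if nh < 1e-9:
        raise DegenerateConfigurationError(
            "calibration clavicle direction is vertical; the base-frame yaw is undefined"
        )
    x = horiz / nh
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    R = np.vstack([x, y, z])  # world -> base

    def to_base(p_w: np.ndarray) -> np.ndarray:
        rel = p_w - sc
        out = rel @ R.T
        out[gap] = np.nan
        return out

    return JointCenterSeries(
        time=frames.time.copy(),
        shoulder=to_base(s_w),
        elbow=to_base(e_w),
        end_effector=to_base(ee_w),
        gap=gap.copy(),
        world_to_base=R,
    )


def geometry_from_centers(centers: JointCenterSeries) -> ArmGeometry:
    """Subject-specific link lengths as median inter-centre distances.

    Applies the 3-D distance formula per valid frame and takes the median,
    which is robust to isolated marker noise.
    """
    ok = ~centers.gap
    if not np.any(ok):
        raise InvalidInputError("no valid frames to derive the geometry from")
    l2 = float(np.median([link_length(np.zeros(3), s) for s in centers.shoulder[ok]]))
    d5 = float(np.median([link_length(s, e) for s, e in zip(centers.shoulder[ok], centers.elbow[ok])]))
    l6 = float(np.median([link_length(e, w) for e, w in zip(centers.elbow[ok], centers.end_effector[ok])]))
    return ArmGeometry(l2=l2, d5=d5, l6=l6)


def build_end_effector_poses(
    centers: JointCenterSeries, collinear_tol: float = 1e-9
) -> list[EndEffectorPose | None]:
    """Wrist frame per frame from the S, E, EE centres.

    x-axis = unit(EE - E) (the forearm direction, so walking back l6 along
    it recovers E); z-axis = unit(x cross (S - E)), which enforces the
    chain's perpendicularity of E-S to the wrist z-axis by construction and
    matches the chain's own wrist frame whenever the elbow flexion is below
    90 degrees (the chain satisfies x6 cross (S - E) = d5*cos(theta_6)*z6);
    y = z cross x; position = EE.  Frames with collinear S, E, EE
    (z undefined) or gaps yield ``None``.
    """
    out: list[EndEffectorPose | None] = []
    for i in range(len(centers)):
        if centers.gap[i]:
            out.append(None)
            continue
        S = centers.shoulder[i]
        E = centers.elbow[i]
        EE = centers.end_effector[i]
        fore = EE - E
        nf = np.linalg.norm(fore)
        if nf < collinear_tol:
            out.append(None)
            continue
        x = fore / nf
        zraw = np.cross(x, S - E)
        nz = np.linalg.norm(zraw)
        if nz < collinear_tol * max(1.0, float(np.linalg.norm(S - E))):
            out.append(None)  # collinear S, E, EE
            continue
        z = zraw / nz
        y = np.cross(z, x)
        R = np.column_stack([x, y, z])
        out.append(EndEffectorPose(position=EE.copy(), rotation=R))
    return out


@dataclass
class AngleTrajectory:
    """Unwrapped joint-angle time series with per-frame QC flags."""

    time: np.ndarray  # (n,)
    theta: np.ndarray  # (n, 6), radians, unwrapped; NaN on flagged frames
    qc: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.theta), axis=1)

    def write_qc_log(self, path: str | Path) -> None:
        """Per-frame QC as JSON lines."""
        with open(path, "w") as fh:
            for rec in self.qc:
                fh.write(json.dumps(rec) + "\n")


def _unwrap_with_gaps(series: np.ndarray) -> np.ndarray:
    """Unwrap one angle series, skipping NaN frames.

    Adds multiples of 2*pi so consecutive valid samples never jump by more
    than pi.
    """
    out = series.copy()
    prev = None
    for i, v in enumerate(out):
        if not math.isfinite(v):
            continue
        if prev is not None:
            k = round((prev - v) / (2.0 * math.pi))
            out[i] = v + 2.0 * math.pi * k
        prev = out[i]
    return out


def angles_over_time(
    poses: Sequence[EndEffectorPose | None],
    geometry: ArmGeometry,
    time: np.ndarray | None = None,
    strict: bool = False,
    residual_tol: float = 1e-6,
    max_flagged_fraction: float = 0.5,
    reference_shoulders: np.ndarray | None = None,
    singular_cos_threshold: float = 0.995,
) -> AngleTrajectory:
    """Closed-form inverse kinematics frame by frame, then unwrapping.

    In streaming mode (``strict=False``, the default) a frame that violates
    the anatomical branch rules, is singular or is otherwise unsolvable is
    carried as a flagged NaN sample so one bad frame does not abort a
    recording; in strict mode the error propagates.

    ``reference_shoulders`` (optionally (n, 3), e.g. the measured shoulder
    centroids) disambiguates poses with two anatomically feasible shoulder
    placements; without it the previous accepted frame is used.  Frames
    where the O-S-E triangle is nearly degenerate
    (``|cos(theta_0)| >= singular_cos_threshold``, arm close to full
    extension) leave theta_1..theta_3 ill-conditioned under measurement
    noise and are flagged ``near_singular`` (NaN) in streaming mode.
    """
    n = len(poses)
    if time is None:
        time = np.arange(n, dtype=float)
    time = np.asarray(time, dtype=float)
    theta = np.full((n, 6), np.nan)
    qc: list[dict] = []
    last_shoulder = None  # last accepted shoulder, for branch continuity
    for i, pose in enumerate(poses):
        rec: dict = {"frame": i, "flag": "ok"}
        if pose is None:
            rec["flag"] = "gap"
            qc.append(rec)
            continue
        if reference_shoulders is not None and np.all(np.isfinite(reference_shoulders[i])):
            reference = reference_shoulders[i]
        else:
            reference = last_shoulder
        try:
            sol = solve_all(
                pose, geometry, residual_tol=residual_tol,
                reference_shoulder=reference,
            )
            rec["residual"] = sol.fk_residual
            if sol.position is not None:
                rec["cos_theta0"] = sol.position.cos_theta0
                rec["es_perp_mm"] = perpendicularity_residual(
                    pose, sol.position.shoulder, sol.position.elbow
                )
                last_shoulder = sol.position.shoulder
                if not strict and abs(sol.position.cos_theta0) >= singular_cos_threshold:
                    rec["flag"] = "near_singular"
                    qc.append(rec)
                    continue
            theta[i] = sol.joints
        except AnatomicalViolationError as exc:
            if strict:
                raise
            rec["flag"] = "violation"
            rec["detail"] = str(exc)
        except (
            UnreachableTargetError,
            SingularConfigurationError,
            DegenerateConfigurationError,
            InconsistentPoseError,
        ) as exc:
            if strict:
                raise
            rec["flag"] = type(exc).__name__
            rec["detail"] = str(exc)
        qc.append(rec)
    flagged = sum(1 for r in qc if r["flag"] != "ok")
    if n and flagged / n > max_flagged_fraction:
        raise TrajectoryQualityError(
            f"{flagged}/{n} frames flagged (> {max_flagged_fraction:.0%}); "
            "the trajectory is not trustworthy"
        )
    for k in range(6):
        theta[:, k] = _unwrap_with_gaps(theta[:, k])
    return AngleTrajectory(time=time, theta=theta, qc=qc)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]


def _cycle_boundaries(series: np.ndarray, time: np.ndarray, smooth_frac: float = 0.02) -> list[int]:
    """Indices splitting the dominant-joint series into repetition cycles.

    Boundaries are the negative-to-positive zero crossings of the smoothed
    signed velocity (the dominant joint comes to rest at each repetition
    endpoint).  Crossings closer together than 10% of the median spacing
    are merged to reject noise-induced chatter.
    """
    n = len(series)
    w = max(1, int(round(smooth_frac * n)))
    smooth = _moving_average(series, w)
    v = np.gradient(smooth, time)
    sign = np.sign(v)
    sign[sign == 0] = 1.0
    crossings = [i for i in range(1, n) if sign[i - 1] < 0 < sign[i]]
    if not crossings:
        return [0, n - 1]
    bounds = [0] + crossings + [n - 1]
    spans = np.diff(bounds)
    min_span = max(2, int(0.1 * np.median(spans)))
    merged = [bounds[0]]
    for b in bounds[1:]:
        if b - merged[-1] >= min_span:
            merged.append(b)
    if merged[-1] != n - 1:
        merged.append(n - 1)
    return merged


def compute_rom(trajectory: AngleTrajectory, mode: str = "per_cycle") -> np.ndarray:
    """Per-joint range of motion in degrees.

    ``global`` mode: max - min of each unwrapped series over valid frames.
    ``per_cycle`` mode: the recording is segmented into repetition cycles at
    the signed-velocity zero crossings of the dominant joint (the one with
    the largest global excursion) and the ROM is the mean of the per-cycle
    max - min, which matches a protocol of N averaged repetitions.
    """
    if mode not in ("global", "per_cycle"):
        raise InvalidInputError(f"unknown ROM mode {mode!r}")
    th = trajectory.theta
    valid = trajectory.valid_mask
    if valid.sum() < 2:
        raise TrajectoryQualityError("fewer than two valid frames; ROM is undefined")
    rom_global = np.degrees(np.nanmax(th, axis=0) - np.nanmin(th, axis=0))
    if mode == "global":
        return rom_global

    dom = int(np.argmax(rom_global))
    t = trajectory.time
    series = th[:, dom]
    # fill isolated gaps by linear interpolation for segmentation only
    finite = np.isfinite(series)
    filled = np.interp(t, t[finite], series[finite])
    bounds = _cycle_boundaries(filled, t)
    roms = []
    seg_lengths = np.diff(bounds)
    min_len = max(2, int(0.5 * np.median(seg_lengths)))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_len:
            continue
        seg = th[a : b + 1]
        with np.errstate(all="ignore"):
            r = np.nanmax(seg, axis=0) - np.nanmin(seg, axis=0)
        if np.all(np.isfinite(r)):
            roms.append(r)
    if not roms:
        return rom_global
    return np.degrees(np.mean(roms, axis=0))


def composite_rom(rom: Sequence[float], motion: str) -> float:
    """Composite ROM of a rehabilitation motion from the six per-joint ROMs.

    Abduction/adduction sums the clavicle vertical angle and the shoulder
    pitch (theta_2 + theta_4); external/internal rotation is carried by the
    humeral axial rotation (theta_5) alone.
    """
    rom = np.asarray(rom, dtype=float).reshape(6)
    if motion == "abduction_adduction":
        return float(rom[1] + rom[3])
    if motion == "external_internal":
        return float(rom[4])
    raise InvalidInputError(f"unknown motion label {motion!r}")


@dataclass(frozen=True)
class ROMRecord:
    """Per-subject per-motion ROM, degrees."""

    subject_id: str
    sex: str  # "M" or "F"
    height: float  # mm (tables print cm-scale integers; stored as given)
    motion: str
    rom: tuple[float, ...]  # six per-joint ROM values, degrees

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise InvalidInputError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.motion not in MOTIONS:
            raise InvalidInputError(f"unknown motion {self.motion!r}")
        if len(self.rom) != 6:
            raise InvalidInputError("rom must hold six per-joint values")
        if any(not math.isfinite(v) or v < 0 for v in self.rom):
            raise InvalidInputError("ROM values must be finite and non-negative")

    @property
    def composite(self) -> float:
        return composite_rom(self.rom, self.motion)


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the tables' reporting convention, unlike
    numpy's banker's rounding)."""
    x = np.asarray(x, dtype=float)
    f = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
    return out if out.ndim else float(out)


_STAT_COLUMNS = ("height",) + THETA_COLUMNS


@dataclass
class CohortTable:
    """Sex-stratified aggregate ROM statistics.

    ``mean``, ``sd`` and ``sem`` map stratum ("M", "F", "T") to per-column
    values at full precision; SD is the population SD (divisor n) and
    SEM = SD / sqrt(n).  :meth:`rounded` renders the 1-decimal reporting
    view with half-away-from-zero rounding.
    """

    motion: str
    n: dict[str, int]
    mean: dict[str, pd.Series]
    sd: dict[str, pd.Series]
    sem: dict[str, pd.Series]
    records: pd.DataFrame

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        rows = {}
        for stratum in ("M", "F", "T"):
            for stat, data in (("avg", self.mean), ("sd", self.sd), ("sem", self.sem)):
                s = data[stratum]
                rows[f"{stratum}_{stat}"] = pd.Series(
                    round_half_away(s.to_numpy(), decimals), index=s.index
                )
        return pd.DataFrame(rows).T

    def to_csv(self, path: str | Path, decimals: int = 1) -> None:
        self.rounded(decimals).to_csv(path)


def cohort_stats(records: Iterable[ROMRecord]) -> CohortTable:
    """Aggregate per-subject ROM records into the cohort table.

    All records must share one motion.  For each sex and for the pooled
    cohort the mean, population SD (divisor n) and SEM = SD/sqrt(n) of the
    height and of each per-joint ROM column are computed at full precision.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("cohort_stats needs at least one record")
    motions = {r.motion for r in records}
    if len(motions) != 1:
        raise InvalidInputError(f"records mix motions: {sorted(motions)}")
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "height": [r.height for r in records],
            **{col: [r.rom[k] for r in records] for k, col in enumerate(THETA_COLUMNS)},
        }
    )
    strata = {"M": df[df.sex == "M"], "F": df[df.sex == "F"], "T": df}
    n, mean, sd, sem = {}, {}, {}, {}
    for key, sub in strata.items():
        if len(sub) == 0:
            raise InvalidInputError(f"empty stratum {key!r}")
        vals = sub[list(_STAT_COLUMNS)]
        n[key] = len(sub)
        mean[key] = vals.mean()
        sd[key] = vals.std(ddof=0)  # population SD
        sem[key] = sd[key] / math.sqrt(n[key])
    return CohortTable(motion=motions.pop(), n=n, mean=mean, sd=sd, sem=sem, records=df)


def records_to_csv(records: Iterable[ROMRecord], path: str | Path) -> None:
    """Write per-subject ROM records (full precision) to CSV."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "height": r.height,
            "motion": r.motion,
            **{col: r.rom[k] for k, col in enumerate(THETA_COLUMNS)},
            "composite": r.composite,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[ROMRecord]:
    df = pd.read_csv(path)
    needed = {"subject_id", "sex", "height", "motion", *THETA_COLUMNS}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return [
        ROMRecord(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            height=float(row["height"]),
            motion=str(row["motion"]),
            rom=tuple(float(row[c]) for c in THETA_COLUMNS),
        )
        for _, row in df.iterrows()
    ]
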