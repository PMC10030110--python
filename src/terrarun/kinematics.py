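"""Gait events and per-step kinematics from labelled marker trajectories.

The marker set mirrors an overground shuttle-running protocol: heel, toe
and ankle markers on the instrumented shoe plus four pelvis markers whose
mean estimates the centre of mass (CoM). Runners go back and forth along
the track (the y axis), so every fore-aft quantity is expressed in the
direction-of-travel frame (positive = forward for that traversal) so
that the two directions pool.

Event detection follows the stance definition used for overground
running on uneven ground: the heel's forward speed is minimised while
its height is within 15 mm of the standing reference height, the
tolerance that keeps stances detectable when the heel lands on a local
peak of the terrain. The numeric realisation (smoothing, minimum event
gap, plateau refinement) is documented in the function docstrings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .collision import GRAVITY, SubjectParams
from .errors import DomainError, ValidationError

HIP_ROLES = ("hip_left_anterior", "hip_right_anterior",
             "hip_left_posterior", "hip_right_posterior")
FOOT_ROLES = ("heel", "toe", "ankle")


@dataclass
class MarkerTrajectorySet:
    """Uniformly sampled 3D marker trajectories with role labels.

    ``markers`` maps role names to ``(n, 3)`` position arrays (x lateral,
    y longitudinal, z up; metres). ``standing_heights`` holds the marker
    heights recorded during quiet standing on flat ground (m), used as
    the stance height reference.
    """

    rate: float
    markers: dict
    standing_heights: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        n = None
        for name, arr in list(self.markers.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"marker '{name}' must be (n, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValidationError("markers must share a common length")
            self.markers[name] = arr

    @property
    def n_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def com(self) -> np.ndarray:
        """Centre-of-mass estimate: mean of the four hip markers."""
        hips = [self.markers[r] for r in HIP_ROLES]
        return np.mean(hips, axis=0)

    def translated(self, offset) -> "MarkerTrajectorySet":
        off = np.asarray(offset, dtype=float)
        return MarkerTrajectorySet(
            self.rate,
            {k: v + off for k, v in self.markers.items()},
            dict(self.standing_heights),
            dict(self.meta),
        )


@dataclass
class StepRecord:
    """All per-step kinematic measures attached to one touchdown."""

    touchdown_time: float
    liftoff_time: float
    direction: int                    # +1 along +y, -1 along -y
    step_length: float = np.nan       # CoM travel to the next touchdown (m)
    step_duration: float = np.nan     # s
    com_speed: float = np.nan         # step_length / step_duration (m/s)
    step_width: float = np.nan        # m, always >= 0
    leg_length_td: float = np.nan     # heel-CoM distance at touchdown (m)
    leg_angle_td: float = np.nan      # rad, + heel ahead of CoM
    foot_landing_velocity: tuple = (np.nan,) * 3   # m/s, travel frame
    com_landing_velocity: tuple = (np.nan,) * 3    # m/s, travel frame
    retraction_rate: float = np.nan   # rad/s
    foot_speed_froude: float = np.nan # forward heel landing speed / sqrt(gl)


@dataclass
class StepSeries:
    """Ordered step records of one trial plus per-traversal meander."""

    records: list
    meanders: list = field(default_factory=list)
    subject: SubjectParams = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = dict(r.__dict__)
            fv = d.pop("foot_landing_velocity")
            cv = d.pop("com_landing_velocity")
            d.update(
                foot_vx=fv[0], foot_vy=fv[1], foot_vz=fv[2],
                com_vx=cv[0], com_vy=cv[1], com_vz=cv[2],
            )
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Track-frame alignment
# ---------------------------------------------------------------------------

MAX_ALIGNMENT_ANGLE = np.radians(5.0)


def align_track_frame(markers: MarkerTrajectorySet) -> MarkerTrajectorySet:
    """Rotate about z so the average CoM path runs parallel to the y axis.

    The dominant horizontal direction of the CoM trajectory is found by
    principal-component analysis (an axis, so both directions of travel
    contribute consistently). Rotations beyond 5 degrees are clamped with
    a warning: larger values indicate a degenerate trajectory rather than
    an instrument misalignment. The applied angle is stored in
    ``meta['alignment_angle']``.
    """
    com = markers.com()[:, :2]
    centered = com - com.mean(axis=0)
    spread = np.linalg.norm(centered, axis=1).max()
    if spread < 1e-6:
        raise DomainError("stationary CoM trajectory: cannot align track frame")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]                     # dominant horizontal direction
    angle = np.arctan2(axis[0], axis[1])
    if angle > np.pi / 2:
        angle -= np.pi
    elif angle < -np.pi / 2:
        angle += np.pi
    if abs(angle) > MAX_ALIGNMENT_ANGLE:
        warnings.warn(
            f"track alignment angle {np.degrees(angle):.1f} deg exceeds "
            f"{np.degrees(MAX_ALIGNMENT_ANGLE):.0f} deg; clamping",
            stacklevel=2,
        )
        angle = float(np.clip(angle, -MAX_ALIGNMENT_ANGLE, MAX_ALIGNMENT_ANGLE))
    # R(angle) carries the detected axis (bearing `angle` from +y) onto +y
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out = MarkerTrajectorySet(
        markers.rate,
        {k: v @ rot.T for k, v in markers.markers.items()},
        dict(markers.standing_heights),
        dict(markers.meta),
    )
    out.meta["alignment_angle"] = float(angle)
    return out


# ---------------------------------------------------------------------------
# Stance detection
# ---------------------------------------------------------------------------

def _lowpass(signal, rate, cutoff):
    nyq = rate / 2.0
    if cutoff >= nyq:
        return signal
    b, a = butter(2, cutoff / nyq)
    return filtfilt(b, a, signal)


def detect_stance_events(
    markers: MarkerTrajectorySet,
    subject: SubjectParams = None,
    height_threshold: float = 0.015,
    speed_cutoff_hz: float = 10.0,
    min_gap: float = 0.3,
    plateau_fraction: float = 0.3,
):
    """Detect stance intervals from the heel marker.

    A stance is a contiguous interval in which the heel height stays
    within ``height_threshold`` (15 mm) above the standing reference and
    the smoothed heel forward speed attains a local minimum. Within each
    such interval the touchdown (liftoff) is then refined to the first
    (last) sample of the *positional* plateau: the heel's longitudinal
    position is constant during stance, so the stance core (samples whose
    smoothed speed is within ``plateau_fraction`` of the interval's speed
    range above its minimum) defines a reference position, and the
    touchdown is the first sample within a noise-scaled tolerance of it.
    Candidate intervals closer than ``min_gap`` to the previous accepted
    touchdown are rejected.

    Returns a list of ``(touchdown_time, liftoff_time)`` pairs.
    """
    if "heel" not in markers.standing_heights:
        raise ValidationError("standing reference height for 'heel' required")
    heel = markers.markers["heel"]
    rate = markers.rate
    t = markers.time
    z_ref = markers.standing_heights["heel"]

    vy_raw = np.abs(np.gradient(heel[:, 1], 1.0 / rate))
    vy = _lowpass(vy_raw, rate, speed_cutoff_hz)
    gate = heel[:, 2] <= z_ref + height_threshold

    # contiguous gated runs
    edges = np.flatnonzero(np.diff(gate.astype(int)))
    starts = list(edges[~gate[edges]] + 1) if edges.size else []
    stops = list(edges[gate[edges]] + 1) if edges.size else []
    if gate[0]:
        starts.insert(0, 0)
    if gate[-1]:
        stops.append(gate.size)

    events = []
    last_td = -np.inf
    y_heel = heel[:, 1]
    for s0, s1 in zip(starts, stops):
        if s1 - s0 < 2:
            continue
        # stance core: low-speed samples around the smoothed-speed minimum
        vmin = vy[s0:s1].min()
        span = max(vy[s0:s1].max() - vmin, 1e-12)
        core = np.flatnonzero(vy[s0:s1] <= vmin + plateau_fraction * span)
        y_core = y_heel[s0:s1][core]
        y_ref = float(np.median(y_core))
        noise = 1.4826 * float(np.median(np.abs(y_core - y_ref)))
        tol = max(0.002, 4.0 * noise)
        near = np.abs(y_heel[s0:s1] - y_ref) <= tol
        k = core[np.argmin(vy[s0:s1][core])]
        a = k
        while a > 0 and near[a - 1]:
            a -= 1
        b = k
        while b < near.size - 1 and near[b + 1]:
            b += 1
        td, lo = t[s0 + a], t[s0 + b]
        if td - last_td < min_gap:
            continue
        events.append((float(td), float(lo)))
        last_td = td
    if not events:
        warnings.warn("no stance events detected", stacklevel=2)
    return events


# ---------------------------------------------------------------------------
# Landing velocity (cubic fit in a pre-touchdown window)
# ---------------------------------------------------------------------------

def landing_velocity(times, xyz, t_td, window: float = 0.1):
    """Velocity at touchdown from a cubic fit over the preceding window.

    A least-squares cubic is fitted per axis to the trajectory over
    ``[t_td - window, t_td)`` and its analytic derivative is evaluated at
    the window end (the instant just prior to touchdown).
    """
    times = np.asarray(times, dtype=float)
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    if xyz.shape[0] == times.size and xyz.ndim == 2:
        pass
    mask = (times >= t_td - window) & (times < t_td)
    if mask.sum() < 4:
        raise DomainError(
            f"landing-velocity window before t={t_td} has {int(mask.sum())} "
            "samples; need at least 4"
        )
    ts = times[mask] - t_td          # local clock, 0 at touchdown
    vel = np.empty(xyz.shape[1])
    for ax in range(xyz.shape[1]):
        coeffs = np.polyfit(ts, xyz[mask, ax], 3)
        vel[ax] = np.polyval(np.polyder(coeffs), 0.0)
    return vel


# ---------------------------------------------------------------------------
# Per-step metrics
# ---------------------------------------------------------------------------

def _fit_line_distance(points, query):
    """Distance of ``query`` from the total-least-squares line through points."""
    pts = np.asarray(points, dtype=float)
    ctr = pts.mean(axis=0)
    d = pts - ctr
    if np.abs(d).max() < 1e-12:
        return float(np.linalg.norm(np.asarray(query) - ctr))
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    u = vt[0]
    rel = np.asarray(query, dtype=float) - ctr
    return float(abs(rel[0] * u[1] - rel[1] * u[0]))


def _path_length(points):
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def per_step_metrics(
    markers: MarkerTrajectorySet,
    events,
    subject: SubjectParams = None,
) -> StepSeries:
    """Compute every per-step kinematic measure from detected stances.

    Step length and duration run from one touchdown to the next within a
    traversal; CoM speed is their ratio. Step width is twice the nearest
    approach of the stance heel to the line fitted to the stance-phase
    CoM path in the horizontal plane. The touchdown leg is the heel-to-
    CoM segment (virtual leg); its angle from vertical is positive when
    the heel is ahead of the CoM in the direction of travel. Landing
    velocities come from the 100 ms cubic pre-touchdown fit, for both the
    heel and the CoM; the retraction rate is the component of the heel
    velocity relative to the CoM perpendicular to the virtual leg,
    divided by the virtual leg length. Meander is computed per traversal
    as the relative excess CoM path length over its straight-line fit.
    """
    subject = subject or SubjectParams()
    com = markers.com()
    heel = markers.markers["heel"]
    t = markers.time
    rate = markers.rate
    froude = subject.froude_speed

    if not events:
        return StepSeries([], [], subject)

    def idx(tv):
        return int(np.clip(round(tv * rate), 0, t.size - 1))

    # direction of travel per stance from CoM displacement around touchdown
    directions = []
    for td, lo in events:
        i0, i1 = idx(td - 0.1), idx(lo + 0.1)
        dy = com[i1, 1] - com[i0, 1]
        directions.append(1 if dy >= 0 else -1)

    records = []
    for k, (td, lo) in enumerate(events):
        j = directions[k]
        i_td = idx(td)
        rec = StepRecord(touchdown_time=td, liftoff_time=lo, direction=j)

        # step to the next touchdown in the same traversal
        if k + 1 < len(events) and directions[k + 1] == j:
            td2 = events[k + 1][0]
            disp = com[idx(td2), :2] - com[i_td, :2]
            rec.step_length = float(np.linalg.norm(disp))
            rec.step_duration = float(td2 - td)
            if rec.step_duration > 0:
                rec.com_speed = rec.step_length / rec.step_duration

        # step width from the stance-phase CoM regression line
        i_lo = idx(lo)
        if i_lo > i_td:
            stance_com = com[i_td:i_lo + 1, :2]
            heel_pos = heel[i_td:i_lo + 1, :2].mean(axis=0)
            rec.step_width = 2.0 * _fit_line_distance(stance_com, heel_pos)

        # virtual leg at touchdown
        leg = com[i_td] - heel[i_td]
        rec.leg_length_td = float(np.linalg.norm(leg))
        rec.leg_angle_td = float(
            np.arctan2(j * (heel[i_td, 1] - com[i_td, 1]),
                       com[i_td, 2] - heel[i_td, 2])
        )

        # landing velocities (travel frame: forward component = j * vy)
        try:
            fv = landing_velocity(t, heel, td)
            cv = landing_velocity(t, com, td)
        except DomainError:
            fv = cv = np.full(3, np.nan)
        frame = np.array([1.0, j, 1.0])
        rec.foot_landing_velocity = tuple(fv * frame)
        rec.com_landing_velocity = tuple(cv * frame)
        rec.foot_speed_froude = float(j * fv[1] / froude)

        # retraction rate: perpendicular relative foot velocity over leg
        if np.all(np.isfinite(fv)) and rec.leg_length_td > 0:
            v_rel = fv - cv
            u = leg / rec.leg_length_td
            v_perp = v_rel - (v_rel @ u) * u
            rec.retraction_rate = float(
                np.linalg.norm(v_perp) / rec.leg_length_td
            )
        records.append(rec)

    # meander per traversal (maximal runs of constant direction)
    meanders = []
    run_start = 0
    bounds = []
    for k in range(1, len(events)):
        if directions[k] != directions[run_start]:
            bounds.append((run_start, k - 1))
            run_start = k
    bounds.append((run_start, len(events) - 1))
    for a, b in bounds:
        if b <= a:
            warnings.warn("single-step traversal: meander skipped", stacklevel=2)
            continue
        i0, i1 = idx(events[a][0]), idx(events[b][0])
        path = com[i0:i1 + 1, :2]
        d = _path_length(path)
        ctr = path.mean(axis=0)
        rel = path - ctr
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        proj = rel @ vt[0]
        d0 = float(proj.max() - proj.min())
        if d0 > 0:
            meanders.append((d - d0) / d0)
    return StepSeries(records, meanders, subject)


# ---------------------------------------------------------------------------
# Trial summary
# ---------------------------------------------------------------------------

def trial_summary(series: StepSeries, subject: SubjectParams = None) -> pd.DataFrame:
    """Central tendency and variability of every per-step measure.

    Returns a table with mean/SD and median/IQR per measure, both in SI
    units and nondimensionalised (%LL for lengths and widths, Froude
    units for speeds) where the normalisation applies.
    """
    subject = subject or series.subject or SubjectParams()
    frame = series.to_frame()
    if len(frame) < 2:
        raise ValidationError("trial summary requires at least 2 steps")
    ell = subject.leg_length
    froude = subject.froude_speed
    norm_map = {
        "step_length": ("%LL", 100.0 / ell),
        "step_width": ("%LL", 100.0 / ell),
        "leg_length_td": ("%LL", 100.0 / ell),
        "com_speed": ("froude", 1.0 / froude),
        "foot_speed_froude": ("froude", 1.0),
    }
    measures = [
        "step_length", "step_duration", "com_speed", "step_width",
        "leg_length_td", "leg_angle_td", "retraction_rate",
        "foot_speed_froude",
    ]
    rows = []
    for m in measures:
        vals = frame[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        row = {
            "measure": m,
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
            "median": q50,
            "iqr": q75 - q25,
            "n": vals.size,
        }
        if m in norm_map:
            unit, scale = norm_map[m]
            row["norm_unit"] = unit
            row["norm_mean"] = row["mean"] * scale
            row["norm_sd"] = row["sd"] * scale
            row["norm_median"] = row["median"] * scale
            row["norm_iqr"] = row["iqr"] * scale
        rows.append(row)
    if series.meanders:
        mv = np.asarray(series.meanders, dtype=float)
        q25, q50, q75 = np.percentile(mv, [25, 50, 75])
        rows.append({
            "measure": "meander",
            "mean": mv.mean(),
            "sd": mv.std(ddof=1) if mv.size > 1 else 0.0,
            "median": q50,
            "iqr": q75 - q25,
            "n": mv.size,
        })
    return pd.DataFrame(rows).set_index("measure")
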