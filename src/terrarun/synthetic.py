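"""Synthetic terrain, trials and respirometry with known ground truth.

Every pipeline stage is testable without any recorded data: this module
generates (i) undulating terrain fields calibrated to target
peak-to-valley amplitude and peak-to-peak wavelength statistics,
(ii) back-and-forth running trials — marker trajectories at 300 Hz and
force-plate traces at 600 Hz — whose gait events, step geometry and
braking impulse fraction are known exactly, and (iii) breath-by-breath
respirometry with an exponential transient to a plateau.

The trial generator idealises the runner: a single "virtual" foot
performs every step (alternating its lateral offset), the heel comes to
rest instantaneously at touchdown, swing trajectories are cubic Hermite
segments (so landing velocities are exact), and the centre of mass
translates piecewise-linearly with a per-step vertical cosine
excursion. These idealisations make recovery tests sharp; they are not
a physiological simulation.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import BROCKWAY_CO2, BROCKWAY_O2, RespirometryTrace
from .errors import CalibrationError, ConfigurationError, ValidationError
from .kinematics import HIP_ROLES, MarkerTrajectorySet
from .kinetics import ForcePlateTrace
from .terrain import TerrainField, measure_amplitude_wavelength

GRAVITY = 9.81

# ---------------------------------------------------------------------------
# Terrain specs and generation
# ---------------------------------------------------------------------------

@dataclass
class TerrainSpec:
    """Target statistics of a synthetic terrain class.

    The presets in :data:`TERRAIN_CLASSES` reproduce the three track
    conditions: flat, and two undulating tracks whose peak-to-valley
    amplitudes are about ankle height (18 and 28 mm) and whose
    peak-to-peak wavelengths are about one foot length (102 and 108 mm).
    """

    label: str = "flat"
    amplitude_mean: float = 0.0       # m, peak-to-valley target
    amplitude_sd: float = 0.0
    wavelength_mean: float = 0.0      # m, peak-to-peak target
    wavelength_sd: float = 0.0
    length: float = 21.6              # m (straight section of the track)
    width: float = 0.6                # m
    resolution: float = 0.005         # m
    seed: int = 0

    def __post_init__(self):
        if self.label == "flat":
            self.amplitude_mean = 0.0
        if min(self.amplitude_mean, self.wavelength_mean) < 0:
            raise ValidationError("terrain targets must be non-negative")


TERRAIN_CLASSES = {
    "flat": dict(amplitude_mean=0.0, amplitude_sd=0.0,
                 wavelength_mean=0.0, wavelength_sd=0.0),
    "uneven1": dict(amplitude_mean=0.018, amplitude_sd=0.006,
                    wavelength_mean=0.102, wavelength_sd=0.045),
    "uneven2": dict(amplitude_mean=0.028, amplitude_sd=0.011,
                    wavelength_mean=0.108, wavelength_sd=0.052),
}


def terrain_spec(label: str, seed: int = 0, **overrides) -> TerrainSpec:
    """Preset spec for one of the track classes (flat/uneven1/uneven2)."""
    if label not in TERRAIN_CLASSES:
        raise ConfigurationError(
            f"unknown terrain class '{label}'; choose from {sorted(TERRAIN_CLASSES)}"
        )
    kwargs = dict(TERRAIN_CLASSES[label])
    kwargs.update(overrides)
    return TerrainSpec(label=label, seed=seed, **kwargs)


def _band_filtered_field(white, dx, dy, wavelength, rel_bandwidth):
    """Unit-RMS Gaussian random field band-passed around one wavelength."""
    ny, nx = white.shape
    ky = np.fft.fftfreq(ny, dy)
    kx = np.fft.rfftfreq(nx, dx)
    k = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
    k0 = 1.0 / wavelength
    weight = np.exp(-0.5 * ((k - k0) / (rel_bandwidth * k0)) ** 2)
    weight[0, 0] = 0.0
    out = np.fft.irfft2(np.fft.rfft2(white) * weight, s=white.shape)
    rms = out.std()
    return out / rms if rms > 0 else out


def generate_terrain(
    spec: TerrainSpec,
    rel_bandwidth: float = 0.4,
    tol_amplitude: float = 0.0005,
    tol_wavelength: float = 0.003,
    max_iter: int = 60,
) -> TerrainField:
    """Generate a terrain field matching the spec's roughness targets.

    A white-noise grid (deterministic per seed) is spectrally band-pass
    filtered around a centre wavelength and rescaled. The centre
    wavelength and the height scale are iterated until the extremum-based
    measurement (:func:`terrarun.terrain.measure_amplitude_wavelength`)
    reproduces the target amplitude and wavelength means within the
    declared tolerances (0.5 mm and 3 mm by default). The same noise
    realisation is refiltered each iteration, so the result is a pure
    function of the spec.
    """
    ny = int(round(spec.length / spec.resolution)) + 1
    nx = int(round(spec.width / spec.resolution)) + 1
    if spec.label == "flat" or spec.amplitude_mean == 0.0:
        return TerrainField(np.zeros((ny, nx)), spec.resolution)
    if spec.length < 2 * spec.wavelength_mean:
        raise ConfigurationError("field must span at least two wavelengths")

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((ny, nx))
    lam_c = spec.wavelength_mean
    scale = spec.amplitude_mean / 2.0
    achieved = None
    for _ in range(max_iter):
        base = _band_filtered_field(
            white, spec.resolution, spec.resolution, lam_c, rel_bandwidth
        )
        field_ = TerrainField(base * scale, spec.resolution)
        stats = measure_amplitude_wavelength(field_)
        achieved = stats
        amp_ok = abs(stats.amplitude_mean - spec.amplitude_mean) <= tol_amplitude
        wl_ok = abs(stats.wavelength_mean - spec.wavelength_mean) <= tol_wavelength
        if amp_ok and wl_ok:
            out = field_.mean_subtracted()
            return out
        if stats.amplitude_mean > 0:
            scale *= spec.amplitude_mean / stats.amplitude_mean
        if stats.wavelength_mean > 0:
            lam_c *= (spec.wavelength_mean / stats.wavelength_mean) ** 0.7
    raise CalibrationError(
        f"terrain calibration did not converge for class '{spec.label}': "
        f"achieved amplitude {achieved.amplitude_mean * 1e3:.1f} mm, "
        f"wavelength {achieved.wavelength_mean * 1e3:.1f} mm",
        achieved=achieved,
    )


# ---------------------------------------------------------------------------
# Gait spec and ground truth
# ---------------------------------------------------------------------------

@dataclass
class GaitSpec:
    """Parameters of the synthetic runner (defaults: the mean subject)."""

    speed: float = 3.2                        # mean CoM speed, m/s
    step_length_mean: float = 1.12            # m (about 126 %LL)
    step_length_sd: float = 0.053             # m (6 %LL)
    step_width_mean: float = 0.042            # m (4.7 %LL)
    step_width_sd: float = 0.030              # m
    duty_factor: float = 0.28                 # stance / stride duration
    approach_duration: float = 0.12           # constant-velocity landing, s
    leg_length: float = 0.89                  # m
    body_mass: float = 66.1                   # kg
    foot_length: float = 0.19                 # m
    touchdown_leg_angle: float = 0.20         # rad
    foot_landing_speed_froude: float = 0.37   # forward heel speed / sqrt(gl)
    foot_landing_speed_sd: float = 0.0
    braking_impulse_fraction: float = 0.06    # of aerial forward momentum
    com_vertical_landing_speed: float = 0.7   # m/s downward
    heel_liftoff_speed: float = 1.2           # m/s upward at liftoff
    heel_landing_sink_speed: float = 0.4      # m/s downward at touchdown
    heel_standing_height: float = 0.03        # heel marker height, standing
    com_height: float = 1.0                   # m, standing CoM height
    duration_s: float = 30.0
    marker_noise_sd: float = 0.0              # m, per coordinate
    force_noise_sd: float = 0.5               # N, plate baseline
    marker_rate: float = 300.0                # Hz
    force_rate: float = 600.0                 # Hz
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.duty_factor < 0.5:
            raise ValidationError(
                "duty factor must lie in (0, 0.5) for the single-virtual-"
                "foot trial model (stance shorter than one step period)"
            )
        if min(self.step_length_sd, self.step_width_sd,
               self.foot_landing_speed_sd) < 0:
            raise ValidationError("spread parameters must be non-negative")

    @property
    def cadence(self) -> float:
        """Nominal step frequency (steps/s)."""
        return self.speed / self.step_length_mean

    @property
    def froude_speed(self) -> float:
        return math.sqrt(GRAVITY * self.leg_length)


@dataclass
class GroundTruth:
    """Everything the generator knows that analyses must recover."""

    touchdown_times: np.ndarray
    liftoff_times: np.ndarray
    footsteps: np.ndarray            # (K, 2) world x, y of the heel
    directions: np.ndarray           # (K,) ±1
    step_lengths: np.ndarray         # (K,) CoM travel to next td; nan at ends
    step_widths: np.ndarray          # (K,)
    foot_landing_speeds: np.ndarray  # (K,) froude units
    braking_fraction: float
    plate_steps: np.ndarray          # indices of steps landing on the plate
    n_turnarounds: int

    def __post_init__(self):
        if np.any(np.diff(self.touchdown_times) <= 0):
            raise ValidationError("touchdown times must strictly increase")
        if self.touchdown_times.size != self.footsteps.shape[0]:
            raise ValidationError("one footstep per stance required")


def _hermite(t0, t1, p0, p1, v0, v1, t):
    """Cubic Hermite interpolation between (p0, v0) and (p1, v1)."""
    h = t1 - t0
    s = (t - t0) / h
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * h * v0 + h01 * p1 + h11 * h * v1


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def generate_trial(
    gait: GaitSpec,
    terrain_field: TerrainField,
    plate_center: float = None,
    plate_length: float = 1.2,
):
    """Simulate one back-and-forth trial on a terrain field.

    Returns ``(markers, forces, truth)``: a
    :class:`~terrarun.kinematics.MarkerTrajectorySet` at the marker rate,
    a :class:`~terrarun.kinetics.ForcePlateTrace` at the plate rate
    (active only for stances inside the plate region at the track
    centre) and the :class:`GroundTruth`.

    The vertical ground reaction is a double-bump profile whose stance
    impulse supports body weight over one step period; the fore-aft
    component has a braking lobe whose impulse is exactly the configured
    fraction of the aerial forward momentum, followed by an equal
    propulsive lobe.
    """
    rng = np.random.default_rng(gait.seed)
    xmin, ymin, xmax, ymax = terrain_field.bounds
    margin = 0.4
    ylo, yhi = ymin + margin, ymax - margin
    usable = yhi - ylo
    if gait.step_length_mean >= usable:
        raise ValidationError(
            f"step length {gait.step_length_mean} m does not fit the "
            f"usable track length {usable:.2f} m"
        )
    if usable < 2 * gait.step_length_mean:
        raise ValidationError("track too short for two steps")
    x_center = 0.5 * (xmin + xmax)
    v = gait.speed
    lead = 1.2 * gait.leg_length * math.sin(gait.touchdown_leg_angle)

    # --- footstep plan (internal clock; re-zeroed before emission) --------
    tds, los, xs, ys, dirs, froudes, slens = [], [], [], [], [], [], []
    t = 1.0
    y = ylo + 0.05 * usable
    j = 1
    n_turn = 0
    t_end = gait.duration_s + 2.0
    while t < t_end:
        sl = float(np.clip(rng.normal(gait.step_length_mean,
                                      gait.step_length_sd), 0.3, 0.9 * usable))
        sw = float(np.clip(rng.normal(gait.step_width_mean,
                                      gait.step_width_sd), 0.0, 0.25))
        fr = float(np.clip(rng.normal(gait.foot_landing_speed_froude,
                                      gait.foot_landing_speed_sd), 0.05, 1.3))
        parity = len(tds) % 2
        x = x_center + (1 if parity == 0 else -1) * sw / 2.0
        # dirs[k] is the direction of travel when ARRIVING at footstep k
        tds.append(t)
        xs.append(x)
        ys.append(y)
        dirs.append(j)
        froudes.append(fr)
        tstep = sl / v
        los.append(t + gait.duty_factor * 2.0 * tstep)
        y_next = y + j * sl
        if y_next > yhi or y_next < ylo:
            j = -j
            n_turn += 1
            y_next = y + j * sl
        slens.append(sl)
        y = y_next
        t = t + tstep

    tds = np.asarray(tds)
    los = np.asarray(los)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    dirs = np.asarray(dirs, dtype=int)
    froudes = np.asarray(froudes)
    slens = np.asarray(slens)
    K = tds.size

    # emission window: start mid-first-swing, re-zero the clock
    t0 = los[0] + 0.02
    t1 = min(tds[-1] - 0.01, t0 + gait.duration_s)
    keep = np.nonzero((tds >= t0 + 0.05) & (los <= t1 - 0.05))[0]
    if keep.size < 2:
        raise ValidationError("duration too short for two full stances")

    # stance heel heights include the local terrain
    z_st = gait.heel_standing_height + terrain_field.interpolate(xs, ys)

    # --- heel trajectory at the marker rate -------------------------------
    n3 = int(round((t1 - t0) * gait.marker_rate)) + 1
    tm = t0 + np.arange(n3) / gait.marker_rate
    heel = np.empty((n3, 3))
    glv = gait.froude_speed
    for k in range(K):
        if k + 1 < K:
            seg = (tm >= tds[k]) & (tm < tds[k + 1])
        else:
            seg = tm >= tds[k]
        if not seg.any():
            continue
        ts = tm[seg]
        stance = ts <= los[k]
        out = np.empty((ts.size, 3))
        out[stance] = [xs[k], ys[k], z_st[k]]
        if (~stance).any() and k + 1 < K:
            # swing = fast transport (Hermite) + constant-velocity
            # landing approach, so landing velocities are locally linear
            sw_t = ts[~stance]
            swing = tds[k + 1] - los[k]
            t_app = min(gait.approach_duration, 0.75 * swing)
            t_split = tds[k + 1] - t_app
            vy_land = dirs[k + 1] * froudes[k + 1] * glv
            vz_land = -gait.heel_landing_sink_speed
            y_app = ys[k + 1] - vy_land * t_app
            z_app = z_st[k + 1] - vz_land * t_app
            early = sw_t < t_split
            yy = np.empty(sw_t.size)
            zz = np.empty(sw_t.size)
            yy[early] = _hermite(los[k], t_split, ys[k], y_app,
                                 0.0, vy_land, sw_t[early])
            zz[early] = _hermite(los[k], t_split, z_st[k], z_app,
                                 gait.heel_liftoff_speed, vz_land,
                                 sw_t[early])
            yy[~early] = y_app + vy_land * (sw_t[~early] - t_split)
            zz[~early] = z_app + vz_land * (sw_t[~early] - t_split)
            out[~stance, 0] = _hermite(los[k], tds[k + 1], xs[k], xs[k + 1],
                                       0.0, 0.0, sw_t)
            out[~stance, 1] = yy
            out[~stance, 2] = zz
        elif (~stance).any():
            out[~stance] = [xs[k], ys[k], z_st[k]]
        heel[seg] = out
    # samples before the first touchdown: swing from footstep 0
    pre = tm < tds[0]
    if pre.any():
        heel[pre] = heel[np.argmin(pre)]  # unreachable by construction

    # --- CoM trajectory ----------------------------------------------------
    anchors = ys - dirs * lead
    com_y = np.interp(tm, tds, anchors)
    # extrapolate linearly outside the anchor range
    com_y[tm < tds[0]] = anchors[0] - dirs[0] * v * (tds[0] - tm[tm < tds[0]])
    com_y[tm > tds[-1]] = anchors[-1] + dirs[-1] * v * (tm[tm > tds[-1]] - tds[-1])
    com_x = np.full(n3, x_center)
    com_z = np.full(n3, gait.com_height)
    phi0 = math.pi / 4
    for k in range(K - 1):
        seg = (tm >= tds[k]) & (tm < tds[k + 1])
        if not seg.any():
            continue
        dk = tds[k + 1] - tds[k]
        amp = gait.com_vertical_landing_speed * dk / (2 * math.pi * math.sin(phi0))
        tau = (tm[seg] - tds[k]) / dk
        com_z[seg] = gait.com_height + amp * (np.cos(2 * math.pi * tau + phi0)
                                              - math.cos(phi0))
    com = np.column_stack([com_x, com_y, com_z])

    # --- assemble markers ---------------------------------------------------
    toe = heel + np.column_stack([np.zeros(n3),
                                  0.95 * gait.foot_length * np.interp(
                                      tm, tds, dirs.astype(float)),
                                  np.full(n3, 0.01)])
    ankle = heel + np.array([0.0, 0.0, 0.05])
    hip_offsets = {
        "hip_left_anterior": (-0.12, 0.05, 0.0),
        "hip_right_anterior": (0.12, 0.05, 0.0),
        "hip_left_posterior": (-0.12, -0.05, 0.0),
        "hip_right_posterior": (0.12, -0.05, 0.0),
    }
    markers = {"heel": heel, "toe": toe, "ankle": ankle}
    for role, off in hip_offsets.items():
        markers[role] = com + np.asarray(off)
    if gait.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, gait.marker_noise_sd, markers[name].shape
            )
    marker_set = MarkerTrajectorySet(
        gait.marker_rate,
        markers,
        standing_heights={"heel": gait.heel_standing_height,
                          "toe": gait.heel_standing_height + 0.01,
                          "ankle": gait.heel_standing_height + 0.05},
        meta={"seed": gait.seed, "terrain_origin": terrain_field.origin},
    )

    # --- force plate trace --------------------------------------------------
    if plate_center is None:
        plate_center = 0.5 * (ymin + ymax)
    n6 = int(round((t1 - t0) * gait.force_rate)) + 1
    tf = t0 + np.arange(n6) / gait.force_rate
    fz = np.zeros(n6)
    fy = np.zeros(n6)
    fx = np.zeros(n6)
    mb, g = gait.body_mass, GRAVITY
    plate_steps = []
    for k in keep:
        if abs(ys[k] - plate_center) > plate_length / 2.0:
            continue
        plate_steps.append(k)
        seg = (tf >= tds[k]) & (tf <= los[k])
        if seg.sum() < 8:
            continue
        ts = tf[seg]
        tau = (ts - tds[k]) / (los[k] - tds[k])
        # vertical: impact + active peak, impulse = weight over one step
        prof = 0.6 * _gauss(tau, 0.15, 0.06) + 1.0 * _gauss(tau, 0.45, 0.16)
        tstep_k = slens[k] / v
        prof_impulse = np.trapezoid(prof, ts)
        fz[seg] += prof * (mb * g * tstep_k / prof_impulse)
        # fore-aft: braking lobe with the exact target impulse, then an
        # equal propulsive lobe
        brake = _gauss(tau, 0.20, 0.08)
        prop = _gauss(tau, 0.70, 0.10)
        b_imp = gait.braking_impulse_fraction * mb * v
        fy[seg] += dirs[k] * (-brake / np.trapezoid(brake, ts) * b_imp
                              + prop / np.trapezoid(prop, ts) * b_imp)
    if gait.force_noise_sd > 0:
        fx += rng.normal(0.0, gait.force_noise_sd, n6)
        fy += rng.normal(0.0, gait.force_noise_sd, n6)
        fz += rng.normal(0.0, gait.force_noise_sd, n6)

    # unloaded baseline: longest quiet gap between plate stances
    quiet_bounds = [t0] + [float(x) for k in plate_steps
                           for x in (tds[k], los[k])] + [t1]
    gaps = [(quiet_bounds[i + 1] - quiet_bounds[i],
             quiet_bounds[i], quiet_bounds[i + 1])
            for i in range(0, len(quiet_bounds), 2)]
    _, g0, g1 = max(gaps)
    baseline = (g0 - t0 + 0.05, g1 - t0 - 0.05)

    force_trace = ForcePlateTrace(
        gait.force_rate, fx, fy, fz,
        baseline_interval=baseline,
        meta={"seed": gait.seed, "plate_center": plate_center,
              "plate_length": plate_length,
              "baseline_sd": gait.force_noise_sd},
    )

    # --- ground truth (emission clock) --------------------------------------
    step_lengths = np.full(keep.size, np.nan)
    for idx_out, k in enumerate(keep):
        if k + 1 < K and dirs[k + 1] == dirs[k] and (k + 1) in keep:
            step_lengths[idx_out] = abs(anchors[k + 1] - anchors[k])
    truth = GroundTruth(
        touchdown_times=tds[keep] - t0,
        liftoff_times=los[keep] - t0,
        footsteps=np.column_stack([xs[keep], ys[keep]]),
        directions=dirs[keep],
        step_lengths=step_lengths,
        step_widths=2.0 * np.abs(xs[keep] - x_center),
        foot_landing_speeds=froudes[keep],
        braking_fraction=gait.braking_impulse_fraction,
        plate_steps=np.array([int(np.nonzero(keep == k)[0][0])
                              for k in plate_steps if k in keep], dtype=int),
        n_turnarounds=n_turn,
    )
    return marker_set, force_trace, truth


# ---------------------------------------------------------------------------
# Respirometry
# ---------------------------------------------------------------------------

def generate_respirometry(
    resting_rate: float,
    running_rate: float,
    transient_tau: float = 30.0,
    duration: float = 480.0,
    seed: int = 0,
    rest_duration: float = 180.0,
    breath_interval_rest: float = 3.0,
    breath_interval_run: float = 1.5,
    noise_sd: float = 0.0,
    rer_rest: float = 0.85,
    rer_run: float = 0.90,
) -> RespirometryTrace:
    """Breath-by-breath gas exchange with an exponential run transient.

    ``resting_rate`` and ``running_rate`` are metabolic powers (W); they
    are converted to VO2/VCO2 via the Brockway equivalence at the given
    respiratory exchange ratios. The running segment rises exponentially
    from the resting power to the running power with time constant
    ``transient_tau`` (s). ``noise_sd`` is the relative (fractional) SD
    of multiplicative breath noise.
    """
    if resting_rate <= 0 or running_rate <= 0:
        raise ValidationError("metabolic rates must be positive")
    if transient_tau <= 0:
        raise ValidationError("transient tau must be positive")
    rng = np.random.default_rng(seed)
    t_rest = np.arange(0.0, rest_duration, breath_interval_rest)
    t_run = np.arange(rest_duration, rest_duration + duration,
                      breath_interval_run)
    p_rest = np.full(t_rest.size, resting_rate)
    p_run = resting_rate + (running_rate - resting_rate) * (
        1.0 - np.exp(-(t_run - rest_duration) / transient_tau)
    )
    times = np.concatenate([t_rest, t_run])
    powers = np.concatenate([p_rest, p_run])
    rers = np.concatenate([np.full(t_rest.size, rer_rest),
                           np.full(t_run.size, rer_run)])
    vo2 = powers / (BROCKWAY_O2 + BROCKWAY_CO2 * rers)
    vco2 = rers * vo2
    if noise_sd > 0:
        vo2 = np.clip(vo2 * (1 + rng.normal(0, noise_sd, vo2.size)), 0, None)
        vco2 = np.clip(vco2 * (1 + rng.normal(0, noise_sd, vco2.size)), 0, None)
    labels = np.array(["rest"] * t_rest.size + ["run"] * t_run.size)
    meta = {"seed": seed, "transient_tau": transient_tau,
            "plateau_expected": duration >= 3 * transient_tau}
    return RespirometryTrace(times, vo2, vco2, labels, meta)


# ---------------------------------------------------------------------------
# External time-series formats (delimited table + JSON header)
# ---------------------------------------------------------------------------

def save_markers(markers: MarkerTrajectorySet, path) -> Path:
    path = Path(path)
    names = sorted(markers.markers)
    cols = [markers.time]
    header = ["t"]
    for n in names:
        cols.append(markers.markers[n])
        header += [f"{n}_{ax}" for ax in "xyz"]
    data = np.column_stack(cols)
    np.savetxt(path, data, fmt="%.17g", delimiter="\t",
               header="\t".join(header), comments="")
    meta = {"rate": markers.rate, "markers": names,
            "standing_heights": markers.standing_heights,
            "meta": {k: v for k, v in markers.meta.items()
                     if isinstance(v, (int, float, str, list, tuple))}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_markers(path) -> MarkerTrajectorySet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    out = {}
    for i, name in enumerate(meta["markers"]):
        out[name] = table[:, 1 + 3 * i:4 + 3 * i]
    return MarkerTrajectorySet(meta["rate"], out,
                               meta.get("standing_heights", {}),
                               meta.get("meta", {}))


def save_forces(trace: ForcePlateTrace, path) -> Path:
    path = Path(path)
    data = np.column_stack([trace.time, trace.fx, trace.fy, trace.fz])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t",
               header="t\tfx\tfy\tfz", comments="")
    meta = {"rate": trace.rate, "baseline_interval": list(trace.baseline_interval)
            if trace.baseline_interval else None,
            "meta": {k: v for k, v in trace.meta.items()
                     if isinstance(v, (int, float, str, list, tuple))}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_forces(path) -> ForcePlateTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    bl = meta.get("baseline_interval")
    return ForcePlateTrace(meta["rate"], table[:, 1], table[:, 2], table[:, 3],
                           tuple(bl) if bl else None, meta.get("meta", {}))


def save_respirometry(trace: RespirometryTrace, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame({
        "t": trace.times, "vo2": trace.vo2, "vco2": trace.vco2,
        "label": trace.labels,
    })
    frame.to_csv(path, index=False)
    return path


def load_respirometry(path) -> RespirometryTrace:
    frame = pd.read_csv(path)
    return RespirometryTrace(frame["t"].to_numpy(), frame["vo2"].to_numpy(),
                             frame["vco2"].to_numpy(),
                             frame["label"].to_numpy())
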