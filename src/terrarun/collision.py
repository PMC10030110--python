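"""Four-link sagittal collision models of heel strike.

At touchdown the leg-plus-torso system undergoes an instantaneous,
inelastic, point-contact collision with the ground: the contact point O on
the foot comes to rest and only the (impulsive) ground reaction at O and
the joint reaction impulses act. Two extremes of joint stiffness are
modelled:

* **rigid joints** — the whole body rotates as one rigid object after the
  collision; a single post-collision angular velocity follows from
  angular momentum balance about O.
* **infinitely compliant joints** — each of the four segments (foot,
  shank, thigh, torso) keeps its own post-collision angular velocity;
  the joints transmit reaction impulses but no torque impulses, giving
  four angular-momentum balance equations (whole body about O, all
  segments above the ankle about the ankle, above the knee about the
  knee, torso about the hip) closed by the kinematic chain from the
  resting contact point.

The fore-aft component of the collisional impulse, normalised by the
pre-collision forward momentum, brackets the momentum fraction a runner
loses during the braking phase of stance: the rigid model overestimates
it, the compliant model underestimates it.

All vectors live in the sagittal plane with ``y`` forward (direction of
travel) and ``z`` up; rotations are about the lateral axis, positive
counterclockwise when viewed from the runner's left (+x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError, ValidationError

GRAVITY = 9.81


def _perp(r):
    """omega x r for unit angular velocity about +x, r = (y, z)."""
    return np.array([-r[1], r[0]])


def _cross(a, b):
    """x-component of the cross product of two sagittal (y, z) vectors."""
    return a[0] * b[1] - a[1] * b[0]


# ---------------------------------------------------------------------------
# Anthropometry and chain construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anthropometry:
    """Segment scaling fractions for the four-link chain.

    Masses are fractions of body mass; the torso (head-arms-trunk) takes
    the remainder. Leg segment lengths are fractions of leg length (the
    greater-trochanter-to-lateral-malleolus distance); they derive from
    standard gait-analysis tables expressed relative to stature, using a
    leg length of 0.53 stature. Centre-of-mass fractions are measured
    from the proximal end of each segment, and radii of gyration are
    about the segment's own centre of mass, as fractions of its length.
    """

    foot_mass: float = 0.0145
    shank_mass: float = 0.0465
    thigh_mass: float = 0.100
    torso_mass: float = None          # None -> remainder of body mass

    shank_length: float = 0.464       # 0.246 stature / 0.53
    thigh_length: float = 0.462       # 0.245 stature / 0.53
    ankle_height: float = 0.074       # 0.039 stature / 0.53
    torso_length: float = 0.543       # hip->C7 trunk, 0.288 stature / 0.53

    foot_com: float = 0.50            # from heel
    shank_com: float = 0.433          # from knee
    thigh_com: float = 0.433          # from hip
    torso_com: float = 0.626          # from hip, along the trunk

    foot_gyration: float = 0.475
    shank_gyration: float = 0.302
    thigh_gyration: float = 0.323
    torso_gyration: float = 0.496

    #: Heel-strike inclination of the foot above horizontal (rad).
    foot_inclination: float = math.radians(20.0)

    def mass_fractions(self):
        mf, ms, mt = self.foot_mass, self.shank_mass, self.thigh_mass
        m_torso = self.torso_mass
        if m_torso is None:
            m_torso = 1.0 - (mf + ms + mt)
        total = mf + ms + mt + m_torso
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"segment mass fractions sum to {total}, expected 1"
            )
        if min(mf, ms, mt, m_torso) <= 0:
            raise ValidationError("segment mass fractions must be positive")
        return mf, ms, mt, m_torso


DEFAULT_ANTHROPOMETRY = Anthropometry()


@dataclass
class SubjectParams:
    """Dimensional parameters of one runner."""

    body_mass: float = 66.1       # kg
    leg_length: float = 0.89      # m
    foot_length: float = 0.19     # m
    ankle_height: float = None    # m; default from anthropometry table
    gravity: float = GRAVITY

    def __post_init__(self):
        if min(self.body_mass, self.leg_length, self.foot_length) <= 0:
            raise ValidationError("subject parameters must be positive")

    @property
    def froude_speed(self) -> float:
        """sqrt(g * leg length), the speed unit (m/s)."""
        return math.sqrt(self.gravity * self.leg_length)


@dataclass
class SegmentChain:
    """A planar four-link body posed at touchdown.

    Points are sagittal ``(y, z)`` coordinates in metres with the heel A
    at the origin: A-B the foot, B-C the shank, C-D the thigh, D-N the
    torso. O is the ground contact at foot-strike index ``s`` along the
    foot. Masses ``m = (foot, shank, thigh, torso)``, segment centres of
    mass ``coms = (E, F, K, H)`` and own-centre inertias ``inertias``.
    """

    points: dict                    # 'A','B','C','D','N','O'
    masses: np.ndarray              # (4,)
    coms: np.ndarray                # (4, 2)
    inertias: np.ndarray            # (4,)
    foot_strike_index: float
    leg_angle: float                # rad from vertical, + heel ahead of CoM

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def com(self) -> np.ndarray:
        """Whole-body centre of mass G by mass-weighted composition."""
        return self.masses @ self.coms / self.total_mass

    @property
    def inertia_about_com(self) -> float:
        """Whole-body I/G by the parallel-axis composition of segments."""
        g = self.com
        d2 = ((self.coms - g) ** 2).sum(axis=1)
        return float(self.inertias.sum() + (self.masses * d2).sum())


def build_chain(
    subject: SubjectParams,
    leg_angle: float,
    foot_strike_index: float = 0.15,
    anthropometry: Anthropometry = DEFAULT_ANTHROPOMETRY,
    touchdown_leg_length: float = None,
) -> SegmentChain:
    """Pose the four-link chain for a heel-strike touchdown.

    The ankle, knee and hip are collinear along the virtual-leg line from
    the heel at ``leg_angle`` from vertical (positive = heel ahead of the
    centre of mass); the torso stands vertically on the hip; the foot
    points forward, inclined heel-down by the anthropometric heel-strike
    angle, with the contact point O at fraction ``foot_strike_index`` of
    the foot length from the heel.

    If ``touchdown_leg_length`` (heel-to-CoM distance, m) is given, the
    leg segments are scaled by a common factor so the composed whole-body
    centre of mass lies at exactly that distance from the heel.
    """
    if not 0.0 <= foot_strike_index <= 1.0:
        raise ValidationError("foot_strike_index must lie in [0, 1]")
    mf, ms, mt, mh = anthropometry.mass_fractions()
    mb = subject.body_mass
    masses = np.array([mf, ms, mt, mh]) * mb
    ell = subject.leg_length
    lf = subject.foot_length
    hf = subject.ankle_height
    if hf is None:
        hf = anthropometry.ankle_height * ell
    ls = anthropometry.shank_length * ell
    lt = anthropometry.thigh_length * ell
    lh = anthropometry.torso_length * ell

    theta = float(leg_angle)
    u = np.array([-math.sin(theta), math.cos(theta)])   # heel -> hip direction
    up = np.array([0.0, 1.0])
    phi = anthropometry.foot_inclination
    fdir = np.array([math.cos(phi), math.sin(phi)])     # heel -> toe

    A = np.zeros(2)
    toe = A + lf * fdir
    E = A + anthropometry.foot_com * lf * fdir          # foot CoM, alpha-free

    # along-leg distances of the joints and leg-segment CoMs (natural)
    d_B = hf
    d_C = hf + ls
    d_D = hf + ls + lt
    d_F = d_C - anthropometry.shank_com * ls
    d_K = d_D - anthropometry.thigh_com * lt
    h_off = anthropometry.torso_com * lh * up           # hip -> torso CoM

    def compose(alpha):
        B = A + alpha * d_B * u
        C = A + alpha * d_C * u
        D = A + alpha * d_D * u
        N = D + lh * up
        F = A + alpha * d_F * u
        K = A + alpha * d_K * u
        H = D + h_off
        return B, C, D, N, F, K, H

    alpha = 1.0
    if touchdown_leg_length is not None:
        # G(alpha) = P0 + alpha * Q * u  -> solve |G - A| = L_td
        P0 = mf * E + mh * h_off
        Q = ms * d_F + mt * d_K + mh * d_D
        a = Q * Q
        b = 2.0 * Q * float(u @ P0)
        c = float(P0 @ P0) - touchdown_leg_length ** 2
        disc = b * b - 4 * a * c
        if disc < 0:
            raise DomainError(
                "requested touchdown leg length is unreachable for this "
                "anthropometry"
            )
        roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]
        roots = [r for r in roots if r > 0]
        if not roots:
            raise DomainError("no positive leg scaling solves the touchdown pose")
        alpha = min(roots, key=lambda r: abs(r - 1.0))

    B, C, D, N, F, K, H = compose(alpha)
    O = A + foot_strike_index * lf * fdir
    inertias = np.array([
        masses[0] * (anthropometry.foot_gyration * lf) ** 2,
        masses[1] * (anthropometry.shank_gyration * alpha * ls) ** 2,
        masses[2] * (anthropometry.thigh_gyration * alpha * lt) ** 2,
        masses[3] * (anthropometry.torso_gyration * lh) ** 2,
    ])
    return SegmentChain(
        points={"A": A, "B": B, "C": C, "D": D, "N": N, "O": O},
        masses=masses,
        coms=np.array([E, F, K, H]),
        inertias=inertias,
        foot_strike_index=foot_strike_index,
        leg_angle=theta,
    )


# ---------------------------------------------------------------------------
# Collision states and results
# ---------------------------------------------------------------------------

@dataclass
class CollisionState:
    """Pre-collision whole-body motion (shared by all segments)."""

    v_com: np.ndarray       # (vy, vz) m/s
    omega: float = 0.0      # rad/s about +x

    def __post_init__(self):
        self.v_com = np.asarray(self.v_com, dtype=float)
        if self.v_com.shape != (2,) or not np.all(np.isfinite(self.v_com)):
            raise ValidationError("v_com must be a finite (vy, vz) pair")
        if not np.isfinite(self.omega):
            raise ValidationError("omega must be finite")


@dataclass
class CollisionResult:
    """Post-collision state and impulses of one touchdown."""

    model: str
    omegas: np.ndarray          # per-segment post angular velocities (4,)
    v_com_post: np.ndarray      # (vy, vz)
    impulse: np.ndarray         # J = Mb (vG+ - vG-), N s
    jy_star: float              # |fore-aft impulse component|, N s
    jb: float                   # Mb * forward momentum normaliser, N s
    normalized_impulse: float   # |Jy*| / Jb
    contact_speed_post: float = 0.0
    residual: float = 0.0


def state_from_landing(
    chain: SegmentChain,
    com_speed: float,
    vertical_speed: float = 0.7,
    foot_speed_froude: float = 0.37,
    subject: SubjectParams = None,
) -> CollisionState:
    """Build a pre-collision state from landing kinematics.

    ``vertical_speed`` is the downward CoM landing speed (m/s, positive
    down); ``foot_speed_froude`` the absolute forward heel speed in units
    of sqrt(g l). The shared pre-collision angular velocity (the leg
    retraction) is the rate that carries the heel at the given forward
    speed while the CoM translates at ``com_speed``.
    """
    subject = subject or SubjectParams()
    v_foot = foot_speed_froude * subject.froude_speed
    g = chain.com
    if abs(g[1]) < 1e-9:
        raise DomainError("degenerate chain: CoM at heel height")
    # heel velocity: v_A = v_G + omega * perp(A - G); forward component
    # v_Ay = vy + omega * G_z
    omega = (v_foot - com_speed) / g[1]
    return CollisionState(np.array([com_speed, -abs(vertical_speed)]), omega)


def _pre_segment_velocities(chain: SegmentChain, state: CollisionState):
    g = chain.com
    return [state.v_com + state.omega * _perp(c - g) for c in chain.coms]


def _make_result(model, chain, state, omegas, v_segments):
    mb = chain.total_mass
    v_post = sum(m * v for m, v in zip(chain.masses, v_segments)) / mb
    impulse = mb * (v_post - state.v_com)
    jy = float(impulse[0])
    jb = mb * float(state.v_com[0])
    jy_star = abs(jy)
    if jb <= 0:
        norm = np.nan if jb == 0 else jy_star / jb
    else:
        norm = jy_star / jb
    return CollisionResult(
        model=model,
        omegas=np.asarray(omegas, dtype=float),
        v_com_post=v_post,
        impulse=impulse,
        jy_star=jy_star,
        jb=jb,
        normalized_impulse=float(norm) if jb != 0 else float("nan"),
    )


def rigid_collision(chain: SegmentChain, state: CollisionState) -> CollisionResult:
    """Inelastic collision with perfectly rigid joints.

    Angular momentum about the contact point O is conserved; the single
    post-collision angular velocity and the CoM velocity follow from the
    contact point coming to rest.
    """
    g = chain.com
    o = chain.points["O"]
    r = g - o
    if float(r @ r) < 1e-16:
        raise DomainError("degenerate geometry: centre of mass at contact point")
    mb = chain.total_mass
    ig = chain.inertia_about_com
    l_pre = mb * _cross(r, state.v_com) + ig * state.omega
    omega_post = l_pre / (mb * float(r @ r) + ig)
    v_post = omega_post * _perp(r)
    # per-segment velocities of the rigid post-collision rotation about O
    v_segments = [omega_post * _perp(c - o) for c in chain.coms]
    res = _make_result("rigid", chain, state, [omega_post] * 4, v_segments)
    res.contact_speed_post = 0.0
    res.residual = abs(
        mb * _cross(r, v_post) + ig * omega_post - l_pre
    ) / max(abs(l_pre), 1.0)
    return res


def compliant_collision(chain: SegmentChain, state: CollisionState) -> CollisionResult:
    """Inelastic collision with infinitely compliant (free-hinge) joints.

    Four angular-momentum balances (whole body about O; shank+thigh+torso
    about the ankle B; thigh+torso about the knee C; torso about the hip
    D) are solved together with the kinematic chain anchored at the
    resting contact point for the four segment angular velocities.
    """
    pts = chain.points
    o, b, c, d = pts["O"], pts["B"], pts["C"], pts["D"]
    coms = chain.coms
    m = chain.masses
    inertia = chain.inertias

    # post-collision velocity of segment i is sum_j V[i][j] * omega_j
    V = [[np.zeros(2) for _ in range(4)] for _ in range(4)]
    V[0][0] = _perp(coms[0] - o)
    V[1][0] = _perp(b - o)
    V[1][1] = _perp(coms[1] - b)
    V[2][0] = _perp(b - o)
    V[2][1] = _perp(c - b)
    V[2][2] = _perp(coms[2] - c)
    V[3][0] = _perp(b - o)
    V[3][1] = _perp(c - b)
    V[3][2] = _perp(d - c)
    V[3][3] = _perp(coms[3] - d)

    pivots = [o, b, c, d]
    seg_sets = [(0, 1, 2, 3), (1, 2, 3), (2, 3), (3,)]
    v_pre = _pre_segment_velocities(chain, state)

    mat = np.zeros((4, 4))
    rhs = np.zeros(4)
    for k, (pivot, segs) in enumerate(zip(pivots, seg_sets)):
        for i in segs:
            arm = coms[i] - pivot
            for j in range(4):
                mat[k, j] += m[i] * _cross(arm, V[i][j])
            mat[k, i] += inertia[i]
            rhs[k] += m[i] * _cross(arm, v_pre[i]) + inertia[i] * state.omega

    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > 1e14:
        raise DomainError(
            f"compliant collision system is singular (condition {cond:.3g}); "
            "check segment masses and geometry"
        )
    omegas = np.linalg.solve(mat, rhs)
    v_segments = [
        sum(omegas[j] * V[i][j] for j in range(4)) for i in range(4)
    ]
    res = _make_result("compliant", chain, state, omegas, v_segments)
    scale = max(np.abs(rhs).max(), 1.0)
    res.residual = float(np.abs(mat @ omegas - rhs).max() / scale)
    res.contact_speed_post = 0.0   # identically, by the chain construction
    return res


def normalized_impulse(
    model: str,
    subject: SubjectParams,
    leg_angle: float,
    com_speed: float,
    vertical_speed: float = 0.7,
    foot_speed_froude: float = 0.37,
    foot_strike_index: float = 0.15,
    touchdown_leg_length: float = None,
    anthropometry: Anthropometry = DEFAULT_ANTHROPOMETRY,
) -> float:
    """Convenience wrapper: pose, collide, return |Jy*|/Jb."""
    chain = build_chain(
        subject, leg_angle, foot_strike_index, anthropometry,
        touchdown_leg_length,
    )
    state = state_from_landing(
        chain, com_speed, vertical_speed, foot_speed_froude, subject
    )
    solver = rigid_collision if model == "rigid" else compliant_collision
    return solver(chain, state).normalized_impulse


def kinetic_energy(chain: SegmentChain, omegas, v_segments) -> float:
    """Total kinetic energy of the chain for given segment motions."""
    ke = 0.0
    for m, inertia, w, v in zip(chain.masses, chain.inertias, omegas, v_segments):
        ke += 0.5 * m * float(v @ v) + 0.5 * inertia * w * w
    return ke


def impulse_speed_slope(
    model: str,
    ensemble,
    subject: SubjectParams = None,
    foot_strike_index: float = 0.15,
    anthropometry: Anthropometry = DEFAULT_ANTHROPOMETRY,
    touchdown_leg_length: float = None,
    mean_geometry: bool = False,
):
    """OLS slope of model-predicted |Jy*|/Jb versus Froude foot speed.

    ``ensemble`` is a mapping with per-step arrays ``foot_speed_froude``,
    ``com_speed``, ``leg_angle`` and optionally ``vertical_speed``. With
    ``mean_geometry=True`` a single chain posed at the mean leg angle is
    reused for every step; otherwise the chain is re-posed per step.

    Returns ``(slope, intercept, predictions)``.
    """
    subject = subject or SubjectParams()
    fs = np.asarray(ensemble["foot_speed_froude"], dtype=float)
    vcom = np.asarray(ensemble["com_speed"], dtype=float)
    theta = np.asarray(ensemble["leg_angle"], dtype=float)
    vz = np.asarray(
        ensemble.get("vertical_speed", np.full_like(fs, 0.7)), dtype=float
    )
    n = fs.size
    if n < 3:
        raise ValidationError("ensemble must contain at least 3 landing states")
    if np.ptp(fs) == 0:
        raise ValidationError(
            "degenerate ensemble: forward foot speed has zero variance"
        )
    solver = rigid_collision if model == "rigid" else compliant_collision
    if mean_geometry:
        chain = build_chain(
            subject, float(theta.mean()), foot_strike_index, anthropometry,
            touchdown_leg_length,
        )
    preds = np.empty(n)
    for k in range(n):
        ch = chain if mean_geometry else build_chain(
            subject, theta[k], foot_strike_index, anthropometry,
            touchdown_leg_length,
        )
        state = state_from_landing(ch, vcom[k], vz[k], fs[k], subject)
        preds[k] = solver(ch, state).normalized_impulse
    slope, intercept = np.polyfit(fs, preds, 1)
    return float(slope), float(intercept), preds
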