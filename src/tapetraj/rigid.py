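"""Rigid-body dynamics for the balance and gait problems.

Two planar models are provided in inverse-dynamics form ``T = f_s(q, v, u_dv)``
(net generalized torques given positions, velocities and
accelerations-as-controls), which is the form the implicit collocation
transcription constrains:

* an N-link inverted pendulum chain on a horizontally translating base
  (:func:`pendulum_inverse_dynamics`), used for the balance-restoration
  problems, and
* a planar 10-coordinate gait skeleton with a floating pelvis
  (:func:`skeleton_inverse_dynamics`), used for the predictive walking
  problem, together with tanh-smoothed Hunt-Crossley sphere-plane contact
  (:func:`contact_force_smooth`).

All routines are written in plain arithmetic on the closed smooth op set, so
they can be recorded on an :mod:`~tapetraj.adgraph` tape (no branches, no
non-smooth primitives).  Conventions: world frame x-forward / y-up, angles in
radians and right-handed, gravity 9.81 m/s^2 downward, ground plane y = 0
with penetration measured positive below the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .adgraph import cos, sin, sqrt, tanh

__all__ = [
    "GRAVITY", "SegmentParams", "PendulumChain", "ContactSphereParams",
    "PlanarSkeleton", "BodySpec", "half_sine_base_pulse",
    "pendulum_inverse_dynamics", "contact_force_smooth",
    "skeleton_inverse_dynamics", "skeleton_kinematics",
    "contact_sphere_kinematics", "default_pendulum_chain",
]

GRAVITY = 9.81


@dataclass
class SegmentParams:
    """One rigid segment: length, mass, COM offset from the proximal joint
    along the segment, and moment of inertia about the COM."""

    length: float
    mass: float
    com_offset: float
    inertia: float

    def __post_init__(self):
        if min(self.length, self.mass, self.com_offset, self.inertia) <= 0:
            raise ValueError("segment parameters must be positive")
        if self.inertia > self.mass * self.length ** 2:
            raise ValueError("inertia exceeds m*L^2; not physical for a segment")


def half_sine_base_pulse(peak: float = 2.0, duration: float = 0.2,
                         sharpness: float = 200.0) -> Callable:
    """Backward (negative-x) half-sine base-acceleration pulse.

    The pulse ``-peak * sin(pi t / duration)`` is gated by two tanh switches
    so the profile is smooth (recordable) over the whole horizon instead of
    piecewise.  ``sharpness`` (1/s) controls the switch steepness.
    """

    def a_base(t):
        gate = 0.25 * (1.0 + tanh(sharpness * t)) * (1.0 + tanh(sharpness * (duration - t)))
        return -peak * sin(np.pi * t / duration) * gate

    return a_base


@dataclass
class PendulumChain:
    """Serial inverted-pendulum chain on a horizontally translating base.

    ``base_motion(t)`` is the prescribed horizontal base acceleration; it
    enters the inverse dynamics as the inertial acceleration of the base
    point ("backward translation of the base of support").
    """

    ndof: int
    segments: list[SegmentParams]
    gravity: float = GRAVITY
    base_motion: Callable = field(default_factory=half_sine_base_pulse)

    def __post_init__(self):
        if not 2 <= self.ndof <= 10:
            raise ValueError("pendulum chains support 2-10 degrees of freedom")
        if len(self.segments) != self.ndof:
            raise ValueError("segment count must equal ndof")


def default_pendulum_chain(ndof: int, peak: float = 2.0) -> PendulumChain:
    """Anthropomorphic default: 1.7 m / 70 kg divided equally among uniform
    rods, COM at mid-length, I = m L^2 / 12."""
    L = 1.7 / ndof
    m = 70.0 / ndof
    seg = SegmentParams(length=L, mass=m, com_offset=L / 2, inertia=m * L * L / 12.0)
    return PendulumChain(ndof=ndof, segments=[seg] * ndof,
                         base_motion=half_sine_base_pulse(peak=peak))


def pendulum_inverse_dynamics(chain: PendulumChain, t, q: Sequence, v: Sequence,
                              u_dv: Sequence):
    """Net joint torques of the chain: ``T = f_s(q, v, u_dv)``.

    Recursive Newton-Euler in the plane.  ``q`` are relative joint angles
    (0 = upright, each link along +y), ``v`` their rates and ``u_dv`` the
    accelerations-as-controls.  The prescribed base acceleration
    ``chain.base_motion(t)`` enters as the linear acceleration of the base
    point.  Returns a list of ``ndof`` torques (plain values or recorded
    scalars, depending on the inputs).
    """
    n = chain.ndof
    if not (len(q) == len(v) == len(u_dv) == n):
        raise ValueError("state dimensions must match ndof")
    g = chain.gravity
    ab_x = chain.base_motion(t)

    # forward pass: absolute angle/velocity/acceleration, COM accelerations
    th = w = al = 0.0
    aj_x, aj_y = ab_x, 0.0  # acceleration of the proximal joint
    acx, acy, alphas, r_com, r_end = [], [], [], [], []
    for i in range(n):
        th = th + q[i]
        w = w + v[i]
        al = al + u_dv[i]
        dx, dy = -sin(th), cos(th)
        seg = chain.segments[i]
        rcx, rcy = seg.com_offset * dx, seg.com_offset * dy
        rex, rey = seg.length * dx, seg.length * dy
        # a_point = a_joint + alpha x r - w^2 r   (planar)
        acx.append(aj_x - al * rcy - w * w * rcx)
        acy.append(aj_y + al * rcx - w * w * rcy)
        aj_x = aj_x - al * rey - w * w * rex
        aj_y = aj_y + al * rex - w * w * rey
        alphas.append(al)
        r_com.append((rcx, rcy))
        r_end.append((rex, rey))

    # backward pass: joint forces and torques
    T: list = [0.0] * n
    f_x = f_y = n_z = 0.0  # wrench transmitted from the distal side
    for i in reversed(range(n)):
        seg = chain.segments[i]
        Fx = seg.mass * acx[i]
        Fy = seg.mass * (acy[i] + g)  # net force = m (a - g), g = (0, -9.81)
        rcx, rcy = r_com[i]
        rex, rey = r_end[i]
        n_z = (seg.inertia * alphas[i] + n_z
               + rcx * Fy - rcy * Fx
               + rex * f_y - rey * f_x)
        f_x = Fx + f_x
        f_y = Fy + f_y
        T[i] = n_z
    return T


# ---------------------------------------------------------------------------
# smoothed Hunt-Crossley contact
# ---------------------------------------------------------------------------

@dataclass
class ContactSphereParams:
    """Sphere-plane compliant contact parameters.

    ``stiffness`` is the plane-strain Hertz coefficient k in N/m^1.5,
    ``dissipation`` the Hunt-Crossley coefficient c in s/m, and the two
    smoothing sharpnesses gate penetration (1/m) and slip velocity (s/m).
    """

    location: tuple[float, float] = (0.0, 0.0)  # in foot frame (m)
    radius: float = 0.035
    stiffness: float = 2.0e6
    dissipation: float = 2.0
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.5
    smooth_penetration: float = 600.0   # 1/m, tanh gate on delta
    smooth_slip: float = 50.0           # s/m, tanh switch on slip velocity
    penetration_eps: float = 1e-4       # m, smooth positive-part width

    def __post_init__(self):
        if self.radius <= 0 or self.stiffness <= 0:
            raise ValueError("radius and stiffness must be positive")
        if self.dissipation < 0:
            raise ValueError("dissipation must be non-negative")


def contact_force_smooth(sphere: ContactSphereParams, pos, vel):
    """Twice continuously differentiable sphere-plane contact force.

    ``pos``/``vel`` are the sphere-center position and velocity in the world
    frame.  Penetration ``delta = radius - y`` is positive below the plane.
    The normal force approximates Hunt-Crossley
    ``k * delta^1.5 * (1 + 1.5 c delta_dot)``: the positive part of the
    penetration is smoothed with a C-infinity softplus of width
    ``penetration_eps`` and the whole normal force is gated by a tanh switch
    on penetration so leakage when airborne is negligible.  The tangential
    force is smoothed Coulomb friction, ``tanh`` of the slip velocity, plus a
    viscous term, both proportional to the normal force.  Returns
    ``(fx, fy, torque_z)`` with ``torque_z = 0`` for a point contact.
    """
    x, y = pos
    vx, vy = vel
    delta = sphere.radius - y
    ddot = -vy
    eps = sphere.penetration_eps
    # smooth positive part of the penetration (C-infinity, always > 0)
    dpos = 0.5 * (delta + sqrt(delta * delta + eps * eps))
    gate = 0.5 * (1.0 + tanh(sphere.smooth_penetration * delta))
    fn = sphere.stiffness * dpos ** 1.5 * (1.0 + 1.5 * sphere.dissipation * ddot) * gate
    ft = -(sphere.mu_dynamic * tanh(sphere.smooth_slip * vx)
           + sphere.mu_viscous * vx) * fn
    return ft, fn, 0.0


# ---------------------------------------------------------------------------
# planar gait skeleton
# ---------------------------------------------------------------------------

@dataclass
class BodySpec:
    """One body of the planar skeleton tree."""

    name: str
    parent: str | None           # None for the root (pelvis)
    joint_coord: int | None      # generalized-coordinate index of the joint
    joint_local: tuple[float, float]  # joint position in the parent frame
    com_local: tuple[float, float]    # COM position in this body's frame
    mass: float
    inertia: float


# coordinate order of the planar skeleton
COORD_NAMES = ["pelvis_tx", "pelvis_ty", "pelvis_tilt", "trunk_ext",
               "hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l"]


@dataclass
class PlanarSkeleton:
    """Planar 10-coordinate gait skeleton: pelvis (tx, ty, tilt) plus trunk
    extension and hip/knee/ankle flexion for each leg.

    The pelvis coordinates are residual (unactuated): the transcription
    drives their inverse-dynamics rows to zero.  Hip/knee/ankle rows are
    muscle-actuated and the trunk row torque-actuated.
    """

    bodies: list[BodySpec]
    coord_names: list[str] = field(default_factory=lambda: list(COORD_NAMES))
    contact_spheres: list[tuple[str, ContactSphereParams]] = field(default_factory=list)
    gravity: float = GRAVITY

    def __post_init__(self):
        if len(self.coord_names) != 10:
            raise ValueError("the planar skeleton has exactly 10 coordinates")
        self._index = {b.name: i for i, b in enumerate(self.bodies)}
        order = {None: -1}
        for b in self.bodies:
            if b.parent is not None and b.parent not in self._index:
                raise ValueError(f"body {b.name} references unknown parent {b.parent}")
        del order

    @property
    def ndof(self) -> int:
        return len(self.coord_names)

    def body(self, name: str) -> BodySpec:
        return self.bodies[self._index[name]]

    @property
    def total_mass(self) -> float:
        return sum(b.mass for b in self.bodies)

    def ancestors(self, name: str) -> list[str]:
        chain = []
        b = self.body(name)
        while b.parent is not None:
            chain.append(b.parent)
            b = self.body(b.parent)
        return chain


def _rot(theta, px, py):
    c, s = cos(theta), sin(theta)
    return c * px - s * py, s * px + c * py


def skeleton_kinematics(model: PlanarSkeleton, q: Sequence, v: Sequence,
                        u_dv: Sequence | None = None) -> dict:
    """Forward kinematics of every body: orientation, angular velocity /
    acceleration, and frame-origin position / velocity / acceleration.

    The root (pelvis) frame origin translates with (tx, ty) and rotates with
    the tilt coordinate; each child body is attached to its parent by a
    revolute joint driven by one generalized coordinate.  Returns a dict
    keyed by body name with entries ``theta, omega, alpha, p, vp, ap``
    (``alpha``/``ap`` are None when ``u_dv`` is None).
    """
    withacc = u_dv is not None
    out: dict = {}
    for b in model.bodies:
        if b.parent is None:
            theta = q[2]
            omega = v[2]
            alpha = u_dv[2] if withacc else None
            p = (q[0], q[1])
            vp = (v[0], v[1])
            ap = (u_dv[0], u_dv[1]) if withacc else None
        else:
            par = out[b.parent]
            k = b.joint_coord
            theta = par["theta"] + q[k]
            omega = par["omega"] + v[k]
            alpha = (par["alpha"] + u_dv[k]) if withacc else None
            rx, ry = _rot(par["theta"], *b.joint_local)
            p = (par["p"][0] + rx, par["p"][1] + ry)
            w = par["omega"]
            vp = (par["vp"][0] - w * ry, par["vp"][1] + w * rx)
            if withacc:
                a = par["alpha"]
                ap = (par["ap"][0] - a * ry - w * w * rx,
                      par["ap"][1] + a * rx - w * w * ry)
            else:
                ap = None
        out[b.name] = {"theta": theta, "omega": omega, "alpha": alpha,
                       "p": p, "vp": vp, "ap": ap}
    return out


def _point_state(model, kin, body_name, local, withacc=True):
    """World position/velocity(/acceleration) of a point fixed in a body."""
    k = kin[body_name]
    rx, ry = _rot(k["theta"], *local)
    p = (k["p"][0] + rx, k["p"][1] + ry)
    w = k["omega"]
    vp = (k["vp"][0] - w * ry, k["vp"][1] + w * rx)
    if not withacc:
        return p, vp
    a = k["alpha"]
    ap = (k["ap"][0] - a * ry - w * w * rx, k["ap"][1] + a * rx - w * w * ry)
    return p, vp, ap


def contact_sphere_kinematics(model: PlanarSkeleton, q: Sequence, v: Sequence):
    """Positions and velocities of all contact-sphere centers."""
    kin = skeleton_kinematics(model, q, v)
    out = []
    for body_name, sphere in model.contact_spheres:
        p, vp = _point_state(model, kin, body_name, sphere.location, withacc=False)
        out.append((p, vp))
    return out


def skeleton_inverse_dynamics(model: PlanarSkeleton, q: Sequence, v: Sequence,
                              u_dv: Sequence,
                              external_forces: Sequence | None = None):
    """Generalized torques ``T = f_s(q, v, u_dv)`` of the skeleton.

    Projected Newton-Euler: for each coordinate i,

        T_i = sum_b [ m_b (a_b - g) . dp_b/dq_i  +  I_b alpha_b dtheta_b/dq_i ]
              - sum_ext F . dP/dq_i

    where the partial position derivatives follow from the joint geometry
    (unit translations for pelvis tx/ty, perpendicular lever arms about each
    revolute joint for bodies in its subtree).  ``external_forces`` is a
    sequence of ``(body_name, local_point, (fx, fy))`` applied point forces
    (e.g. contact forces at sphere centers).  The pelvis rows are the
    residual forces the optimizer drives to zero.
    """
    n = model.ndof
    kin = skeleton_kinematics(model, q, v, u_dv)

    # subtree membership and joint anchor per revolute coordinate
    rev_coords: dict[int, tuple] = {}  # coord index -> (joint world pos, subtree names)
    for b in model.bodies:
        if b.parent is None:
            continue
        jx, jy = _rot(kin[b.parent]["theta"], *b.joint_local)
        jpos = (kin[b.parent]["p"][0] + jx, kin[b.parent]["p"][1] + jy)
        subtree = {b.name}
        for other in model.bodies:
            if b.name in model.ancestors(other.name):
                subtree.add(other.name)
        rev_coords[b.joint_coord] = (jpos, subtree)

    g = model.gravity
    # net inertial+gravity force and COM position per body
    body_terms = {}
    for b in model.bodies:
        k = kin[b.name]
        rx, ry = _rot(k["theta"], *b.com_local)
        pc = (k["p"][0] + rx, k["p"][1] + ry)
        w, a = k["omega"], k["alpha"]
        ac = (k["ap"][0] - a * ry - w * w * rx, k["ap"][1] + a * rx - w * w * ry)
        Fx = b.mass * ac[0]
        Fy = b.mass * (ac[1] + g)
        body_terms[b.name] = (pc, Fx, Fy, b.inertia * a)

    ext = []
    if external_forces:
        for body_name, local, (fx, fy) in external_forces:
            p, _ = _point_state(model, kin, body_name, local, withacc=False)
            ext.append((body_name, p, fx, fy))

    T: list = []
    pelvis_p = kin[model.bodies[0].name]["p"]
    for i in range(n):
        acc = 0.0
        if i == 0:      # pelvis_tx: dp/dq = (1, 0) for every body
            for name, (pc, Fx, Fy, Ia) in body_terms.items():
                acc = acc + Fx
            for (_, p, fx, fy) in ext:
                acc = acc - fx
        elif i == 1:    # pelvis_ty
            for name, (pc, Fx, Fy, Ia) in body_terms.items():
                acc = acc + Fy
            for (_, p, fx, fy) in ext:
                acc = acc - fy
        elif i == 2:    # pelvis tilt: lever about the pelvis origin, all bodies
            for name, (pc, Fx, Fy, Ia) in body_terms.items():
                rx, ry = pc[0] - pelvis_p[0], pc[1] - pelvis_p[1]
                acc = acc + (rx * Fy - ry * Fx) + Ia
            for (_, p, fx, fy) in ext:
                rx, ry = p[0] - pelvis_p[0], p[1] - pelvis_p[1]
                acc = acc - (rx * fy - ry * fx)
        else:           # revolute joint coordinate
            jpos, subtree = rev_coords[i]
            for name in subtree:
                pc, Fx, Fy, Ia = body_terms[name]
                rx, ry = pc[0] - jpos[0], pc[1] - jpos[1]
                acc = acc + (rx * Fy - ry * Fx) + Ia
            for (bname, p, fx, fy) in ext:
                if bname in subtree:
                    rx, ry = p[0] - jpos[0], p[1] - jpos[1]
                    acc = acc - (rx * fy - ry * fx)
        T.append(acc)
    return T


def default_gait_skeleton(contact: bool = True) -> PlanarSkeleton:
    """Representative planar gait anthropometry (~72.5 kg, ~1.0 m pelvis
    height): pelvis + torso (head/arms/trunk) + thigh/shank/foot per leg.

    Values are fixture defaults for a generic adult model; no result depends
    on the specific numbers.
    """
    bodies = [
        BodySpec("pelvis", None, None, (0.0, 0.0), (0.0, 0.0), 11.78, 0.10),
        BodySpec("torso", "pelvis", 3, (0.0, 0.08), (0.0, 0.30), 33.87, 1.40),
        BodySpec("thigh_r", "pelvis", 4, (0.0, -0.08), (0.0, -0.18), 8.81, 0.15),
        BodySpec("shank_r", "thigh_r", 5, (0.0, -0.41), (0.0, -0.19), 3.49, 0.055),
        BodySpec("foot_r", "shank_r", 6, (0.0, -0.43), (0.05, -0.025), 1.13, 0.007),
        BodySpec("thigh_l", "pelvis", 7, (0.0, -0.08), (0.0, -0.18), 8.81, 0.15),
        BodySpec("shank_l", "thigh_l", 8, (0.0, -0.41), (0.0, -0.19), 3.49, 0.055),
        BodySpec("foot_l", "shank_l", 9, (0.0, -0.43), (0.05, -0.025), 1.13, 0.007),
    ]
    spheres = []
    if contact:
        heel = ContactSphereParams(location=(-0.05, -0.045))
        toe = ContactSphereParams(location=(0.16, -0.045))
        spheres = [("foot_r", heel), ("foot_r", toe),
                   ("foot_l", heel), ("foot_l", toe)]
    return PlanarSkeleton(bodies=bodies, contact_spheres=spheres)
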