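"""Concrete problem builders, initial guesses, and the benchmark harness.

Two problem families are provided:

* :func:`build_pendulum` -- perturbed-balance problems for an N-link
  inverted pendulum on a translating base: restore the upright posture
  within one second while minimizing squared scaled joint torques (plus a
  small acceleration penalty against singular arcs), with the torques
  entering through an implicit inverse-dynamics path constraint.
* :func:`build_gait2d` -- a predictive simulation of one symmetric half
  gait cycle of a planar 10-coordinate, 18-muscle walking model at a
  prescribed average speed of 1.33 m/s, minimizing muscle fatigue
  (activations cubed) plus trunk-excitation and acceleration terms, all
  normalized by distance traveled.

The gait muscle geometry is synthetic: straight-line/via-point paths with
anthropometric attachment points (the ``gait2d.yaml`` fixture) generate
muscle-tendon length and moment-arm samples from which the polynomial
geometry is fitted.

The benchmark harness (:func:`run_benchmark`) solves problems under
derivative scenarios (ad / fd) and Hessian modes (exact / lbfgs), records
per-run statistics, and summarizes cost ratios over runs that converged to
the same optimum (matching trajectory fingerprints); mismatching runs are
excluded and counted.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import adgraph as ad
from . import collocation as col
from . import muscle as mus
from . import rigid

__all__ = [
    "PENDULUM_DEFAULT_MESH", "build_pendulum", "build_gait2d",
    "load_gait_fixture", "build_muscle_geometry", "make_initial_guesses",
    "trajectory_fingerprint", "fingerprints_match", "BenchmarkRecord", "run_benchmark",
    "GaitModel",
]

# Back-solved default mesh sizes reproducing the printed pendulum NLP
# dimensions: N=25 for 2-6 dof, N=50 for 7-9 dof, N=100 for 10 dof.
PENDULUM_DEFAULT_MESH = {2: 25, 3: 25, 4: 25, 5: 25, 6: 25,
                         7: 50, 8: 50, 9: 50, 10: 100}


# ---------------------------------------------------------------------------
# pendulum balance problems
# ---------------------------------------------------------------------------

def build_pendulum(ndof: int, N: int | None = None, peak: float = 2.0,
                   chain: rigid.PendulumChain | None = None,
                   mode: str = "ad"):
    """Build and transcribe the ndof-link balance problem.

    States are joint angles ``q`` (bounds +-3 pi, scale s_q = 3) and rates
    ``v`` (+-20, scale s_q/s_t with s_t = 0.2); controls are accelerations
    ``u_dv`` (+-500, scale s_q/s_t^2) and joint torques ``u_T`` (+-1000,
    scale s_T = 500).  The dynamics are implicit (``dq/dt = v``,
    ``dv/dt = u_dv``) with the inverse-dynamics torque equation
    ``f_s(q, v, u_dv) = u_T`` as a path equality, zero scaled boundary
    conditions at both ends, and horizon 1 s.  Returns the transcribed NLP.
    """
    if not 2 <= ndof <= 10:
        raise ValueError("pendulum problems support 2-10 degrees of freedom")
    if N is None:
        N = PENDULUM_DEFAULT_MESH[ndof]
    if chain is None:
        chain = rigid.default_pendulum_chain(ndof, peak=peak)
    n = ndof
    s_q, s_t, s_T = 3.0, 0.2, 500.0
    s_v = s_q / s_t
    s_dv = s_q / s_t ** 2
    scaling = col.ScalingSet(
        x_scale=np.concatenate([np.full(n, s_q), np.full(n, s_v)]),
        u_scale=np.concatenate([np.full(n, s_dv), np.full(n, s_T)]),
        p_scale=np.ones(0))

    def rates(x, u, p, t):
        return list(x[n:]) + list(u[:n])

    def integrand(x, u, p, t):
        acc = 0.0
        for i in range(n):
            uT = u[n + i] / s_T
            udv = u[i] / s_dv
            acc = acc + uT * uT + 0.1 * udv * udv
        return acc

    def path_eq(x, u, p, t):
        T = rigid.pendulum_inverse_dynamics(chain, t, x[:n], x[n:], u[:n])
        return [(T[i] - u[n + i]) / s_T for i in range(n)]

    def boundary(x0, xN, p):
        res = []
        for i in range(n):
            res.append(x0[i] / s_q)
            res.append(x0[n + i] / s_v)
            res.append(xN[i] / s_q)
            res.append(xN[n + i] / s_v)
        return res

    ocp = col.OptimalControlProblem(
        state_names=[f"q{i}" for i in range(n)] + [f"v{i}" for i in range(n)],
        control_names=[f"udv{i}" for i in range(n)] + [f"uT{i}" for i in range(n)],
        x_lb=np.concatenate([np.full(n, -3 * np.pi), np.full(n, -20.0)]),
        x_ub=np.concatenate([np.full(n, 3 * np.pi), np.full(n, 20.0)]),
        u_lb=np.concatenate([np.full(n, -500.0), np.full(n, -1000.0)]),
        u_ub=np.concatenate([np.full(n, 500.0), np.full(n, 1000.0)]),
        rates=rates, integrand=integrand, path_eq=path_eq, boundary=boundary,
        scaling=scaling, t_f=1.0,
        nominal_x=np.zeros(2 * n), nominal_u=np.zeros(2 * n),
        name=f"pendulum{ndof}")
    return col.transcribe(ocp, N, mode=mode)


# ---------------------------------------------------------------------------
# gait model fixture and muscle geometry
# ---------------------------------------------------------------------------

_R_LEG = {"hip": 4, "knee": 5, "ankle": 6}
_L_LEG = {"hip": 7, "knee": 8, "ankle": 9}


def load_gait_fixture() -> dict:
    """Load the packaged gait2d YAML fixture."""
    with resources.files("tapetraj").joinpath("data/gait2d.yaml").open() as f:
        return yaml.safe_load(f)


def _leg_path_points(path, q_hip, q_knee, q_ankle, thigh_len=0.41, shank_len=0.43):
    """World (pelvis-frame) positions of the via points of one leg muscle."""
    def rot(th, p):
        c, s = ad.cos(th), ad.sin(th)
        return c * p[0] - s * p[1], s * p[0] + c * p[1]

    th1 = q_hip
    th2 = q_hip + q_knee
    th3 = th2 + q_ankle
    knee = rot(th1, (0.0, -thigh_len))
    ankle_x, ankle_y = rot(th2, (0.0, -shank_len))
    ankle = (knee[0] + ankle_x, knee[1] + ankle_y)
    pts = []
    for body, p in path:
        if body == "pelvis":
            pts.append(tuple(p))
        elif body == "thigh":
            pts.append(rot(th1, p))
        elif body == "shank":
            x, y = rot(th2, p)
            pts.append((knee[0] + x, knee[1] + y))
        elif body == "foot":
            x, y = rot(th3, p)
            pts.append((ankle[0] + x, ankle[1] + y))
        else:
            raise ValueError(f"unknown body {body!r} in muscle path")
    return pts


def muscle_tendon_length(path, q_hip, q_knee, q_ankle):
    """Exact via-point muscle-tendon length (recordable)."""
    pts = _leg_path_points(path, q_hip, q_knee, q_ankle)
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        dx, dy = x1 - x0, y1 - y0
        total = total + ad.sqrt(dx * dx + dy * dy)
    return total


def geometry_samples(fixture: dict, n_grid_1d: int = 201, n_grid_2d: int = 25) -> dict:
    """Sample exact lengths and moment arms of every muscle on a dense grid
    over the joint ranges.  Moment arms come from a reverse sweep of the
    recorded length tape, so they are exact derivatives of the via-point
    geometry (no truncation error)."""
    ranges = fixture["joint_ranges"]
    samples = {}
    for name, mdef in fixture["muscles"].items():
        spans = mdef["spans"]
        axes = [np.linspace(*ranges[c], n_grid_1d if len(spans) == 1 else n_grid_2d)
                for c in spans]
        grids = np.meshgrid(*axes, indexing="ij")
        Q = np.column_stack([g.ravel() for g in grids])

        def fn(qs, spans=spans, path=mdef["path"]):
            vals = {"hip": 0.0, "knee": 0.0, "ankle": 0.0}
            for c, q in zip(spans, qs):
                vals[c] = q
            return muscle_tendon_length(path, vals["hip"], vals["knee"], vals["ankle"])

        tape = ad.record(fn, Q[0])
        X = [Q[:, j] for j in range(Q.shape[1])]
        vals = ad._values_at(tape, X, check_branches=False)
        lmt = np.asarray(vals[tape.output_ids[0]], float)
        bars = ad.reverse_sweep(tape, [np.ones(Q.shape[0])], x=X)
        ma = -np.column_stack([np.broadcast_to(b, Q.shape[0]) for b in bars])
        samples[name] = {"coords": spans, "Q": Q, "lmt": lmt, "ma": ma}
    return samples


@dataclass
class GaitModel:
    """Assembled planar walking model: skeleton, contact, muscles with fitted
    polynomial geometry, activation constants and the trunk actuator."""

    skeleton: rigid.PlanarSkeleton
    muscles_r: list[mus.MuscleParams]
    muscles_l: list[mus.MuscleParams]
    geoms: dict
    fit_reports: list
    activation: mus.ActivationConstants
    trunk: mus.TorqueActuatorParams
    muscle_names: list[str]


def build_muscle_geometry(fixture: dict | None = None, max_order: int = 9):
    """Fit the polynomial muscle geometry to the synthetic via-point samples."""
    if fixture is None:
        fixture = load_gait_fixture()
    samples = geometry_samples(fixture)
    return mus.fit_polynomials(samples, max_order=max_order)


def _skeleton_from_fixture(fixture: dict) -> rigid.PlanarSkeleton:
    bodies = [rigid.BodySpec(b["name"], b["parent"], b["coord"],
                             tuple(b["joint"]), tuple(b["com"]),
                             b["mass"], b["inertia"])
              for b in fixture["skeleton"]["bodies"]]
    c = fixture["contact"]
    spheres = []
    for foot in ("foot_r", "foot_l"):
        for s in c["spheres"]:
            spheres.append((foot, rigid.ContactSphereParams(
                location=tuple(s["point"]), radius=c["radius"],
                stiffness=c["stiffness"], dissipation=c["dissipation"],
                mu_dynamic=c["mu_dynamic"], mu_viscous=c["mu_viscous"],
                smooth_penetration=c["smooth_penetration"],
                smooth_slip=c["smooth_slip"])))
    return rigid.PlanarSkeleton(bodies=bodies, contact_spheres=spheres)


def build_gait_model(fixture: dict | None = None) -> GaitModel:
    if fixture is None:
        fixture = load_gait_fixture()
    geoms, reports = build_muscle_geometry(fixture)
    names = list(fixture["muscles"].keys())
    muscles = []
    for name in names:
        mdef = fixture["muscles"][name]
        l0 = geoms[name].length(np.zeros(len(mdef["spans"])))
        lts = float(l0) - mdef["l_M_opt"] * np.cos(mdef["alpha_opt"])
        if lts <= 0:
            raise ValueError(f"derived tendon slack length <= 0 for {name}")
        muscles.append(mus.MuscleParams(
            F_max=mdef["F_max"], l_M_opt=mdef["l_M_opt"],
            l_T_slack=lts, alpha_opt=mdef["alpha_opt"], name=name))
    return GaitModel(
        skeleton=_skeleton_from_fixture(fixture),
        muscles_r=muscles, muscles_l=muscles, geoms=geoms,
        fit_reports=reports, activation=mus.ActivationConstants(),
        trunk=mus.TorqueActuatorParams(), muscle_names=names)


# ---------------------------------------------------------------------------
# 2D predictive walking problem
# ---------------------------------------------------------------------------

# state layout: a (18: R then L), F_t (18), q (10), v (10), a_trunk
_NM = 9        # muscles per leg
_NMUS = 18
_NQ = 10
_N_X = _NMUS + _NMUS + _NQ + _NQ + 1   # 57
_N_U = _NMUS + _NMUS + _NQ + 1         # 47

_STAND_TY = 1.0  # standing pelvis height; contact spheres just graze the plane


def build_gait2d(N: int = 50, model: GaitModel | None = None,
                 speed: float = 1.33,
                 weights: tuple = (1.0, 1.0, 0.05), mode: str = "ad"):
    """Build and transcribe the predictive half-gait-cycle problem.

    All Hill contraction residuals and skeleton torque equations enter as
    per-interval path equalities, Raasch activation-rate bounds as
    per-interval path inequalities, and left-right symmetry plus the
    prescribed-speed equality as boundary rows.  The half-cycle duration
    ``t_f`` is a free parameter in [0.1, 1] s; the objective is
    ``(w1 ||a||_3^3 + w2 e_trunk^2 + w3 ||u_dv~||^2 + L_p) / d`` with
    penalty ``L_p = 0.001 (||u_da||^2 + ||u_dFt||^2)`` and distance
    ``d = speed * t_f``.
    """
    if model is None:
        model = build_gait_model()
    act = model.activation
    trunk = model.trunk
    skel = model.skeleton
    w1, w2, w3 = weights

    q_lb = np.array([-0.5, 0.75, -0.5, -0.5, -0.8, -2.1, -0.9, -0.8, -2.1, -0.9])
    q_ub = np.array([2.0, 1.15, 0.5, 0.5, 0.8, 0.1, 0.6, 0.8, 0.1, 0.6])
    v_lb = np.array([-2.0, -2.0] + [-15.0] * 8)
    v_ub = np.array([3.0, 2.0] + [15.0] * 8)
    udv_lb = np.array([-50.0, -80.0] + [-300.0] * 8)
    udv_ub = -udv_lb

    x_lb = np.concatenate([np.zeros(_NMUS), np.zeros(_NMUS), q_lb, v_lb, [-1.0]])
    x_ub = np.concatenate([np.ones(_NMUS), np.full(_NMUS, 5.0), q_ub, v_ub, [1.0]])
    uda_lb, uda_ub = -1.0 / (act.s_da * act.tau_d), 1.0 / (act.s_da * act.tau_a)
    u_lb = np.concatenate([np.full(_NMUS, uda_lb), np.full(_NMUS, -1.0),
                           udv_lb, [-1.0]])
    u_ub = np.concatenate([np.full(_NMUS, uda_ub), np.full(_NMUS, 1.0),
                           udv_ub, [1.0]])
    scaling = col.ScalingSet.from_bounds(x_lb, x_ub, u_lb, u_ub, [0.1], [1.0])
    s_udv = scaling.u_scale[2 * _NMUS:2 * _NMUS + _NQ]

    iq, iv = 2 * _NMUS, 2 * _NMUS + _NQ
    iatr = 2 * _NMUS + 2 * _NQ

    def rates(x, u, p, t):
        out = []
        for m in range(_NMUS):
            out.append(act.s_da * u[m])
        for m in range(_NMUS):
            out.append(100.0 * u[_NMUS + m])
        out.extend(x[iv:iv + _NQ])
        out.extend(u[2 * _NMUS:2 * _NMUS + _NQ])
        out.append((u[2 * _NMUS + _NQ] - x[iatr]) / trunk.tau)
        return out

    def _muscle_kin(q, v, side):
        legmap = _R_LEG if side == "r" else _L_LEG
        out = []
        for name in model.muscle_names:
            geom = model.geoms[name]
            idx = [legmap[c] for c in geom.coords]
            qs = [q[i] for i in idx]
            vs = [v[i] for i in idx]
            lmt = geom.length(qs)
            mas = geom.moment_arms(qs)
            vmt = 0.0
            for ma_j, vj in zip(mas, vs):
                vmt = vmt + (-ma_j) * vj
            out.append((lmt, vmt, mas, idx))
        return out

    def path_eq(x, u, p, t):
        q = x[iq:iq + _NQ]
        v = x[iv:iv + _NQ]
        udv = u[2 * _NMUS:2 * _NMUS + _NQ]
        res = []
        kin = {"r": _muscle_kin(q, v, "r"), "l": _muscle_kin(q, v, "l")}
        # Hill residuals, right then left
        for si, side in enumerate(("r", "l")):
            params = model.muscles_r if side == "r" else model.muscles_l
            for m, (lmt, vmt, mas, idx) in enumerate(kin[side]):
                gm = si * _NM + m
                res.append(mus.hill_residual(
                    x[gm], lmt, vmt, x[_NMUS + gm], u[_NMUS + gm], params[m]))
        # skeleton torque rows
        forces = []
        kin_s = rigid.contact_sphere_kinematics(skel, q, v)
        for (bn, sph), (ppos, pvel) in zip(skel.contact_spheres, kin_s):
            fx, fy, _ = rigid.contact_force_smooth(sph, ppos, pvel)
            forces.append((bn, sph.location, (fx, fy)))
        T = rigid.skeleton_inverse_dynamics(skel, q, v, udv, forces)
        s_res = 500.0
        for i in range(3):  # pelvis residual rows
            res.append(T[i] / s_res)
        for si, side in enumerate(("r", "l")):  # muscle-driven rows
            legmap = _R_LEG if side == "r" else _L_LEG
            params = model.muscles_r if side == "r" else model.muscles_l
            for c in ("hip", "knee", "ankle"):
                ci = legmap[c]
                tq = T[ci]
                for m, (lmt, vmt, mas, idx) in enumerate(kin[side]):
                    geom = model.geoms[model.muscle_names[m]]
                    if ci in idx:
                        j = idx.index(ci)
                        tq = tq - mas[j] * x[_NMUS + si * _NM + m] * params[m].F_max
                res.append(tq / s_res)
        res.append(T[3] / trunk.scale - x[iatr])  # trunk actuator row
        return res

    BIG = 1e3

    def path_ineq(x, u, p, t):
        vals, lo, hi = [], [], []
        for m in range(_NMUS):
            r_lo, r_hi = mus.raasch_bounds(x[m], u[m], act)
            vals.append(act.tau_a * r_lo)
            lo.append(0.0)
            hi.append(BIG)
            vals.append(act.tau_a * r_hi)
            lo.append(-BIG)
            hi.append(0.0)
        return vals, lo, hi

    # symmetry map: swap legs in every block, identity elsewhere
    swap = np.arange(_N_X)
    for m in range(_NM):
        swap[m], swap[_NM + m] = _NM + m, m
        swap[_NMUS + m], swap[_NMUS + _NM + m] = _NMUS + _NM + m, _NMUS + m
    for c in ("hip", "knee", "ankle"):
        r_, l_ = iq + _R_LEG[c], iq + _L_LEG[c]
        swap[r_], swap[l_] = l_, r_
        swap[r_ + _NQ], swap[l_ + _NQ] = l_ + _NQ, r_ + _NQ
    _SWAP = [int(s) for s in swap]

    def boundary(x0, xN, p):
        res = []
        for i in range(_N_X):
            if i == iq:  # pelvis forward position excluded (translation)
                continue
            res.append((xN[_SWAP[i]] - x0[i]) / scaling.x_scale[i])
        res.append((xN[iq] - x0[iq]) / p[0] - speed)
        return res

    def integrand(x, u, p, t):
        d = speed * p[0]
        acc = 0.0
        for m in range(_NMUS):
            acc = acc + w1 * x[m] * x[m] * x[m]
        etr = u[2 * _NMUS + _NQ]
        acc = acc + w2 * etr * etr
        for i in range(_NQ):
            udvs = u[2 * _NMUS + i] / s_udv[i]
            acc = acc + w3 * udvs * udvs
        pen = 0.0
        for m in range(_NMUS):
            pen = pen + u[m] * u[m] + u[_NMUS + m] * u[_NMUS + m]
        return (acc + 0.001 * pen) / d

    nominal_x = np.concatenate([
        np.full(_NMUS, 0.1), np.full(_NMUS, 0.2),
        [0.0, _STAND_TY, 0, 0, 0, -0.02, 0, 0, -0.02, 0],
        np.zeros(_NQ), [0.0]])
    state_names = ([f"a_{n}_{s}" for s in "rl" for n in model.muscle_names]
                   + [f"Ft_{n}_{s}" for s in "rl" for n in model.muscle_names]
                   + rigid.COORD_NAMES + [f"v_{c}" for c in rigid.COORD_NAMES]
                   + ["a_trunk"])
    control_names = ([f"uda_{n}_{s}" for s in "rl" for n in model.muscle_names]
                     + [f"udFt_{n}_{s}" for s in "rl" for n in model.muscle_names]
                     + [f"udv_{c}" for c in rigid.COORD_NAMES] + ["e_trunk"])

    ocp = col.OptimalControlProblem(
        state_names=state_names, control_names=control_names,
        x_lb=x_lb, x_ub=x_ub, u_lb=u_lb, u_ub=u_ub,
        rates=rates, integrand=integrand, path_eq=path_eq,
        path_ineq=path_ineq, boundary=boundary,
        scaling=scaling, t_f=None, tf_param=0,
        param_names=["t_f"], p_lb=np.array([0.1]), p_ub=np.array([1.0]),
        nominal_x=nominal_x, nominal_u=np.zeros(_N_U),
        nominal_p=np.array([0.5]),
        anchor_x0={iq: 0.0},
        name="gait2d")
    nlp = col.transcribe(ocp, N, mode=mode)
    nlp.gait_model = model
    return nlp


# ---------------------------------------------------------------------------
# initial guesses
# ---------------------------------------------------------------------------

def make_initial_guesses(nlp: col.TranscribedNLP, count: int = 1,
                         seed: int = 0) -> list[np.ndarray]:
    """Deterministic within-bounds initial guesses.

    The first guess is the canonical one: all-zeros (clipped into bounds)
    for the pendulum problems, a quasi-static standing pose swept forward
    at the prescribed speed for the gait problem.  Subsequent guesses
    perturb the canonical one uniformly within 10% of the scaled bound
    range, seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    z0 = (_gait_canonical_guess(nlp) if nlp.ocp.name == "gait2d"
          else nlp.initial_guess_zero())
    guesses = [z0]
    rng_range = np.where(np.isfinite(nlp.z_ub - nlp.z_lb),
                         nlp.z_ub - nlp.z_lb, 1.0)
    for _ in range(count - 1):
        dz = 0.1 * rng_range * rng.uniform(-0.5, 0.5, size=nlp.n_vars)
        guesses.append(np.clip(z0 + dz, nlp.z_lb, nlp.z_ub))
    return guesses


def _gait_canonical_guess(nlp: col.TranscribedNLP) -> np.ndarray:
    """Quasi-static pose swept forward at the prescribed speed, with the
    legs split in anti-phase (right leg leading at t = 0, swapped at t_f).

    The leg split matters: the walking problem and the solver are exactly
    left-right symmetric, so a guess with identical legs confines the
    deterministic iteration to same-phase (hopping-like) motions;
    anti-phase walking is only reachable from a leg-split start.  The
    split is a smooth sinusoid compatible with the swap-symmetry boundary
    rows.
    """
    ocp = nlp.ocp
    sx, su, sp = ocp.scaling.x_scale, ocp.scaling.u_scale, ocp.scaling.p_scale
    tf = 0.5
    speed = 1.33
    hip_amp, knee_amp, knee0 = 0.3, 0.5, -0.1
    x_stand = np.concatenate([
        np.full(_NMUS, 0.1), np.full(_NMUS, 0.2),
        [0.0, _STAND_TY, 0, 0, 0, knee0, 0, 0, knee0, 0],
        [speed] + [0.0] * (_NQ - 1), [0.0]])
    z = np.zeros(nlp.n_vars)
    iq = 2 * _NMUS

    def x_at(t):
        x = x_stand.copy()
        phase = np.pi * t / tf
        w = np.pi / tf
        x[iq] = speed * t
        x[iq + 4] = hip_amp * np.cos(phase)           # hip_r: +amp -> -amp
        x[iq + 7] = -hip_amp * np.cos(phase)          # hip_l: -amp -> +amp
        # left knee flexes mid-swing; sin^2 keeps the velocity
        # swap-periodic (zero at both ends)
        x[iq + 8] = knee0 - knee_amp * np.sin(phase) ** 2
        x[iq + _NQ + 4] = -hip_amp * w * np.sin(phase)
        x[iq + _NQ + 7] = hip_amp * w * np.sin(phase)
        x[iq + _NQ + 8] = -knee_amp * w * np.sin(2 * phase)
        return x

    for k in range(nlp.N + 1):
        z[nlp.idx_mesh(k):nlp.idx_mesh(k) + ocp.n_x] = x_at(k * tf / nlp.N) / sx
    for k in range(nlp.N):
        for j in range(nlp.d):
            t = (k + nlp.scheme.points[j]) * tf / nlp.N
            z[nlp.idx_coll(k, j):nlp.idx_coll(k, j) + ocp.n_x] = x_at(t) / sx
    z[nlp.off_p] = tf / sp[0]
    return np.clip(z, nlp.z_lb, nlp.z_ub)


def gait_plausibility_report(nlp: col.TranscribedNLP,
                             record: col.SolveRecord,
                             grf_threshold: float = 1.0) -> dict:
    """Plausibility gates of a converged gait (informational, not targets).

    Reports, per foot, the stance fraction (share of mesh points with
    vertical ground reaction force above ``grf_threshold`` N) and whether
    the force is positive throughout that stance, plus the total vertical
    impulse of both feet over the half cycle relative to body weight times
    cycle time (1.0 for any periodic motion by momentum balance) and
    relative to body weight times the any-foot stance fraction (close to
    1.0 only for walking-like gaits without flight phases).
    """
    model = nlp.gait_model
    skel = model.skeleton
    tr = record.trajectories
    X, tf = tr["X_mesh"], tr["t_f"]
    iq, iv = 2 * _NMUS, 2 * _NMUS + _NQ
    fr, fl = [], []
    for k in range(X.shape[0]):
        kin = rigid.contact_sphere_kinematics(skel, X[k, iq:iq + _NQ],
                                              X[k, iv:iv + _NQ])
        f = [rigid.contact_force_smooth(s, p, vp)[1]
             for (bn, s), (p, vp) in zip(skel.contact_spheres, kin)]
        fr.append(f[0] + f[1])
        fl.append(f[2] + f[3])
    fr, fl = np.array(fr), np.array(fl)
    bw = skel.total_mass * skel.gravity
    # trapezoid impulse over the half cycle, both feet
    h = tf / (X.shape[0] - 1)
    impulse = np.trapezoid(fr + fl, dx=h)
    any_stance = (fr > grf_threshold) | (fl > grf_threshold)
    stance_fraction = float(np.mean(any_stance))
    return {
        "grf_right": fr, "grf_left": fl, "body_weight": bw,
        "stance_fraction_right": float(np.mean(fr > grf_threshold)),
        "stance_fraction_left": float(np.mean(fl > grf_threshold)),
        "stance_fraction_any": stance_fraction,
        "grf_positive_in_stance": bool(
            np.all(fr[fr > grf_threshold] > 0)
            and np.all(fl[fl > grf_threshold] > 0)),
        "impulse_over_bw_cycle": float(impulse / (bw * tf)),
        "impulse_over_bw_stance": float(impulse / (bw * tf * stance_fraction))
        if stance_fraction else np.inf,
    }


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def trajectory_fingerprint(record: col.SolveRecord, tol: float = 1e-3) -> str:
    """Fingerprint of the scaled solution rounded to ``tol``.

    Two quantization grids offset by half a bin are hashed; runs are treated
    as having converged to the same optimum iff either hash matches
    (:func:`fingerprints_match`).  The two-grid scheme makes the comparison
    robust to solver noise far smaller than ``tol`` landing on a bin edge.
    """
    h1 = hashlib.sha1(np.floor(record.z / tol).tobytes()).hexdigest()[:12]
    h2 = hashlib.sha1(np.floor(record.z / tol + 0.5).tobytes()).hexdigest()[:12]
    return f"{h1}:{h2}"


def fingerprints_match(f1: str, f2: str) -> bool:
    """True iff the runs behind the two fingerprints reached the same
    optimum (either quantization grid agrees)."""
    a1, a2 = f1.split(":")
    b1, b2 = f2.split(":")
    return a1 == b1 or a2 == b2


@dataclass
class BenchmarkRecord:
    problem: str
    scenario: str
    hessian: str
    seed: int
    status: str
    iterations: int
    time_s: float
    grad_time_share: float
    jac_time_share: float
    objective: float
    fingerprint: str


BENCH_COLUMNS = ["problem", "ndof_or_mesh", "scenario_idx", "scenario",
                 "hessian", "seed", "status", "iterations", "time_s",
                 "grad_time_share", "jac_time_share", "objective",
                 "fingerprint"]


def run_benchmark(problems: dict, scenarios=(("ad", "lbfgs"), ("fd", "lbfgs")),
                  seeds=(0,), n_guesses: int = 1, tol: float = 1e-6,
                  max_iter: int = 3000):
    """Solve every problem under every (derivative scenario, Hessian mode)
    from seeded initial guesses; return the record table and a ratio summary.

    ``problems`` maps a problem id to a zero-argument factory returning a
    fresh :class:`~tapetraj.collocation.TranscribedNLP`.  Ratios
    (time, iterations, time/iteration of each scenario relative to the
    first) are averaged over runs whose fingerprints match the reference
    scenario's; mismatching runs are excluded and counted, mirroring the
    screening of runs that converged to different optima.
    """
    rows = []
    for pid, factory in problems.items():
        for seed in seeds:
            for si, (deriv, hess) in enumerate(scenarios):
                nlp = factory()
                guesses = make_initial_guesses(nlp, count=n_guesses, seed=seed)
                for gi, g in enumerate(guesses):
                    rec = col.solve(nlp, col.SolveOptions(
                        deriv_mode=deriv, hessian=hess, tol=tol,
                        max_iter=max_iter, initial_guess=g))
                    tot = max(rec.wall_time, 1e-12)
                    rows.append({
                        "problem": pid, "ndof_or_mesh": nlp.N,
                        "scenario_idx": si, "scenario": deriv, "hessian": hess,
                        "seed": seed * 1000 + gi, "status": rec.status,
                        "iterations": rec.iterations, "time_s": rec.wall_time,
                        "grad_time_share": rec.timings["grad"] / tot,
                        "jac_time_share": rec.timings["jac"] / tot,
                        "objective": rec.objective,
                        "fingerprint": trajectory_fingerprint(rec),
                    })
    table = pd.DataFrame(rows, columns=BENCH_COLUMNS)

    summary_rows = []
    excluded = 0
    for pid in problems:
        sub = table[table.problem == pid]
        ref = sub[sub.scenario_idx == 0]
        for si, (deriv, hess) in enumerate(scenarios[1:], start=1):
            alt = sub[sub.scenario_idx == si]
            merged = ref.merge(alt, on="seed", suffixes=("_ref", "_alt"))
            ok = [fingerprints_match(a, b) for a, b in
                  zip(merged.fingerprint_ref, merged.fingerprint_alt)]
            match = merged[np.asarray(ok, dtype=bool)] if len(merged) else merged
            excluded += len(merged) - len(match)
            if len(match) == 0:
                warnings_msg = "all runs excluded (no matching optima)"
                summary_rows.append({"problem": pid, "scenario": f"{deriv}/{hess}",
                                     "n": 0, "time_ratio_mean": np.nan,
                                     "time_ratio_std": np.nan,
                                     "iter_ratio_mean": np.nan,
                                     "note": warnings_msg})
                continue
            tr = match.time_s_alt / match.time_s_ref
            ir = match.iterations_alt / match.iterations_ref
            summary_rows.append({
                "problem": pid, "scenario": f"{deriv}/{hess}", "n": len(match),
                "time_ratio_mean": float(tr.mean()), "time_ratio_std": float(tr.std(ddof=0)),
                "iter_ratio_mean": float(ir.mean()), "note": ""})
    summary = pd.DataFrame(summary_rows)
    summary.attrs["excluded"] = excluded
    return table, summary
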