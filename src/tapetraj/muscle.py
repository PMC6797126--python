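"""Muscle and actuator dynamics.

Four pieces feed the muscle-driven walking problem:

* Raasch-style activation dynamics expressed as rate *bounds* rather than a
  first-order ODE: the scaled activation-rate control ``u_da`` must keep the
  rate ``s_da * u_da`` inside the band ``[-a/tau_d, (1 - a)/tau_a]``
  (:func:`raasch_bounds`),
* an implicit Hill-type contraction residual in which the normalized tendon
  force ``F_t`` is a state and its scaled rate ``u_dFt`` a control
  (:func:`hill_residual`); fiber kinematics are recovered from the state
  through the invertible tendon force-length curve,
* a first-order ideal torque actuator for the trunk
  (:func:`torque_actuator_rate`), and
* polynomial muscle-tendon geometry: multivariate polynomials in the joint
  angles fitted to length and moment-arm samples, with moment arms defined
  as the negative length gradient so they are AD-consistent by construction
  (:func:`fit_polynomials`, :func:`eval_lmt_vmt_ma`).

The Hill curve set follows the standard C2 formulation used for implicit
contraction dynamics: an exponential tendon force-length curve, a
sum-of-Gaussians active force-length curve, an arcsinh-type force-velocity
curve and an exponential passive curve.  All constants are overridable
through :class:`HillCurves`; the defaults are documented in the gait fixture
and the methods note.  Pennation uses the constant-thickness model
(``l_M sin(alpha)`` constant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .adgraph import exp, log, sqrt

__all__ = [
    "ActivationConstants", "MuscleParams", "TorqueActuatorParams", "HillCurves",
    "PolynomialGeometry", "FitReport", "raasch_bounds", "hill_residual",
    "torque_actuator_rate", "fit_polynomials", "eval_lmt_vmt_ma",
    "fit_reports_table", "tendon_force_length", "tendon_length_from_force", "active_force_length",
    "force_velocity", "force_velocity_inverse", "passive_force_length",
]


@dataclass
class ActivationConstants:
    """Raasch activation-dynamics constants: activation and deactivation time
    constants (s) and the scale of the activation-rate control."""

    tau_a: float = 0.015
    tau_d: float = 0.060
    s_da: float = 100.0

    def __post_init__(self):
        if not 0 < self.tau_a < self.tau_d:
            raise ValueError("require 0 < tau_a < tau_d")


@dataclass
class MuscleParams:
    """Hill-type muscle-tendon parameters.

    ``F_max`` maximal isometric force (N); ``l_M_opt`` optimal fiber length
    (m); ``v_M_max`` maximal shortening velocity (l_M_opt/s); ``l_T_slack``
    tendon slack length (m); ``alpha_opt`` optimal pennation angle (rad);
    ``k_T`` tendon stiffness shape parameter; ``F_t_ub`` upper bound of the
    normalized tendon force state; ``s_dFt`` scale of the tendon-force-rate
    control.
    """

    F_max: float
    l_M_opt: float
    v_M_max: float = 10.0
    l_T_slack: float = 0.2
    alpha_opt: float = 0.1
    k_T: float = 35.0
    F_t_ub: float = 5.0
    s_dFt: float = 100.0
    name: str = ""

    def __post_init__(self):
        if min(self.F_max, self.l_M_opt, self.v_M_max, self.l_T_slack) <= 0:
            raise ValueError("muscle forces/lengths/velocities must be positive")
        if not 0 <= self.alpha_opt < np.pi / 2:
            raise ValueError("pennation angle must lie in [0, pi/2)")
        if self.F_t_ub <= 0:
            raise ValueError("tendon force bound must be positive")


@dataclass
class TorqueActuatorParams:
    """Ideal first-order torque actuator (trunk): excitation-to-activation
    time constant (s) and torque scale (N m)."""

    tau: float = 0.035
    scale: float = 150.0

    def __post_init__(self):
        if self.tau <= 0 or self.scale <= 0:
            raise ValueError("tau and scale must be positive")


@dataclass
class HillCurves:
    """Constants of the C2 Hill curve set (all overridable).

    Tendon:    f_T(lt)  = c1 * exp(kT (lt - c2)) - c3
    Active FL: f_act(lm) = sum_i b1i * exp(-0.5 (lm - b2i)^2 / (b3i + b4i lm)^2)
    FV:        f_v(vm)  = d1 * log(d2 vm + d3 + sqrt((d2 vm + d3)^2 + 1)) + d4
    Passive:   f_pas(lm) = (exp(kpe (lm - 1) / e0) - 1) / (exp(kpe) - 1)
    """

    tendon_c1: float = 0.200
    tendon_c2: float = 0.995
    tendon_c3: float = 0.250
    fl_b: tuple = ((0.815, 1.055, 0.162, 0.063),
                   (0.433, 0.717, -0.030, 0.200),
                   (0.100, 1.000, 0.354, 0.000))
    fv_d: tuple = (-0.318, -8.149, -0.374, 0.886)
    pas_kpe: float = 4.0
    pas_e0: float = 0.6


_DEFAULT_CURVES = HillCurves()


def tendon_force_length(lt_norm, k_T=35.0, curves: HillCurves = _DEFAULT_CURVES):
    """Normalized tendon force from normalized tendon length."""
    return curves.tendon_c1 * exp(k_T * (lt_norm - curves.tendon_c2)) - curves.tendon_c3


def tendon_length_from_force(ft_norm, k_T=35.0, curves: HillCurves = _DEFAULT_CURVES):
    """Inverse tendon curve: normalized tendon length from normalized force."""
    return curves.tendon_c2 + log((ft_norm + curves.tendon_c3) / curves.tendon_c1) / k_T


def active_force_length(lm_norm, curves: HillCurves = _DEFAULT_CURVES):
    total = 0.0
    for b1, b2, b3, b4 in curves.fl_b:
        den = b3 + b4 * lm_norm
        total = total + b1 * exp(-0.5 * (lm_norm - b2) ** 2 / (den * den))
    return total


def force_velocity(vm_norm, curves: HillCurves = _DEFAULT_CURVES):
    d1, d2, d3, d4 = curves.fv_d
    z = d2 * vm_norm + d3
    return d1 * log(z + sqrt(z * z + 1.0)) + d4


def force_velocity_inverse(fv, curves: HillCurves = _DEFAULT_CURVES):
    """Normalized fiber velocity at which the force-velocity curve equals fv."""
    d1, d2, d3, d4 = curves.fv_d
    z = np.sinh((fv - d4) / d1)
    return (z - d3) / d2


def passive_force_length(lm_norm, curves: HillCurves = _DEFAULT_CURVES):
    kpe, e0 = curves.pas_kpe, curves.pas_e0
    return (exp(kpe * (lm_norm - 1.0) / e0) - 1.0) / (np.exp(kpe) - 1.0)


def raasch_bounds(a, u_da, c: ActivationConstants = ActivationConstants()):
    """Raasch activation-dynamics residual pair.

    ``r_lo = s_da u_da + a / tau_d`` is feasible iff >= 0 (deactivation rate
    limited by the current activation) and ``r_hi = s_da u_da + a / tau_a
    - 1 / tau_a`` is feasible iff <= 0 (activation rate limited by the
    remaining headroom).  For any ``a`` in [0, 1] the feasible ``u_da``
    interval is non-empty.
    """
    r_lo = c.s_da * u_da + a / c.tau_d
    r_hi = c.s_da * u_da + a / c.tau_a - 1.0 / c.tau_a
    return r_lo, r_hi


def torque_actuator_rate(e, act, p: TorqueActuatorParams = TorqueActuatorParams()):
    """First-order ideal-actuator activation rate ``(e - act) / tau``."""
    return (e - act) / p.tau


def hill_residual(a, l_MT, v_MT, F_t, u_dFt, p: MuscleParams,
                  curves: HillCurves = _DEFAULT_CURVES):
    """Implicit Hill-type contraction-dynamics residual ``f_c = 0``.

    The normalized tendon force ``F_t`` is a state and ``u_dFt`` its scaled
    rate control (``dF_t/dt = s_dFt * u_dFt``).  Tendon length follows from
    the invertible tendon curve, fiber length from the constant-thickness
    pennation model, and fiber velocity from differentiating the tendon
    curve.  The residual is the normalized fiber-force projection minus the
    tendon force:

        r = (a f_act(lm) f_v(vm) + f_pas(lm)) cos(alpha) - F_t

    and is zero exactly at muscle-tendon equilibrium.  It is C2 in all
    arguments (every curve in the set is smooth).
    """
    # tendon kinematics from the force state
    lt_norm = tendon_length_from_force(F_t, p.k_T, curves)
    l_T = lt_norm * p.l_T_slack
    dlt_dt = p.l_T_slack * p.s_dFt * u_dFt / (p.k_T * (F_t + curves.tendon_c3))

    # fiber kinematics: constant-thickness pennation
    proj = l_MT - l_T                      # fiber projection on the MT line
    h = p.l_M_opt * np.sin(p.alpha_opt)    # constant fiber height
    l_M = sqrt(proj * proj + h * h)
    cos_alpha = proj / l_M
    lm_norm = l_M / p.l_M_opt
    # d l_M / dt = cos(alpha) * (v_MT - v_T)
    vm_norm = cos_alpha * (v_MT - dlt_dt) / (p.l_M_opt * p.v_M_max)

    f_act = active_force_length(lm_norm, curves)
    f_v = force_velocity(vm_norm, curves)
    f_pas = passive_force_length(lm_norm, curves)
    return (a * f_act * f_v + f_pas) * cos_alpha - F_t


# ---------------------------------------------------------------------------
# polynomial muscle-tendon geometry
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Per-muscle polynomial fit quality."""

    name: str
    order: int
    n_coeffs: int
    rms_length: float       # m
    rms_moment_arm: float   # m


@dataclass
class PolynomialGeometry:
    """Multivariate polynomial muscle-tendon length model for one muscle.

    ``l_MT(q) = sum_k coeffs[k] * prod_j q_j ** exponents[k][j]`` over the
    spanned coordinates.  Moment arm about coordinate j is the negative
    partial derivative ``-d l_MT / d q_j``; evaluated through the same
    polynomial (or its AD tape) the two are consistent to machine precision
    by construction.
    """

    name: str
    coords: list[int]                  # indices of spanned coordinates
    exponents: list[tuple[int, ...]]   # one tuple per monomial
    coeffs: np.ndarray
    order: int
    q_min: np.ndarray | None = None
    q_max: np.ndarray | None = None

    def length(self, q_span):
        """l_MT at the spanned coordinates (generic over value types)."""
        total = 0.0
        for ex, c in zip(self.exponents, self.coeffs):
            term = float(c)
            for qj, e in zip(q_span, ex):
                for _ in range(e):
                    term = term * qj
            total = total + term
        return total

    def moment_arms(self, q_span):
        """Moment arms ``-d l_MT / d q_j`` (analytic polynomial gradient)."""
        out = []
        for j in range(len(self.coords)):
            total = 0.0
            for ex, c in zip(self.exponents, self.coeffs):
                if ex[j] == 0:
                    continue
                term = -float(c) * ex[j]
                for k, (qj, e) in enumerate(zip(q_span, ex)):
                    p = e - 1 if k == j else e
                    for _ in range(p):
                        term = term * qj
                total = total + term
            out.append(total)
        return out


def _monomial_exponents(n_coords: int, order: int):
    exps = []
    for combo in itertools.product(range(order + 1), repeat=n_coords):
        if sum(combo) <= order:
            exps.append(tuple(combo))
    exps.sort(key=lambda e: (sum(e), e))
    return exps


def _design_matrices(Q: np.ndarray, exps):
    """Length rows and per-coordinate moment-arm rows for the monomials."""
    n, m = Q.shape
    A_len = np.ones((n, len(exps)))
    A_ma = np.zeros((m, n, len(exps)))
    for k, ex in enumerate(exps):
        col = np.ones(n)
        for j, e in enumerate(ex):
            if e:
                col = col * Q[:, j] ** e
        A_len[:, k] = col
        for j, e in enumerate(ex):
            if e == 0:
                continue
            dcol = -float(e) * np.ones(n)
            for jj, ee in enumerate(ex):
                p = ee - 1 if jj == j else ee
                if p:
                    dcol = dcol * Q[:, jj] ** p
            A_ma[j, :, k] = dcol
    return A_len, A_ma


def fit_polynomials(samples: dict, max_order: int = 9, rms_tol: float = 0.003,
                    ma_weight: float = 1.0) -> tuple[dict, list[FitReport]]:
    """Fit per-muscle polynomial length models to (length, moment arm) samples.

    ``samples`` maps muscle name to a dict with keys ``coords`` (spanned
    coordinate indices), ``Q`` (grid points, shape ``(n, m)``), ``lmt``
    (lengths, shape ``(n,)``) and ``ma`` (moment arms, shape ``(n, m)``).
    The least-squares fit jointly penalizes length and moment-arm mismatch
    (moment arms are the negative length gradient, so both constrain the
    same coefficients).  For each muscle the lowest order whose length AND
    moment-arm RMS deviations are <= ``rms_tol`` (m) is selected, capped at
    ``max_order``.

    Returns ``(geometries, reports)``; raises ``RuntimeError`` naming the
    worst-fitting muscle if the tolerance cannot be met at ``max_order``.
    """
    geoms: dict[str, PolynomialGeometry] = {}
    reports: list[FitReport] = []
    failures: list[tuple[str, float]] = []
    for name, s in samples.items():
        Q = np.asarray(s["Q"], dtype=float)
        lmt = np.asarray(s["lmt"], dtype=float)
        ma = np.asarray(s["ma"], dtype=float)
        n, m = Q.shape
        best = None
        for order in range(1, max_order + 1):
            exps = _monomial_exponents(m, order)
            if n < 10 * len(exps):
                break  # keep >= 10x more samples than coefficients
            A_len, A_ma = _design_matrices(Q, exps)
            A = np.vstack([A_len] + [ma_weight * A_ma[j] for j in range(m)])
            b = np.concatenate([lmt] + [ma_weight * ma[:, j] for j in range(m)])
            coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
            rms_len = float(np.sqrt(np.mean((A_len @ coeffs - lmt) ** 2)))
            rms_ma = float(np.sqrt(np.mean(
                [(A_ma[j] @ coeffs - ma[:, j]) ** 2 for j in range(m)])))
            best = (order, exps, coeffs, rms_len, rms_ma)
            if rms_len <= rms_tol and rms_ma <= rms_tol:
                break
        order, exps, coeffs, rms_len, rms_ma = best
        if rms_len > rms_tol or rms_ma > rms_tol:
            failures.append((name, max(rms_len, rms_ma)))
        geoms[name] = PolynomialGeometry(
            name=name, coords=list(s["coords"]), exponents=exps,
            coeffs=coeffs, order=order,
            q_min=Q.min(axis=0), q_max=Q.max(axis=0))
        reports.append(FitReport(name, order, len(exps), rms_len, rms_ma))
    if failures:
        worst = max(failures, key=lambda f: f[1])
        raise RuntimeError(
            f"polynomial fit failed at order {max_order}: worst muscle "
            f"{worst[0]!r} with RMS length deviation {worst[1] * 1e3:.2f} mm")
    return geoms, reports


def fit_reports_table(reports: Sequence[FitReport]):
    """Fit-quality reports as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame([{
        "muscle": r.name, "order": r.order, "n_coeffs": r.n_coeffs,
        "rms_length_mm": r.rms_length * 1e3,
        "rms_moment_arm_mm": r.rms_moment_arm * 1e3,
    } for r in reports])


def eval_lmt_vmt_ma(geom: PolynomialGeometry, q: Sequence, v: Sequence,
                    warn_out_of_range: bool = True):
    """Muscle-tendon length, lengthening velocity and moment arms.

    When ``geom.coords`` holds integer indices, ``q``/``v`` are full
    coordinate vectors and the spanned subset is selected through them;
    when it holds coordinate names, ``q``/``v`` are already in spanned
    order.  ``v_MT = sum_j (d l_MT / d q_j) v_j`` and the moment arms are
    the negative gradient, so ``v_MT = -MA . v``.
    """
    if geom.coords and isinstance(geom.coords[0], (int, np.integer)):
        q_span = [q[j] for j in geom.coords]
        v_span = [v[j] for j in geom.coords]
    else:
        q_span, v_span = list(q), list(v)
    if warn_out_of_range and geom.q_min is not None:
        try:
            qa = np.asarray([float(x) for x in q_span])
            if np.any(qa < geom.q_min - 1e-9) or np.any(qa > geom.q_max + 1e-9):
                import warnings
                warnings.warn(f"muscle {geom.name!r}: coordinates outside the "
                              "fitted range; polynomial is extrapolating")
        except (TypeError, ValueError):
            pass  # recorded scalars: range checking is a runtime concern only
    lmt = geom.length(q_span)
    mas = geom.moment_arms(q_span)
    vmt = 0.0
    for ma_j, vj in zip(mas, v_span):
        vmt = vmt + (-ma_j) * vj
    return lmt, vmt, mas
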