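"""Direct collocation transcription and NLP solution.

An :class:`OptimalControlProblem` (Bolza problem with implicit dynamics:
state derivatives appear as controls and the dynamic equations as algebraic
constraints) is transcribed into a scaled sparse NLP with a Radau IIA
collocation scheme:

* states live at the ``N + 1`` mesh points and at the ``d`` collocation
  points of every mesh interval (the right endpoint is a collocation point),
* controls are piecewise constant, one value per mesh interval,
* the collocation equations equate the interpolating-polynomial derivative
  with the (scaled) dynamics at every collocation point; continuity rows tie
  each interval's final collocation state to the next mesh state,
* equality path constraints are imposed once per mesh interval at the left
  mesh point, inequality path constraints likewise,
* the objective is the Radau quadrature of the integrand.

Derivative callbacks come either from :mod:`~tapetraj.adgraph` tapes
(``mode='ad'``: one vectorized reverse sweep for the gradient, batched
forward/reverse sweeps for the block-sparse Jacobian, forward-over-reverse
for exact Hessians) or from forward finite differences (``mode='fd'``:
``n + 1`` function evaluations per gradient).  The NLP is handed to an
interior-point solver through a thin adapter (scipy's ``trust-constr``);
the ``linear_solver`` option is a pass-through string.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sps
from numpy.polynomial import Polynomial
from numpy.polynomial import legendre as _leg
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from . import adgraph as ad

__all__ = [
    "RadauScheme", "make_radau", "ScalingSet", "OptimalControlProblem",
    "TranscribedNLP", "SolveOptions", "SolveRecord", "transcribe", "solve",
    "mesh_refine_check",
]


# ---------------------------------------------------------------------------
# Radau IIA scheme
# ---------------------------------------------------------------------------

@dataclass
class RadauScheme:
    """Radau IIA collocation data on the unit interval.

    ``points`` are the ``d`` abscissae on (0, 1] (last point exactly 1);
    ``diff_matrix`` has shape ``(d, d + 1)`` and maps interpolant values at
    ``[0, points...]`` to interpolant derivatives at the collocation points;
    ``quad_weights`` integrate exactly polynomials up to degree ``2d - 2``.
    """

    degree: int
    points: np.ndarray
    diff_matrix: np.ndarray
    quad_weights: np.ndarray


def make_radau(d: int = 3) -> RadauScheme:
    """Construct the degree-``d`` Radau IIA scheme (order ``2d - 1``)."""
    if d < 1:
        raise ValueError("degree must be >= 1")
    if d > 9:
        raise ValueError("degrees above 9 are not supported")
    # Radau IIA abscissae: roots of P_d - P_{d-1} mapped from [-1,1] to [0,1]
    c = np.zeros(d + 1)
    c[d] = 1.0
    c[d - 1] -= 1.0
    pts = np.sort((_leg.legroots(c) + 1.0) / 2.0)
    pts[-1] = 1.0

    basis = np.concatenate([[0.0], pts])
    D = np.empty((d, d + 1))
    for i in range(d + 1):
        y = np.zeros(d + 1)
        y[i] = 1.0
        ell = Polynomial.fit(basis, y, d).deriv()
        D[:, i] = ell(pts)
    w = np.empty(d)
    for j in range(d):
        y = np.zeros(d)
        y[j] = 1.0
        ell = Polynomial.fit(pts, y, d - 1).integ()
        w[j] = ell(1.0) - ell(0.0)
    return RadauScheme(degree=d, points=pts, diff_matrix=D, quad_weights=w)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingSet:
    """Per-variable multiplicative scales mapping physical -> scaled
    (``x_scaled = x / scale``); applying then inverting is the identity."""

    x_scale: np.ndarray
    u_scale: np.ndarray
    p_scale: np.ndarray

    def __post_init__(self):
        for s in (self.x_scale, self.u_scale, self.p_scale):
            if np.any(np.asarray(s) == 0):
                raise ValueError("scale factors must be nonzero")

    @staticmethod
    def from_bounds(x_lb, x_ub, u_lb, u_ub, p_lb=(), p_ub=()) -> "ScalingSet":
        """Bound-derived scales ``max(|lb|, |ub|)`` mapping bounds into
        [-1, 1] (the walking-problem convention)."""
        def mk(lb, ub):
            s = np.maximum(np.abs(np.asarray(lb, float)), np.abs(np.asarray(ub, float)))
            s[s == 0] = 1.0
            return s
        return ScalingSet(mk(x_lb, x_ub), mk(u_lb, u_ub),
                          mk(p_lb, p_ub) if len(np.atleast_1d(p_lb)) else np.ones(0))


# ---------------------------------------------------------------------------
# optimal control problem
# ---------------------------------------------------------------------------

@dataclass
class OptimalControlProblem:
    """Continuous-time problem data in the implicit-dynamics form.

    ``rates(x, u, p, t)`` returns the state derivatives (the dynamic
    constraints); ``integrand`` the running cost; ``path_eq``/``path_ineq``
    algebraic path constraints (equalities, and inequalities with bounds);
    ``boundary(x0, xN, p)`` boundary/periodicity equality residuals.  All
    model functions receive *physical* quantities and must be branch-free
    compositions of the supported smooth ops so they can be recorded on a
    tape.  ``t_f`` is the fixed horizon, or None with ``tf_param`` naming
    the free-final-time parameter index.
    """

    state_names: list[str]
    control_names: list[str]
    x_lb: np.ndarray
    x_ub: np.ndarray
    u_lb: np.ndarray
    u_ub: np.ndarray
    rates: Callable
    integrand: Callable
    scaling: ScalingSet
    param_names: list[str] = field(default_factory=list)
    p_lb: np.ndarray = field(default_factory=lambda: np.zeros(0))
    p_ub: np.ndarray = field(default_factory=lambda: np.zeros(0))
    path_eq: Callable | None = None
    path_ineq: Callable | None = None
    boundary: Callable | None = None
    t_f: float | None = 1.0
    tf_param: int | None = None
    nominal_x: np.ndarray | None = None
    nominal_u: np.ndarray | None = None
    nominal_p: np.ndarray | None = None
    # state indices whose initial mesh value is pinned (variable bound fixed)
    anchor_x0: dict = field(default_factory=dict)
    name: str = "ocp"

    def __post_init__(self):
        self.x_lb = np.asarray(self.x_lb, float)
        self.x_ub = np.asarray(self.x_ub, float)
        self.u_lb = np.asarray(self.u_lb, float)
        self.u_ub = np.asarray(self.u_ub, float)
        self.p_lb = np.asarray(self.p_lb, float)
        self.p_ub = np.asarray(self.p_ub, float)
        if np.any(self.x_lb > self.x_ub) or np.any(self.u_lb > self.u_ub):
            raise ValueError("lower bounds exceed upper bounds")
        if self.t_f is None and self.tf_param is None:
            raise ValueError("free final time requires tf_param")
        if self.nominal_x is None:
            self.nominal_x = 0.5 * (self.x_lb + self.x_ub)
        if self.nominal_u is None:
            self.nominal_u = 0.5 * (self.u_lb + self.u_ub)
        if self.nominal_p is None:
            self.nominal_p = 0.5 * (self.p_lb + self.p_ub) if self.n_p else np.zeros(0)

    @property
    def n_x(self) -> int:
        return len(self.state_names)

    @property
    def n_u(self) -> int:
        return len(self.control_names)

    @property
    def n_p(self) -> int:
        return len(self.param_names)


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------

def _as_batch(out, B):
    """Normalize a list of per-output values (scalars or length-B arrays)
    into an (n_out, B) array."""
    M = np.empty((len(out), B))
    for i, v in enumerate(out):
        M[i, :] = v
    return M


class TranscribedNLP:
    """Scaled sparse NLP produced by :func:`transcribe`.

    Decision vector layout (all scaled): mesh states ``(N+1) * n_x``,
    collocation states ``N * d * n_x``, controls ``N * n_u``, parameters
    ``n_p``.  Equality rows: collocation equations, continuity, per-interval
    path equalities, boundary; inequality rows: per-interval path
    inequalities.  Callbacks are attached by ``mode`` ('ad' or 'fd').
    """

    def __init__(self, ocp: OptimalControlProblem, N: int, scheme: RadauScheme,
                 mode: str = "ad"):
        if N < 1:
            raise ValueError("need at least one mesh interval")
        self.ocp = ocp
        self.N = N
        self.scheme = scheme
        self.mode = mode
        d = scheme.degree
        n_x, n_u, n_p = ocp.n_x, ocp.n_u, ocp.n_p
        self.d = d

        self.off_mesh = 0
        self.off_coll = (N + 1) * n_x
        self.off_u = self.off_coll + N * d * n_x
        self.off_p = self.off_u + N * n_u
        self.n_vars = self.off_p + n_p

        self.counters = {"obj_evals": 0, "con_evals": 0, "grad_evals": 0,
                         "jac_evals": 0, "hess_evals": 0, "fd_evals": 0}
        self.timings = {"obj": 0.0, "grad": 0.0, "con": 0.0, "jac": 0.0, "hess": 0.0}

        self._build_bounds()
        self._record_tapes()
        self._build_linear_parts()
        self._build_gathers()
        self._vjp = {}

    # -- layout helpers ----------------------------------------------------

    def idx_mesh(self, k, s=None):
        base = self.off_mesh + k * self.ocp.n_x
        return base if s is None else base + s

    def idx_coll(self, k, j, s=None):
        base = self.off_coll + (k * self.d + j) * self.ocp.n_x
        return base if s is None else base + s

    def idx_u(self, k, c=None):
        base = self.off_u + k * self.ocp.n_u
        return base if c is None else base + c

    # -- construction ------------------------------------------------------

    def _build_bounds(self):
        ocp, N, d = self.ocp, self.N, self.d
        sx, su, sp = ocp.scaling.x_scale, ocp.scaling.u_scale, ocp.scaling.p_scale
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)
        xlb, xub = ocp.x_lb / sx, ocp.x_ub / sx
        for k in range(N + 1):
            lb[self.idx_mesh(k):self.idx_mesh(k) + ocp.n_x] = xlb
            ub[self.idx_mesh(k):self.idx_mesh(k) + ocp.n_x] = xub
        for k in range(N):
            for j in range(d):
                lb[self.idx_coll(k, j):self.idx_coll(k, j) + ocp.n_x] = xlb
                ub[self.idx_coll(k, j):self.idx_coll(k, j) + ocp.n_x] = xub
            lb[self.idx_u(k):self.idx_u(k) + ocp.n_u] = ocp.u_lb / su
            ub[self.idx_u(k):self.idx_u(k) + ocp.n_u] = ocp.u_ub / su
        if ocp.n_p:
            lb[self.off_p:] = ocp.p_lb / sp
            ub[self.off_p:] = ocp.p_ub / sp
        for s, val in ocp.anchor_x0.items():
            lb[self.idx_mesh(0, s)] = ub[self.idx_mesh(0, s)] = val / sx[s]
        self.z_lb, self.z_ub = lb, ub

    def _wrap_point_fn(self, fn, want_h: bool):
        """Build a tape function over scaled inputs [x~, u~, p~, tnorm]."""
        ocp = self.ocp
        sx, su, sp = ocp.scaling.x_scale, ocp.scaling.u_scale, ocp.scaling.p_scale
        N = self.N

        def wrapped(zz):
            x = [zz[i] * sx[i] for i in range(ocp.n_x)]
            u = [zz[ocp.n_x + i] * su[i] for i in range(ocp.n_u)]
            p = [zz[ocp.n_x + ocp.n_u + i] * sp[i] for i in range(ocp.n_p)]
            tn = zz[-1]
            tf = ocp.t_f if ocp.t_f is not None else p[ocp.tf_param]
            t = tn * tf
            out = fn(x, u, p, t)
            if want_h:
                h = tf / N
                out = [h * o for o in out]
            return out

        return wrapped

    def _record_tapes(self):
        ocp = self.ocp
        sx = ocp.scaling.x_scale
        zz0 = np.concatenate([
            np.asarray(ocp.nominal_x, float) / sx,
            np.asarray(ocp.nominal_u, float) / ocp.scaling.u_scale,
            (np.asarray(ocp.nominal_p, float) / ocp.scaling.p_scale) if ocp.n_p else np.zeros(0),
            [0.5 / self.N],
        ])

        def scaled_rates(x, u, p, t):
            r = ocp.rates(x, u, p, t)
            return [ri / si for ri, si in zip(r, sx)]

        self.rate_tape = ad.record(self._wrap_point_fn(scaled_rates, want_h=True), zz0)
        self.integrand_tape = ad.record(
            self._wrap_point_fn(lambda x, u, p, t: [ocp.integrand(x, u, p, t)],
                                want_h=True), zz0)
        if ocp.path_eq is not None:
            self.patheq_tape = ad.record(
                self._wrap_point_fn(lambda x, u, p, t: ocp.path_eq(x, u, p, t),
                                    want_h=False), zz0)
            self.n_patheq = self.patheq_tape.n_outputs
        else:
            self.patheq_tape = None
            self.n_patheq = 0
        if ocp.path_ineq is not None:
            def ineq_vals(x, u, p, t):
                vals, lo, hi = ocp.path_ineq(x, u, p, t)
                return vals
            self.pathineq_tape = ad.record(
                self._wrap_point_fn(ineq_vals, want_h=False), zz0)
            _, lo, hi = ocp.path_ineq(list(ocp.nominal_x), list(ocp.nominal_u),
                                      list(ocp.nominal_p), 0.0)
            self.ineq_lb_pt = np.asarray(lo, float)
            self.ineq_ub_pt = np.asarray(hi, float)
            self.n_pathineq = self.pathineq_tape.n_outputs
        else:
            self.pathineq_tape = None
            self.n_pathineq = 0
        if ocp.boundary is not None:
            sxv, spv = sx, ocp.scaling.p_scale

            def bfn(zz):
                x0 = [zz[i] * sxv[i] for i in range(ocp.n_x)]
                xN = [zz[ocp.n_x + i] * sxv[i] for i in range(ocp.n_x)]
                p = [zz[2 * ocp.n_x + i] * spv[i] for i in range(ocp.n_p)]
                return ocp.boundary(x0, xN, p)

            zb0 = np.concatenate([zz0[:ocp.n_x], zz0[:ocp.n_x],
                                  zz0[ocp.n_x + ocp.n_u:-1]])
            self.boundary_tape = ad.record(bfn, zb0)
            self.n_boundary = self.boundary_tape.n_outputs
        else:
            self.boundary_tape = None
            self.n_boundary = 0

        # equality-row layout
        N, d, n_x = self.N, self.d, ocp.n_x
        self.n_coll_rows = N * d * n_x
        self.n_cont_rows = N * n_x
        self.row_coll = 0
        self.row_cont = self.n_coll_rows
        self.row_patheq = self.row_cont + self.n_cont_rows
        self.row_boundary = self.row_patheq + N * self.n_patheq
        self.n_eq = self.row_boundary + self.n_boundary
        self.n_ineq = N * self.n_pathineq
        self.ineq_lb = np.tile(self.ineq_lb_pt, N) if self.n_pathineq else np.zeros(0)
        self.ineq_ub = np.tile(self.ineq_ub_pt, N) if self.n_pathineq else np.zeros(0)

    def _build_linear_parts(self):
        N, d, n_x = self.N, self.d, self.ocp.n_x
        D = self.scheme.diff_matrix
        rows, cols, vals = [], [], []
        for k in range(N):
            for j in range(d):
                for s in range(n_x):
                    r = self.row_coll + (k * d + j) * n_x + s
                    rows.append(r)
                    cols.append(self.idx_mesh(k, s))
                    vals.append(D[j, 0])
                    for i in range(d):
                        rows.append(r)
                        cols.append(self.idx_coll(k, i, s))
                        vals.append(D[j, i + 1])
        for k in range(N):
            for s in range(n_x):
                r = self.row_cont + k * n_x + s
                rows.extend([r, r])
                cols.extend([self.idx_mesh(k + 1, s), self.idx_coll(k, d - 1, s)])
                vals.extend([1.0, -1.0])
        self._A_lin = sps.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_eq, self.n_vars)).tocsr()
        self._lin_rows = np.array(rows)

    def _build_gathers(self):
        """Index maps from the flat decision vector into tape-input batches."""
        ocp, N, d = self.ocp, self.N, self.d
        n_x, n_u, n_p = ocp.n_x, ocp.n_u, ocp.n_p
        n_in = n_x + n_u + n_p  # decision inputs (tnorm handled separately)

        # batch over all N*d collocation points (rate/integrand tapes)
        B1 = N * d
        cmap = np.empty((n_in, B1), dtype=np.intp)
        for k in range(N):
            for j in range(d):
                b = k * d + j
                for s in range(n_x):
                    cmap[s, b] = self.idx_coll(k, j, s)
                for c in range(n_u):
                    cmap[n_x + c, b] = self.idx_u(k, c)
                for i in range(n_p):
                    cmap[n_x + n_u + i, b] = self.off_p + i
        tn1 = np.empty(B1)
        for k in range(N):
            for j in range(d):
                tn1[k * d + j] = (k + self.scheme.points[j]) / N
        self._cmap_coll, self._tn_coll = cmap, tn1
        self._wq = np.tile(self.scheme.quad_weights, N)

        # batch over the N interval left mesh points (path tapes)
        B2 = N
        pmap = np.empty((n_in, B2), dtype=np.intp)
        for k in range(N):
            for s in range(n_x):
                pmap[s, k] = self.idx_mesh(k, s)
            for c in range(n_u):
                pmap[n_x + c, k] = self.idx_u(k, c)
            for i in range(n_p):
                pmap[n_x + n_u + i, k] = self.off_p + i
        self._cmap_path = pmap
        self._tn_path = np.arange(N) / N

        if self.boundary_tape is not None:
            bmap = np.empty(2 * n_x + n_p, dtype=np.intp)
            for s in range(n_x):
                bmap[s] = self.idx_mesh(0, s)
                bmap[n_x + s] = self.idx_mesh(N, s)
            for i in range(n_p):
                bmap[2 * n_x + i] = self.off_p + i
            self._bmap = bmap

        # static COO patterns for the nonlinear Jacobian blocks
        self._jac_patterns = {}
        for tag, tape, cmapM, row0, nrows_pt in self._nl_blocks():
            n_out = tape.n_outputs
            B = cmapM.shape[1]
            rows = np.empty((n_out, n_in, B), dtype=np.intp)
            cols = np.empty_like(rows)
            for o in range(n_out):
                for i in range(n_in):
                    rows[o, i, :] = row0 + np.arange(B) * nrows_pt + o
                    cols[o, i, :] = cmapM[i]
            self._jac_patterns[tag] = (rows.ravel(), cols.ravel())

    def _nl_blocks(self):
        """(tag, tape, colmap, first row, rows per batch point) for each
        nonlinear equality block."""
        blocks = [("rate", self.rate_tape, self._cmap_coll, self.row_coll,
                   self.ocp.n_x)]
        if self.patheq_tape is not None:
            blocks.append(("patheq", self.patheq_tape, self._cmap_path,
                           self.row_patheq, self.n_patheq))
        return blocks

    # -- evaluation helpers ------------------------------------------------

    def _gather(self, z, cmapM, tn):
        X = [z[cmapM[i]] for i in range(cmapM.shape[0])]
        X.append(tn)
        return X

    def _tape_inputs(self):
        return self.ocp.n_x + self.ocp.n_u + self.ocp.n_p

    # -- callbacks: values -------------------------------------------------

    def objective(self, z):
        t0 = time.perf_counter()
        self.counters["obj_evals"] += 1
        X = self._gather(z, self._cmap_coll, self._tn_coll)
        vals = ad._values_at(self.integrand_tape, X, check_branches=False)
        out = vals[self.integrand_tape.output_ids[0]]
        val = float(np.dot(self._wq, np.broadcast_to(out, self._wq.shape)))
        self.timings["obj"] += time.perf_counter() - t0
        return val

    def constraints_eq(self, z):
        t0 = time.perf_counter()
        self.counters["con_evals"] += 1
        N, d, n_x = self.N, self.d, self.ocp.n_x
        c = self._A_lin @ z
        X = self._gather(z, self._cmap_coll, self._tn_coll)
        vals = ad._values_at(self.rate_tape, X, check_branches=False)
        hr = _as_batch([vals[i] for i in self.rate_tape.output_ids], N * d)
        c[self.row_coll:self.row_coll + self.n_coll_rows] -= hr.T.ravel()
        if self.patheq_tape is not None:
            Xp = self._gather(z, self._cmap_path, self._tn_path)
            vp = ad._values_at(self.patheq_tape, Xp, check_branches=False)
            g = _as_batch([vp[i] for i in self.patheq_tape.output_ids], N)
            c[self.row_patheq:self.row_patheq + N * self.n_patheq] = g.T.ravel()
        if self.boundary_tape is not None:
            c[self.row_boundary:] = ad.replay(self.boundary_tape, z[self._bmap])
        self.timings["con"] += time.perf_counter() - t0
        return c

    def constraints_ineq(self, z):
        if self.pathineq_tape is None:
            return np.zeros(0)
        Xp = self._gather(z, self._cmap_path, self._tn_path)
        vp = ad._values_at(self.pathineq_tape, Xp, check_branches=False)
        g = _as_batch([vp[i] for i in self.pathineq_tape.output_ids], self.N)
        return g.T.ravel()

    # -- callbacks: first derivatives (ad) ---------------------------------

    def gradient(self, z):
        t0 = time.perf_counter()
        self.counters["grad_evals"] += 1
        if self.mode == "fd":
            g = self._fd_gradient(z)
            self.timings["grad"] += time.perf_counter() - t0
            return g
        n_in = self._tape_inputs()
        X = self._gather(z, self._cmap_coll, self._tn_coll)
        bars = ad.reverse_sweep(self.integrand_tape, [self._wq], x=X)
        g = np.zeros(self.n_vars)
        for i in range(n_in):
            b = bars[i]
            if np.ndim(b) == 0:
                b = np.broadcast_to(b, self._wq.shape)
            np.add.at(g, self._cmap_coll[i], b)
        self.timings["grad"] += time.perf_counter() - t0
        return g

    def jacobian_eq(self, z):
        t0 = time.perf_counter()
        self.counters["jac_evals"] += 1
        if self.mode == "fd":
            J = self._fd_jacobian(self.constraints_eq, z, self.n_eq)
            self.timings["jac"] += time.perf_counter() - t0
            return J
        n_in = self._tape_inputs()
        parts = [self._A_lin]
        rows_all, cols_all, vals_all = [], [], []
        for tag, tape, cmapM, row0, nrows_pt in self._nl_blocks():
            tn = self._tn_coll if tag == "rate" else self._tn_path
            X = self._gather(z, cmapM, tn)
            J = ad.batch_jacobian(tape, X, inputs=range(n_in))
            if tag == "rate":
                J = -J  # collocation rows are (linear part) - h * rates
            rows, cols = self._jac_patterns[tag]
            rows_all.append(rows)
            cols_all.append(cols)
            vals_all.append(J.ravel())
        if self.boundary_tape is not None:
            Jb = ad.jacobian(self.boundary_tape, x=z[self._bmap])
            r, c = np.nonzero(np.ones_like(Jb))
            rows_all.append(self.row_boundary + r)
            cols_all.append(self._bmap[c])
            vals_all.append(Jb.ravel())
        Jnl = sps.coo_matrix(
            (np.concatenate(vals_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(self.n_eq, self.n_vars)).tocsr()
        out = (parts[0] + Jnl).tocsr()
        self.timings["jac"] += time.perf_counter() - t0
        return out

    def jacobian_ineq(self, z):
        if self.pathineq_tape is None:
            return sps.csr_matrix((0, self.n_vars))
        if self.mode == "fd":
            return self._fd_jacobian(self.constraints_ineq, z, self.n_ineq)
        n_in = self._tape_inputs()
        X = self._gather(z, self._cmap_path, self._tn_path)
        J = ad.batch_jacobian(self.pathineq_tape, X, inputs=range(n_in))
        n_out, B = self.n_pathineq, self.N
        rows = np.empty((n_out, n_in, B), dtype=np.intp)
        cols = np.empty_like(rows)
        for o in range(n_out):
            for i in range(n_in):
                rows[o, i, :] = np.arange(B) * n_out + o
                cols[o, i, :] = self._cmap_path[i]
        return sps.coo_matrix(
            (J.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.n_ineq, self.n_vars)).tocsr()

    # -- callbacks: fd mode -------------------------------------------------

    def _fd_gradient(self, z, h=1e-6):
        f0 = self.objective(z)
        g = np.empty(self.n_vars)
        for i in range(self.n_vars):
            zp = z.copy()
            zp[i] += h
            g[i] = (self.objective(zp) - f0) / h
        self.counters["fd_evals"] += self.n_vars + 1
        return g

    def _fd_jacobian(self, fn, z, n_rows, h=1e-6):
        f0 = fn(z)
        cols = []
        for i in range(self.n_vars):
            zp = z.copy()
            zp[i] += h
            cols.append((fn(zp) - f0) / h)
        self.counters["fd_evals"] += self.n_vars + 1
        return sps.csr_matrix(np.column_stack(cols)) if n_rows else \
            sps.csr_matrix((0, self.n_vars))

    # -- callbacks: exact Hessians (forward-over-reverse) --------------------

    def _get_vjp(self, tag, tape):
        if tag not in self._vjp:
            self._vjp[tag] = ad.vjp_tape(tape)
        return self._vjp[tag]

    def _batch_hessian_contrib(self, tape, tag, cmapM, tn, z, W,
                               rows_cols_out):
        """Accumulate per-point weighted Hessian blocks of ``tape`` into COO
        triplets.  ``W`` is an (n_out, B) array of seed weights."""
        n_in = self._tape_inputs()
        vt = self._get_vjp(tag, tape)
        X = self._gather(z, cmapM, tn)
        Z = X + [W[o] for o in range(tape.n_outputs)]
        B = cmapM.shape[1]
        # forward-over-reverse: forward sweeps of the recorded reverse sweep
        # over the decision inputs, vectorized over seeds and batch
        Hb = ad.multi_forward(vt, Z, inputs=range(n_in))  # (n_in, n_in, B)
        for i in range(n_in):
            for i2 in range(n_in):
                v = Hb[i2, i, :]
                if not np.any(v):
                    continue
                rows_cols_out[0].append(cmapM[i2])
                rows_cols_out[1].append(cmapM[i])
                rows_cols_out[2].append(v)

    def hessian_objective(self, z):
        self.counters["hess_evals"] += 1
        W = self._wq[None, :]
        acc = ([], [], [])
        self._batch_hessian_contrib(self.integrand_tape, "integrand",
                                    self._cmap_coll, self._tn_coll, z, W, acc)
        return self._acc_to_sparse(acc)

    def hessian_eq(self, z, v):
        self.counters["hess_evals"] += 1
        N, d, n_x = self.N, self.d, self.ocp.n_x
        acc = ([], [], [])
        v_coll = v[self.row_coll:self.row_coll + self.n_coll_rows]
        W = -v_coll.reshape(N * d, n_x).T  # minus: rows are linear - h*rates
        self._batch_hessian_contrib(self.rate_tape, "rate",
                                    self._cmap_coll, self._tn_coll, z, W, acc)
        if self.patheq_tape is not None:
            vp = v[self.row_patheq:self.row_patheq + N * self.n_patheq]
            Wp = vp.reshape(N, self.n_patheq).T
            self._batch_hessian_contrib(self.patheq_tape, "patheq",
                                        self._cmap_path, self._tn_path, z, Wp, acc)
        H = self._acc_to_sparse(acc)
        if self.boundary_tape is not None:
            vb = v[self.row_boundary:]
            if np.any(vb != 0.0):
                vt = self._get_vjp("boundary", self.boundary_tape)
                nb = self.boundary_tape.n_inputs
                Z = list(z[self._bmap]) + list(vb)
                Hb = ad.multi_forward(vt, Z, inputs=range(nb))[:nb, :, 0]
                bm = self._bmap
                H = H + sps.coo_matrix(
                    (Hb.ravel(),
                     (np.repeat(bm, bm.size), np.tile(bm, bm.size))),
                    shape=(self.n_vars, self.n_vars)).tocsr()
        return H

    def hessian_ineq(self, z, v):
        if self.pathineq_tape is None:
            return sps.csr_matrix((self.n_vars, self.n_vars))
        acc = ([], [], [])
        W = v.reshape(self.N, self.n_pathineq).T
        self._batch_hessian_contrib(self.pathineq_tape, "pathineq",
                                    self._cmap_path, self._tn_path, z, W, acc)
        return self._acc_to_sparse(acc)

    def _acc_to_sparse(self, acc):
        rows, cols, vals = acc
        if not rows:
            return sps.csr_matrix((self.n_vars, self.n_vars))
        return sps.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_vars, self.n_vars)).tocsr()

    # -- solution handling ---------------------------------------------------

    def initial_guess_zero(self):
        z = np.zeros(self.n_vars)
        return np.clip(z, self.z_lb, self.z_ub)

    def unscale(self, z):
        """Physical trajectories from a scaled decision vector."""
        ocp, N, d = self.ocp, self.N, self.d
        sx, su, sp = ocp.scaling.x_scale, ocp.scaling.u_scale, ocp.scaling.p_scale
        p = z[self.off_p:] * sp if ocp.n_p else np.zeros(0)
        tf = ocp.t_f if ocp.t_f is not None else p[ocp.tf_param]
        X_mesh = np.array([z[self.idx_mesh(k):self.idx_mesh(k) + ocp.n_x] * sx
                           for k in range(N + 1)])
        X_coll = np.array([[z[self.idx_coll(k, j):self.idx_coll(k, j) + ocp.n_x] * sx
                            for j in range(d)] for k in range(N)])
        U = np.array([z[self.idx_u(k):self.idx_u(k) + ocp.n_u] * su
                      for k in range(N)])
        t_mesh = np.linspace(0.0, tf, N + 1)
        t_coll = np.array([[(k + self.scheme.points[j]) * tf / N
                            for j in range(d)] for k in range(N)])
        return {"t_mesh": t_mesh, "X_mesh": X_mesh, "t_coll": t_coll,
                "X_coll": X_coll, "U": U, "p": p, "t_f": tf}

    def interp_states(self, z, ts):
        """Evaluate the collocation interpolant (physical units) at times ts."""
        traj = self.unscale(z)
        tf, N, d = traj["t_f"], self.N, self.d
        basis = np.concatenate([[0.0], self.scheme.points])
        out = np.empty((len(ts), self.ocp.n_x))
        h = tf / N
        for it, t in enumerate(ts):
            k = min(int(np.floor(t / h)), N - 1)
            tau = (t - k * h) / h
            vals = np.vstack([traj["X_mesh"][k][None, :], traj["X_coll"][k]])
            # Lagrange interpolation on the d+1 basis points
            acc = np.zeros(self.ocp.n_x)
            for i in range(d + 1):
                Li = 1.0
                for jj in range(d + 1):
                    if jj != i:
                        Li *= (tau - basis[jj]) / (basis[i] - basis[jj])
                acc += Li * vals[i]
            out[it] = acc
        return out


def transcribe(ocp: OptimalControlProblem, N: int,
               scheme: RadauScheme | None = None,
               scaling: ScalingSet | None = None,
               mode: str = "ad") -> TranscribedNLP:
    """Transcribe ``ocp`` on an ``N``-interval mesh with the given Radau
    scheme (default degree 3) and scaling (default: the problem's own)."""
    if scheme is None:
        scheme = make_radau(3)
    if scaling is not None:
        ocp.scaling = scaling
    return TranscribedNLP(ocp, N, scheme, mode=mode)


# ---------------------------------------------------------------------------
# solver adapter
# ---------------------------------------------------------------------------

@dataclass
class SolveOptions:
    """Options forwarded to the interior-point solve."""

    deriv_mode: str = "ad"          # 'ad' or 'fd'
    hessian: str = "exact"          # 'exact' or 'lbfgs'
    tol: float = 1e-6
    max_iter: int = 3000
    initial_guess: np.ndarray | None = None   # scaled decision vector
    linear_solver: str = "default"  # pass-through; not interpreted here
    verbose: int = 0
    # optional early stop: halt as soon as the iterate satisfies both
    # targets (constraint violation and first-order optimality).  Useful
    # for problems where feasibility at tolerance is the goal and the
    # optimality tail is slow; None disables.
    stop_viol: float | None = None
    stop_opt: float | None = None


@dataclass
class SolveRecord:
    """Solution trajectories plus convergence statistics."""

    status: str                     # solved | max_iter | stalled | infeasible | error
    objective: float
    iterations: int
    constr_violation: float
    optimality: float
    z: np.ndarray
    trajectories: dict
    counters: dict
    timings: dict
    wall_time: float
    deriv_mode: str
    hessian_mode: str
    message: str = ""


class _Memo:
    """Cache the last evaluation (trust-constr calls fun/jac separately)."""

    def __init__(self, fn):
        self.fn = fn
        self.key = None
        self.val = None

    def __call__(self, x, *rest):
        key = (x.tobytes(), tuple(np.asarray(r).tobytes() for r in rest))
        if key != self.key:
            self.val = self.fn(x, *rest)
            self.key = key
        return self.val


def solve(nlp: TranscribedNLP, options: SolveOptions | None = None) -> SolveRecord:
    """Solve the transcribed NLP with the interior-point adapter.

    Returns a :class:`SolveRecord`; solver failure is surfaced through the
    record's ``status``, not raised.  Repeated runs with identical options
    and guess produce identical iterates (the solver is deterministic).
    """
    if options is None:
        options = SolveOptions()
    nlp.mode = options.deriv_mode
    z0 = options.initial_guess
    if z0 is None:
        z0 = nlp.initial_guess_zero()
    z0 = np.asarray(z0, float)
    if np.any(z0 < nlp.z_lb - 1e-12) or np.any(z0 > nlp.z_ub + 1e-12):
        warnings.warn("initial guess outside bounds; clamping")
    # clamp strictly inside (bounds are kept feasible by the solver and a
    # start exactly on a bound is rejected); anchored rows stay put
    strict = nlp.z_lb < nlp.z_ub
    margin = np.where(strict, 1e-9 * np.maximum(nlp.z_ub - nlp.z_lb, 1e-3), 0.0)
    z0 = np.clip(z0, nlp.z_lb + margin, nlp.z_ub - margin)

    cons = []
    kw_eq = dict(jac=_Memo(nlp.jacobian_eq))
    kw_iq = dict(jac=_Memo(nlp.jacobian_ineq))
    if options.hessian == "exact" and options.deriv_mode == "ad":
        kw_eq["hess"] = nlp.hessian_eq
        kw_iq["hess"] = nlp.hessian_ineq
        hess_obj = _Memo(nlp.hessian_objective)
    else:
        from scipy.optimize import BFGS
        kw_eq["hess"] = BFGS()
        kw_iq["hess"] = BFGS()
        hess_obj = BFGS()
    cons.append(NonlinearConstraint(_Memo(nlp.constraints_eq), 0.0, 0.0, **kw_eq))
    if nlp.n_ineq:
        cons.append(NonlinearConstraint(_Memo(nlp.constraints_ineq),
                                        nlp.ineq_lb, nlp.ineq_ub, **kw_iq))

    callback = None
    if options.stop_viol is not None:
        sv = options.stop_viol
        so = options.stop_opt if options.stop_opt is not None else np.inf

        def callback(xk, state):
            return (state.constr_violation <= sv and state.optimality <= so)

    t0 = time.perf_counter()
    try:
        # variable bounds are hard (tape domains such as tendon-force
        # positivity and the free-time parameter rely on them); equal
        # bounds (anchored variables) cannot be flagged keep_feasible
        keep = nlp.z_lb < nlp.z_ub
        res = minimize(
            _Memo(nlp.objective), z0, jac=_Memo(nlp.gradient), hess=hess_obj,
            method="trust-constr", constraints=cons, callback=callback,
            bounds=Bounds(nlp.z_lb, nlp.z_ub, keep_feasible=keep),
            options=dict(maxiter=options.max_iter, gtol=options.tol,
                         xtol=1e-14, barrier_tol=options.tol * 1e-2,
                         sparse_jacobian=True, verbose=options.verbose))
    except Exception as exc:  # surfaced, not raised
        return SolveRecord(
            status="error", objective=np.nan, iterations=0,
            constr_violation=np.nan, optimality=np.nan, z=z0,
            trajectories={}, counters=dict(nlp.counters),
            timings=dict(nlp.timings), wall_time=time.perf_counter() - t0,
            deriv_mode=options.deriv_mode, hessian_mode=options.hessian,
            message=f"{type(exc).__name__}: {exc}")
    wall = time.perf_counter() - t0

    viol = float(res.constr_violation)
    opt = float(res.optimality)
    if viol <= options.tol and opt <= options.tol:
        status = "solved"
    elif res.status == 3 and viol <= options.tol:
        status = "feasible_stop"  # early-stop targets reached
    elif res.status == 0:
        status = "max_iter"
    elif viol > options.tol:
        status = "infeasible"
    else:
        status = "stalled"
    return SolveRecord(
        status=status, objective=float(res.fun), iterations=int(res.niter),
        constr_violation=viol, optimality=opt, z=np.asarray(res.x),
        trajectories=nlp.unscale(res.x), counters=dict(nlp.counters),
        timings=dict(nlp.timings), wall_time=wall,
        deriv_mode=options.deriv_mode, hessian_mode=options.hessian,
        message=str(res.message))


def mesh_refine_check(make_nlp: Callable[[int], TranscribedNLP], N: int,
                      factor: int = 2, threshold: float = 1e-3,
                      options: SolveOptions | None = None) -> dict:
    """Solve at mesh sizes ``N`` and ``factor * N`` and report the maximum
    scaled state discrepancy of the interpolants on the fine mesh times."""
    nlp_c = make_nlp(N)
    nlp_f = make_nlp(factor * N)
    rec_c = solve(nlp_c, options)
    rec_f = solve(nlp_f, options)
    ts = rec_f.trajectories["t_mesh"]
    Xc = nlp_c.interp_states(rec_c.z, ts)
    Xf = rec_f.trajectories["X_mesh"]
    sx = nlp_c.ocp.scaling.x_scale
    disc = float(np.max(np.abs((Xc - Xf) / sx)))
    return {"N": N, "factor": factor, "discrepancy": disc,
            "pass": disc <= threshold, "coarse": rec_c, "fine": rec_f,
            "threshold": threshold}
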