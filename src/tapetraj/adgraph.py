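"""Tape-based algorithmic differentiation.

A numeric function built from a closed set of smooth elementary operations is
evaluated once at a nominal point with :class:`ADScalar` inputs, which records
the function's expression graph on a :class:`Tape`.  The tape can then be

* replayed at new inputs (:func:`replay`),
* swept forward with an input seed to obtain a directional derivative
  ``J @ xdot`` (:func:`forward_sweep`),
* swept in reverse with an output seed to obtain ``J.T @ ybar``
  (:func:`reverse_sweep`) -- for a scalar output, one reverse sweep yields the
  full gradient,
* differentiated twice exactly by recording the reverse sweep itself and
  sweeping that tape forward (:func:`hessian_lagrangian`, :func:`vjp_tape`),
* emitted as flat single-assignment source text (:func:`emit_source`).

Sweeps accept plain floats or numpy arrays as inputs, so a tape recorded for a
single evaluation point can be evaluated in batch across many points at once.

The operation set is closed and contains only twice continuously
differentiable operations; non-smooth primitives (``abs``, ``min``, ``max``,
``floor``) raise :class:`UnsupportedOperationError`.  Comparisons are allowed
during recording -- their boolean outcomes are stored in the tape's branch
signature -- but replaying the tape at a point where any comparison outcome
differs raises :class:`StaleTapeError` (the recorded straight-line code is
only valid while the branches taken at the nominal point remain valid).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ADScalar", "Node", "Tape", "ADError", "RecordingError",
    "UnsupportedOperationError", "StaleTapeError", "DimensionError",
    "record", "replay", "forward_sweep", "reverse_sweep", "jacobian",
    "hessian", "hessian_lagrangian", "vjp_tape", "batch_jacobian",
    "emit_source", "compile_source", "fd_jacobian", "CountingFunction",
    "tape_to_json", "tape_from_json",
    "sin", "cos", "tan", "tanh", "atan", "exp", "log", "sqrt",
]


class ADError(Exception):
    """Base class for AD engine errors."""


class RecordingError(ADError):
    """Raised when a function cannot be recorded at the nominal point."""


class UnsupportedOperationError(RecordingError):
    """Raised when a function uses an operation outside the closed op set."""


class StaleTapeError(ADError):
    """Raised when a tape is replayed at a point with a different branch
    signature than the one recorded; the caller must re-record at the new
    point."""


class DimensionError(ADError):
    """Seed or input length does not match the tape."""


# Closed operation vocabulary: tag -> arity.
OPS = {
    "const": 0, "input": 0,
    "add": 2, "sub": 2, "mul": 2, "div": 2, "pow": 2,
    "neg": 1, "sqrt": 1, "exp": 1, "log": 1,
    "sin": 1, "cos": 1, "tan": 1, "tanh": 1, "atan": 1,
    # pow with a constant exponent stored in ``aux`` (single parent)
    "powc": 1,
}


@dataclass
class Node:
    """One elementary operation of the expression graph."""

    id: int
    op: str
    parents: tuple[int, ...]
    aux: float | None = None  # const value, or constant exponent for powc


@dataclass
class Tape:
    """Recorded expression graph with nominal values and branch signature."""

    nodes: list[Node] = field(default_factory=list)
    input_ids: list[int] = field(default_factory=list)
    output_ids: list[int] = field(default_factory=list)
    nominal_in: np.ndarray | None = None
    nominal_out: np.ndarray | None = None
    # (op, lhs_id, rhs_id) with op in {lt, le, gt, ge}; outcomes in signature
    branch_tests: list[tuple[str, int, int]] = field(default_factory=list)
    branch_signature: list[bool] = field(default_factory=list)
    # evaluation counters (cost-mechanism bookkeeping for the benchmarks)
    n_replays: int = 0
    n_forward_sweeps: int = 0
    n_reverse_sweeps: int = 0

    _values: list = field(default_factory=list, repr=False)
    _const_cache: dict = field(default_factory=dict, repr=False)
    _recording: bool = field(default=False, repr=False)

    @property
    def n_inputs(self) -> int:
        return len(self.input_ids)

    @property
    def n_outputs(self) -> int:
        return len(self.output_ids)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- recording ---------------------------------------------------------

    def _add_node(self, op: str, parents: tuple[int, ...], aux=None, value=None):
        nid = len(self.nodes)
        self.nodes.append(Node(nid, op, parents, aux))
        self._values.append(value)
        return nid

    def _const(self, value: float) -> int:
        value = float(value)
        if not math.isfinite(value):
            raise RecordingError("non-finite constant encountered while recording")
        key = value
        nid = self._const_cache.get(key)
        if nid is None:
            nid = self._add_node("const", (), aux=value, value=value)
            self._const_cache[key] = nid
        return nid

    def _record_op(self, op: str, parent_ids: tuple[int, ...], aux=None) -> "ADScalar":
        if op not in OPS:
            raise UnsupportedOperationError(f"operation {op!r} is not in the supported op set")
        pv = [self._values[p] for p in parent_ids]
        value = _op_value(op, pv, aux)
        if not math.isfinite(value):
            raise RecordingError(
                f"operation {op!r} produced a non-finite value at the nominal point")
        nid = self._add_node(op, parent_ids, aux=aux, value=value)
        return ADScalar(self, nid)

    def _record_branch(self, op: str, lhs: int, rhs: int, outcome: bool) -> None:
        self.branch_tests.append((op, lhs, rhs))
        self.branch_signature.append(bool(outcome))


_CMP = {"lt": np.less, "le": np.less_equal, "gt": np.greater, "ge": np.greater_equal}


def _op_value(op, pv, aux):
    """Elementary-operation value; generic over floats / arrays / ADScalar."""
    if op == "const":
        return aux
    if op == "add":
        return pv[0] + pv[1]
    if op == "sub":
        return pv[0] - pv[1]
    if op == "mul":
        return pv[0] * pv[1]
    if op == "div":
        return pv[0] / pv[1]
    if op == "neg":
        return -pv[0]
    if op == "powc":
        return pv[0] ** aux
    if op == "pow":
        return pv[0] ** pv[1]
    if op == "sqrt":
        return sqrt(pv[0])
    if op == "exp":
        return exp(pv[0])
    if op == "log":
        return log(pv[0])
    if op == "sin":
        return sin(pv[0])
    if op == "cos":
        return cos(pv[0])
    if op == "tan":
        return tan(pv[0])
    if op == "tanh":
        return tanh(pv[0])
    if op == "atan":
        return atan(pv[0])
    raise UnsupportedOperationError(f"operation {op!r} is not in the supported op set")


def _op_partials(op, pv, value, aux):
    """Local partial derivatives w.r.t. each parent, generic over value types."""
    if op in ("const", "input"):
        return ()
    if op == "add":
        return (1.0, 1.0)
    if op == "sub":
        return (1.0, -1.0)
    if op == "mul":
        return (pv[1], pv[0])
    if op == "div":
        return (1.0 / pv[1], -pv[0] / (pv[1] * pv[1]))
    if op == "neg":
        return (-1.0,)
    if op == "powc":
        if aux == 2.0:
            return (2.0 * pv[0],)
        if aux == 1.0:
            return (1.0,)
        return (aux * pv[0] ** (aux - 1.0),)
    if op == "pow":
        return (pv[1] * pv[0] ** (pv[1] - 1.0), value * log(pv[0]))
    if op == "sqrt":
        return (0.5 / value,)
    if op == "exp":
        return (value,)
    if op == "log":
        return (1.0 / pv[0],)
    if op == "sin":
        return (cos(pv[0]),)
    if op == "cos":
        return (-sin(pv[0]),)
    if op == "tan":
        return (1.0 + value * value,)
    if op == "tanh":
        return (1.0 - value * value,)
    if op == "atan":
        return (1.0 / (1.0 + pv[0] * pv[0]),)
    raise UnsupportedOperationError(f"operation {op!r} has no derivative rule")


class ADScalar:
    """Operator-overloaded scalar that records onto a :class:`Tape`."""

    __slots__ = ("tape", "id")
    __array_priority__ = 1000  # make numpy defer to our reflected operators

    def __init__(self, tape: Tape, nid: int):
        self.tape = tape
        self.id = nid

    @property
    def value(self):
        return self.tape._values[self.id]

    def _coerce(self, other) -> int:
        if isinstance(other, ADScalar):
            if other.tape is not self.tape:
                raise RecordingError("cannot mix scalars from different tapes")
            return other.id
        return self.tape._const(other)

    # arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return self.tape._record_op("add", (self.id, self._coerce(other)))

    def __radd__(self, other):
        return self.tape._record_op("add", (self._coerce(other), self.id))

    def __sub__(self, other):
        return self.tape._record_op("sub", (self.id, self._coerce(other)))

    def __rsub__(self, other):
        return self.tape._record_op("sub", (self._coerce(other), self.id))

    def __mul__(self, other):
        return self.tape._record_op("mul", (self.id, self._coerce(other)))

    def __rmul__(self, other):
        return self.tape._record_op("mul", (self._coerce(other), self.id))

    def __truediv__(self, other):
        return self.tape._record_op("div", (self.id, self._coerce(other)))

    def __rtruediv__(self, other):
        return self.tape._record_op("div", (self._coerce(other), self.id))

    def __neg__(self):
        return self.tape._record_op("neg", (self.id,))

    def __pos__(self):
        return self

    def __pow__(self, other):
        if isinstance(other, ADScalar):
            return self.tape._record_op("pow", (self.id, self._coerce(other)))
        return self.tape._record_op("powc", (self.id,), aux=float(other))

    def __rpow__(self, other):
        return self.tape._record_op("pow", (self._coerce(other), self.id))

    # elementary functions -------------------------------------------------
    def sqrt(self):
        return self.tape._record_op("sqrt", (self.id,))

    def exp(self):
        return self.tape._record_op("exp", (self.id,))

    def log(self):
        return self.tape._record_op("log", (self.id,))

    def sin(self):
        return self.tape._record_op("sin", (self.id,))

    def cos(self):
        return self.tape._record_op("cos", (self.id,))

    def tan(self):
        return self.tape._record_op("tan", (self.id,))

    def tanh(self):
        return self.tape._record_op("tanh", (self.id,))

    def atan(self):
        return self.tape._record_op("atan", (self.id,))

    # branches -------------------------------------------------------------
    def _compare(self, op, other, reflected=False):
        lhs, rhs = self.id, self._coerce(other)
        if reflected:
            lhs, rhs = rhs, lhs
        outcome = bool(_CMP[op](self.tape._values[lhs], self.tape._values[rhs]))
        self.tape._record_branch(op, lhs, rhs, outcome)
        return outcome

    def __lt__(self, other):
        return self._compare("lt", other)

    def __le__(self, other):
        return self._compare("le", other)

    def __gt__(self, other):
        return self._compare("gt", other)

    def __ge__(self, other):
        return self._compare("ge", other)

    # unsupported, non-smooth ----------------------------------------------
    def __abs__(self):
        raise UnsupportedOperationError("abs is not smooth; use a tanh approximation")

    def __floordiv__(self, other):
        raise UnsupportedOperationError("floordiv is not in the supported op set")

    def __mod__(self, other):
        raise UnsupportedOperationError("mod is not in the supported op set")

    def __floor__(self):
        raise UnsupportedOperationError("floor is not in the supported op set")

    def __repr__(self):
        return f"ADScalar(id={self.id}, value={self.value})"


def _dispatch(name):
    np_fn = {"sin": np.sin, "cos": np.cos, "tan": np.tan, "tanh": np.tanh,
             "atan": np.arctan, "exp": np.exp, "log": np.log, "sqrt": np.sqrt}[name]

    def fn(x):
        if isinstance(x, ADScalar):
            return getattr(x, name)()
        return np_fn(x)

    fn.__name__ = name
    fn.__doc__ = f"{name}(x), dispatching on ADScalar vs numeric/array input."
    return fn


sin = _dispatch("sin")
cos = _dispatch("cos")
tan = _dispatch("tan")
tanh = _dispatch("tanh")
atan = _dispatch("atan")
exp = _dispatch("exp")
log = _dispatch("log")
sqrt = _dispatch("sqrt")


# ---------------------------------------------------------------------------
# recording and sweeps
# ---------------------------------------------------------------------------

def record(fn: Callable, nominal_in: Sequence[float]) -> Tape:
    """Record ``fn``'s expression graph by evaluating it at ``nominal_in``.

    ``fn`` receives a list of :class:`ADScalar` and must return a scalar or a
    sequence of scalars built only from supported operations.  Comparison
    outcomes encountered during the evaluation are stored in the tape's
    branch signature.
    """
    nominal_in = np.atleast_1d(np.asarray(nominal_in, dtype=float))
    if not np.all(np.isfinite(nominal_in)):
        raise RecordingError("nominal input contains NaN/Inf")
    tape = Tape()
    xs = []
    for v in nominal_in:
        nid = tape._add_node("input", (), value=float(v))
        tape.input_ids.append(nid)
        xs.append(ADScalar(tape, nid))
    out = fn(xs)
    if isinstance(out, (ADScalar, float, int)):
        out = [out]
    out_ids = []
    for o in out:
        if isinstance(o, ADScalar):
            if o.tape is not tape:
                raise RecordingError("output recorded on a different tape")
            out_ids.append(o.id)
        else:
            out_ids.append(tape._const(float(o)))
    tape.output_ids = out_ids
    tape.nominal_in = nominal_in
    tape.nominal_out = np.array([tape._values[i] for i in out_ids], dtype=float)
    if not np.all(np.isfinite(tape.nominal_out)):
        raise RecordingError("function output is NaN/Inf at the nominal point")
    return tape


def _values_at(tape: Tape, x, check_branches: bool = True):
    """Evaluate all node values at input ``x`` (floats, arrays, or ADScalar)."""
    if len(x) != tape.n_inputs:
        raise DimensionError(f"expected {tape.n_inputs} inputs, got {len(x)}")
    vals = [None] * len(tape.nodes)
    for i, nid in enumerate(tape.input_ids):
        vals[nid] = x[i]
    for node in tape.nodes:
        if node.op == "input":
            continue
        if node.op == "const":
            vals[node.id] = node.aux
        else:
            vals[node.id] = _op_value(node.op, [vals[p] for p in node.parents], node.aux)
    if check_branches and tape.branch_tests:
        for (op, lhs, rhs), recorded in zip(tape.branch_tests, tape.branch_signature):
            outcome = _CMP[op](vals[lhs], vals[rhs])
            if not np.all(outcome == recorded):
                raise StaleTapeError(
                    "branch signature mismatch: a comparison recorded as "
                    f"{recorded} evaluates differently at the new point; "
                    "re-record the tape at this point")
    return vals


def replay(tape: Tape, x) -> np.ndarray:
    """Re-evaluate the recorded function at ``x`` (checks branch signature)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ADError("replay input contains NaN/Inf")
    vals = _values_at(tape, x)
    tape.n_replays += 1
    return np.array([vals[i] for i in tape.output_ids], dtype=float)


def _partials_at(tape: Tape, vals):
    return [
        _op_partials(n.op, [vals[p] for p in n.parents], vals[n.id], n.aux)
        if n.parents else ()
        for n in tape.nodes
    ]


def _nominal_state(tape: Tape):
    vals = tape._values
    parts = getattr(tape, "_nominal_partials", None)
    if parts is None:
        parts = _partials_at(tape, vals)
        tape._nominal_partials = parts
    return vals, parts


def forward_sweep(tape: Tape, xdot, x=None):
    """Propagate a forward seed input->output; returns ``J @ xdot``.

    With ``x=None`` the sweep runs at the tape's nominal point.  Entries of
    ``x``/``xdot`` may be numpy arrays for batched evaluation.
    """
    if len(xdot) != tape.n_inputs:
        raise DimensionError(f"forward seed length {len(xdot)} != n inputs {tape.n_inputs}")
    if x is None:
        vals, parts = _nominal_state(tape)
    else:
        vals = _values_at(tape, x, check_branches=False)
        parts = _partials_at(tape, vals)
    dots = [None] * len(tape.nodes)
    for i, nid in enumerate(tape.input_ids):
        dots[nid] = xdot[i]
    for node in tape.nodes:
        if not node.parents:
            continue  # inputs seeded above; constants carry no tangent
        acc = None
        for p, dp in zip(node.parents, parts[node.id]):
            d = dots[p]
            if d is None:
                continue
            term = dp * d
            acc = term if acc is None else acc + term
        dots[node.id] = 0.0 if acc is None else acc
    tape.n_forward_sweeps += 1
    out = [dots[i] if dots[i] is not None else 0.0 for i in tape.output_ids]
    if x is None or all(np.isscalar(v) or np.ndim(v) == 0 for v in out):
        try:
            return np.array(out, dtype=float)
        except (TypeError, ValueError):
            pass
    return out


def reverse_sweep(tape: Tape, ybar, x=None):
    """Propagate a reverse seed output->input; returns ``J.T @ ybar``.

    For a scalar-output tape, ``ybar=[1]`` yields the full gradient in a
    single sweep.
    """
    if len(ybar) != tape.n_outputs:
        raise DimensionError(f"reverse seed length {len(ybar)} != n outputs {tape.n_outputs}")
    if x is None:
        vals, parts = _nominal_state(tape)
    else:
        vals = _values_at(tape, x, check_branches=False)
        parts = _partials_at(tape, vals)
    bars = _reverse_generic(tape, parts, ybar)
    tape.n_reverse_sweeps += 1
    out = [bars[i] if bars[i] is not None else 0.0 for i in tape.input_ids]
    if x is None or all(np.isscalar(v) or np.ndim(v) == 0 for v in out):
        try:
            return np.array(out, dtype=float)
        except (TypeError, ValueError):
            pass
    return out


def _reverse_generic(tape: Tape, parts, ybar):
    """Core reverse accumulation; generic over value types (float/array/ADScalar)."""
    bars = [None] * len(tape.nodes)
    for oid, s in zip(tape.output_ids, ybar):
        bars[oid] = s if bars[oid] is None else bars[oid] + s
    for node in reversed(tape.nodes):
        b = bars[node.id]
        if b is None or not node.parents:
            continue
        for p, dp in zip(node.parents, parts[node.id]):
            term = b * dp
            bars[p] = term if bars[p] is None else bars[p] + term
    return bars


def jacobian(tape: Tape, x=None) -> np.ndarray:
    """Dense Jacobian, assembled by ``n`` forward sweeps if ``n <= m`` else
    ``m`` reverse sweeps (mode chosen purely by dimensions)."""
    n, m = tape.n_inputs, tape.n_outputs
    J = np.empty((m, n))
    if n <= m:
        for i in range(n):
            seed = np.zeros(n)
            seed[i] = 1.0
            J[:, i] = forward_sweep(tape, seed, x=x)
    else:
        for o in range(m):
            seed = np.zeros(m)
            seed[o] = 1.0
            J[o, :] = reverse_sweep(tape, seed, x=x)
    return J


def _batch_size(X):
    B = 1
    for v in X:
        if np.ndim(v) > 0:
            B = max(B, np.shape(v)[0])
    return B


def multi_forward(tape: Tape, X: list, inputs: Sequence[int], chunk: int = 64) -> np.ndarray:
    """Forward sweeps with identity seeds over ``inputs``, vectorized over
    both the seed index and the evaluation batch.

    ``X`` entries are scalars or arrays of shape ``(B,)``.  A block of
    ``chunk`` unit seeds is propagated per pass with node tangents of shape
    ``(chunk, B)``.  Returns ``J`` of shape ``(m, len(inputs), B)``.
    """
    inputs = list(inputs)
    B = _batch_size(X)
    vals = _values_at(tape, X, check_branches=False)
    parts = _partials_at(tape, vals)
    m = tape.n_outputs
    J = np.zeros((m, len(inputs), B))
    for c0 in range(0, len(inputs), chunk):
        sel = inputs[c0:c0 + chunk]
        c = len(sel)
        dots = [None] * len(tape.nodes)
        for r, i in enumerate(sel):
            seed = np.zeros((c, 1))
            seed[r, 0] = 1.0
            dots[tape.input_ids[i]] = seed
        for node in tape.nodes:
            if not node.parents:
                continue
            acc = None
            for p, dp in zip(node.parents, parts[node.id]):
                d = dots[p]
                if d is None:
                    continue
                term = dp * d
                acc = term if acc is None else acc + term
            dots[node.id] = acc
        tape.n_forward_sweeps += 1
        for o, oid in enumerate(tape.output_ids):
            d = dots[oid]
            if d is not None:
                J[o, c0:c0 + c, :] = d
    return J


def multi_reverse(tape: Tape, X: list, inputs: Sequence[int], chunk: int = 64) -> np.ndarray:
    """Reverse sweeps with identity output seeds, vectorized over the seed
    index and the evaluation batch; returns ``(m, len(inputs), B)``."""
    inputs = list(inputs)
    B = _batch_size(X)
    vals = _values_at(tape, X, check_branches=False)
    parts = _partials_at(tape, vals)
    m = tape.n_outputs
    J = np.zeros((m, len(inputs), B))
    for c0 in range(0, m, chunk):
        sel = list(range(c0, min(c0 + chunk, m)))
        c = len(sel)
        bars = [None] * len(tape.nodes)
        for r, o in enumerate(sel):
            seed = np.zeros((c, 1))
            seed[r, 0] = 1.0
            oid = tape.output_ids[o]
            bars[oid] = seed if bars[oid] is None else bars[oid] + seed
        for node in reversed(tape.nodes):
            b = bars[node.id]
            if b is None or not node.parents:
                continue
            for p, dp in zip(node.parents, parts[node.id]):
                term = b * dp
                bars[p] = term if bars[p] is None else bars[p] + term
        tape.n_reverse_sweeps += 1
        for ci, i in enumerate(inputs):
            b = bars[tape.input_ids[i]]
            if b is not None:
                J[c0:c0 + c, ci, :] = b
    return J


def batch_jacobian(tape: Tape, X: list, inputs: Sequence[int] | None = None) -> np.ndarray:
    """Jacobian of the tape at a batch of points.

    ``X`` is a list of length ``n_inputs`` whose entries are arrays of common
    shape ``(B,)`` (or scalars, broadcast).  Returns an array of shape
    ``(m, len(inputs), B)``.  Sweeps in whichever mode needs fewer passes,
    with seeds propagated in vectorized blocks.
    """
    n, m = tape.n_inputs, tape.n_outputs
    if inputs is None:
        inputs = range(n)
    inputs = list(inputs)
    if len(inputs) <= m:
        return multi_forward(tape, X, inputs)
    return multi_reverse(tape, X, inputs)


# ---------------------------------------------------------------------------
# second derivatives: forward-over-reverse
# ---------------------------------------------------------------------------

def vjp_tape(tape: Tape, nominal_w=None) -> Tape:
    """Record the reverse sweep of ``tape`` as a new tape.

    The new tape maps ``[x (n), w (m)] -> J(x).T @ w``; differentiating it
    (forward sweeps over the ``x`` block) yields exact weighted Hessians --
    the forward-over-reverse scheme.
    """
    n, m = tape.n_inputs, tape.n_outputs
    if nominal_w is None:
        nominal_w = np.ones(m)

    def gfn(zs):
        xs, ws = zs[:n], zs[n:]
        vals = _values_at(tape, xs, check_branches=False)
        parts = _partials_at(tape, vals)
        bars = _reverse_generic(tape, parts, ws)
        return [bars[i] if bars[i] is not None else 0.0 for i in tape.input_ids]

    nominal = np.concatenate([tape.nominal_in, np.asarray(nominal_w, dtype=float)])
    return record(gfn, nominal)


def hessian(tape: Tape, x=None, weights=None) -> np.ndarray:
    """Exact Hessian of ``weights @ outputs`` via forward-over-reverse."""
    n, m = tape.n_inputs, tape.n_outputs
    if weights is None:
        if m != 1:
            raise DimensionError("weights required for multi-output tape")
        weights = np.ones(1)
    gt = vjp_tape(tape, nominal_w=weights)
    if x is None:
        x = tape.nominal_in
    z = list(np.concatenate([np.asarray(x, dtype=float), np.asarray(weights, dtype=float)]))
    H = np.empty((n, n))
    for i in range(n):
        seed = np.zeros(n + m)
        seed[i] = 1.0
        H[:, i] = forward_sweep(gt, seed, x=z)
    return H


def hessian_lagrangian(tapes: Sequence[Tape], multipliers, obj_weight: float = 1.0,
                       x=None, sym_tol: float = 1e-10) -> np.ndarray:
    """Exact Hessian of ``obj_weight * f + multipliers @ g``.

    ``tapes[0]`` is the (scalar-output) objective tape; the remaining tapes
    are constraint tapes whose outputs consume ``multipliers`` in order.  All
    tapes must share the same input vector.  The result is symmetrized after
    checking that the raw asymmetry is below ``sym_tol`` relative.
    """
    multipliers = np.atleast_1d(np.asarray(multipliers, dtype=float))
    n = tapes[0].n_inputs
    for t in tapes:
        if t.n_inputs != n:
            raise DimensionError("all tapes must share the same input vector")
    H = obj_weight * hessian(tapes[0], x=x)
    k = 0
    for t in tapes[1:]:
        w = multipliers[k:k + t.n_outputs]
        k += t.n_outputs
        if np.any(w != 0.0):
            H += hessian(t, x=x, weights=w)
    scale = max(1.0, float(np.max(np.abs(H))))
    asym = float(np.max(np.abs(H - H.T)))
    if asym > sym_tol * scale:
        raise ADError(f"Hessian asymmetry {asym:.3e} exceeds tolerance")
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# source emission
# ---------------------------------------------------------------------------

_EMIT = {
    "add": "{0} + {1}", "sub": "{0} - {1}", "mul": "{0} * {1}",
    "div": "{0} / {1}", "neg": "-{0}", "pow": "{0} ** {1}",
    "sqrt": "np.sqrt({0})", "exp": "np.exp({0})", "log": "np.log({0})",
    "sin": "np.sin({0})", "cos": "np.cos({0})", "tan": "np.tan({0})",
    "tanh": "np.tanh({0})", "atan": "np.arctan({0})",
}


def emit_source(tape: Tape, name: str) -> str:
    """Emit flat single-assignment Python source implementing replay,
    forward and reverse sweeps of the tape.

    The emitted functions agree numerically with the interpreted sweeps; the
    textual form is not part of the contract.  Compile with
    :func:`compile_source`.
    """
    lines = ["import numpy as np", ""]

    def assigns():
        body = []
        for node in tape.nodes:
            v = f"v{node.id}"
            if node.op == "input":
                body.append(f"    {v} = x[{tape.input_ids.index(node.id)}]")
            elif node.op == "const":
                body.append(f"    {v} = {node.aux!r}")
            elif node.op == "powc":
                body.append(f"    {v} = v{node.parents[0]} ** {node.aux!r}")
            else:
                expr = _EMIT[node.op].format(*[f"v{p}" for p in node.parents])
                body.append(f"    {v} = {expr}")
        return body

    out_expr = "[" + ", ".join(f"v{i}" for i in tape.output_ids) + "]"

    lines.append(f"def {name}_replay(x):")
    lines += assigns()
    lines.append(f"    return np.array({out_expr})")
    lines.append("")

    # forward sweep: values then tangents
    lines.append(f"def {name}_forward(x, xdot):")
    lines += assigns()
    for node in tape.nodes:
        d = f"d{node.id}"
        if node.op == "input":
            lines.append(f"    {d} = xdot[{tape.input_ids.index(node.id)}]")
        elif node.op == "const":
            lines.append(f"    {d} = 0.0")
        else:
            terms = []
            for k, p in enumerate(node.parents):
                terms.append(f"({_emit_partial(tape, node, k)}) * d{p}")
            lines.append(f"    {d} = " + " + ".join(terms))
    dout = "[" + ", ".join(f"d{i}" for i in tape.output_ids) + "]"
    lines.append(f"    return np.array({dout})")
    lines.append("")

    # reverse sweep: values then adjoints
    lines.append(f"def {name}_reverse(x, ybar):")
    lines += assigns()
    for node in tape.nodes:
        lines.append(f"    b{node.id} = 0.0")
    for k, oid in enumerate(tape.output_ids):
        lines.append(f"    b{oid} = b{oid} + ybar[{k}]")
    for node in reversed(tape.nodes):
        for k, p in enumerate(node.parents):
            lines.append(f"    b{p} = b{p} + b{node.id} * ({_emit_partial(tape, node, k)})")
    bout = "[" + ", ".join(f"b{i}" for i in tape.input_ids) + "]"
    lines.append(f"    return np.array({bout})")
    lines.append("")
    return "\n".join(lines)


def _emit_partial(tape: Tape, node: Node, k: int) -> str:
    p = [f"v{q}" for q in node.parents]
    v = f"v{node.id}"
    op = node.op
    if op == "add":
        return "1.0"
    if op == "sub":
        return "1.0" if k == 0 else "-1.0"
    if op == "mul":
        return p[1] if k == 0 else p[0]
    if op == "div":
        return f"1.0 / {p[1]}" if k == 0 else f"-{p[0]} / ({p[1]} * {p[1]})"
    if op == "neg":
        return "-1.0"
    if op == "powc":
        return f"{node.aux!r} * {p[0]} ** ({node.aux!r} - 1.0)"
    if op == "pow":
        return (f"{p[1]} * {p[0]} ** ({p[1]} - 1.0)" if k == 0
                else f"{v} * np.log({p[0]})")
    if op == "sqrt":
        return f"0.5 / {v}"
    if op == "exp":
        return v
    if op == "log":
        return f"1.0 / {p[0]}"
    if op == "sin":
        return f"np.cos({p[0]})"
    if op == "cos":
        return f"-np.sin({p[0]})"
    if op == "tan":
        return f"1.0 + {v} * {v}"
    if op == "tanh":
        return f"1.0 - {v} * {v}"
    if op == "atan":
        return f"1.0 / (1.0 + {p[0]} * {p[0]})"
    raise UnsupportedOperationError(op)


def compile_source(source: str) -> dict:
    """Exec emitted source and return its namespace of functions."""
    ns: dict = {}
    exec(compile(source, "<tapetraj-emitted>", "exec"), ns)
    return ns


# ---------------------------------------------------------------------------
# finite-difference comparator
# ---------------------------------------------------------------------------

class CountingFunction:
    """Wrap a vector function, counting evaluations (for cost comparisons)."""

    def __init__(self, fn: Callable):
        self.fn = fn
        self.count = 0

    def __call__(self, x):
        self.count += 1
        return np.atleast_1d(np.asarray(self.fn(x), dtype=float))


def fd_jacobian(fn: Callable, x, h: float = 1e-6, scheme: str = "forward") -> np.ndarray:
    """Finite-difference Jacobian of ``fn`` at ``x``.

    ``scheme='forward'`` uses ``n+1`` evaluations (the NLP-solver default FD
    comparator, truncation error O(h)); ``scheme='central'`` uses ``2n``
    evaluations with O(h^2) error and serves as the oracle in tests.  Pass a
    :class:`CountingFunction` to expose the evaluation counter.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    x = np.asarray(x, dtype=float)
    n = x.size
    if scheme == "forward":
        f0 = np.atleast_1d(np.asarray(fn(x), dtype=float))
        if not np.all(np.isfinite(f0)):
            raise ADError("non-finite function value in fd_jacobian")
        J = np.empty((f0.size, n))
        for i in range(n):
            xp = x.copy()
            xp[i] += h
            fi = np.atleast_1d(np.asarray(fn(xp), dtype=float))
            if not np.all(np.isfinite(fi)):
                raise ADError("non-finite function value in fd_jacobian")
            J[:, i] = (fi - f0) / h
        return J
    if scheme == "central":
        cols = []
        for i in range(n):
            xp = x.copy()
            xm = x.copy()
            xp[i] += h
            xm[i] -= h
            fp = np.atleast_1d(np.asarray(fn(xp), dtype=float))
            fm = np.atleast_1d(np.asarray(fn(xm), dtype=float))
            if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
                raise ADError("non-finite function value in fd_jacobian")
            cols.append((fp - fm) / (2 * h))
        return np.column_stack(cols)
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def tape_to_json(tape: Tape) -> str:
    """Serialize a tape to the documented JSON schema.

    Schema: ``{"nodes": [{"id", "op", "parents", "aux"}...], "input_ids",
    "output_ids", "nominal_in", "nominal_out", "branch_tests",
    "branch_signature"}``.
    """
    return json.dumps({
        "nodes": [{"id": n.id, "op": n.op, "parents": list(n.parents), "aux": n.aux}
                  for n in tape.nodes],
        "input_ids": tape.input_ids,
        "output_ids": tape.output_ids,
        "nominal_in": list(map(float, tape.nominal_in)),
        "nominal_out": list(map(float, tape.nominal_out)),
        "branch_tests": [list(t) for t in tape.branch_tests],
        "branch_signature": tape.branch_signature,
    })


def tape_from_json(text: str) -> Tape:
    d = json.loads(text)
    tape = Tape()
    for nd in d["nodes"]:
        tape.nodes.append(Node(nd["id"], nd["op"], tuple(nd["parents"]), nd["aux"]))
        tape._values.append(None)
    tape.input_ids = list(d["input_ids"])
    tape.output_ids = list(d["output_ids"])
    tape.nominal_in = np.asarray(d["nominal_in"], dtype=float)
    tape.branch_tests = [tuple(t) for t in d["branch_tests"]]
    tape.branch_signature = list(d["branch_signature"])
    # rebuild nominal node values by one replay
    vals = _values_at(tape, tape.nominal_in, check_branches=False)
    tape._values = vals
    tape.nominal_out = np.array([vals[i] for i in tape.output_ids], dtype=float)
    if not np.allclose(tape.nominal_out, np.asarray(d["nominal_out"]), rtol=0, atol=0):
        raise ADError("deserialized tape does not reproduce stored nominal outputs")
    return tape
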