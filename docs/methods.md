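# Methods

This note documents the models, numerical choices and limitations behind
`tapetraj`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script.

## Tape-based algorithmic differentiation

A function built from the closed operation set {const, input, +, −, ×, ÷,
neg, pow, sqrt, exp, log, sin, cos, tan, tanh, atan} is evaluated once at a
nominal point with an operator-overloaded scalar; every elementary
operation appends a node (operation tag, parent ids) to a tape. The tape is
a topologically ordered expression graph with the nominal input/output
values attached.

*Sweeps.* A forward sweep propagates an input-side seed ẋ through the
local partial derivatives to give the directional derivative J·ẋ; a
reverse sweep propagates an output-side seed ȳ backwards to give Jᵀ·ȳ.
Both cost a small multiple of one function evaluation, which is the whole
point: a scalar objective's gradient costs one reverse sweep regardless of
the number of inputs, while one-sided finite differences cost n+1
evaluations. Full Jacobians are assembled by n forward sweeps when n ≤ m
and m reverse sweeps otherwise; seeds are propagated in vectorized blocks,
and tape values may be numpy arrays, so one tape evaluates whole batches of
collocation points at once.

*Second derivatives* use forward-over-reverse: the reverse sweep itself is
recorded as a new tape mapping (x, w) ↦ J(x)ᵀw, and forward sweeps of that
tape give exact weighted Hessians. The raw result is checked for symmetry
(tolerance 10⁻¹⁰ relative) and symmetrized.

*Branches.* Comparisons during recording are allowed; their boolean
outcomes form the tape's branch signature. Replaying at a point where any
comparison would resolve differently raises a hard stale-tape error rather
than silently re-taping — recorded straight-line code is only valid while
the nominal point's branches remain valid. All dynamics shipped in this
package are branch-free; non-smooth primitives (abs, min, max, floor) are
rejected at recording time because exact Hessians require C² models, and
smoothness is instead built into the models with tanh approximations.

*Source emission* produces flat single-assignment Python for replay,
forward and reverse sweeps. Numerical equality with the interpreted sweeps
is the contract (checked on random tapes at 100 points); textual form is
not.

*Finite differences* are provided as the comparison baseline: forward
differences with step h = 10⁻⁶ on scaled variables (the common NLP-solver
default), central differences as the oracle in tests. Evaluation counts
are exposed through a counting wrapper; the cost comparison AD-vs-FD is
asserted on counters, never on wall time.

## Rigid-body models

*Pendulum chain.* N ∈ [2, 10] rigid links on a horizontally translating
base, relative joint angles, upright = 0. Inverse dynamics
T = f_s(q, v, u_dv) by planar recursive Newton–Euler with the prescribed
base acceleration entering as the base-point linear acceleration. Default
anthropometry: 1.7 m / 70 kg split equally among uniform rods (I =
mL²/12). The balance perturbation is a backward half-sine base-acceleration
pulse, by default 2 m/s² peak for 0.2 s, gated with tanh switches
(sharpness 200 s⁻¹) so the profile is smooth and recordable; amplitude and
duration are configuration, not reproduction targets. The defaults keep
all recovery torques far inside the ±1000 N·m bounds. The implementation
is verified against an independent sympy Euler–Lagrange derivation to
10⁻¹⁰ relative and against an energy-balance identity.

*Gait skeleton.* Planar 10-coordinate model: pelvis (tx, ty, tilt), trunk
extension, hip/knee/ankle flexion per leg; 8 segments with representative
adult anthropometry (~72.5 kg, pelvis at ~1.0 m), all values fixture data
in `data/gait2d.yaml` — no result depends on the specific numbers.
Generalized torques come from projected Newton–Euler: body accelerations
by forward recursion, then T_i = Σ_b [m_b(a_b − g)·∂p_b/∂q_i +
I_b α_b ∂θ_b/∂q_i] − Σ F_ext·∂P/∂q_i with the geometric position
Jacobians of prismatic and revolute coordinates. Pelvis rows are residual
forces the optimizer drives to zero. Sign conventions: x forward, y up,
right-handed angles; positive hip = flexion, knee flexion negative,
positive ankle = dorsiflexion.

*Contact.* Sphere–plane Hunt–Crossley per sphere (two per foot):
F_n = k·p(δ)^{3/2}·(1 + 1.5 c δ̇)·gate(δ), with penetration δ = r − y,
p(δ) = (δ + √(δ² + ε²))/2 a C-infinity positive part (ε = 10⁻⁴ m) and
gate(δ) = (1 + tanh(b_p δ))/2. Tangential force is smoothed Coulomb plus
viscous friction: −(μ_d tanh(b_v v_slip) + μ_v v_slip)·F_n. Defaults
k = 2×10⁶ N/m^1.5, c = 2 s/m, μ_d = 0.8, μ_v = 0.5, b_v = 50 s/m. The
penetration gate sharpness is b_p = 600 m⁻¹: sharp enough that a static
5 mm penetration reproduces the closed-form k·δ^1.5 within 1% while
airborne leakage one radius above the plane is far below 10⁻⁶ N; a softer
gate (e.g. 300 m⁻¹) would bleed ~5% of the Hertz force at 5 mm, which is
why the steeper default was chosen. All components are C²; the curvature
continuity across touchdown is verified by grid-refinement of second
finite differences.

## Muscle model

*Activation dynamics* (Raasch form) are rate bounds rather than an ODE
right-hand side: with the scaled control u_da (s_da = 100), feasibility
requires 0 ≤ s_da·u_da + a/τ_d and s_da·u_da + a/τ_a ≤ 1/τ_a, with
τ_a = 15 ms, τ_d = 60 ms. For every a ∈ [0, 1] the feasible u_da interval
is non-empty. The control bounds are ±1/(s_da τ_d) below and
1/(s_da τ_a) above, i.e. exactly the rates achievable at the activation
extremes. In the transcription the two residuals are multiplied by τ_a so
the inequality rows are O(1).

*Contraction dynamics* are implicit: the normalized tendon force F_t
(bounded [0, 5]) is a state and its scaled rate u_dFt (s_dFt = 100) a
control. The tendon force–length curve is inverted to recover tendon
length from F_t, the constant-thickness pennation model (l_M sin α
constant) recovers fiber length, and differentiating the tendon curve
gives fiber velocity from u_dFt. The residual

    f_c = (a·f_act(l̃_M)·f_v(ṽ_M) + f_pas(l̃_M))·cos α − F_t

is zero exactly at muscle–tendon equilibrium and C² in all arguments. The
curve set is the standard C² family used with implicit formulations:
exponential tendon (c₁ e^{k_T(l̃_T−c₂)} − c₃ with c₁ = 0.200, c₂ = 0.995,
c₃ = 0.250, k_T = 35), sum-of-three-Gaussians active force–length,
arcsinh-type force–velocity (d₁ ln(z + √(z²+1)) + d₄), and exponential
passive curve (k_pe = 4, e₀ = 0.6). All constants are overridable through
`HillCurves`; no tendon damping term is included. The trunk is driven by
an ideal first-order torque actuator, da/dt = (e − a)/τ with τ = 35 ms and
torque scale 150 N·m.

*Muscle geometry.* The 9-muscle-per-leg roster (hip flexor/extensor,
biarticular hamstrings and rectus femoris, vasti, short biceps femoris,
gastrocnemius, soleus, tibialis anterior) is a synthetic via-point fixture:
straight-line segments between anthropometric attachment points fixed in
the pelvis/thigh/shank/foot frames. Exact lengths are C-infinity in the
joint angles and recordable, so exact moment arms come from a reverse
sweep of the length tape (−∂l_MT/∂q, no truncation error). Tendon slack
lengths are derived at build time so the neutral pose places each fiber at
its optimal length. Per-muscle multivariate polynomials in the spanned
joint angles are then fitted by least squares jointly to lengths and
moment arms on a dense grid over the gait joint ranges (201 points for
one-joint muscles, 25² for two-joint ones), selecting the lowest total
order at which both RMS deviations are ≤ 3 mm, capped at order nine. With
this fixture the fits need orders 2–3 and reach a worst-case length RMS
of 0.37 mm; the fitted moment arms stay within 5 mm of the exact via-point
values over the whole grid. Within the optimal control problems the moment
arm is by construction exactly the negative gradient of the polynomial
length, so muscle joint torques and muscle-tendon velocities are
AD-consistent.

## Collocation transcription

Radau IIA abscissae of degree d are the roots of P_d − P_{d−1} mapped to
(0, 1]; the right endpoint is a collocation point and the scheme has order
2d − 1, with quadrature exact through degree 2d − 2 (d = 3 integrates
quartics exactly; asserted). The default is d = 3 ("third order" scheme).

Per mesh interval k of length h = t_f/N the state interpolant is the
degree-d polynomial through the left mesh state and the d collocation
states. Equality rows are:

* collocation equations D·x̃ = h·f̃ at all d points (scaled rates:
  each dynamic row divided by its state's scale factor),
* continuity x̃_{k+1} = x̃_{k,d} (the right endpoint is a collocation
  point, so this is a variable identification),
* path equalities (pendulum torque equations, gait Hill residuals and
  skeleton torque rows) once per mesh interval, evaluated at the left
  mesh point with that interval's controls,
* boundary/periodicity rows on the first/last mesh states and parameters.

Inequality path constraints (the Raasch bounds) are likewise imposed once
per interval. Controls are piecewise constant (one value per interval).
This layout reproduces, for every pendulum configuration at mesh sizes
N = 25 (2–6 dof), 50 (7–9) and 100 (10 dof), the printed NLP dimensions —
e.g. 504 variables / 458 equality constraints at 2 dof and 10020 / 9040 at
10 dof — and for the walking problem at N = 50 it gives 12857 equality and
1800 inequality rows. One consequence of per-interval path equality rows
is sampling: a time-dependent forcing (the balance pulse) is only seen at
mesh points by the torque rows, so meshes must resolve it (the defaults
do; N = 5 would alias a 0.2 s pulse).

*Scaling.* Pendulum: s_q = 3, s_t = 0.2, s_T = 500, so states/controls are
scaled by s_q, s_q/s_t, s_q/s_t², s_T as printed in the problem
formulation. Gait: bound-derived scales max(|lb|, |ub|) mapping everything
into [−1, 1]. Scale-then-unscale round-trips at machine precision.

*Callbacks.* One tape each is recorded per problem for the scaled rates,
the integrand, the path equalities, the path inequalities and the boundary
rows, at a nominal point supplied by the problem builder. Values and
derivatives are evaluated in batch: the rate/integrand tapes across all
N·d collocation points at once, the path tapes across the N mesh points.
The constraint Jacobian is the constant sparse linear part (differentiation
matrix, continuity) plus scattered batched tape Jacobians; the gradient is
one reverse sweep of the integrand tape with the quadrature weights as the
seed. Exact Hessians assemble per-point forward-over-reverse blocks from
the recorded reverse-sweep tapes. In `fd` mode the same value paths are
differenced forward with h = 10⁻⁶ (n+1 evaluations per gradient or
Jacobian), giving the comparison scenario.

*Free final time.* The gait half-cycle duration t_f ∈ [0.1, 1] s is a
bounded parameter; h = t_f/N multiplies the rates inside the tape, so all
t_f sensitivities flow through AD. Time enters model functions as
t = t_norm·t_f with t_norm a per-point constant.

*Solver adapter.* The transcribed NLP is handed to scipy's `trust-constr`
interior-point method: sparse Jacobians, exact sparse Hessians or a
quasi-Newton (BFGS) approximation ("lbfgs" mode), gtol = barrier-scaled
tolerance 10⁻⁶ by default, xtol tightened to 10⁻¹⁴ so termination is by
optimality rather than step size. Variable bounds are enforced as hard
(kept-feasible) constraints — tape domains such as tendon-force positivity
and the positivity of the free-time parameter rely on them — except
equal-bound (anchored) variables, which the solver cannot keep strictly
feasible and which are pinned instead. The `linear_solver` option is a
pass-through string; the adapter does not interpret it. A solve is
reported "solved" only when both the scaled constraint violation and the
first-order optimality are at or below the tolerance; failures are
surfaced through the record's status, never raised. Identical options and
guesses reproduce identical iterates (the method is deterministic).

## Study problems and sizes

*Pendulum balance* (2–10 dof): bounds q ∈ [−3π, 3π], v ∈ [−20, 20],
u_dv ∈ [−500, 500], u_T ∈ [−1000, 1000]; objective ‖ũ_T‖² + 0.1‖ũ_dv‖²
(the acceleration penalty avoids singular arcs); zero scaled boundary
conditions at both ends; horizon 1 s. All nine problems solve with exact
Hessians in 14–20 interior-point iterations at their full default meshes
(the 10-dof/N = 100 problem, 10020 variables, takes ~15 s), so the test
suite runs them all. With a zero-amplitude pulse the optimum is exactly
zero torque.

*Predictive walking*: 57 states (18 activations, 18 normalized tendon
forces, 10 q, 10 v, trunk activation), 47 controls, free t_f; objective
(w₁‖a‖₃³ + w₂ e_trunk² + w₃‖ũ_dv‖₂² + 0.001(‖u_da‖² + ‖u_dFt‖²))/d with
d = 1.33·t_f the distance traveled. The weights w₁ = 1, w₂ = 1, w₃ = 0.05
are configuration: the qualitative requirement is only that the
muscle-fatigue term dominates, and the defaults order the terms that way.
Left–right symmetry maps the state at t_f to the leg-swapped state at 0
(pelvis forward position excluded; its initial value is anchored at 0),
so only half a gait cycle is optimized; the prescribed-speed row fixes
(q_pelvis,x(t_f) − q_pelvis,x(0))/t_f = 1.33 m/s.

The canonical initial guess is a quasi-static pose swept forward at the
prescribed speed with feet grazing the ground — with one essential
addition: the legs are split in anti-phase (hips ±0.3 rad sinusoidally,
the swing knee flexing with a sin² bump, velocities consistent and
swap-periodic). The split matters because the problem and the
interior-point iteration are exactly left–right symmetric: from a guess
with identical legs every iterate keeps identical legs, so the solver can
only reach same-phase (hopping/bounding) motions; anti-phase gaits are
reachable only from a symmetry-broken start. Both starts converge to
feasible periodic motions at the prescribed speed; the anti-phase one
produces a single-support stride.

With the synthetic muscle fixture and default weights, the fatigue-optimal
anti-phase motion at the reduced mesh is a grounded-run-like gait: a
single-leg stance with a pronounced landing force peak followed by a short
flight phase (half-cycle ≈ 0.38 s). Human subjects walk at 1.33 m/s;
whether walking or running is optimal here depends on the fixture's muscle
strengths and the contact model, which is exactly the kind of conclusion
the synthetic setup cannot support (see the closing section). The
plausibility report therefore distinguishes the momentum-balance impulse
check (total vertical impulse = body weight × cycle time, which any
converged periodic motion must satisfy and this one does to ~1%) from the
walking-specific stance-fraction version, which flags the flight phase.

The acceptance-scale solve uses a reduced mesh of N = 8 intervals (2246
variables) and stops early once the iterate is feasible at 10⁻⁶ with
first-order optimality below 10⁻⁴ — the interior-point method's optimality
tail on this problem is long, and the acceptance question is constraint
satisfaction of the converged motion, not the last digit of the objective.
N = 50 reproduces the printed problem size and behaves identically in
structure. The paper-scale observation that quasi-Newton Hessians beat
exact ones on this problem is hardware- and solver-dependent and is
reported by the benchmark harness, not asserted (at these sizes a dense
quasi-Newton Hessian also makes the trust-region subproblems dense, so the
exact sparse Hessian is the practical default here).

*Benchmark harness.* Runs (derivative scenario × Hessian mode × seeded
initial guesses), fingerprints each converged trajectory (scaled solution
quantized at 10⁻³ on two half-offset grids and hashed; two runs match if
either grid agrees), excludes pairs that reached different optima, and
reports mean ± sd time and iteration ratios plus per-callback time shares.
Wall-clock ratios are informational — they depend on hardware and solver
build — and no test asserts them; the AD-vs-FD *evaluation-count* ratio is
asserted instead (1 reverse sweep vs n+1 evaluations per gradient).

## What the synthetic setup does and does not show

The pendulum problems are fully specified by their printed formulation, so
their tests check the real thing end to end. The gait model's skeleton
anthropometry, muscle attachments and Hill constants are representative
fixtures, not measurements: passing tests show that the formulation is
assembled correctly (constraint structure, bounds, symmetry, speed,
equilibria), that the derivatives are exact, and that the coupled
muscle–skeleton–contact NLP is solvable to tolerance — they do not
validate the model against experimental gait data, and the optimized
motions should be read as plausible, not as physiological predictions.
Known limitations: no 3-D dynamics, no joint-limit stops, no tendon
damping, no metabolic-energy objective; sparsity inside a collocation
point is not exploited by graph coloring; the interior-point method's
iteration counts differ from other solvers'.
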