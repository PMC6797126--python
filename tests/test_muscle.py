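"""Muscle dynamics tests: Raasch rate bounds, implicit Hill residual,
torque actuator, and polynomial geometry fitting."""

import numpy as np
import pytest

from tapetraj import adgraph as ad
from tapetraj import muscle as mus
from tapetraj import problems


@pytest.fixture
def rng():
    return np.random.default_rng(3)


@pytest.fixture(scope="module")
def act():
    return mus.ActivationConstants()


class TestRaaschBounds:
    def test_direct_substitution_of_constants(self, act):
        r_lo, r_hi = mus.raasch_bounds(0.5, 0.0, act)
        assert r_lo == pytest.approx(0.5 / 0.060)
        assert r_hi == pytest.approx(0.5 / 0.015 - 1 / 0.015)
        assert r_lo >= 0 and r_hi <= 0  # feasible at zero rate

    def test_rest_and_saturation_boundaries(self, act):
        r_lo, r_hi = mus.raasch_bounds(0.0, 0.0, act)
        assert r_lo == 0.0
        assert r_hi == pytest.approx(-1 / act.tau_a)
        r_lo, r_hi = mus.raasch_bounds(1.0, 0.0, act)
        assert r_hi == pytest.approx(0.0, abs=1e-12)

    def test_feasible_band_nonempty_for_all_activations(self, act):
        # for every a in [0,1] there is a u_da satisfying both residuals
        for a in np.linspace(0, 1, 51):
            u_lo = -a / act.tau_d / act.s_da          # makes r_lo = 0
            u_hi = (1 - a) / act.tau_a / act.s_da     # makes r_hi = 0
            assert u_lo <= u_hi
            u_mid = 0.5 * (u_lo + u_hi)
            r_lo, r_hi = mus.raasch_bounds(a, u_mid, act)
            assert r_lo >= -1e-12 and r_hi <= 1e-12

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            mus.ActivationConstants(tau_a=0.06, tau_d=0.015)


class TestTorqueActuator:
    def test_rates(self):
        p = mus.TorqueActuatorParams()
        assert mus.torque_actuator_rate(0.3, 0.3, p) == 0.0
        assert mus.torque_actuator_rate(1.0, 0.0, p) == pytest.approx(1 / 0.035)
        assert mus.torque_actuator_rate(-1.0, 1.0, p) == pytest.approx(-2 / 0.035)


@pytest.fixture(scope="module")
def params():
    return mus.MuscleParams(F_max=1000.0, l_M_opt=0.1, l_T_slack=0.2,
                            alpha_opt=0.0)


def lmt_for_equilibrium(ft, p, lm_norm=1.0):
    """Muscle-tendon length placing the fiber at lm_norm with tendon force ft."""
    return p.l_T_slack * mus.tendon_length_from_force(ft, p.k_T) \
        + lm_norm * p.l_M_opt


class TestHillResidual:
    def test_passive_free_slack_equilibrium(self, params):
        # a = 0, fiber at a length where the passive curve is ~0, tendon
        # force consistent with ~zero tendon stretch -> residual ~ 0
        ft0 = mus.tendon_force_length(1.0, params.k_T)  # force at slack length
        lm = 0.8  # below optimal: passive force negligible
        if ft0 < 0:
            ft0 = 1e-9
        lmt = lmt_for_equilibrium(max(ft0, 1e-9), params, lm)
        r = mus.hill_residual(0.0, lmt, 0.0, max(ft0, 1e-9), 0.0, params)
        assert abs(r) < 5e-2  # small residual: slack, passive-free state

    def test_isometric_equilibrium_closed_form(self, params):
        # a=1, isometric, fiber at optimal length, no pennation: equilibrium
        # tendon force equals f_act(1) f_v(0) + f_pas(1) from the curve set
        ft_eq = mus.active_force_length(1.0) * mus.force_velocity(0.0) \
            + mus.passive_force_length(1.0)
        lmt = lmt_for_equilibrium(ft_eq, params)
        r = mus.hill_residual(1.0, lmt, 0.0, ft_eq, 0.0, params)
        assert r == pytest.approx(0.0, abs=1e-12)
        # off equilibrium the residual is nonzero with sign matching the
        # force imbalance (monotone decreasing in F_t near equilibrium)
        r_hi = mus.hill_residual(1.0, lmt, 0.0, ft_eq + 0.05, 0.0, params)
        r_lo = mus.hill_residual(1.0, lmt, 0.0, ft_eq - 0.05, 0.0, params)
        assert r_hi < 0 < r_lo

    def test_monotone_in_tendon_force_near_equilibrium(self, params, rng):
        for _ in range(10):
            lm = rng.uniform(0.85, 1.15)
            a = rng.uniform(0.2, 1.0)
            ft = a * mus.active_force_length(lm) * mus.force_velocity(0.0) \
                + mus.passive_force_length(lm)
            lmt = lmt_for_equilibrium(ft, params, lm)
            r0 = mus.hill_residual(a, lmt, 0.0, ft, 0.0, params)
            assert abs(r0) < 1e-10
            d = 1e-3
            assert mus.hill_residual(a, lmt, 0.0, ft + d, 0.0, params) < r0
            assert mus.hill_residual(a, lmt, 0.0, ft - d, 0.0, params) > r0

    def test_residual_smooth_c2_in_all_arguments(self, params):
        # second finite differences along sweeps of every argument show no
        # spikes (continuous curvature)
        base = dict(a=0.6, lmt=lmt_for_equilibrium(0.8, params, 1.0),
                    vmt=0.02, ft=0.8, udft=0.1)

        def res(**kw):
            z = {**base, **kw}
            return mus.hill_residual(z["a"], z["lmt"], z["vmt"], z["ft"],
                                     z["udft"], params)

        for arg, lo, hi in [("a", 0.0, 1.0), ("lmt", base["lmt"] - 0.02, base["lmt"] + 0.02),
                            ("vmt", -0.2, 0.2), ("ft", 0.05, 3.0), ("udft", -1, 1)]:
            xs = np.linspace(lo, hi, 101)
            h = xs[1] - xs[0]
            vals = np.array([res(**{arg: x}) for x in xs])
            second = (vals[:-2] - 2 * vals[1:-1] + vals[2:]) / h ** 2
            jumps = np.abs(np.diff(second))
            scale = np.max(np.abs(second)) + 1.0
            assert np.max(jumps) < 0.5 * scale, arg

    def test_pennation_model_constant_thickness(self):
        p = mus.MuscleParams(F_max=1000.0, l_M_opt=0.1, l_T_slack=0.2,
                             alpha_opt=0.3)
        # at equilibrium with pennation, the projected fiber force balances
        ft = 0.5
        lt = p.l_T_slack * mus.tendon_length_from_force(ft, p.k_T)
        h = p.l_M_opt * np.sin(p.alpha_opt)
        # choose the muscle-tendon length putting the fiber exactly at l_M_opt
        proj = np.sqrt(p.l_M_opt ** 2 - h ** 2)
        lmt = lt + proj
        cos_a = proj / p.l_M_opt
        r = mus.hill_residual(0.7, lmt, 0.0, ft, 0.0, p)
        expect = (0.7 * mus.active_force_length(1.0) * mus.force_velocity(0.0)
                  + mus.passive_force_length(1.0)) * cos_a - ft
        assert r == pytest.approx(expect, abs=1e-12)

    def test_recordable_on_tape(self, params, rng):
        def fn(z):
            return mus.hill_residual(z[0], z[1], z[2], z[3], z[4], params)

        z0 = np.array([0.5, lmt_for_equilibrium(0.8, params), 0.01, 0.8, 0.1])
        tape = ad.record(fn, z0)
        assert tape.branch_signature == []
        J = ad.jacobian(tape)
        Jfd = ad.fd_jacobian(lambda x: ad.replay(tape, x), z0,
                             h=1e-7, scheme="central")
        assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-7)


class TestPolynomialGeometry:
    def test_linear_geometry_exact_at_order_one(self):
        # l_MT = l0 - r q: constant moment arm r recovered exactly
        l0, r = 0.3, 0.05
        Q = np.linspace(-1, 1, 50)[:, None]
        samples = {"lin": {"coords": [0], "Q": Q,
                           "lmt": l0 - r * Q[:, 0],
                           "ma": np.full((50, 1), r)}}
        geoms, reports = mus.fit_polynomials(samples)
        g = geoms["lin"]
        assert reports[0].order == 1
        assert g.length([0.3]) == pytest.approx(l0 - r * 0.3, abs=1e-12)
        assert g.moment_arms([0.3])[0] == pytest.approx(r, abs=1e-12)

    def test_via_point_fixture_fits_within_3mm(self):
        fixture = problems.load_gait_fixture()
        samples = problems.geometry_samples(fixture)
        geoms, reports = mus.fit_polynomials(samples)
        assert all(r.order <= 9 for r in reports)
        assert max(r.rms_length for r in reports) <= 0.003
        assert max(r.rms_moment_arm for r in reports) <= 0.003

    def test_fitted_moment_arm_close_to_analytic(self):
        # AD moment arm of the fitted polynomial vs the exact via-point
        # moment arm: max abs deviation <= 5 mm over the grid
        fixture = problems.load_gait_fixture()
        samples = problems.geometry_samples(fixture)
        geoms, _ = mus.fit_polynomials(samples)
        for name, s in samples.items():
            g = geoms[name]
            ma_fit = np.array([g.moment_arms(q) for q in s["Q"]])
            assert np.max(np.abs(ma_fit - s["ma"])) <= 0.005, name

    def test_moment_arm_is_negative_ad_gradient(self, rng):
        fixture = problems.load_gait_fixture()
        samples = problems.geometry_samples(fixture)
        geoms, _ = mus.fit_polynomials(samples)
        g = geoms["hamstrings"]
        for _ in range(10):
            q = rng.uniform([-0.5, -1.5], [0.5, 0.0])
            tape = ad.record(lambda x: g.length(x), q)
            ma_ad = -np.asarray(ad.reverse_sweep(tape, [1.0]))
            assert np.allclose(ma_ad, g.moment_arms(q), rtol=0, atol=1e-14)

    def test_eval_lmt_vmt_ma_identities(self, rng):
        fixture = problems.load_gait_fixture()
        samples = problems.geometry_samples(fixture)
        geoms, _ = mus.fit_polynomials(samples)
        g = geoms["gastrocnemius"]
        q = [0.0] * 2
        lmt, vmt, mas = mus.eval_lmt_vmt_ma(g, q, [0.0, 0.0])
        assert vmt == 0.0
        # v_MT matches a central difference of l_MT along a moving trajectory
        qv = rng.uniform(-0.3, 0.0, size=2)
        vv = rng.normal(size=2)
        _, vmt, _ = mus.eval_lmt_vmt_ma(g, qv, vv, warn_out_of_range=False)
        h = 1e-6
        l_p = g.length(qv + h * vv)
        l_m = g.length(qv - h * vv)
        assert vmt == pytest.approx((l_p - l_m) / (2 * h), rel=1e-6, abs=1e-9)

    def test_fit_failure_names_worst_muscle(self):
        # a target that a 9th-order polynomial cannot represent to 3 mm
        Q = np.linspace(-1, 1, 2000)[:, None]
        wild = 0.3 + 0.05 * np.sign(np.sin(40 * Q[:, 0]))
        samples = {"impossible": {"coords": [0], "Q": Q, "lmt": wild,
                                  "ma": np.zeros((2000, 1))}}
        with pytest.raises(RuntimeError, match="impossible"):
            mus.fit_polynomials(samples)
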