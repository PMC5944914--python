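import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antcargo.meanfield import (
    PhasePoint,
    half_space_excursion,
    integrate,
    jacobian_origin,
    nullcline_branches,
    nullcline_roots,
    q_eval,
    restoring_force,
)
from antcargo.params import InvalidParameterError, RescaledParams


class TestRestoringForce:
    @pytest.mark.parametrize(
        "mode,kwargs",
        [("tanh", {"eps": 1.0}), ("sign", {}), ("projection2d", {"r": 1.0})],
    )
    def test_odd_and_vanishing_at_origin(self, mode, kwargs):
        assert restoring_force(0.0, g=0.1, mode=mode, **kwargs) == 0.0
        assert restoring_force(2.0, 0.1, mode=mode, **kwargs) == pytest.approx(
            -restoring_force(-2.0, 0.1, mode=mode, **kwargs)
        )

    def test_saturates_at_g(self):
        assert restoring_force(50.0, 0.1, eps=1.0, mode="tanh") == pytest.approx(0.1, rel=1e-6)
        assert restoring_force(50.0, 0.1, mode="projection2d", r=1.0) == pytest.approx(0.1, rel=1e-3)

    def test_tanh_approximates_geometric_projection(self):
        # the tanh regularization with eps ~ r tracks the projected pull of a
        # ring cargo of radius r; the two profiles stay within ~0.13 g
        x = np.linspace(-5, 5, 201)
        tanh = restoring_force(x, 1.0, eps=1.0, mode="tanh")
        proj = restoring_force(x, 1.0, mode="projection2d", r=1.0)
        assert np.max(np.abs(tanh - proj)) < 0.15

    def test_tanh_with_zero_eps_directs_to_sign(self):
        with pytest.raises(InvalidParameterError, match="sign"):
            restoring_force(1.0, 0.1, eps=0.0, mode="tanh")


class TestVectorField:
    def test_origin_is_a_fixed_point(self, red_marker):
        assert q_eval((0.0, 0.0), red_marker) == 0.0
        assert q_eval((0.0, 0.0), red_marker.with_(eps=0.1)) == 0.0

    @given(x=st.floats(-5, 5), v=st.floats(-1, 1), eps=st.sampled_from([0.0, 0.05, 0.3]))
    @settings(max_examples=150, derandomize=True)
    def test_field_is_odd_under_state_reflection(self, x, v, eps):
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.23, eps=eps)
        assert q_eval((-x, -v), rp) == pytest.approx(-q_eval((x, v), rp), rel=1e-12, abs=1e-12)

    def test_matches_independent_transcription(self):
        # independent evaluation of the acceleration at (x, v) = (1, 0.2)
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.23, eps=0.1, k_c=1.0)
        u = 0.2 / 0.23
        expected = (
            0.8 * math.sinh(u)
            - 2.0 * (0.2 + 0.1 * math.tanh(10.0)) * math.cosh(u)
        ) - 0.2 * (0.1 / 0.1) / math.cosh(10.0) ** 2
        assert q_eval((1.0, 0.2), rp) == pytest.approx(expected, rel=1e-14)

    def test_unique_rest_position(self, red_marker):
        # q(x, 0) = 0 only at x = 0 when a restoring force is present
        for x in np.linspace(-4, 4, 41):
            q = q_eval((x, 0.0), red_marker.with_(eps=0.2))
            if x != 0:
                assert np.sign(q) == -np.sign(x)


class TestJacobian:
    def test_no_restoring_force_decouples_position(self):
        rp = RescaledParams(n=0.8, g=0.0, f_ind=0.23, eps=0.1)
        assert jacobian_origin(rp)[1, 0] == 0.0

    def test_matches_finite_differences(self, red_marker):
        rp = red_marker.with_(eps=0.07)
        J = jacobian_origin(rp)
        h = 1e-6
        dq_dx = (q_eval((h, 0.0), rp) - q_eval((-h, 0.0), rp)) / (2 * h)
        dq_dv = (q_eval((0.0, h), rp) - q_eval((0.0, -h), rp)) / (2 * h)
        assert J[1, 0] == pytest.approx(dq_dx, rel=1e-6)
        assert J[1, 1] == pytest.approx(dq_dv, rel=1e-6)

    def test_undefined_for_discontinuous_field(self, red_marker):
        with pytest.raises(InvalidParameterError):
            jacobian_origin(red_marker)


class TestIntegration:
    def test_origin_stays_put(self, red_marker):
        traj = integrate(red_marker, (0.0, 0.0), T=5.0)
        assert np.all(traj.x == 0.0) and np.all(traj.v == 0.0)

    def test_high_individuality_converges_from_everywhere(self):
        # above the saddle-node threshold every orbit spirals to the opening
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.28, eps=0.0)
        for ic in [(3.0, 0.0), (0.0, 0.5), (-2.0, -0.3)]:
            traj = integrate(rp, ic, T=400.0)
            assert traj.meta["converged"], f"IC {ic} did not converge"

    def test_low_individuality_escapes_outside_separatrix(self):
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.18, eps=0.0)
        traj = integrate(rp, (0.0, 0.6), T=400.0)
        assert traj.meta["escaped"]

    def test_limit_cycle_peak_speed_on_nullcline(self, red_marker):
        # phase-(ii) relaxation oscillations ride the velocity nullcline: the
        # inbound peak speed equals the nullcline branch value far from the
        # opening
        traj = integrate(red_marker, (0.0, 0.6), T=300.0)
        assert not traj.meta["converged"] and not traj.meta["escaped"]
        late = traj.v[traj.t > 200.0]
        peak = np.max(np.abs(late))
        roots = nullcline_roots(5.0, red_marker)
        inbound = min(roots)  # negative branch: motion back toward the opening
        assert peak == pytest.approx(abs(inbound), rel=0.02)

    def test_flow_commutes_with_reflection(self, red_marker):
        a = integrate(red_marker, (1.0, 0.2), T=20.0)
        b = integrate(red_marker, (-1.0, -0.2), T=20.0)
        m = min(len(a), len(b))
        assert np.allclose(a.x[:m], -b.x[:m], atol=1e-6)
        assert np.allclose(a.v[:m], -b.v[:m], atol=1e-6)

    def test_smooth_field_spirals_into_origin(self):
        # above the Hopf threshold (f_c1 = 0.267 at eps = 0.1) the origin is
        # stable; an orbit released inside the separatrix spirals in
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.28, eps=0.1)
        traj = integrate(rp, (0.1, 0.0), T=300.0)
        assert abs(traj.x[-1]) < 1e-6 and abs(traj.v[-1]) < 1e-6

    def test_crossing_rule_reflects_slow_cargo(self, red_marker):
        # released at rest near the opening, the cargo arrives slower than
        # the 2g velocity drop, cannot cross, and is captured; released
        # farther out, the tug-of-war orders en route and it reaches the
        # oscillatory mode instead (bi-stability)
        assert integrate(red_marker, (0.05, 0.0), T=100.0).meta["converged"]
        far = integrate(red_marker, (0.5, 0.0), T=200.0)
        assert not far.meta["converged"]
        assert np.max(np.abs(far.v[far.t > 150.0])) > 0.4


class TestNullclines:
    def test_branches_pair_under_reflection(self, red_marker):
        for x in (1.3, 2.7):
            plus = np.sort(nullcline_roots(x, red_marker))
            minus = np.sort(nullcline_roots(-x, red_marker))
            assert np.allclose(plus, -minus[::-1], atol=1e-8)

    def test_far_field_roots_match_scalar_bisection(self, red_marker):
        # at large |x| the nullcline solves n sinh(v/f) = 2 (v + g) cosh(v/f)
        from scipy.optimize import brentq

        def h(v):
            return 0.8 * math.sinh(v / 0.23) - 2.0 * (v + 0.1) * math.cosh(v / 0.23)

        roots = nullcline_roots(50.0, red_marker)
        for r in roots:
            rr = brentq(h, r - 0.01, r + 0.01)
            assert rr == pytest.approx(r, abs=1e-8)

    def test_branches_merge_across_homoclinic_threshold(self):
        # below the threshold three branches coexist in a half-space; above
        # it two have merged and only the inbound branch remains
        lo = RescaledParams(n=0.8, g=0.1, f_ind=0.18, eps=0.0)
        hi = RescaledParams(n=0.8, g=0.1, f_ind=0.21, eps=0.0)
        assert len(nullcline_roots(3.0, lo)) == 3
        assert len(nullcline_roots(3.0, hi)) == 1

    def test_branch_assembly_covers_all_roots(self, red_marker):
        xs = np.linspace(0.5, 4.0, 15)
        branches = nullcline_branches(red_marker, xs)
        total = sum(len(b.x) for b in branches)
        expected = sum(len(nullcline_roots(x, red_marker)) for x in xs)
        assert total == expected
        for b in branches:
            for x, v in zip(b.x, b.v):
                assert abs(q_eval((x, v), red_marker)) < 1e-7


class TestHalfSpaceExcursion:
    def test_fast_launch_escapes_in_phase_i(self):
        rp = RescaledParams(n=0.8, g=0.1, f_ind=0.18, eps=0.0)
        outcome, _, _ = half_space_excursion(rp, 0.8)
        assert outcome == "escape"

    def test_fast_launch_returns_in_phase_ii(self, red_marker):
        outcome, speed, _ = half_space_excursion(red_marker, 0.8)
        assert outcome == "return"
        assert speed > 0
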