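import dataclasses
import itertools
import math

import numpy as np
import pytest
import scipy.linalg
from scipy import stats

from antcargo.gillespie1d import (
    CargoState1D,
    _Sim,
    gillespie_step,
    removal_role_assignment,
    role_switch_rates,
    run_scheme,
    total_force_1d,
)
from antcargo.params import InvalidParameterError, PARAMS_1D_MODEL


class TestRates:
    def test_zero_force_gives_basal_rates(self):
        assert role_switch_rates(0.0, 23.0, 1.0) == (1.0, 1.0)

    def test_rate_product_is_basal_squared(self):
        for proj in (-40.0, -3.0, 11.0):
            r_lp, r_pl = role_switch_rates(proj, 23.0, 2.0)
            assert r_lp * r_pl == pytest.approx(4.0, rel=1e-12)

    def test_threshold_projection_gives_e_fold(self):
        r_lp, r_pl = role_switch_rates(23.0, 23.0, 1.0)
        assert r_lp == pytest.approx(math.e)
        assert r_pl == pytest.approx(1.0 / math.e)

    def test_nonpositive_individuality_rejected(self):
        with pytest.raises(InvalidParameterError):
            role_switch_rates(1.0, 0.0, 1.0)


class TestForceBalance:
    def test_all_lifters_no_informed_is_forceless(self):
        st = CargoState1D(x=1.0, n_l_front=40, n_l_back=40, n_max=80)
        assert total_force_1d(st, f0=1.0, G_effective=0.0) == 0.0

    def test_tug_of_war_minus_restoring(self):
        st = CargoState1D(x=0.7, n_p_front=5, n_p_back=3, n_l_front=30,
                          n_l_back=42, n_max=80)
        assert total_force_1d(st, f0=1.0, G_effective=2.0) == pytest.approx(0.0)

    def test_mirror_state_reverses_force(self):
        st = CargoState1D(x=0.7, n_p_front=9, n_p_back=2, n_l_front=30,
                          n_l_back=39, n_max=80)
        mirror = CargoState1D(x=-0.7, n_p_front=2, n_p_back=9, n_l_front=39,
                              n_l_back=30, n_max=80)
        f = total_force_1d(st, 1.0, 3.0)
        assert total_force_1d(mirror, 1.0, 3.0) == pytest.approx(-f)


class TestRemovalRole:
    def test_balanced_projection_is_a_coin_flip(self):
        assert removal_role_assignment(0.0, 23.0, 0.49) == "puller"
        assert removal_role_assignment(0.0, 23.0, 0.51) == "lifter"

    def test_saturation_toward_puller(self):
        assert removal_role_assignment(1e4, 23.0, 0.999) == "puller"

    def test_empirical_frequency_matches_equilibrium(self):
        rng = np.random.default_rng(5)
        proj, F = 10.0, 23.0
        N_p = 1.0 / (1.0 + math.exp(-2.0 * proj / F))
        n = 100_000
        draws = rng.random(n)
        freq = np.mean(draws < N_p)  # removal_role_assignment is this comparison
        hits = sum(
            removal_role_assignment(proj, F, u) == "puller" for u in draws[:2000]
        )
        assert abs(freq - N_p) < 3 * math.sqrt(N_p * (1 - N_p) / n)
        assert abs(hits / 2000 - N_p) < 3 * math.sqrt(N_p * (1 - N_p) / 2000)


class TestGillespieStep:
    def test_waiting_times_are_exponential(self):
        # frozen state: the dt distribution must be Exp(R_tot)
        rng = np.random.default_rng(11)
        base = CargoState1D(x=0.2, n_p_front=25, n_p_back=15, n_l_front=15,
                            n_l_back=25, n_max=80)
        sim = _Sim("role_switch", PARAMS_1D_MODEL, state=dataclasses.replace(base))
        R_tot = sum(sim.rates().values())
        dts = []
        for _ in range(3000):
            dt, _, _ = gillespie_step(
                dataclasses.replace(base), "role_switch", PARAMS_1D_MODEL, rng
            )
            dts.append(dt)
        ks = stats.kstest(dts, "expon", args=(0, 1.0 / R_tot))
        assert ks.pvalue > 0.01

    def test_site_conservation_across_all_event_types(self):
        rng = np.random.default_rng(3)
        tr = run_scheme(3, T=30.0, seed=3)
        sums = tr.n_pullers + tr.n_lifters + tr.n_informed
        assert np.all(sums <= 110)
        assert np.all(sums >= 0)

    def test_symmetric_walk_at_infinite_individuality(self):
        # with F_ind -> infinity both switch rates equal k_c: the puller
        # count is a symmetric random walk (zero drift)
        p = PARAMS_1D_MODEL.with_(F_ind=1e12)
        tr = run_scheme(1, params=p, T=300.0, seed=9)
        drift = (tr.n_pullers[-1] - tr.n_pullers[0]) / tr.t[-1]
        assert abs(tr.n_pullers.mean() - 40.0) < 2.0
        assert abs(drift) < 0.1


class TestRunScheme:
    def test_identical_seeds_reproduce_trajectories(self):
        a = run_scheme(2, T=20.0, seed=4)
        b = run_scheme(2, T=20.0, seed=4)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.v, b.v)

    def test_mean_drift_matches_tug_of_war_formula(self):
        # exact one-step expectation: E[d(n_pf - n_pb)]/dt at a frozen state
        # equals k_c[(n_lf + n_pb) e^{f/F} - (n_pf + n_lb) e^{-f/F}]
        p = PARAMS_1D_MODEL
        base = CargoState1D(x=0.5, n_p_front=25, n_p_back=15, n_l_front=15,
                            n_l_back=25, n_max=80)
        sim0 = _Sim("role_switch", p, freeze_position=True,
                    state=dataclasses.replace(base))
        f = sim0.f_tot
        phi = math.exp(f / p.F_ind)
        predicted = p.k_c * (
            (base.n_l_front + base.n_p_back) * phi
            - (base.n_p_front + base.n_l_back) / phi
        )
        R_tot = sum(sim0.rates().values())
        rng = np.random.default_rng(21)
        M = 20_000
        total = 0
        for _ in range(M):
            sim = _Sim("role_switch", p, freeze_position=True,
                       state=dataclasses.replace(base))
            sim.step(rng)
            st = sim.state
            total += (st.n_p_front - st.n_p_back) - (base.n_p_front - base.n_p_back)
        empirical = total / M * R_tot
        sigma = R_tot / math.sqrt(M)  # jump variance is at most 1 per step
        assert abs(empirical - predicted) < 3 * sigma

    def test_tiny_system_matches_master_equation(self):
        # two sites, frozen cargo, no informed force: the stationary
        # puller-configuration distribution has an exact solution
        p = PARAMS_1D_MODEL.with_(n_tot=2.0, n_max=2, G=0.0, F_ind=1.0,
                                  f0=1.0, gamma=1.0)
        states = list(itertools.product([0, 1], [0, 1]))
        idx = {s: i for i, s in enumerate(states)}
        Q = np.zeros((4, 4))
        for pf, pb in states:
            f = pf - pb
            if pf == 0:
                Q[idx[pf, pb], idx[1, pb]] += math.exp(f)       # front lifter -> puller
            else:
                Q[idx[pf, pb], idx[0, pb]] += math.exp(-f)      # front puller -> lifter
            if pb == 0:
                Q[idx[pf, pb], idx[pf, 1]] += math.exp(-f)      # back lifter -> puller
            else:
                Q[idx[pf, pb], idx[pf, 0]] += math.exp(f)       # back puller -> lifter
        G = Q - np.diag(Q.sum(axis=1))
        pi = scipy.linalg.null_space(G.T)[:, 0]
        pi /= pi.sum()

        rng = np.random.default_rng(1)
        sim = _Sim(
            "role_switch", p, freeze_position=True,
            state=CargoState1D(x=0.3, n_l_front=1, n_l_back=1, n_max=2),
        )
        occ = np.zeros(4)
        for _ in range(100_000):
            s = (sim.state.n_p_front, sim.state.n_p_back)
            dt, _ = sim.step(rng)
            occ[idx[s]] += dt
        occ /= occ.sum()
        assert np.max(np.abs(occ - pi)) < 0.01

    @pytest.mark.parametrize("scheme,expected_u,expected_inf", [
        (2, 80.0, None),     # two-state occupancy: 100 * k_on/(k_on+k_off)
        (3, 80.0, 10.0),     # three-state occupancy of 110 sites
    ])
    def test_long_run_occupancy_matches_steady_state(self, scheme, expected_u,
                                                     expected_inf):
        tr = run_scheme(scheme, T=3000.0, seed=3)
        w = np.diff(tr.t)
        n_u = (tr.n_pullers + tr.n_lifters)[:-1]
        mean_u = float((n_u * w).sum() / w.sum())
        assert mean_u == pytest.approx(expected_u, rel=0.03)
        if expected_inf is not None:
            mean_inf = float((tr.n_informed[:-1] * w).sum() / w.sum())
            assert mean_inf == pytest.approx(expected_inf, rel=0.05)

    def test_overfull_cargo_rejected(self):
        with pytest.raises(InvalidParameterError):
            run_scheme(1, params=PARAMS_1D_MODEL.with_(n_tot=90.0, n_max=80))
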