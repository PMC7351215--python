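"""Per-cycle bounded least-squares identification and warm-start chaining."""

import numpy as np
import pytest
from scipy.optimize import minimize

import wkident as wk
from wkident.identification import IdentConfig, initial_state, _residuals
from conftest import make_open_loop_cycle, random_theta

TRUTH = wk.NORMAL_PARAMS.as_array()


class TestCost:
    def test_zero_at_generating_parameters(self, open_loop_cycle):
        """Predictor == generator: the cost vanishes at the true theta."""
        J = wk.cost(wk.NORMAL_PARAMS, open_loop_cycle, x0_policy="zero")
        assert J <= 1e-18

    def test_nonnegative_everywhere(self, open_loop_cycle, rng):
        for _ in range(50):
            theta = random_theta(rng)
            try:
                assert wk.cost(theta, open_loop_cycle, x0_policy="zero") >= 0.0
            except wk.DivergenceError:
                pass  # unstable Euler corner of the box; checked below

    def test_single_sample_by_hand(self):
        """m = 1... (padded to the buffer minimum): J = sum h (Y - x0[0])^2
        since no dynamics step affects recorded outputs before it."""
        h = 1e-3
        U = np.zeros((10, 3))
        Y = np.full(10, 2.0)
        cyc = wk.CycleBuffer(h=h, U=U, Y=Y, cycle_index=0)
        # zero initial state, zero inputs: prediction decays from 0 -> stays 0
        J = wk.cost(wk.NORMAL_PARAMS, cyc, x0_policy="zero")
        assert J == pytest.approx(10 * h * 4.0, rel=1e-12)

    def test_divergence_carries_theta(self, open_loop_cycle):
        bad = wk.WindkesselParams(0.5, 1.0, 0.9, 0.25, 1e-5)
        with pytest.raises(wk.DivergenceError) as err:
            wk.cost(bad, open_loop_cycle, x0_policy="zero")
        assert err.value.theta is not None
        assert err.value.step > 0

    def test_analytic_jacobian_matches_finite_differences(self, open_loop_cycle):
        """The forward-sensitivity Jacobian agrees with central FD."""
        theta = TRUTH * 1.1
        _, jac, _ = _residuals(theta, open_loop_cycle, "enddiastolic", True)
        for i in range(5):
            dt = 1e-6 * theta[i]
            tp, tm = theta.copy(), theta.copy()
            tp[i] += dt
            tm[i] -= dt
            rp, _, _ = _residuals(tp, open_loop_cycle, "enddiastolic", False)
            rm, _, _ = _residuals(tm, open_loop_cycle, "enddiastolic", False)
            fd = (rp - rm) / (2 * dt)
            scale = np.abs(fd).max()
            np.testing.assert_allclose(jac[:, i], fd, atol=1e-5 * scale)


class TestIdentifyCycle:
    def test_start_at_truth_stays(self, open_loop_cycle):
        cfg = IdentConfig(x0_policy="zero")
        r = wk.identify_cycle(open_loop_cycle, wk.NORMAL_PARAMS, cfg)
        np.testing.assert_allclose(r.theta_hat.as_array(), TRUTH, rtol=1e-6)
        assert r.cost <= 1e-12
        assert r.n_iter <= 2
        assert r.converged

    def test_recovery_from_perturbed_start(self, open_loop_cycle):
        """+20% on every parameter: the four well-identified parameters
        come back within 1% (the inertance is only weakly constrained)."""
        cfg = IdentConfig(x0_policy="zero")
        init = wk.WindkesselParams.from_array(TRUTH * 1.2)
        r = wk.identify_cycle(open_loop_cycle, init, cfg)
        rel = np.abs(r.theta_hat.as_array() - TRUTH) / TRUTH
        assert np.all(rel[:4] < 0.01)

    def test_out_of_bounds_start_rejected(self, open_loop_cycle):
        init = wk.WindkesselParams(0.1, 3.0, 0.9, 0.25, 3e-4)  # Rsa > ub = 2.0
        with pytest.raises(ValueError, match="bounds"):
            wk.identify_cycle(open_loop_cycle, init)

    def test_result_respects_bounds(self, normal_cycles):
        r = wk.identify_cycle(normal_cycles[0], wk.DEFAULT_BOUNDS.ub)
        assert wk.DEFAULT_BOUNDS.contains(r.theta_hat, atol=1e-12)

    def test_truth_on_bound_stays_active(self):
        """Generator truth placed on the upper Rsa bound: the KKT point
        sits on that bound (to the reflective solver's approach tolerance,
        which nears active bounds asymptotically rather than exactly)."""
        theta_edge = wk.WindkesselParams(0.1, 2.0, 0.9, 0.25, 3e-4)
        cyc = make_open_loop_cycle(theta=theta_edge)
        init = wk.WindkesselParams(0.1, 1.8, 0.9, 0.25, 3e-4)
        r = wk.identify_cycle(cyc, init, IdentConfig(x0_policy="zero"))
        assert r.theta_hat.Rsa == pytest.approx(2.0, abs=1e-4)

    def test_oracle_equivalence_small_cycle(self):
        """On a 20-sample toy cycle the solver's optimum matches an
        independent coarse-search + derivative-free polish of the same
        cost surface."""
        cyc = make_open_loop_cycle(m=20, h=1e-3)
        lb = wk.DEFAULT_BOUNDS.lb.as_array()
        ub = wk.DEFAULT_BOUNDS.ub.as_array()

        def J(th):
            if np.any(th < lb) or np.any(th > ub):
                return 1e12
            try:
                return wk.cost(th, cyc, x0_policy="zero")
            except wk.DivergenceError:
                return 1e12

        # oracle: random box search then Nelder-Mead polish (no gradients)
        oracle_rng = np.random.default_rng(5)
        cands = np.exp(oracle_rng.uniform(np.log(lb), np.log(ub), size=(4000, 5)))
        best = min(cands, key=J)
        polish = minimize(J, best, method="Nelder-Mead",
                          options={"maxiter": 4000, "fatol": 1e-14, "xatol": 1e-12})
        r = wk.identify_cycle(
            cyc,
            wk.WindkesselParams.from_array(np.clip(TRUTH * 1.3, lb, ub)),
            IdentConfig(x0_policy="zero"),
        )
        assert r.cost <= polish.fun * (1 + 1e-6) + 1e-12


class TestRunOnline:
    def test_one_result_per_cycle(self, normal_trace):
        res = wk.run_online(normal_trace, cold_start=wk.NORMAL_PARAMS)
        assert len(res) == 12
        assert [r.cycle_index for r in res] == list(range(12))

    def test_stationary_estimates_on_constant_trace(self, normal_trace):
        """Noiseless constant-parameter run: the warm-start chain is a
        fixed point — cycle-to-cycle drift below 0.1%."""
        res = wk.run_online(normal_trace, cold_start=wk.NORMAL_PARAMS)
        arr = np.array([r.theta_hat.as_array() for r in res])
        drift = np.abs(np.diff(arr[2:], axis=0)) / arr[2:-1]
        assert drift.max() < 1e-3

    def test_closed_loop_recovery_noiseless(self, normal_trace):
        """Identified parameters on clean closed-loop data agree with the
        generator's embedded truth to a few percent (Euler predictor and
        end-diastolic initial-state heuristic are the only mismatches)."""
        init = wk.WindkesselParams.from_array(TRUTH * 1.2)
        res = wk.run_online(normal_trace, cold_start=init)
        arr = np.array([r.theta_hat.as_array() for r in res])
        rel = np.abs(arr.mean(axis=0) - TRUTH) / TRUTH
        assert np.all(rel[:4] < 0.03)
        assert rel[4] < 0.25

    def test_explicit_array_cold_start(self, normal_trace):
        res = wk.run_online(normal_trace, cold_start=[0.12, 1.1, 0.8, 0.3, 4e-4])
        assert len(res) == 12


class TestInitialStatePolicies:
    def test_enddiastolic_matches_quasistatic_runoff(self, normal_cycles):
        cyc = normal_cycles[1]
        x0, S0 = initial_state(cyc, "enddiastolic", TRUTH)
        assert x0[0] == x0[1] == cyc.Y[0]
        frac = 0.9 / (0.9 + 0.25)
        expected = -frac * (cyc.Y[0] - cyc.U[0, 2]) / 1.0
        assert x0[2] == pytest.approx(expected, rel=1e-12)
        assert S0[2, 1] != 0.0 and np.all(S0[:2] == 0.0)

    def test_unknown_policy_rejected(self, normal_cycles):
        with pytest.raises(ValueError):
            initial_state(normal_cycles[0], "nope", TRUTH)
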