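"""Core self-replicator model: dynamics, steady states, closed-form optimum."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from selfreplicator import (
    DimParams,
    NondimParams,
    nondimensionalize,
    growth_rate_nondim,
    rhs_nondim,
    rhs_dim,
    steady_state_for_alpha,
    trivial_steady_state,
    optimal_allocation_env,
    optimal_allocation_dim,
    optimal_curve_g,
    optimal_curve_mu,
    optimal_precursor,
)

REF = NondimParams(E_M=1.0, K=0.003)


class TestNondimensionalization:
    def test_reference_parameters_reduce_to_unit_environment(self):
        nd, k_R = nondimensionalize(DimParams(e_M=3.6, k_R=3.6, K_R=1.0, beta=0.003))
        assert nd.E_M == 1.0
        assert nd.K == pytest.approx(0.003, abs=0)
        assert k_R == 3.6

    def test_matched_scales_give_unit_constants(self):
        nd, _ = nondimensionalize(DimParams(e_M=2.0, k_R=2.0, K_R=1 / 0.003, beta=0.003))
        assert nd.E_M == 1.0
        assert nd.K == pytest.approx(1.0, rel=1e-15)

    @pytest.mark.parametrize("bad", [dict(e_M=0.0), dict(k_R=-1.0), dict(beta=0.0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            DimParams(**bad)

    def test_dimensional_and_nondimensional_integration_agree(self):
        """Integrating the dimensional equations and rescaling reproduces the
        nondimensional trajectory (round-trip to < 1e-6 relative)."""
        dim = DimParams(e_M=2.5, k_R=3.6, K_R=1.0, beta=0.003)
        nd, k_R = nondimensionalize(dim)
        alpha = 0.4
        p0_hat, r0_hat = 0.05, 0.3
        t_hat_end = 5.0

        sol_nd = solve_ivp(
            lambda t, x: rhs_nondim(x[0], x[1], alpha, nd),
            (0, t_hat_end), [p0_hat, r0_hat], rtol=1e-12, atol=1e-14,
        )
        sol_d = solve_ivp(
            lambda t, x: rhs_dim(x[0], x[1], alpha, dim)[:2],
            (0, t_hat_end / k_R), [p0_hat / dim.beta, r0_hat / dim.beta],
            rtol=1e-12, atol=1e-14,
        )
        final_nd = np.array(sol_nd.y[:, -1])
        final_d = np.array(sol_d.y[:, -1]) * dim.beta
        assert np.allclose(final_nd, final_d, rtol=1e-6)


class TestRightHandSides:
    def test_zero_precursor_stalls_machinery_synthesis(self):
        dp, dr = rhs_nondim(0.0, 0.6, 0.7, REF)
        assert dp == pytest.approx((1 - 0.6) * REF.E_M)
        assert dr == 0.0

    def test_full_machinery_depletes_precursors(self):
        dp, dr = rhs_nondim(0.5, 1.0, 1.0, REF)
        assert dp < 0
        assert dr == 0.0

    def test_alpha_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            rhs_nondim(0.1, 0.5, 1.5, REF)
        with pytest.raises(ValueError):
            rhs_dim(0.1, 50.0, -0.1, DimParams())

    def test_dimensional_limits(self):
        dim = DimParams()
        # machinery-only composition: no metabolic flux
        dp, _, _ = rhs_dim(0.0, 1 / dim.beta, 0.5, dim)
        assert dp == pytest.approx(0.0, abs=1e-12)
        # half-saturation of translation
        _, dr, mu = rhs_dim(dim.K_R, 100.0, 1.0, dim)
        v_R = dim.k_R * 100.0 / 2
        assert mu == pytest.approx(dim.beta * v_R, rel=1e-14)

    @given(
        p=st.floats(1e-4, 5.0),
        r=st.floats(1e-3, 0.999),
        a=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_dim_nondim_consistency_at_random_points(self, p, r, a):
        """The two right-hand sides agree under the rescaling map."""
        dim = DimParams(e_M=2.9, k_R=3.6, K_R=1.0, beta=0.003)
        nd, k_R = nondimensionalize(dim)
        dp_h, dr_h = rhs_nondim(p, r, a, nd)
        dp, dr, _ = rhs_dim(p / dim.beta, r / dim.beta, a, dim)
        assert dp_h == pytest.approx(dim.beta * dp / k_R, rel=1e-12, abs=1e-15)
        assert dr_h == pytest.approx(dim.beta * dr / k_R, rel=1e-12, abs=1e-15)

    def test_growth_rate_limits(self):
        assert growth_rate_nondim(REF.K, 0.8, REF) == pytest.approx(0.4)
        assert growth_rate_nondim(0.0, 0.8, REF) == 0.0
        assert growth_rate_nondim(1e9, 0.8, REF) == pytest.approx(0.8, rel=1e-8)


class TestSteadyStates:
    def test_preshift_steady_state_matches_phase_plane_coordinates(self):
        """The optimal steady state of the poor medium (0.2*E_M) sits at
        (0.024, 0.18) to the printed rounding."""
        opt = optimal_allocation_env(0.2, 0.003)
        ss = steady_state_for_alpha(opt.alpha, NondimParams(E_M=0.2, K=0.003))
        assert ss.p_hat == pytest.approx(0.024, abs=5e-4)
        assert ss.r_hat == pytest.approx(0.18, abs=5e-3)

    @pytest.mark.parametrize("alpha,E_M", [(0.45, 1.0), (0.2, 0.5), (0.7, 3.0)])
    def test_fixed_point_residual_vanishes(self, alpha, E_M):
        params = NondimParams(E_M=E_M, K=0.003)
        ss = steady_state_for_alpha(alpha, params)
        dp, dr = rhs_nondim(ss.p_hat, ss.r_hat, alpha, params)
        assert abs(dp) < 1e-10 and abs(dr) < 1e-10
        assert ss.r_hat == alpha

    def test_positive_root_is_unique_nonnegative_branch(self):
        """The '-' branch of the steady-state quadratic is negative."""
        alpha, params = 0.45, REF
        b = (1 - alpha) * params.E_M - alpha
        disc = np.sqrt(b * b + 4 * alpha * (1 - alpha) * params.E_M * params.K)
        assert (b - disc) / (2 * alpha) < 0

    def test_nontrivial_steady_state_is_stable_over_random_environments(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            alpha = rng.uniform(0.02, 0.98)
            E_M = 10.0 ** rng.uniform(-1.5, 1.5)
            ss = steady_state_for_alpha(alpha, NondimParams(E_M=E_M, K=0.003))
            assert ss.stable, (alpha, E_M, ss.eigenvalues)

    def test_trivial_steady_state_is_unstable(self):
        ss = trivial_steady_state(REF)
        assert (ss.p_hat, ss.r_hat) == (0.0, 1.0)
        assert ss.mu_hat == 0.0
        dp, dr = rhs_nondim(0.0, 1.0, 1.0, REF)
        assert abs(dp) < 1e-12 and abs(dr) < 1e-12
        assert not ss.stable
        assert max(ev.real for ev in ss.eigenvalues) > 0

    def test_boundary_allocations_flagged_degenerate(self):
        with pytest.warns(UserWarning):
            ss1 = steady_state_for_alpha(1.0, REF)
        assert ss1.degenerate and (ss1.p_hat, ss1.r_hat) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            ss0 = steady_state_for_alpha(0.0, REF)
        assert ss0.degenerate and ss0.r_hat == 0.0 and ss0.mu_hat == 0.0


class TestOptimalAllocation:
    def test_unit_environment_optimum_is_one_half(self):
        opt = optimal_allocation_env(1.0, 0.003)
        assert opt.alpha == 0.5  # exact: (1+sqrt(K))/(2+2*sqrt(K))... = 1/2
        assert opt.mu_hat == pytest.approx(1 / (2 + 2 * np.sqrt(0.003)), rel=1e-15)

    def test_poor_medium_optimum_coordinates(self):
        opt = optimal_allocation_env(0.2, 0.003)
        assert opt.p_hat == pytest.approx(0.024, abs=5e-4)
        assert opt.r_hat == pytest.approx(0.18, abs=5e-3)

    def test_closed_form_matches_brute_force_grid_maximization(self):
        """Grid search over constant allocations confirms the closed form."""
        rng = np.random.default_rng(7)
        grid = np.linspace(1e-4, 1 - 1e-4, 10_000)
        for _ in range(20):
            E_M = 10.0 ** rng.uniform(-1, 1)
            K = 10.0 ** rng.uniform(-3, -1)
            params = NondimParams(E_M=E_M, K=K)
            # closed-form steady-state growth rate over the grid
            b = (1 - grid) * E_M - grid
            p = (b + np.sqrt(b * b + 4 * grid * (1 - grid) * E_M * K)) / (2 * grid)
            mu = grid * p / (K + p)
            alpha_best = grid[np.argmax(mu)]
            opt = optimal_allocation_env(E_M, K)
            assert abs(opt.alpha - alpha_best) <= grid[1] - grid[0]
            assert opt.mu_hat >= mu.max() - 1e-10

    def test_first_order_condition_at_optimal_precursor(self):
        """d(mu*)/dp* = 0 at p* = sqrt(K*E_M), checked numerically along the
        precursor nullcline."""
        for E_M in (0.2, 1.0, 5.0):
            K = 0.003
            p_opt = optimal_precursor(E_M, K)

            def mu_of_p(p):
                r = E_M * (K + p) / (E_M * (K + p) + p * (1 + p))
                return r * p / (K + p)

            h = 1e-6 * p_opt
            deriv = (mu_of_p(p_opt + h) - mu_of_p(p_opt - h)) / (2 * h)
            assert abs(deriv) < 1e-6

    def test_dimensional_route_agrees_with_nondimensional(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            e_M = rng.uniform(0.3, 10.0)
            k_R = rng.uniform(0.5, 6.0)
            K = rng.uniform(1e-3, 0.05)
            a_dim, mu_dim = optimal_allocation_dim(e_M, k_R, K)
            opt = optimal_allocation_env(e_M / k_R, K)
            assert a_dim == pytest.approx(opt.alpha, rel=1e-12)
            assert mu_dim == pytest.approx(k_R * opt.mu_hat, rel=1e-12)

    def test_fast_translation_limit_needs_no_machinery(self):
        # k_R -> infinity: optimal allocation tends to 0
        alphas = [optimal_allocation_dim(3.6, k, 0.003)[0] for k in (10, 1e3, 1e6)]
        assert alphas[0] > alphas[1] > alphas[2]
        assert alphas[2] < 2e-3

    def test_growth_law_curve_monotone_and_asymptotically_linear(self):
        e_grid = np.linspace(0.2, 40.0, 200)
        mus, alphas = [], []
        for e in e_grid:
            a, m = optimal_allocation_dim(e, 2.23, 0.003)
            alphas.append(a)
            mus.append(m)
        mus, alphas = np.array(mus), np.array(alphas)
        assert np.all(np.diff(mus) > 0) and np.all(np.diff(alphas) > 0)
        # quasi-linearity at high growth rates: a straight line explains the
        # upper half of the mu range almost perfectly
        upper = mus > 0.5 * (mus[0] + mus[-1])
        coeffs = np.polyfit(mus[upper], alphas[upper], 1)
        resid = alphas[upper] - np.polyval(coeffs, mus[upper])
        r2 = 1 - resid.var() / alphas[upper].var()
        assert r2 > 0.99


class TestOptimalCurve:
    def test_limits(self):
        assert optimal_curve_g(0.0, 0.003) == 0.0
        assert optimal_curve_g(1e9, 0.003) == pytest.approx(1.0, rel=1e-8)
        assert optimal_curve_g(0.0245, 0.003) == pytest.approx(0.18, abs=5e-3)

    def test_strictly_increasing_and_below_one(self):
        p = np.linspace(0.0, 10.0, 2000)
        g = optimal_curve_g(p, 0.003)
        assert np.all(np.diff(g) > 0)
        assert np.all(g < 1.0)

    def test_curve_consistent_with_environment_parameterization(self):
        """g evaluated at the optimal precursor level reproduces the optimal
        allocation of every environment (closed-form consistency)."""
        for E_M in np.geomspace(0.01, 100.0, 50):
            opt = optimal_allocation_env(E_M, 0.003)
            assert abs(optimal_curve_g(opt.p_hat, 0.003) - opt.alpha) < 1e-10
            assert abs(optimal_curve_mu(opt.p_hat, 0.003) - opt.mu_hat) < 1e-10


class TestForwardInvariance:
    @given(
        p0=st.floats(0.0, 2.0),
        r0=st.floats(0.0, 1.0),
        a=st.floats(0.0, 1.0),
        E_M=st.floats(0.1, 5.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_state_box_is_forward_invariant(self, p0, r0, a, E_M):
        """r_hat stays in [0, 1] and p_hat stays nonnegative along any
        constant-allocation trajectory."""
        params = NondimParams(E_M=E_M, K=0.003)
        sol = solve_ivp(
            lambda t, x: rhs_nondim(max(x[0], 0.0), min(max(x[1], 0.0), 1.0), a, params),
            (0, 10.0), [p0, r0], rtol=1e-9, atol=1e-12, dense_output=True,
        )
        ts = np.linspace(0, 10.0, 200)
        traj = sol.sol(ts)
        assert np.all(traj[0] >= -1e-9)
        assert np.all(traj[1] >= -1e-9) and np.all(traj[1] <= 1 + 1e-9)
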