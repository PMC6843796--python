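"""Chance-constrained DEA solver: reductions, oracles, certificates."""

import numpy as np
import pytest
from scipy.stats import norm

from haze_ccdea.ccdea import (
    DEFAULT_ALPHAS,
    CCDEAProblem,
    CCDEAResult,
    SolverOptions,
    _ScaledData,
    efficiency_profile,
    normal_quantile,
    solve_bcc_output,
    solve_ccdea,
)
from haze_ccdea.oracles import grid_oracle_theta
from haze_ccdea.panel import IndicatorPanel
from haze_ccdea.synthetic import random_panel


def bisect_normal_quantile(alpha, tol=1e-12):
    """Independent quantile via bisection on the normal CDF."""
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if norm.cdf(mid) < alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestNormalQuantile:
    def test_median_is_zero(self):
        assert normal_quantile(0.5) == 0.0

    def test_antisymmetry(self):
        assert normal_quantile(0.05) == pytest.approx(-normal_quantile(0.95), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.8, 0.95, 0.999])
    def test_against_bisection_oracle(self, alpha):
        assert normal_quantile(alpha) == pytest.approx(
            bisect_normal_quantile(alpha), abs=1e-10
        )

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.3])
    def test_domain(self, alpha):
        with pytest.raises(ValueError):
            normal_quantile(alpha)


class TestBCC:
    def test_undominated_unit_is_efficient(self, two_dmu_panel):
        res = solve_bcc_output(two_dmu_panel, 0)
        assert res.theta == pytest.approx(1.0, abs=1e-9)
        assert res.efficiency == pytest.approx(1.0, abs=1e-9)

    def test_dominated_unit_theta_two(self, two_dmu_panel):
        # vertex enumeration of the 2-point LP: best benchmark is lam=e_A,
        # theta = y_A / y_B = 2
        res = solve_bcc_output(two_dmu_panel, 1)
        assert res.theta == pytest.approx(2.0, abs=1e-9)
        assert res.efficiency == pytest.approx(0.5, abs=1e-9)
        assert res.lambdas[0] == pytest.approx(1.0, abs=1e-7)

    def test_single_unit_self_reference(self):
        z = np.zeros((1, 1))
        p = IndicatorPanel(("A",), ("x",), ("y",), [[3.0]], z, [[5.0]], z)
        assert solve_bcc_output(p, 0).theta == pytest.approx(1.0, abs=1e-9)

    def test_lambda_on_simplex(self):
        panel = random_panel(11)
        for o in range(panel.n_dmus):
            res = solve_bcc_output(panel, o)
            assert res.lambdas.sum() == pytest.approx(1.0, abs=1e-8)
            assert (res.lambdas >= -1e-10).all()


class TestReductions:
    @pytest.mark.parametrize("seed", range(5))
    def test_alpha_half_equals_bcc(self, seed):
        panel = random_panel(seed)
        for o in [0, 5, 12]:
            eff_cc = solve_ccdea(CCDEAProblem(panel, o, 0.5)).efficiency
            eff_lp = solve_bcc_output(panel, o).efficiency
            assert eff_cc == pytest.approx(eff_lp, abs=1e-6)

    def test_zero_sd_constant_over_alpha(self):
        panel = random_panel(3, cv=0.0)
        for o in [1, 7]:
            eff_lp = solve_bcc_output(panel, o).efficiency
            for res in efficiency_profile(panel, o):
                assert res.efficiency == pytest.approx(eff_lp, abs=1e-6)


class TestStochasticSolve:
    def test_identity_point_feasible_at_every_alpha(self):
        panel = random_panel(4)
        for o in [0, 6]:
            data = _ScaledData(panel, o)
            lam = np.zeros(panel.n_dmus)
            lam[o] = 1.0
            for alpha in DEFAULT_ALPHAS:
                q = normal_quantile(alpha)
                assert data.constraint_values(lam, 1.0, q).min() >= -1e-12

    def test_solution_certificates(self):
        panel = random_panel(8)
        for o in range(0, panel.n_dmus, 3):
            for alpha in (0.05, 0.8, 0.95):
                res = solve_ccdea(CCDEAProblem(panel, o, alpha))
                data = _ScaledData(panel, o)
                q = normal_quantile(alpha)
                assert data.constraint_values(res.lambdas, res.theta, q).min() >= -1e-7
                assert res.lambdas.sum() == pytest.approx(1.0, abs=1e-8)
                assert (res.lambdas >= -1e-10).all()
                assert 0.0 < res.efficiency <= 1.0 + 1e-12
                assert res.efficiency == pytest.approx(1.0 / res.theta)

    def test_profile_theta_monotone(self):
        panel = random_panel(9)
        for o in range(panel.n_dmus):
            thetas = [r.theta for r in efficiency_profile(panel, o)]
            assert all(b >= a - 1e-6 for a, b in zip(thetas, thetas[1:]))

    def test_alpha_brackets_bcc_on_noisy_panel(self):
        """Phi^-1 flips sign around 0.5: low alpha tightens the program
        below the BCC optimum, high alpha relaxes it above."""
        panel = random_panel(10, n_dmus=6, m_inputs=3, cv=0.15)
        for o in range(6):
            t_lo = solve_ccdea(CCDEAProblem(panel, o, 0.05)).theta
            t_bcc = solve_bcc_output(panel, o).theta
            t_hi = solve_ccdea(CCDEAProblem(panel, o, 0.95)).theta
            assert t_lo <= t_bcc + 1e-8
            assert t_hi >= t_bcc - 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(
            1000 + seed,
            n_dmus=int(rng.integers(2, 4)),
            m_inputs=int(rng.integers(1, 3)),
            s_outputs=1,
            cv=float(rng.uniform(0.05, 0.2)),
        )
        for o in range(panel.n_dmus):
            t_solver = solve_ccdea(CCDEAProblem(panel, o, 0.95)).theta
            t_grid = grid_oracle_theta(panel, o, 0.95, step=0.01)
            assert t_solver == pytest.approx(t_grid, abs=1e-2)
            # the lattice is a restriction: the solver may only be better
            assert t_solver >= t_grid - 1e-9

    def test_warm_start_never_hurts(self):
        panel = random_panel(12)
        o = 2
        base = solve_ccdea(CCDEAProblem(panel, o, 0.9))
        warm = solve_ccdea(CCDEAProblem(panel, o, 0.95), warm_start=base.lambdas)
        assert warm.theta >= base.theta - 1e-9

    def test_theta_capped_when_output_noise_dominates(self):
        # with q*sd_out > ybar the output constraint cannot bind: theta is
        # unbounded and the solver reports the cap
        z = np.zeros((1, 1))
        p = IndicatorPanel(("A",), ("x",), ("y",), [[1.0]], z, [[1.0]],
                           np.array([[2.0]]))
        res = solve_ccdea(CCDEAProblem(p, 0, 0.95), SolverOptions(theta_max=1e6))
        assert res.solver_status == "at-theta-bound"
        assert res.theta == pytest.approx(1e6)


class TestProfileAPI:
    def test_unsorted_alphas_rejected(self):
        panel = random_panel(2)
        with pytest.raises(ValueError, match="ascending"):
            efficiency_profile(panel, 0, [0.5, 0.1])

    def test_invalid_problem_parameters(self):
        panel = random_panel(2)
        with pytest.raises(ValueError):
            CCDEAProblem(panel, 0, 1.5)
        with pytest.raises(ValueError):
            CCDEAProblem(panel, 99, 0.5)

    def test_result_efficiency_flag(self):
        r = CCDEAResult(1.0, 1.0, np.array([1.0]), 0.9, "optimal")
        assert r.is_efficient()
        r2 = CCDEAResult(1.25, 0.8, np.array([1.0]), 0.9, "optimal")
        assert not r2.is_efficient()
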