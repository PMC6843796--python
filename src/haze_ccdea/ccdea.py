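"""Output-oriented VRS DEA with chance constraints on random inputs/outputs.

For the evaluated unit *o* the program is

    max theta
    s.t.  sum_j lam_j xbar_ij
            - z_a * sqrt( sum_{j!=o} lam_j^2 sI_ij^2 + (lam_o-1)^2 sI_io^2 )
            <= xbar_io                                    for each input i,
          sum_j lam_j ybar_rj
            + z_a * sqrt( sum_{j!=o} lam_j^2 sO_rj^2 + (lam_o-theta)^2 sO_ro^2 )
            >= theta * ybar_ro                            for each output r,
          sum_j lam_j = 1,   lam_j >= 0,

where ``z_a = Phi^-1(alpha)`` is the standard-normal quantile at the risk
level alpha and sI/sO are the cell standard deviations.  The stochastic
efficiency of unit *o* is ``1/theta``.  The identity point
(lam = e_o, theta = 1) is always feasible, so theta* >= 1 and the
efficiency lies in (0, 1].

Solution strategy (scipy only):

* alpha = 0.5, or every SD zero — the square-root terms vanish and the
  program *is* the output-oriented BCC linear program; solved exactly with
  HiGHS (:func:`scipy.optimize.linprog`).
* alpha < 0.5 (z_a < 0) — the constraints are second-order-cone shaped and
  the program is convex, so a local SQP solution is global; SLSQP is run
  from the identity and BCC starts.
* alpha > 0.5 (z_a > 0) — the program is nonconvex; SLSQP is run from the
  identity, the BCC solution, an optional warm start, and random simplex
  points (multistart), and the best certified-feasible point is kept.

Every SLSQP iterate is "polished": its lambda is projected back onto the
simplex and the exactly largest feasible theta for that lambda is
recomputed by bisection, so each reported solution satisfies the
constraints as printed (no smoothing residue) and carries a feasibility
certificate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from haze_ccdea.panel import IndicatorPanel

logger = logging.getLogger(__name__)

#: the risk-level sweep used throughout the analysis
DEFAULT_ALPHAS: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.8, 0.9, 0.95)

_SMOOTH_EPS = 1e-18  # under the square root, for differentiability at 0 only


def normal_quantile(alpha: float) -> float:
    """Standard-normal quantile Phi^-1(alpha), for alpha in (0, 1)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    return float(norm.ppf(alpha))


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs of the chance-constrained solve.

    ``n_starts`` random simplex starts are used in the nonconvex regime
    (alpha > 0.5); the loop stops early once ``stall_limit`` consecutive
    random starts fail to improve the incumbent.  ``eff_one_tol`` is the
    tolerance under which an efficiency is reported as exactly 1.
    """

    n_starts: int = 20
    seed: int = 0
    theta_max: float = 1e6
    feas_tol: float = 1e-7
    stall_limit: int = 6
    slsqp_maxiter: int = 200
    slsqp_ftol: float = 1e-12
    eff_one_tol: float = 1e-4


@dataclass(frozen=True)
class CCDEAProblem:
    panel: IndicatorPanel
    o: int
    alpha: float

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not 0 <= self.o < self.panel.n_dmus:
            raise ValueError(f"DMU index {self.o} out of range [0, {self.panel.n_dmus})")


@dataclass(frozen=True)
class CCDEAResult:
    theta: float
    efficiency: float
    lambdas: np.ndarray
    alpha: float | None
    solver_status: str
    n_starts_used: int = 1
    dmu_id: str | None = None

    def is_efficient(self, tol: float = 1e-4) -> bool:
        return self.efficiency >= 1.0 - tol


# ---------------------------------------------------------------------------
# scaled problem data


class _ScaledData:
    """Panel slice for one evaluated DMU, with unit-magnitude columns.

    The model is invariant to rescaling any variable together with its SD
    (the whole constraint row scales), so columns are divided by their
    largest mean to make absolute feasibility tolerances meaningful.
    """

    def __init__(self, panel: IndicatorPanel, o: int):
        self.n, self.m, self.s = panel.n_dmus, panel.n_inputs, panel.n_outputs
        self.o = o
        xscale = np.maximum(np.abs(panel.input_mean).max(axis=0), 1e-300)
        yscale = np.maximum(np.abs(panel.output_mean).max(axis=0), 1e-300)
        self.X = panel.input_mean / xscale      # (n, m)
        self.SX = panel.input_sd / xscale
        self.Y = panel.output_mean / yscale     # (n, s)
        self.SY = panel.output_sd / yscale
        self.stochastic = bool((self.SX > 0).any() or (self.SY > 0).any())

    def constraint_values(self, lam: np.ndarray, theta: float, q: float) -> np.ndarray:
        """Exact slacks (>= 0 means satisfied) of the m + s chance constraints."""
        lam_in = lam.copy()
        lam_in[self.o] -= 1.0
        v_in = (lam_in[:, None] ** 2 * self.SX**2).sum(axis=0)
        g_in = self.X[self.o] - lam @ self.X + q * np.sqrt(v_in)
        lam_out = lam.copy()
        lam_out[self.o] -= theta
        v_out = (lam_out[:, None] ** 2 * self.SY**2).sum(axis=0)
        g_out = lam @ self.Y + q * np.sqrt(v_out) - theta * self.Y[self.o]
        return np.concatenate([g_in, g_out])

    def is_feasible(self, lam: np.ndarray, theta: float, q: float, tol: float) -> bool:
        if abs(lam.sum() - 1.0) > 1e-8 or (lam < -1e-10).any():
            return False
        return bool(self.constraint_values(lam, theta, q).min() >= -tol)

    def max_theta_given_lambda(
        self, lam: np.ndarray, q: float, theta_max: float
    ) -> float | None:
        """Largest feasible theta in [1, theta_max] for a fixed lambda.

        Input constraints do not involve theta, so lambda is first screened
        against them.  Per output the slack h(theta) is convex for q > 0 and
        non-increasing for q <= 0 (theta >= 1 >= lam_o), so the feasible set
        within [1, theta_max] is an interval [1, a] or the whole box, and the
        endpoint is found by bisection.  Returns None when lambda is
        infeasible even at theta = 1.
        """
        lam_in = lam.copy()
        lam_in[self.o] -= 1.0
        v_in = (lam_in[:, None] ** 2 * self.SX**2).sum(axis=0)
        g_in = self.X[self.o] - lam @ self.X + q * np.sqrt(v_in)
        if g_in.min() < -1e-12:
            return None

        lam_sq = lam.copy()
        lam_sq[self.o] = 0.0
        c = (lam_sq[:, None] ** 2 * self.SY**2).sum(axis=0)  # (s,) j != o part
        a = lam @ self.Y                                     # (s,)
        lam_o = lam[self.o]
        best = theta_max
        for r in range(self.s):
            sd_o, y_o = self.SY[self.o, r], self.Y[self.o, r]

            def h(theta: float) -> float:
                return a[r] + q * np.sqrt(c[r] + (lam_o - theta) ** 2 * sd_o**2) - theta * y_o

            if h(1.0) < -1e-12:
                return None
            if h(best) >= 0.0:
                continue
            lo, hi = 1.0, best
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if h(mid) >= 0.0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo <= 1e-12 * max(1.0, lo):
                    break
            best = lo
        return float(best)


# ---------------------------------------------------------------------------
# deterministic LP (output-oriented BCC)


def _solve_lp(data: _ScaledData, theta_max: float) -> tuple[float, np.ndarray]:
    n, m, s, o = data.n, data.m, data.s, data.o
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.zeros((m + s, n + 1))
    b_ub = np.zeros(m + s)
    A_ub[:m, :n] = data.X.T
    b_ub[:m] = data.X[o]
    A_ub[m:, :n] = -data.Y.T
    A_ub[m:, n] = data.Y[o]
    A_eq = np.zeros((1, n + 1))
    A_eq[0, :n] = 1.0
    bounds = [(0.0, 1.0)] * n + [(1.0, theta_max)]
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0], bounds=bounds, method="highs"
    )
    if not res.success:
        raise RuntimeError(
            f"BCC LP failed for DMU {o}: {res.message} "
            "(the identity point lam=e_o, theta=1 should always be feasible)"
        )
    lam = np.clip(res.x[:n], 0.0, None)
    lam /= lam.sum()
    return float(res.x[n]), lam


def solve_bcc_output(panel: IndicatorPanel, o: int, theta_max: float = 1e6) -> CCDEAResult:
    """Deterministic output-oriented BCC model (all SD terms dropped).

    This is the exact reduction of the chance-constrained program at
    alpha = 0.5 or with all standard deviations zero, and serves as the LP
    oracle for the stochastic solver.
    """
    if not 0 <= o < panel.n_dmus:
        raise ValueError(f"DMU index {o} out of range")
    data = _ScaledData(panel, o)
    theta, lam = _solve_lp(data, theta_max)
    theta = max(theta, 1.0)
    return CCDEAResult(
        theta=theta,
        efficiency=1.0 / theta,
        lambdas=lam,
        alpha=None,
        solver_status="optimal",
        n_starts_used=1,
        dmu_id=panel.dmu_ids[o],
    )


# ---------------------------------------------------------------------------
# stochastic solve


def _slsqp_once(
    data: _ScaledData,
    q: float,
    lam0: np.ndarray,
    theta0: float,
    opts: SolverOptions,
) -> np.ndarray | None:
    """One SLSQP descent; returns the final lambda (unvalidated) or None."""
    n, o = data.n, data.o
    X, SX, Y, SY = data.X, data.SX, data.Y, data.SY

    def split(z):
        return z[:n], z[n]

    def ineq(z):
        lam, theta = split(z)
        lam_in = lam.copy()
        lam_in[o] -= 1.0
        v_in = (lam_in[:, None] ** 2 * SX**2).sum(axis=0) + _SMOOTH_EPS
        g_in = X[o] - lam @ X + q * np.sqrt(v_in)
        lam_out = lam.copy()
        lam_out[o] -= theta
        v_out = (lam_out[:, None] ** 2 * SY**2).sum(axis=0) + _SMOOTH_EPS
        g_out = lam @ Y + q * np.sqrt(v_out) - theta * Y[o]
        return np.concatenate([g_in, g_out])

    def ineq_jac(z):
        lam, theta = split(z)
        m, s = data.m, data.s
        J = np.zeros((m + s, n + 1))
        lam_in = lam.copy()
        lam_in[o] -= 1.0
        r_in = np.sqrt((lam_in[:, None] ** 2 * SX**2).sum(axis=0) + _SMOOTH_EPS)  # (m,)
        # d g_in_i / d lam_j = -X_ji + q * lam_in_j * SX_ji^2 / r_i
        J[:m, :n] = -X.T + q * (lam_in[None, :] * (SX**2).T) / r_in[:, None]
        lam_out = lam.copy()
        lam_out[o] -= theta
        r_out = np.sqrt((lam_out[:, None] ** 2 * SY**2).sum(axis=0) + _SMOOTH_EPS)  # (s,)
        J[m:, :n] = Y.T + q * (lam_out[None, :] * (SY**2).T) / r_out[:, None]
        # d g_out_r / d theta = q * (theta - lam_o) * SY_or^2 / r_r - Y_or
        J[m:, n] = q * (theta - lam[o]) * SY[o] ** 2 / r_out - Y[o]
        return J

    z0 = np.concatenate([lam0, [theta0]])
    try:
        res = optimize.minimize(
            lambda z: -z[n],
            z0,
            jac=lambda z: np.concatenate([np.zeros(n), [-1.0]]),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n + [(1.0, opts.theta_max)],
            constraints=[
                {"type": "ineq", "fun": ineq, "jac": ineq_jac},
                {
                    "type": "eq",
                    "fun": lambda z: np.array([z[:n].sum() - 1.0]),
                    "jac": lambda z: np.concatenate([np.ones(n), [0.0]])[None, :],
                },
            ],
            options={"maxiter": opts.slsqp_maxiter, "ftol": opts.slsqp_ftol},
        )
    except (ValueError, FloatingPointError):  # pragma: no cover - solver blow-up
        return None
    lam = np.clip(res.x[:n], 0.0, None)
    tot = lam.sum()
    if tot <= 0 or not np.isfinite(tot):
        return None
    return lam / tot


def solve_ccdea(
    problem: CCDEAProblem,
    options: SolverOptions | None = None,
    warm_start: np.ndarray | None = None,
) -> CCDEAResult:
    """Solve the chance-constrained program for one DMU at one risk level.

    ``warm_start`` may carry the lambda vector of a solve at a lower risk
    level; it is re-polished under the current quantile, which makes a
    sweep over increasing alpha structurally monotone in theta.
    """
    opts = options or SolverOptions()
    panel, o, alpha = problem.panel, problem.o, problem.alpha
    q = normal_quantile(alpha)
    data = _ScaledData(panel, o)

    # exact reductions: the square-root terms vanish
    if abs(q) < 1e-12 or not data.stochastic:
        theta, lam = _solve_lp(data, opts.theta_max)
        theta = max(theta, 1.0)
        return CCDEAResult(
            theta=theta,
            efficiency=1.0 / theta,
            lambdas=lam,
            alpha=alpha,
            solver_status="optimal",
            n_starts_used=1,
            dmu_id=panel.dmu_ids[o],
        )

    candidates: list[tuple[float, np.ndarray]] = []

    def consider(lam: np.ndarray | None) -> float | None:
        if lam is None:
            return None
        theta = data.max_theta_given_lambda(lam, q, opts.theta_max)
        if theta is None:
            return None
        candidates.append((theta, lam))
        return theta

    n = data.n
    e_o = np.zeros(n)
    e_o[o] = 1.0
    theta_bcc, lam_bcc = _solve_lp(data, opts.theta_max)
    if q < 0 and theta_bcc <= 1.0 + 1e-9:
        # the q<0 feasible set is contained in the BCC set and theta* >= 1
        # always holds, so theta* = 1 exactly; no NLP needed
        return CCDEAResult(
            theta=1.0,
            efficiency=1.0,
            lambdas=e_o,
            alpha=alpha,
            solver_status="optimal",
            n_starts_used=0,
            dmu_id=panel.dmu_ids[o],
        )
    consider(e_o)  # always feasible with theta >= 1
    consider(lam_bcc)
    deterministic_starts = [(e_o, 1.0), (lam_bcc, max(theta_bcc, 1.0))]
    if warm_start is not None:
        ws = np.clip(np.asarray(warm_start, dtype=float), 0.0, None)
        if ws.shape == (n,) and ws.sum() > 0:
            ws = ws / ws.sum()
            t_ws = consider(ws)
            if t_ws is not None:
                deterministic_starts.append((ws, t_ws))
    n_used = 0
    for lam0, theta0 in deterministic_starts:
        consider(_slsqp_once(data, q, lam0, theta0, opts))
        n_used += 1

    status = "optimal" if q < 0 else "multistart-best"
    if q > 0:
        # nonconvex regime: random simplex starts with early stopping
        rng = np.random.default_rng([opts.seed, o, int(round(alpha * 1000))])
        best = max((t for t, _ in candidates), default=1.0)
        stall = 0
        for _ in range(opts.n_starts):
            lam0 = rng.dirichlet(np.ones(n))
            t_direct = consider(lam0)
            t_slsqp = consider(_slsqp_once(data, q, lam0, max(t_direct or 1.0, 1.0), opts))
            n_used += 1
            new_best = max(best, t_direct or 1.0, t_slsqp or 1.0)
            if new_best > best + 1e-9:
                best, stall = new_best, 0
            else:
                stall += 1
                if stall >= opts.stall_limit:
                    break

    if not candidates:  # pragma: no cover - identity point always qualifies
        raise RuntimeError(f"no feasible candidate for DMU {o} at alpha={alpha}")
    best_theta = max(t for t, _ in candidates)
    # tie-break: minimal ||lambda||_2 among near-optimal candidates
    near = [(t, lam) for t, lam in candidates if t >= best_theta - 1e-9]
    theta, lam = min(near, key=lambda tl: float(np.linalg.norm(tl[1])))
    if not data.is_feasible(lam, theta, q, opts.feas_tol):  # pragma: no cover
        raise RuntimeError(
            f"certificate failure for DMU {o} at alpha={alpha}: "
            f"violation {-data.constraint_values(lam, theta, q).min():.3e}"
        )
    status = status if theta < opts.theta_max else "at-theta-bound"
    return CCDEAResult(
        theta=float(theta),
        efficiency=1.0 / float(theta),
        lambdas=lam,
        alpha=alpha,
        solver_status=status,
        n_starts_used=n_used,
        dmu_id=panel.dmu_ids[o],
    )


def efficiency_profile(
    panel: IndicatorPanel,
    o: int,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    options: SolverOptions | None = None,
) -> list[CCDEAResult]:
    """Solve one DMU across an ascending grid of risk levels.

    Each solve warm-starts from the previous level's weights; because the
    constraint sets are nested in the quantile, the resulting theta path is
    non-decreasing (the efficiency path non-increasing).  Solver errors at
    one level are recorded (status ``"error"``) without aborting the sweep.
    """
    alphas = list(alphas)
    if alphas != sorted(alphas):
        raise ValueError("alphas must be sorted ascending")
    opts = options or SolverOptions()
    results: list[CCDEAResult] = []
    warm = None
    for alpha in alphas:
        try:
            res = solve_ccdea(CCDEAProblem(panel, o, alpha), opts, warm_start=warm)
            warm = res.lambdas
        except RuntimeError as exc:  # keep sweeping
            logger.error("alpha=%s DMU %s failed: %s", alpha, o, exc)
            res = CCDEAResult(
                theta=float("nan"),
                efficiency=float("nan"),
                lambdas=np.full(panel.n_dmus, np.nan),
                alpha=alpha,
                solver_status="error",
                n_starts_used=0,
                dmu_id=panel.dmu_ids[o],
            )
        results.append(res)
    return results
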