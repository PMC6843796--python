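"""Brute-force reference solvers for small chance-constrained DEA instances.

These deliberately re-derive everything from the printed constraint system
with naive enumeration, independent of the production solver's internals,
so they can serve as correctness oracles in tests:

* :func:`grid_oracle_theta` — exhaustive search over a lattice on the
  lambda simplex, maximising theta per lattice point by 1-D bisection.
* :func:`bcc_vertex_oracle` — the 2-DMU output-oriented BCC optimum by
  direct enumeration of candidate vertices (1-D line search).

Only practical for a handful of DMUs; complexity grows as
``(1/step)^(n-1)``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from haze_ccdea.panel import IndicatorPanel


def _simplex_lattice(n: int, step: float):
    """All lambda vectors on the simplex with coordinates multiple of step."""
    k = round(1.0 / step)
    for comp in itertools.product(range(k + 1), repeat=n - 1):
        if sum(comp) <= k:
            rest = k - sum(comp)
            yield np.array(list(comp) + [rest], dtype=float) / k


def _max_theta_bisect(a, c, lam_o, sd_o, y_o, q, theta_cap):
    """Largest theta in [1, cap] with a + q*sqrt(c + (lam_o-theta)^2 sd_o^2) >= theta*y_o."""

    def h(theta):
        return a + q * math.sqrt(c + (lam_o - theta) ** 2 * sd_o**2) - theta * y_o

    if h(1.0) < 0.0:
        return None
    if h(theta_cap) >= 0.0:
        return theta_cap
    lo, hi = 1.0, theta_cap
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    return lo


def grid_oracle_theta(
    panel: IndicatorPanel,
    o: int,
    alpha: float,
    step: float = 0.01,
    theta_cap: float = 1e6,
) -> float:
    """Exhaustive-lattice optimum of the chance-constrained program.

    Enumerates every lambda on the simplex lattice of spacing ``step``,
    screens it against the input chance constraints, and maximises theta
    per lattice point by bisection on each output constraint.  Returns the
    best theta found (at least 1: the identity point is on every lattice).
    """
    from scipy.stats import norm

    q = float(norm.ppf(alpha))
    X, SX = panel.input_mean, panel.input_sd
    Y, SY = panel.output_mean, panel.output_sd
    n, m, s = panel.n_dmus, panel.n_inputs, panel.n_outputs
    best = 1.0
    for lam in _simplex_lattice(n, step):
        ok = True
        for i in range(m):
            v = sum(lam[j] ** 2 * SX[j, i] ** 2 for j in range(n) if j != o)
            v += (lam[o] - 1.0) ** 2 * SX[o, i] ** 2
            if lam @ X[:, i] - q * math.sqrt(v) > X[o, i] + 1e-12:
                ok = False
                break
        if not ok:
            continue
        theta_lam = theta_cap
        for r in range(s):
            c = sum(lam[j] ** 2 * SY[j, r] ** 2 for j in range(n) if j != o)
            t = _max_theta_bisect(
                float(lam @ Y[:, r]), c, float(lam[o]), float(SY[o, r]), float(Y[o, r]),
                q, theta_cap,
            )
            if t is None:
                theta_lam = None
                break
            theta_lam = min(theta_lam, t)
        if theta_lam is not None and theta_lam > best:
            best = theta_lam
    return float(best)


def bcc_vertex_oracle(panel: IndicatorPanel, o: int, step: float = 1e-4) -> float:
    """Dense line/lattice search optimum of the deterministic BCC program.

    Scans the lambda simplex at fine spacing and takes the best ratio
    theta = min_r (sum_j lam_j y_rj / y_ro) among input-feasible points.
    Intended for n <= 3 only.
    """
    X, Y = panel.input_mean, panel.output_mean
    n = panel.n_dmus
    best = 1.0
    for lam in _simplex_lattice(n, step if n == 2 else 0.01):
        if (lam @ X <= X[o] + 1e-12).all():
            theta = float((lam @ Y / Y[o]).min())
            best = max(best, theta)
    return best
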