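"""Mean-field model of hidden-unit responses under gain scaling.

The net input to a typical rectified-linear hidden unit, for input gain
``g``, is modeled as Gaussian with mean ``mu_* = g mu + mu_b`` and
variance ``sigma_*^2 = g^2 + sigma_b^2`` (the input SD sets the unit of
measurement, so sigma = 1).  The mean response is then the rectified-
Gaussian mean

    mu_bar(g) = [1 - Phi(-mu_*/sigma_*)] mu_* + phi(-mu_*/sigma_*) sigma_*

The sensitivity of the mean response to gain is summarized by the total
variation T_var = int_{gmin}^{gmax} |mu_bar'(g)| dg, which is minimized
over (mu, mu_b, sigma_b) subject to the mean response across gains being
a positive constant K (ruling out the silent solution).  The minimizer --
negative mean input, positive mean bias, large bias spread -- is the
parameter regime in which hidden activity sparsifies with gain while its
mean stays flat, the mechanism behind the sparsity code for posterior
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize
from scipy.stats import norm


@dataclass
class MeanFieldParams:
    """(mu, mu_b, sigma_b) in units of the input SD, plus the gain range."""

    mu: float
    mu_b: float
    sigma_b: float
    g_min: float = 1.0
    g_max: float = 10.0
    K: float = 2.0

    def __post_init__(self):
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be nonnegative")
        if not self.g_min < self.g_max:
            raise ValueError("need g_min < g_max")


def _moments(p: MeanFieldParams, g):
    g = np.asarray(g, float)
    mu_star = g * p.mu + p.mu_b
    sigma_star = np.sqrt(g ** 2 + p.sigma_b ** 2)
    return mu_star, sigma_star


def mean_response(p: MeanFieldParams, g):
    """Rectified-Gaussian mean response mu_bar(g).

    Returns ``(mu_bar, p_active, mean_active)``: the mean response, the
    probability of a non-zero response, and the mean of the suprathreshold
    responses (mu_bar / p_active), the two factors whose product stays
    constant at the sparsity optimum.
    """
    mu_star, sigma_star = _moments(p, g)
    z = mu_star / sigma_star
    p_active = norm.cdf(z)
    mu_bar = p_active * mu_star + norm.pdf(z) * sigma_star
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_active = np.where(p_active > 0, mu_bar / p_active, 0.0)
    return mu_bar, p_active, mean_active


def mean_response_prime(p: MeanFieldParams, g):
    """Analytic d mu_bar / d g.

    From d/dm E[x]_+ = Phi(m/s) and d/ds E[x]_+ = phi(m/s), with
    dm/dg = mu and ds/dg = g / s.
    """
    mu_star, sigma_star = _moments(p, g)
    z = mu_star / sigma_star
    return p.mu * norm.cdf(z) + norm.pdf(z) * np.asarray(g, float) / sigma_star


def t_var(p: MeanFieldParams, tol: float = 1e-9) -> float:
    """Total variation of mu_bar over the gain range (adaptive quadrature)."""
    val, err = quad(lambda g: abs(mean_response_prime(p, g)),
                    p.g_min, p.g_max, epsabs=tol, epsrel=tol, limit=200)
    if not np.isfinite(val):
        raise RuntimeError("quadrature failed")
    return float(val)


def mean_over_gains(p: MeanFieldParams) -> float:
    """Gain-averaged mean response (left side of the K constraint)."""
    val, _ = quad(lambda g: mean_response(p, g)[0], p.g_min, p.g_max,
                  epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(val / (p.g_max - p.g_min))


def solve_mu_b(mu: float, sigma_b: float, K: float,
               g_range: Tuple[float, float], lo: float = -50.0,
               hi: float = 50.0) -> float:
    """mu_b satisfying the mean-rate constraint at given (mu, sigma_b).

    The gain-averaged mean response is strictly increasing in mu_b, so a
    1-D root find on the constraint is exact; this keeps the search on
    the constraint manifold without penalty terms.
    """
    def f(mu_b):
        return mean_over_gains(MeanFieldParams(mu, mu_b, sigma_b, *g_range, K)) - K
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("constraint infeasible within mu_b bounds")
    return float(brentq(f, lo, hi, xtol=1e-10))


def constrained_tvar(mu: float, sigma_b: float, K: float,
                     g_range: Tuple[float, float]) -> Tuple[float, float]:
    """(T_var, mu_b) on the constraint manifold at (mu, sigma_b)."""
    mu_b = solve_mu_b(mu, sigma_b, K, g_range)
    return t_var(MeanFieldParams(mu, mu_b, sigma_b, *g_range, K)), mu_b


def minimize_tvar(g_range: Tuple[float, float] = (1.0, 10.0), K: float = 2.0,
                  mu_bounds: Tuple[float, float] = (-3.0, 1.0),
                  sigma_b_bounds: Tuple[float, float] = (0.1, 5.0),
                  n_grid: int = 9) -> MeanFieldParams:
    """Constrained minimization of T_var over (mu, mu_b, sigma_b).

    The constraint is enforced by solving for mu_b at each (mu, sigma_b);
    a coarse grid seeds Nelder-Mead polishing.  Returns the optimal
    :class:`MeanFieldParams` (with the constraint-satisfying mu_b).
    """
    mus = np.linspace(*mu_bounds, n_grid)
    sbs = np.linspace(*sigma_b_bounds, n_grid)
    best = (np.inf, None)
    for mu in mus:
        for sb in sbs:
            try:
                tv, _ = constrained_tvar(mu, sb, K, g_range)
            except ValueError:
                continue
            if tv < best[0]:
                best = (tv, (mu, sb))
    if best[1] is None:
        raise ValueError("constraint infeasible everywhere in the box")

    def obj(x):
        mu = np.clip(x[0], *mu_bounds)
        sb = np.clip(x[1], *sigma_b_bounds)
        try:
            return constrained_tvar(mu, sb, K, g_range)[0]
        except ValueError:
            return 1e6

    res = minimize(obj, np.asarray(best[1]), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400})
    mu = float(np.clip(res.x[0], *mu_bounds))
    sb = float(np.clip(res.x[1], *sigma_b_bounds))
    mu_b = solve_mu_b(mu, sb, K, g_range)
    return MeanFieldParams(mu, mu_b, sb, *g_range, K)


def tvar_landscape(g_range=(1.0, 10.0), K: float = 2.0,
                   mu_grid=None, mu_b_grid=None, sigma_b_grid=None):
    """log10 T_var over a (mu, mu_b, sigma_b) box (constraint ignored).

    Used to draw the sensitivity surface; rows are
    (mu, mu_b, sigma_b, log10 T_var).
    """
    mu_grid = np.linspace(-3, 1, 17) if mu_grid is None else mu_grid
    mu_b_grid = np.linspace(-1, 3, 17) if mu_b_grid is None else mu_b_grid
    sigma_b_grid = np.linspace(0.1, 5, 9) if sigma_b_grid is None else sigma_b_grid
    rows = []
    for mu in mu_grid:
        for mb in mu_b_grid:
            for sb in sigma_b_grid:
                tv = t_var(MeanFieldParams(mu, mb, sb, *g_range, K), tol=1e-7)
                rows.append((mu, mb, sb, np.log10(max(tv, 1e-300))))
    return np.asarray(rows)


def landscape_to_csv(path, **kw) -> None:
    """Write the sensitivity surface as CSV (mu, mu_b, sigma_b, log10_tvar)."""
    rows = tvar_landscape(**kw)
    header = "mu,mu_b,sigma_b,log10_tvar"
    np.savetxt(path, rows, delimiter=",", header=header, comments="")
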