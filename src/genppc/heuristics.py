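"""Non-probabilistic reference models and decision-boundary fitting.

Two families live here.  The first are the heuristic observers used as a
performance floor: in continuous tasks they estimate each cue optimally
(marginalizing the unknown gain) but combine the cue estimates with equal
weights regardless of reliability; in categorical tasks they apply the
optimal decision rule with every input's reliability replaced by a single
fitted common value.  The second family are the psychophysical
decision-boundary models for the categorization task -- FIX, LIN, QUAD,
OPT and OPT-P -- fitted to binary choices by maximum likelihood and
compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from . import ideal
from . import tasks as T
from .tasks import TuningSpec

FAMILIES = ("FIX", "LIN", "QUAD", "OPT", "OPT_P")
#: free parameters per family (boundary coefficients / prior odds + lapse)
N_PARAMS = {"FIX": 2, "LIN": 3, "QUAD": 4, "OPT": 1, "OPT_P": 2}


# ---------------------------------------------------------------------------
# heuristic observers


def equal_weight_estimate(r_list, specs, gains_list, task: str = "cc",
                          grid: Optional[ideal.GridSpec] = None) -> np.ndarray:
    """Equal-weight combination of per-cue optimal estimates.

    Each cue is decoded by its own gain-marginalized grid posterior mean;
    the cue estimates are then averaged with equal weights regardless of
    their reliabilities.
    """
    ests = []
    for r, spec, gains in zip(r_list, specs, gains_list):
        ps = ideal.grid_posterior_mean([r], task, [spec], [gains], grid)
        ests.append(ps.mean)
    return np.mean(ests, axis=0)


def equal_weight_kalman(counts: np.ndarray, spec: TuningSpec,
                        gamma: float = T.KF_GAMMA):
    """Kalman-filtering heuristic: average prediction and observation.

    The momentary stimulus estimate is the optimal (spike-weighted) one,
    but it is combined with the propagated previous estimate by a plain
    average instead of precision weighting; zero-count steps keep the
    prediction.
    """
    n, steps, _ = counts.shape
    est = np.zeros((n, steps))
    prev = np.zeros(n)
    for t in range(steps):
        r = counts[:, t].astype(float)
        total = r.sum(axis=1)
        mu_in = np.where(total > 0, r @ spec.preferred / np.where(total > 0, total, 1), 0.0)
        pred = (1 - gamma) * prev
        prev = np.where(total > 0, 0.5 * (mu_in + pred), pred)
        est[:, t] = prev
    return est


def common_reliability_bc(r: np.ndarray, spec: TuningSpec, g_common: float,
                          sigma1: float = T.BC_SIGMA1,
                          sigma2: float = T.BC_SIGMA2) -> np.ndarray:
    """Binary-categorization rule with a fixed assumed reliability.

    The internal measurement is the spike-weighted preferred stimulus; its
    assumed noise variance is the one implied by gain ``g_common`` instead
    of the trial's actual spike count.  Zero-count trials fall back to the
    prior (p = 0.5).
    """
    r = np.atleast_2d(r).astype(float)
    total = r.sum(axis=1)
    x = np.where(total > 0, r @ spec.preferred / np.where(total > 0, total, 1), 0.0)
    sig2 = float(T.bc_sigma_from_gain(spec, g_common)) ** 2
    q1 = sigma1 ** 2 + sig2
    q2 = sigma2 ** 2 + sig2
    d = 0.5 * np.log(q2 / q1) - 0.5 * x ** 2 * (1.0 / q1 - 1.0 / q2)
    p = ideal.llr_to_prob(d)
    return np.where(total > 0, p, 0.5)


def common_reliability_ci(r1: np.ndarray, r2: np.ndarray, spec: TuningSpec,
                          g_common: float, J_s: float) -> np.ndarray:
    """Causal-inference rule with both reliability terms fixed.

    The count-dependent reliabilities z12, z22 in the optimal rule are
    replaced by the expected reliability at gain ``g_common``; the
    stimulus-location statistics z11, z21 keep their trial values (scaled
    to the common reliability).
    """
    r1 = np.atleast_2d(r1).astype(float)
    r2 = np.atleast_2d(r2).astype(float)
    sf2 = spec.width ** 2
    grid = np.linspace(spec.preferred[0], spec.preferred[-1], 101)
    zbar = g_common * T.mean_rates(spec, grid, 1.0).sum(axis=1).mean() / sf2
    t1, t2 = r1.sum(axis=1), r2.sum(axis=1)
    x1 = np.where(t1 > 0, r1 @ spec.preferred / np.where(t1 > 0, t1, 1), 0.0)
    x2 = np.where(t2 > 0, r2 @ spec.preferred / np.where(t2 > 0, t2, 1), 0.0)
    z11, z21 = x1 * zbar, x2 * zbar
    z12 = z22 = np.full(len(r1), zbar)
    tot = z12 + z22 + J_s
    d = (z11 * z21 / tot
         - 0.5 * (z22 * z11 ** 2 / ((z12 + J_s) * tot)
                  + z12 * z21 ** 2 / ((z22 + J_s) * tot)
                  - np.log1p(z12 * z22 / (J_s * tot))))
    return ideal.llr_to_prob(d)


def fit_common_reliability(rule_fn, g_grid, posterior, prior,
                           metric_fn) -> float:
    """Pick the common reliability minimizing information loss on a batch.

    ``rule_fn(g)`` returns the heuristic class probabilities at assumed
    gain g; ``metric_fn(q, p, prior)`` scores them (fractional information
    loss).  Returns the best gain on the grid.
    """
    losses = [metric_fn(rule_fn(g), posterior, prior) for g in g_grid]
    return float(np.asarray(g_grid)[int(np.argmin(losses))])


# ---------------------------------------------------------------------------
# decision-boundary models (categorization psychophysics)


@dataclass
class BoundaryModel:
    """Decision boundary k(sigma) on the internal-measurement axis.

    FIX: k0; LIN: k0 + k1 sigma; QUAD: k0 + k1 sigma + k2 sigma^2;
    OPT: the Bayes boundary for the true class SDs; OPT_P: Bayes boundary
    with free prior log-odds.  All families share a lapse rate: the choice
    is a coin flip with probability ``2 * lapse`` (so lapse 0.5 is pure
    guessing).
    """

    family: str
    params: np.ndarray
    lapse: float = 0.0
    sigma1: float = T.BC_SIGMA1
    sigma2: float = T.BC_SIGMA2
    loglik: Optional[float] = None
    aic: Optional[float] = None

    def threshold(self, sigma) -> np.ndarray:
        sigma = np.asarray(sigma, float)
        p = self.params
        if self.family == "FIX":
            return np.broadcast_to(np.maximum(p[0], 0.0), sigma.shape)
        if self.family == "LIN":
            return np.maximum(p[0] + p[1] * sigma, 0.0)
        if self.family == "QUAD":
            return np.maximum(p[0] + p[1] * sigma + p[2] * sigma ** 2, 0.0)
        if self.family in ("OPT", "OPT_P"):
            log_odds = p[0] if self.family == "OPT_P" else 0.0
            q1 = self.sigma1 ** 2 + sigma ** 2
            q2 = self.sigma2 ** 2 + sigma ** 2
            num = np.log(q2 / q1) + 2.0 * log_odds
            den = 1.0 / q1 - 1.0 / q2
            return np.sqrt(np.maximum(num / den, 0.0))
        raise ValueError(f"unknown family {self.family!r}")

    def prob_choice1(self, s, sigma) -> np.ndarray:
        """P(report class 1 | stimulus, sensory noise), marginalizing the
        internal measurement."""
        s = np.asarray(s, float)
        sigma = np.asarray(sigma, float)
        k = self.threshold(sigma)
        p_in = norm.cdf((k - s) / sigma) - norm.cdf((-k - s) / sigma)
        return self.lapse + (1.0 - 2.0 * self.lapse) * p_in


def _nll(model: BoundaryModel, choices, s, sigma) -> float:
    p = np.clip(model.prob_choice1(s, sigma), 1e-9, 1 - 1e-9)
    c = np.asarray(choices, float)
    return float(-np.sum(c * np.log(p) + (1 - c) * np.log(1 - p)))


def fit_boundary_model(choices, s, sigma, family: str,
                       sigma1: float = T.BC_SIGMA1, sigma2: float = T.BC_SIGMA2,
                       n_starts: int = 10, seed: int = 0,
                       extra_starts: Sequence[np.ndarray] = ()) -> BoundaryModel:
    """Maximum-likelihood fit of a boundary family to binary choices.

    ``choices`` are 0/1 reports of class 1, ``s`` the true stimulus values
    and ``sigma`` the per-trial sensory noise.  Multi-start bounded
    quasi-Newton (L-BFGS-B) over the boundary coefficients and the lapse
    rate; AIC = 2k - 2 logL with k the family's free-parameter count.
    Raises if the best fit is non-identifiable (non-finite likelihood).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    n_coef = {"FIX": 1, "LIN": 2, "QUAD": 3, "OPT": 0, "OPT_P": 1}[family]
    k_scale = max(sigma1, 1.0)

    def build(theta):
        coef, lapse = theta[:n_coef], theta[-1]
        return BoundaryModel(family, np.asarray(coef), lapse, sigma1, sigma2)

    def obj(theta):
        return _nll(build(theta), choices, s, sigma)

    bounds = []
    if family in ("FIX", "LIN", "QUAD"):
        bounds.append((0.0, 10 * k_scale))
        for _ in range(n_coef - 1):
            bounds.append((-10 * k_scale, 10 * k_scale))
    elif family == "OPT_P":
        bounds.append((-5.0, 5.0))
    bounds.append((1e-4, 0.45))  # lapse

    starts = [np.array([rng.uniform(lo, hi) for lo, hi in bounds])
              for _ in range(n_starts)]
    starts += [np.clip(np.asarray(x, float), [lo for lo, _ in bounds],
                       [hi for _, hi in bounds]) for x in extra_starts
               if len(x) == len(bounds)]
    best = None
    for x0 in starts:
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("non-identifiable boundary fit (flat likelihood)")
    model = build(best.x)
    model.loglik = -float(best.fun)
    model.aic = 2 * N_PARAMS[family] - 2 * model.loglik
    return model


def compare_boundary_models(choices, s, sigma,
                            families: Sequence[str] = FAMILIES,
                            **kw) -> dict:
    """Fit every family and return {family: BoundaryModel}.

    Nested families (FIX within LIN within QUAD) are seeded with the
    simpler family's solution so the log-likelihood nesting holds.
    """
    out = {}
    for f in families:
        extra = []
        if f == "LIN" and "FIX" in out:
            m = out["FIX"]
            extra.append(np.array([m.params[0], 0.0, m.lapse]))
        if f == "QUAD":
            if "LIN" in out:
                m = out["LIN"]
                extra.append(np.array([m.params[0], m.params[1], 0.0, m.lapse]))
            elif "FIX" in out:
                m = out["FIX"]
                extra.append(np.array([m.params[0], 0.0, 0.0, m.lapse]))
        out[f] = fit_boundary_model(choices, s, sigma, f,
                                    extra_starts=extra, **kw)
    return out


def aic_winner(models: dict) -> str:
    return min(models, key=lambda f: models[f].aic)


def aic_table(models: dict, window: str = ""):
    """Model-comparison table: one row per family, AIC-sorted."""
    import pandas as pd
    rows = [{"window": window, "family": f, "loglik": m.loglik,
             "aic": m.aic, "lapse": m.lapse,
             "params": list(np.round(m.params, 4))}
            for f, m in models.items()]
    df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    df["winner"] = df["family"] == aic_winner(models)
    return df
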