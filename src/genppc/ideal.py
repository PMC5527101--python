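"""Bayes-optimal observers for the task battery.

Closed forms are available for several tasks under the dense-tiling
approximation (population-summed tuning independent of the stimulus):
the spike-weighted mean for cue combination, a two-equation natural-
parameter recursion for Kalman filtering, and log-likelihood-ratio
expressions for binary categorization, causal inference and visual
search.  Because the closed forms degrade when priors are informative or
populations small, posterior means and class posteriors are also computed
numerically on stimulus grids, marginalizing the unknown gain over the
regime's gain set; the grid versions are the reference ("optimal")
observers throughout the package, and the closed forms are validated
against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import tasks as T
from .tasks import TuningSpec, mean_rates


@dataclass
class GridSpec:
    """1-D stimulus grid: ``n`` points spanning ``[lo, hi]``."""

    lo: float
    hi: float
    n: int = 521

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)


@dataclass
class PosteriorSummary:
    """Posterior summaries per trial: mean/sd (continuous) or class probs."""

    kind: str
    mean: Optional[np.ndarray] = None
    sd: Optional[np.ndarray] = None
    class_probs: Optional[np.ndarray] = None
    llr: Optional[np.ndarray] = None


def summary_table(ps: "PosteriorSummary", task: str, gains=None):
    """PosteriorSummary as a tidy DataFrame (one row per trial)."""
    import pandas as pd
    if ps.kind == "continuous":
        df = pd.DataFrame({"mean": ps.mean, "sd": ps.sd})
    else:
        probs = np.atleast_2d(ps.class_probs)
        df = pd.DataFrame(probs, columns=[f"p_class{k+1}"
                                          for k in range(probs.shape[1])])
        if ps.llr is not None:
            df["llr"] = ps.llr
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(1, "task", task)
    if gains is not None:
        g = np.atleast_2d(np.asarray(gains))
        for i in range(g.shape[1]):
            df[f"g{i+1}"] = g[:, i]
    return df


def _gain_grid(gains) -> np.ndarray:
    """Discrete gain values to marginalize over (16-point grid for ranges)."""
    if isinstance(gains, tuple) and len(gains) == 2 and np.isscalar(gains[0]):
        return np.linspace(gains[0], gains[1], 16)
    return np.asarray(gains, float)


def log_evidence_1d(r: np.ndarray, spec: TuningSpec, gains,
                    grid: np.ndarray) -> np.ndarray:
    """log p(r | s) on a stimulus grid, marginalized over the gain set.

    ``r``: (n_trials, n_neurons) counts.  Returns (n_trials, G).  The
    Poisson likelihood under gain g is
    ``sum_j r_j log(g f_j(s)) - g sum_j f_j(s)`` up to r-only constants;
    the unknown gain is summed out with equal weight on each value.
    """
    r = np.atleast_2d(r)
    gset = _gain_grid(gains)
    f = mean_rates(spec, grid, 1.0)            # (G, m)
    logf = np.log(np.clip(f, 1e-300, None))
    A = r @ logf.T                             # (n, G)
    F = f.sum(axis=1)                          # (G,)
    nt = r.sum(axis=1)                         # (n,)
    # (n, G, n_gains) assembled implicitly via logsumexp accumulation
    out = np.full(A.shape, -np.inf)
    for g in gset:
        out = np.logaddexp(out, A + np.log(g) * nt[:, None] - g * F[None, :])
    return out - np.log(len(gset))


def _moments(logpost: np.ndarray, grid: np.ndarray):
    w = np.exp(logpost - logpost.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    mean = w @ grid
    var = (w * (grid[None, :] - mean[:, None]) ** 2).sum(axis=1)
    return mean, np.sqrt(var)


def grid_posterior_mean(r_list: Sequence[np.ndarray], task: str,
                        specs: Sequence[TuningSpec], gains_list,
                        grid: Optional[GridSpec] = None,
                        prior: str = "uniform") -> PosteriorSummary:
    """Numeric posterior mean/SD of the target variable.

    ``cc``/``cc3``: all populations encode the same s (uniform prior on the
    stimulus range); ``ct``: target is s1 + s2 with independent uniform
    priors (the posterior over the sum has mean/variance equal to the sums
    of the per-variable ones); a single-population list decodes one cue.
    ``gains_list`` gives, per population, the gain set to marginalize over
    (pass a one-element list for a known gain).
    """
    if grid is None:
        grid = GridSpec(-T.STIM_RANGE, T.STIM_RANGE)
    g = grid.points
    for spec in specs:
        if grid.step > spec.width / 4:
            raise ValueError("grid resolution coarser than sigma_f / 4")
    if task in ("cc", "cc3") or len(r_list) == 1:
        L = np.zeros((np.atleast_2d(r_list[0]).shape[0], grid.n))
        for r, spec, gains in zip(r_list, specs, gains_list):
            L = L + log_evidence_1d(r, spec, gains, g)
        mean, sd = _moments(L, g)
        return PosteriorSummary("continuous", mean=mean, sd=sd)
    if task == "ct":
        m1, s1 = _moments(log_evidence_1d(r_list[0], specs[0], gains_list[0], g), g)
        m2, s2 = _moments(log_evidence_1d(r_list[1], specs[1], gains_list[1], g), g)
        return PosteriorSummary("continuous", mean=m1 + m2,
                                sd=np.sqrt(s1 ** 2 + s2 ** 2))
    raise ValueError(f"unsupported task {task!r}")


# ---------------------------------------------------------------------------
# closed forms


def cc_linear_estimate(r1: np.ndarray, r2: Optional[np.ndarray],
                       preferred: np.ndarray):
    """Spike-weighted mean of preferred stimuli (flat-prior closed form).

    ``s_hat = phi' (r1 + r2) / 1' (r1 + r2)``.  Returns ``(estimate,
    defined)`` where ``defined`` flags trials with at least one spike; the
    estimate on undefined trials is 0 (callers substitute the prior mean).
    """
    r = np.atleast_2d(r1).astype(float)
    if r2 is not None:
        r = r + np.atleast_2d(r2)
    total = r.sum(axis=1)
    defined = total > 0
    est = np.zeros(len(r))
    est[defined] = (r[defined] @ preferred) / total[defined]
    return est, defined


def kalman_step(mu_prev, var_prev, r_t: np.ndarray, preferred: np.ndarray,
                sigma_f: float, gamma: float = T.KF_GAMMA,
                sigma_eta2: float = T.KF_SIGMA_ETA2):
    """One step of the natural-parameter posterior recursion.

    Prediction has mean ``(1-gamma) mu_prev`` and variance
    ``(1-gamma)^2 var_prev + sigma_eta2``; the momentary likelihood
    contributes precision ``1'r / sigma_f^2`` at the spike-weighted mean.
    Zero-count steps contribute no precision (pure prediction).
    """
    if np.any(np.asarray(var_prev) <= 0):
        raise ValueError("variance must be positive")
    r_t = np.atleast_2d(r_t).astype(float)
    total = r_t.sum(axis=1)
    pred_var = (1 - gamma) ** 2 * np.asarray(var_prev) + sigma_eta2
    pred_mu = (1 - gamma) * np.asarray(mu_prev)
    prec_in = total / sigma_f ** 2
    mu_in = np.where(total > 0, (r_t @ preferred) / np.where(total > 0, total, 1.0), 0.0)
    prec = 1.0 / pred_var + prec_in
    mu = (pred_mu / pred_var + mu_in * prec_in) / prec
    return mu, 1.0 / prec


def kalman_filter(counts: np.ndarray, spec: TuningSpec,
                  mu0: float = 0.0, var0: Optional[float] = None,
                  gamma: float = T.KF_GAMMA, sigma_eta2: float = T.KF_SIGMA_ETA2):
    """Run the recursion over (n, T, m) count sequences.

    The prior on the initial state defaults to a moment-matched Gaussian
    for the uniform start prior on the stimulus range.  Returns posterior
    means and variances, each (n, T).
    """
    n, steps, _ = counts.shape
    if var0 is None:
        var0 = T.STIM_RANGE ** 2 / 3.0
    mus = np.empty((n, steps))
    vars_ = np.empty((n, steps))
    mu, var = np.full(n, mu0, float), np.full(n, var0, float)
    for t in range(steps):
        mu, var = kalman_step(mu, var, counts[:, t], spec.preferred,
                              spec.width, gamma, sigma_eta2)
        mus[:, t], vars_[:, t] = mu, var
    return mus, vars_


def bc_llr(r: np.ndarray, preferred: np.ndarray, sigma_f: float,
           sigma1: float = T.BC_SIGMA1, sigma2: float = T.BC_SIGMA2) -> np.ndarray:
    """Closed-form class log-likelihood ratio for binary categorization.

    With ``e = phi / sigma_f^2`` and ``a = 1 / sigma_f^2``,
    ``d = 0.5 [ log((1 + s2^2 a'r)/(1 + s1^2 a'r))
              - (s2^2 - s1^2)(e'r)^2 / ((1 + s1^2 a'r)(1 + s2^2 a'r)) ]``.
    """
    r = np.atleast_2d(r).astype(float)
    ar = r.sum(axis=1) / sigma_f ** 2
    er = r @ preferred / sigma_f ** 2
    q1 = 1.0 + sigma1 ** 2 * ar
    q2 = 1.0 + sigma2 ** 2 * ar
    return 0.5 * (np.log(q2 / q1) - (sigma2 ** 2 - sigma1 ** 2) * er ** 2 / (q1 * q2))


def ci_llr(r1: np.ndarray, r2: np.ndarray, preferred: np.ndarray,
           sigma_f: float, J_s: float) -> np.ndarray:
    """Closed-form common-cause log-likelihood ratio for causal inference.

    Uses the sufficient statistics ``z11 = phi'r1/sigma_f^2``,
    ``z12 = 1'r1/sigma_f^2`` (and likewise for population 2) in the
    Gaussian-prior marginalization formula; both populations share the
    preferred-stimulus vector.
    """
    r1 = np.atleast_2d(r1).astype(float)
    r2 = np.atleast_2d(r2).astype(float)
    sf2 = sigma_f ** 2
    z11 = r1 @ preferred / sf2
    z12 = r1.sum(axis=1) / sf2
    z21 = r2 @ preferred / sf2
    z22 = r2.sum(axis=1) / sf2
    tot = z12 + z22 + J_s
    d = (z11 * z21 / tot
         - 0.5 * (z22 * z11 ** 2 / ((z12 + J_s) * tot)
                  + z12 * z21 ** 2 / ((z22 + J_s) * tot)
                  - np.log1p(z12 * z22 / (J_s * tot))))
    return d


def vs_llr(r_list: Sequence[np.ndarray], s_T: float, spec: TuningSpec,
           n_quad: int = 720):
    """Target-presence log-likelihood ratio for visual search.

    Per item ``d_i = h(s_T)'r_i - log (1/pi) int exp(h(s)'r_i) ds`` with
    kernel ``h = log f`` (von Mises tuning, positive baseline), the
    integral over [0, pi) by composite quadrature on ``n_quad`` points;
    items combine as ``d = log mean_i exp(d_i)``.  The input gain cancels
    from ``d_i`` exactly, so the expression holds with unknown gains.
    Returns ``(d, d_i)``.
    """
    if spec.baseline <= 0:
        raise ValueError("visual search kernel needs a positive baseline")
    sgrid = np.arange(n_quad) * np.pi / n_quad  # periodic -> midpoint-exact
    H = np.log(mean_rates(spec, sgrid, 1.0))    # (G, m)
    hT = np.log(mean_rates(spec, np.array([s_T]), 1.0))[0]
    ds = []
    for r in r_list:
        r = np.atleast_2d(r).astype(float)
        E = r @ H.T                              # (n, G)
        ds.append(r @ hT - (logsumexp(E, axis=1) - np.log(n_quad)))
    d_i = np.stack(ds, axis=1)                   # (n, N)
    d = logsumexp(d_i, axis=1) - np.log(d_i.shape[1])
    return d, d_i


def llr_to_prob(d: np.ndarray, prior_odds: float = 1.0) -> np.ndarray:
    """Posterior probability of the first hypothesis from its LLR.

    ``p = 1 / (1 + exp(-(d + log prior_odds)))``.
    """
    z = np.asarray(d, float) + np.log(prior_odds)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# numeric class posteriors (truth for the information-loss metric)


def bc_posterior(r: np.ndarray, spec: TuningSpec, gains,
                 sigma1: float = T.BC_SIGMA1, sigma2: float = T.BC_SIGMA2,
                 grid: Optional[GridSpec] = None) -> np.ndarray:
    """p(C = 1 | r) by numeric marginalization over stimulus and gain."""
    if grid is None:
        grid = GridSpec(-5 * sigma2, 5 * sigma2, 801)
    g = grid.points
    L = log_evidence_1d(np.atleast_2d(r), spec, gains, g)
    def class_logev(sig):
        logprior = -0.5 * (g / sig) ** 2 - np.log(sig)
        return logsumexp(L + logprior[None, :], axis=1)
    d = class_logev(sigma1) - class_logev(sigma2)
    return llr_to_prob(d)


def ci_posterior(r1: np.ndarray, r2: np.ndarray, spec: TuningSpec, gains,
                 sigma_s: float = T.CI_SIGMA_S,
                 grid: Optional[GridSpec] = None) -> np.ndarray:
    """p(common cause | r1, r2) by numeric marginalization.

    The separate-cause evidence factorizes over populations, so all
    integrals are one-dimensional.
    """
    if grid is None:
        lim = min(4 * sigma_s, np.max(np.abs(spec.preferred)) + 3 * spec.width)
        grid = GridSpec(-lim, lim, 801)
    g = grid.points
    logprior = -0.5 * (g / sigma_s) ** 2
    logprior = logprior - logsumexp(logprior)
    L1 = log_evidence_1d(np.atleast_2d(r1), spec, gains, g)
    L2 = log_evidence_1d(np.atleast_2d(r2), spec, gains, g)
    log_common = logsumexp(L1 + L2 + logprior[None, :], axis=1)
    log_sep = (logsumexp(L1 + logprior[None, :], axis=1)
               + logsumexp(L2 + logprior[None, :], axis=1))
    return llr_to_prob(log_common - log_sep)


def vs_posterior(r_list: Sequence[np.ndarray], s_T: float, spec: TuningSpec,
                 n_quad: int = 720) -> np.ndarray:
    """p(target present | display) via the per-item LLRs."""
    d, _ = vs_llr(r_list, s_T, spec, n_quad)
    return llr_to_prob(d)


def sd_posterior(r: np.ndarray, model: T.MixingModel, mc: int = 10_000,
                 seed: int = 0, conc_grid: Optional[int] = None) -> np.ndarray:
    """Per-source presence probabilities p(s_k = 1 | r) for demixing.

    Enumerates all 2^K source configurations; within each, concentrations
    of present sources are integrated out by fixed-seed Monte Carlo over
    U[conc_lo, conc_hi] (or a product grid of ``conc_grid`` points per
    source).  Returns (n_trials, K) marginals.
    """
    if conc_grid is None and mc < 100:
        raise ValueError("mc < 100: too few draws to integrate concentrations")
    r = np.atleast_2d(r).astype(float)
    K = model.n_sources
    rng = np.random.default_rng(seed)
    if conc_grid is not None:
        axes = [np.linspace(model.conc_lo, model.conc_hi, conc_grid)] * K
        mesh = np.meshgrid(*axes, indexing="ij")
        draws = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        draws = rng.uniform(model.conc_lo, model.conc_hi, size=(mc, K))
    n = len(r)
    log_ev = np.empty((n, 2 ** K))
    configs = np.array([[(m >> k) & 1 for k in range(K)]
                        for m in range(2 ** K)], float)
    for ci, cfg in enumerate(configs):
        lam = model.rates(np.tile(cfg, (len(draws), 1)), draws)  # (mc, d)
        loglam = np.log(lam)
        # log p(r | cfg, c) summed over neurons, then averaged over draws
        ll = r @ loglam.T - lam.sum(axis=1)[None, :]    # (n, mc)
        log_ev[:, ci] = logsumexp(ll, axis=1) - np.log(len(draws))
    prior = (model.source_prior ** configs.sum(1)
             * (1 - model.source_prior) ** (K - configs.sum(1)))
    logpost = log_ev + np.log(prior)[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    return np.stack([post[:, configs[:, k] == 1].sum(axis=1) for k in range(K)],
                    axis=1)
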