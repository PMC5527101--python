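"""Quantitative readouts: fractional errors, cue weights, sparsity, scaling.

Continuous tasks are scored by fractional RMSE,
``100 (RMSE_net - RMSE_opt) / RMSE_opt``, the percent excess root mean
squared error of the network over the posterior-mean estimator on the same
trials.  Categorical tasks are scored by fractional information loss, the
mean KL divergence from the true class posterior to the network's output
normalized by the mutual information between class and responses; the
normalizer is estimated on the same trials as the numerator, so a decoder
that always reports the prior loses exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import networks as nets
from . import tasks as T

EPS = 1e-12


@dataclass
class MetricReport:
    task: str
    regime: str
    seed: int
    value: float                       # fractional RMSE or info loss, %
    kind: str = "fractional_rmse"
    per_condition: dict = field(default_factory=dict)
    n_eval: int = 0


@dataclass
class SparsityStats:
    """Per-trial activity summaries and their correlations.

    ``r_sparsity`` is the Pearson correlation between the kurtosis of
    hidden activity (non-excess, m4/m2^2 across units within a trial) and
    the mean input response; ``r_mean`` the correlation between mean
    hidden and mean input response.  Parameter statistics are reported in
    units of the input-to-hidden weight SD, matching the mean-field
    parameterization.
    """

    mean_in: np.ndarray
    mean_hid: np.ndarray
    kurtosis: np.ndarray
    r_mean: float
    r_sparsity: float
    mean_W_over_sd: float
    mean_b_over_sd: float
    sd_b_over_sd: float
    n_dropped: int = 0


def report_frame(report: "MetricReport"):
    """MetricReport as a one-row DataFrame plus per-condition rows."""
    import pandas as pd
    rows = [{"task": report.task, "regime": report.regime,
             "seed": report.seed, "condition": "all",
             "kind": report.kind, "value": report.value,
             "n_eval": report.n_eval}]
    for cond, val in report.per_condition.items():
        rows.append({"task": report.task, "regime": report.regime,
                     "seed": report.seed, "condition": str(cond),
                     "kind": report.kind, "value": val,
                     "n_eval": report.n_eval})
    return pd.DataFrame(rows)


def sparsity_frame(stats: "SparsityStats"):
    """Per-trial sparsity table with the summary statistics attached."""
    import pandas as pd
    df = pd.DataFrame({"mean_in": stats.mean_in, "mean_hid": stats.mean_hid,
                       "kurtosis": stats.kurtosis})
    df.attrs.update(r_mean=stats.r_mean, r_sparsity=stats.r_sparsity,
                    mean_W_over_sd=stats.mean_W_over_sd,
                    mean_b_over_sd=stats.mean_b_over_sd,
                    sd_b_over_sd=stats.sd_b_over_sd)
    return df


def fractional_rmse(net_outputs, optimal_outputs, targets) -> float:
    """Percent excess RMSE of the network over the optimal estimator."""
    net_outputs = np.asarray(net_outputs, float).ravel()
    optimal_outputs = np.asarray(optimal_outputs, float).ravel()
    targets = np.asarray(targets, float).ravel()
    rmse_net = np.sqrt(np.mean((net_outputs - targets) ** 2))
    rmse_opt = np.sqrt(np.mean((optimal_outputs - targets) ** 2))
    if rmse_opt == 0:
        raise ZeroDivisionError("optimal estimator has zero RMSE")
    return 100.0 * (rmse_net - rmse_opt) / rmse_opt


def _as_dist(p) -> np.ndarray:
    """Binary probabilities (n,) -> (n, 2); vectors pass through."""
    p = np.asarray(p, float)
    if p.ndim == 1:
        return np.stack([p, 1.0 - p], axis=1)
    return p


def _kl_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    q = np.clip(q, EPS, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return t.sum(axis=1)


def fractional_information_loss(net_probs, posterior_probs, prior) -> float:
    """Information loss of a probabilistic decoder, in percent.

    ``100 E[KL(p(C|r) || q_net(C|r))] / E[KL(p(C|r) || p(C))]`` with both
    expectations over the same trials.  For multi-output tasks (stimulus
    demixing) the per-source losses are summed in numerator and
    normalizer.  Out-of-range decoder outputs are clipped at 1e-12.
    """
    net_probs = np.asarray(net_probs, float)
    posterior_probs = np.asarray(posterior_probs, float)
    if net_probs.ndim == 2 and net_probs.shape[1] > 1 and np.ndim(prior) == 0:
        num = den = 0.0
        for k in range(net_probs.shape[1]):
            p = _as_dist(posterior_probs[:, k])
            num += _kl_rows(p, _as_dist(net_probs[:, k])).mean()
            den += _kl_rows(p, _as_dist(np.full(len(p), float(prior)))).mean()
    else:
        p = _as_dist(posterior_probs)
        q = _as_dist(net_probs)
        prior_dist = _as_dist(np.full(len(p), float(prior))) \
            if np.ndim(prior) == 0 else _as_dist(np.broadcast_to(prior, p.shape))
        num = _kl_rows(p, q).mean()
        den = _kl_rows(p, prior_dist).mean()
    if den <= 0:
        raise ZeroDivisionError("zero mutual-information estimate")
    return 100.0 * num / den


def cue_weight(net_outputs, s1_opt, s2_opt) -> float:
    """Least-squares weight w in ``s_hat = w s1_opt + (1 - w) s2_opt``."""
    y = np.asarray(net_outputs, float) - np.asarray(s2_opt, float)
    x = np.asarray(s1_opt, float) - np.asarray(s2_opt, float)
    denom = np.sum(x * x)
    if denom < EPS:
        raise ZeroDivisionError("degenerate conflict trials: s1_opt == s2_opt")
    return float(np.sum(x * y) / denom)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def trial_kurtosis(H: np.ndarray) -> np.ndarray:
    """Non-excess Pearson kurtosis m4/m2^2 across units, per trial (row)."""
    c = H - H.mean(axis=1, keepdims=True)
    m2 = (c ** 2).mean(axis=1)
    m4 = (c ** 4).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m2 > 0, m4 / m2 ** 2, np.nan)


def sparsity_analysis(net: nets.NetworkSpec, batch: T.TrialBatch,
                      H: Optional[np.ndarray] = None) -> SparsityStats:
    """Sparsity/mean-rate correlates of the hidden representation.

    Computes, per evaluation trial, the mean input response, the mean
    hidden response and the kurtosis of hidden activity across units, then
    correlates the latter two with the former across trials.  Trials with
    constant hidden activity (undefined kurtosis) are dropped and counted.
    """
    if H is None:
        _, H = nets.forward(net, batch.inputs.astype(float))
    if H.ndim == 3:
        H = H[:, -1]
    mean_in = batch.inputs.reshape(batch.n, -1).mean(axis=1)
    mean_hid = H.mean(axis=1)
    kurt = trial_kurtosis(H)
    ok = np.isfinite(kurt)
    sd_W = net.W_in.std()
    return SparsityStats(
        mean_in=mean_in, mean_hid=mean_hid, kurtosis=kurt,
        r_mean=_pearson(mean_in, mean_hid),
        r_sparsity=_pearson(mean_in[ok], kurt[ok]),
        mean_W_over_sd=float(net.W_in.mean() / sd_W),
        mean_b_over_sd=float(net.b.mean() / sd_W),
        sd_b_over_sd=float(net.b.std() / sd_W),
        n_dropped=int((~ok).sum()),
    )


def tuning_curves(net: nets.NetworkSpec, task: str, s_grid: np.ndarray,
                  gains: Sequence[float], seed: int = 0,
                  n_avg: int = 200, variable: int = 0) -> np.ndarray:
    """Hidden-unit tuning to one stimulus variable, marginalizing the other.

    For a two-stimulus task, fixes variable ``variable`` at each grid
    value, draws the other stimulus and the Poisson noise ``n_avg`` times
    at each common gain, and averages the hidden responses.  Returns an
    array (n_gains, len(s_grid), n_hid).
    """
    spec = T.make_tuning(task if task in ("cc", "ct", "ci") else "cc")
    rng = np.random.default_rng(seed)
    out = np.empty((len(gains), len(s_grid), net.n_hid))
    for gi, g in enumerate(gains):
        for si, s in enumerate(s_grid):
            sv = np.full(n_avg, s)
            so = rng.uniform(-T.STIM_RANGE, T.STIM_RANGE, n_avg) \
                if task != "ci" else rng.normal(0, T.CI_SIGMA_S, n_avg)
            s1, s2 = (sv, so) if variable == 0 else (so, sv)
            r1 = rng.poisson(T.mean_rates(spec, s1, g))
            r2 = rng.poisson(T.mean_rates(spec, s2, g))
            X = np.concatenate([r1, r2], axis=1).astype(float)
            _, H = nets.forward(net, X)
            out[gi, si] = H.mean(axis=0)
    return out


def fwhm(curve: np.ndarray, s_grid: np.ndarray) -> float:
    """Full width at half maximum of a tuning curve (nan if flat)."""
    c = curve - curve.min()
    if c.max() <= 0:
        return np.nan
    above = c >= 0.5 * c.max()
    idx = np.where(above)[0]
    return float(s_grid[idx[-1]] - s_grid[idx[0]])


def min_hidden_scan(train_eval_fn, d_list: Sequence[int],
                    n_grid: Sequence[int], threshold: float,
                    seeds: Sequence[int]):
    """Minimum hidden-layer size n*(d) reaching a performance threshold.

    ``train_eval_fn(d, n, seed)`` must return the task metric (fractional
    RMSE or information loss, percent).  For each input size d, networks
    are trained at increasing n and n* is the smallest n whose median
    metric over seeds beats ``threshold``; unreachable thresholds are
    recorded as censored (n* = nan).  Returns ``(table, slope)`` where
    table rows are (d, n_star, median metric at n_star) and slope is the
    least-squares slope of log n* on log d over uncensored d.
    """
    rows = []
    for d in d_list:
        n_star, val = np.nan, np.nan
        for n in sorted(n_grid):
            med = float(np.median([train_eval_fn(d, n, s) for s in seeds]))
            if med <= threshold:
                n_star, val = n, med
                break
        rows.append((d, n_star, val))
    ok = [(d, n) for d, n, _ in rows if np.isfinite(n)]
    slope = np.nan
    if len(ok) >= 2:
        ld = np.log([d for d, _ in ok])
        ln = np.log([n for _, n in ok])
        slope = float(np.polyfit(ld, ln, 1)[0])
    return rows, slope
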