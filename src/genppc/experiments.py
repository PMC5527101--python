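"""Reproducible experiment recipes.

Each recipe wires trial generation, training, ideal observers and metrics
into one of the study's headline computations and returns plain dicts /
dataclasses; :func:`run` dispatches on an :class:`ExperimentConfig` and
writes CSV/JSON tables plus a manifest sufficient to re-run bit-identically.
All randomness flows from a single integer seed per recipe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import heuristics, ideal, metrics, networks as nets, tasks as T, training

EXPERIMENTS = ("fig2_performance", "fig3_modular", "fig4_generalization",
               "fig5_6_sparsity", "fig7_tuning", "fig8_controls",
               "fig9_learning", "fig10_scaling")


def _seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    return [int(s) % (2 ** 31) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def marginal_gain_sets(regime: T.GainRegime):
    """Per-population gain values to marginalize over at test time."""
    if regime.gain_sets is not None:
        gs = np.asarray(regime.gain_sets)
        return [np.unique(gs[:, i]) for i in range(gs.shape[1])]
    if regime.per_step_choices is not None:
        return [np.asarray(regime.per_step_choices)]
    return [(regime.lo, regime.hi)]


def optimal_continuous(batch: T.TrialBatch, test_regime: T.GainRegime,
                       grid: Optional[ideal.GridSpec] = None) -> np.ndarray:
    """Numeric posterior-mean estimates for a cc/cc3/ct batch."""
    gains = marginal_gain_sets(test_regime)
    if len(gains) == 1:
        gains = gains * len(batch.pops)
    ps = ideal.grid_posterior_mean(batch.split(), batch.task, batch.specs,
                                   gains, grid)
    return ps.mean


# ---------------------------------------------------------------------------
# few-shot generalization (cue combination at high gain)


#: Adam schedule for the few-shot experiment (learning rate, epochs)
CC_GEN_SCHEDULE = ((1e-3, 5_000), (1e-4, 4_000), (1e-5, 2_000))


def cc_generalization(seed: int, n_train: int = 50,
                      schedule=CC_GEN_SCHEDULE, n_hid: int = 200,
                      n_test: int = 6_000, interval: float = T.CONFLICT_L) -> dict:
    """Few-shot generalization: 50 training examples at gain pairs
    (5,5)/(25,25), tested on the full 25-pair high-gain grid.

    A training example is a fixed (stimulus, gain pair) condition; the
    Poisson population response is redrawn at every presentation, as for a
    subject repeatedly shown the same 50 stimulus conditions.  Stimuli
    live on the cue-conflict experiment's interval of length ``interval``
    (the protocol this experiment belongs to); cues are non-conflicting.
    Input weights are initialized at the usual scale divided by the
    largest training gain (matching the input magnitude), and biases at
    SD 1, the large-bias-spread regime the mean-field analysis favors.

    Returns the fractional RMSE against the gain-marginalized numeric
    posterior-mean estimator on the shared test set.
    """
    s_train, s_net, s_test = _seeds(seed, 3)
    spec = T.make_tuning("cc")
    lo, hi = -interval / 2, interval / 2
    rng = np.random.default_rng(s_train)
    s50 = rng.uniform(lo, hi, n_train)
    gp50 = np.array([[5.0, 5.0], [25.0, 25.0]])[rng.integers(2, size=n_train)]

    net = nets.init("feedforward", 2 * spec.n, n_hid, 1, seed=s_net)
    net.W_in /= 25.0
    net.b *= 10.0
    final_loss = np.nan
    for lr, n_epochs in schedule:
        opt_state = training.Adam(net.params(), lr)
        for _ in range(n_epochs):
            X = np.concatenate(
                [rng.poisson(T.mean_rates(spec, s50, gp50[:, 0])),
                 rng.poisson(T.mean_rates(spec, s50, gp50[:, 1]))],
                axis=1).astype(float)
            grads = nets.backward(net, X, s50[:, None], "mse")
            opt_state.step(net.params(), grads)
        final_loss = nets.loss_value(net, X, s50[:, None], "mse")

    rng_t = np.random.default_rng(s_test)
    s_te = rng_t.uniform(lo, hi, n_test)
    pairs = T.gain_conditions("cc", "high_g").gain_sets
    gp_te = pairs[rng_t.integers(len(pairs), size=n_test)]
    X_te = np.concatenate(
        [rng_t.poisson(T.mean_rates(spec, s_te, gp_te[:, 0])),
         rng_t.poisson(T.mean_rates(spec, s_te, gp_te[:, 1]))],
        axis=1).astype(float)
    grid = ideal.GridSpec(lo - 0.5, hi + 0.5, 101)
    opt = ideal.grid_posterior_mean(
        [X_te[:, :spec.n], X_te[:, spec.n:]], "cc", [spec] * 2,
        [np.array(T.CC_HIGH_GAINS)] * 2, grid).mean
    fr = metrics.fractional_rmse(y := nets.forward(net, X_te)[0].ravel(),
                                 opt, s_te)
    return {"fractional_rmse": fr, "n_train": n_train, "n_test": n_test,
            "final_train_loss": final_loss, "net": net,
            "test_inputs": X_te, "test_stimuli": s_te, "test_gains": gp_te,
            "optimal": opt, "outputs": y}


def cc_cue_weights(net: nets.NetworkSpec, seed: int, n_per_cond: int = 1000,
                   gains=T.CC_HIGH_GAINS) -> list:
    """Cue weights on conflict trials as a function of the gain ratio.

    For each (g1, g2) pair, generates conflict trials (offsets from the
    standard +-2l set), decodes each cue optimally at its known gain, and
    regresses the network output on the two single-cue estimates.
    Rows: (g1, g2, w_network, w_optimal).
    """
    spec = T.make_tuning("cc")
    rows = []
    rng_seeds = iter(_seeds(seed, len(gains) ** 2 * 8))
    for g1 in gains:
        for g2 in gains:
            regime = T.GainRegime("cc", "custom", np.array([[g1, g2]]))
            y_all, s1o_all, s2o_all = [], [], []
            for delta_l in (-0.5, 0.5, -1.0, 1.0):
                b = T.generate_trials("cc", regime, n_per_cond // 4,
                                      next(rng_seeds),
                                      conflict=delta_l * T.CONFLICT_L)
                r1, r2 = b.split()
                s1o = ideal.grid_posterior_mean([r1], "cc", [spec], [[g1]]).mean
                s2o = ideal.grid_posterior_mean([r2], "cc", [spec], [[g2]]).mean
                y, _ = nets.forward(net, b.inputs.astype(float))
                y_all.append(y.ravel())
                s1o_all.append(s1o)
                s2o_all.append(s2o)
            y = np.concatenate(y_all)
            s1o = np.concatenate(s1o_all)
            s2o = np.concatenate(s2o_all)
            w_net = metrics.cue_weight(y, s1o, s2o)
            prec1 = g1 / (g1 + g2)
            rows.append((g1, g2, w_net, prec1))
    return rows


# ---------------------------------------------------------------------------
# sparsity experiments


def sparsity_experiment(task: str, seed: int, n_batches: int = 30_000,
                        n_eval: int = 5000, n_hid: int = 200,
                        lr: float = 1e-3) -> dict:
    """Train a network on ct or ci (all-g) and analyze its hidden code.

    Returns the :class:`~genppc.metrics.SparsityStats` of the trained
    network on an evaluation set spanning all gain conditions, together
    with the task performance metric.
    """
    if task not in ("ct", "ci"):
        raise ValueError("sparsity experiment runs on ct or ci")
    s_net, s_train, s_eval = _seeds(seed, 3)
    d = 2 * T._POP_SIZE[task]
    output = "linear" if task == "ct" else "sigmoid"
    net = nets.init("feedforward", d, n_hid, 1, seed=s_net, output=output)
    cfg = training.TrainConfig(seed=s_train, n_batches=n_batches, lr=lr)
    net, hist = training.train(net, task, "all_g", cfg)
    regime = T.gain_conditions(task, "all_g")
    batch = T.generate_trials(task, regime, n_eval, s_eval)
    y, H = nets.forward(net, batch.inputs.astype(float))
    stats = metrics.sparsity_analysis(net, batch, H=H)
    if task == "ct":
        opt = optimal_continuous(batch, regime)
        perf = metrics.fractional_rmse(y.ravel(), opt, batch.target)
    else:
        r1, r2 = batch.split()
        post = ideal.ci_posterior(r1, r2, batch.specs[0],
                                  np.unique(regime.gain_sets))
        perf = metrics.fractional_information_loss(y.ravel(), post, 0.5)
    return {"stats": stats, "performance": perf, "net": net, "batch": batch,
            "history": hist}


def prior_decoder_loss(seed: int, n: int = 2000) -> float:
    """Information loss of the decoder that always reports the prior.

    Exactly 100% under the shared-sample estimator, for any categorical
    task; computed here on binary categorization (all-g).
    """
    batch = T.generate_trials("bc", "all_g", n, seed)
    post = ideal.bc_posterior(batch.inputs, batch.specs[0], T.BC_GAINS)
    q = np.full(n, 0.5)
    return metrics.fractional_information_loss(q, post, 0.5)


# ---------------------------------------------------------------------------
# architectural controls


def random_network_cc(seed: int, n_batches: int = 20_000, n_eval: int = 5000,
                      n_hid: int = 200, lr: float = 1e-3) -> float:
    """Fractional RMSE of a frozen-random-hidden-layer network on cc."""
    s_net, s_train, s_eval = _seeds(seed, 3)
    net = nets.init("random_ff", 2 * T._POP_SIZE["cc"], n_hid, 1, seed=s_net)
    cfg = training.TrainConfig(seed=s_train, n_batches=n_batches, lr=lr)
    net, _ = training.train(net, "cc", "all_g", cfg)
    regime = T.gain_conditions("cc", "all_g")
    batch = T.generate_trials("cc", regime, n_eval, s_eval)
    y, _ = nets.forward(net, batch.inputs.astype(float))
    opt = optimal_continuous(batch, regime)
    return metrics.fractional_rmse(y.ravel(), opt, batch.target)


def ei_control(seed: int, n_batches: int = 8000, n_eval: int = 3000,
               n_hid: int = 200, lr: float = 1e-3) -> dict:
    """Recurrent Dale-constrained EI network vs. feedforward on cc.

    The EI network sees the input spread over 10 time steps with the gain
    divided by 10 (equated input information) and is read out at the final
    step.  Returns both fractional RMSEs and their gap.
    """
    s_net, s_train, s_eval = _seeds(seed, 3)
    d = 2 * T._POP_SIZE["cc"]
    regime = T.gain_conditions("cc", "all_g")
    cfg = training.TrainConfig(seed=s_train, n_batches=n_batches, lr=lr)

    ff = nets.init("feedforward", d, n_hid, 1, seed=s_net)
    ff, _ = training.train(ff, "cc", "all_g", cfg)
    ei = nets.init("recurrent_ei", d, n_hid, 1, seed=s_net, T=10)
    ei, _ = training.train(ei, "cc", "all_g",
                           training.TrainConfig(seed=s_train,
                                                n_batches=n_batches, lr=lr))

    batch = T.generate_trials("cc", regime, n_eval, s_eval)
    opt = optimal_continuous(batch, regime)
    y_ff, _ = nets.forward(ff, batch.inputs.astype(float))
    rng = np.random.default_rng(s_eval + 1)
    Xr = training.recurrent_inputs(batch, ei.T, rng).astype(float)
    y_ei, _ = nets.forward(ei, Xr)
    fr_ff = metrics.fractional_rmse(y_ff.ravel(), opt, batch.target)
    fr_ei = metrics.fractional_rmse(y_ei[:, -1].ravel(), opt, batch.target)
    return {"fractional_rmse_ff": fr_ff, "fractional_rmse_ei": fr_ei,
            "gap": fr_ei - fr_ff}


# ---------------------------------------------------------------------------
# efficiency scan


def scaling_scan_ct(seed: int, d_list: Sequence[int] = (20, 60, 180),
                    n_grid: Sequence[int] = (2, 4, 8, 16, 32, 64),
                    n_seeds: int = 3, threshold: float = 10.0,
                    n_batches: int = 6000, n_eval: int = 2000):
    """n*(d) scan for coordinate transformation; returns (table, slope).

    For each total input count d (split over the two populations), trains
    networks of increasing hidden size and finds the smallest n whose
    median fractional RMSE over seeds beats the threshold.
    """
    base_seeds = _seeds(seed, n_seeds)
    regime = T.gain_conditions("ct", "all_g")

    def train_eval(d, n, s):
        pop = d // 2
        s_net, s_train, s_eval = _seeds(s + 7919 * d + 104729 * n, 3)
        net = nets.init("feedforward", d, n, 1, seed=s_net)
        # two-stage schedule: the final low-rate phase removes optimizer
        # jitter, which otherwise dominates at larger input counts
        for k, lr in enumerate((1e-3, 1e-4)):
            cfg = training.TrainConfig(seed=s_train + k, lr=lr,
                                       n_batches=n_batches if k == 0
                                       else n_batches // 2)
            net, _ = training.train(net, "ct", "all_g", cfg, pop_size=pop)
        batch = T.generate_trials("ct", regime, n_eval, s_eval, pop_size=pop)
        y, _ = nets.forward(net, batch.inputs.astype(float))
        opt = optimal_continuous(batch, regime)
        return metrics.fractional_rmse(y.ravel(), opt, batch.target)

    return metrics.min_hidden_scan(train_eval, d_list, n_grid, threshold,
                                   base_seeds)


# ---------------------------------------------------------------------------
# error-based learning and model comparison


def make_bc_stream(seed: int, n_trials: int) -> dict:
    """A binary-categorization trial stream with per-trial sensory sigma."""
    batch = T.generate_trials("bc", "all_g", n_trials, seed)
    sigma = T.bc_sigma_from_gain(batch.specs[0], batch.gains)
    return {"batch": batch, "sigma": sigma}


def synthetic_subject_curve(stream: dict, boundary: heuristics.BoundaryModel,
                            extra_sigma: float, lapse: float, seed: int):
    """Choices and cumulative accuracy of a synthetic boundary subject."""
    batch = stream["batch"]
    choices = T.simulate_subject(batch.stimuli, stream["sigma"] + extra_sigma,
                                 boundary, lapse, seed)
    correct = (choices == batch.target).astype(float)
    return choices, np.cumsum(correct) / np.arange(1, batch.n + 1)


def network_subject(stream: dict, seed: int, eta0: float = 0.2,
                    gamma_lr: float = 1e-3, n_hid: int = 200):
    """Online-SGD network run over the stream; returns choices and trace."""
    batch = stream["batch"]
    net = nets.init("feedforward", batch.inputs.shape[1], n_hid, 1,
                    seed=seed, output="sigmoid")
    choices, trace = training.train_online(net, batch.inputs.astype(float),
                                           batch.target[:, None], eta0,
                                           gamma_lr)
    return net, choices, trace


def winner_progression(stream: dict, n_subjects: int, seed: int,
                       windows=((0, 0.4), (0.6, 1.0)),
                       families=heuristics.FAMILIES, n_starts: int = 6,
                       **subject_kw):
    """AIC-winning boundary families in early vs. late training windows.

    Trains ``n_subjects`` online network subjects on the stream, fits the
    FIX/LIN/QUAD/OPT/OPT_P families to each subject's choices within each
    trial window, and tallies winners.  Returns a list (one dict per
    window) mapping family -> win count.
    """
    batch = stream["batch"]
    n = batch.n
    tallies = [dict.fromkeys(families, 0) for _ in windows]
    for subj in _seeds(seed, n_subjects):
        _, choices, _ = network_subject(stream, subj, **subject_kw)
        for wi, (lo, hi) in enumerate(windows):
            sl = slice(int(lo * n), int(hi * n))
            models = heuristics.compare_boundary_models(
                choices[sl], batch.stimuli[sl], stream["sigma"][sl],
                families=families, n_starts=n_starts)
            tallies[wi][heuristics.aic_winner(models)] += 1
    return tallies


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int = 0
    out_dir: Optional[str] = None
    overrides: dict = field(default_factory=dict)


def _manifest(cfg: ExperimentConfig) -> dict:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return {"experiment": cfg.experiment, "seed": cfg.seed,
            "overrides": cfg.overrides,
            "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def run(cfg: ExperimentConfig) -> dict:
    """Execute one experiment recipe; write tables + manifest if out_dir."""
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {cfg.experiment!r}")
    kw = cfg.overrides
    if cfg.experiment == "fig4_generalization":
        res = cc_generalization(cfg.seed, **kw)
        result = {"fractional_rmse": res["fractional_rmse"]}
    elif cfg.experiment == "fig5_6_sparsity":
        task = kw.pop("task", "ct")
        res = sparsity_experiment(task, cfg.seed, **kw)
        st = res["stats"]
        result = {"task": task, "r_sparsity": st.r_sparsity,
                  "r_mean": st.r_mean, "performance": res["performance"],
                  "mean_W_over_sd": st.mean_W_over_sd,
                  "mean_b_over_sd": st.mean_b_over_sd,
                  "sd_b_over_sd": st.sd_b_over_sd}
    elif cfg.experiment == "fig8_controls":
        result = {"random_ff_fractional_rmse":
                  random_network_cc(cfg.seed, **kw.get("random", {})),
                  **ei_control(cfg.seed, **kw.get("ei", {}))}
    elif cfg.experiment == "fig10_scaling":
        table, slope = scaling_scan_ct(cfg.seed, **kw)
        result = {"table": table, "slope": slope}
    elif cfg.experiment == "fig9_learning":
        stream = make_bc_stream(cfg.seed, kw.pop("n_trials", 4000))
        tallies = winner_progression(stream, kw.pop("n_subjects", 10),
                                     cfg.seed, **kw)
        result = {"early": tallies[0], "late": tallies[-1]}
    elif cfg.experiment == "fig3_modular":
        cfg1 = training.TrainConfig(seed=cfg.seed,
                                    n_batches=kw.get("n_batches", 8000))
        cfg2 = training.TrainConfig(seed=cfg.seed + 1,
                                    n_batches=kw.get("n_batches", 8000))
        net2, net1, _ = training.train_modular(kw.get("stage1", "cc"),
                                               cfg1, cfg2)
        regime = T.gain_conditions("cc3", "all_g")
        batch = T.generate_trials("cc3", regime, kw.get("n_eval", 3000),
                                  cfg.seed + 2)
        y, _ = nets.forward(net2, batch.inputs.astype(float))
        opt = optimal_continuous(batch, regime)
        result = {"fractional_rmse":
                  metrics.fractional_rmse(y.ravel(), opt, batch.target)}
    else:  # fig2_performance / fig7_tuning handled as smoke-scale tables
        result = _fig2_smoke(cfg.seed, **kw)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(_manifest(cfg), fh, indent=2)
        with open(out / "result.json", "w") as fh:
            json.dump({k: v for k, v in result.items()
                       if isinstance(v, (int, float, str, list, dict))},
                      fh, indent=2, default=float)
    return result


def _fig2_smoke(seed: int, n_batches: int = 2000, n_eval: int = 1000) -> dict:
    """Reduced-budget performance table over the continuous tasks."""
    out = {}
    for task in ("cc", "ct"):
        s_net, s_train, s_eval = _seeds(seed + hash(task) % 1000, 3)
        net = nets.init("feedforward", 2 * T._POP_SIZE[task], 200, 1,
                        seed=s_net)
        cfgt = training.TrainConfig(seed=s_train, n_batches=n_batches)
        net, _ = training.train(net, task, "all_g", cfgt)
        regime = T.gain_conditions(task, "all_g")
        batch = T.generate_trials(task, regime, n_eval, s_eval)
        y, _ = nets.forward(net, batch.inputs.astype(float))
        opt = optimal_continuous(batch, regime)
        out[task] = metrics.fractional_rmse(y.ravel(), opt, batch.target)
    return out


def load_behavior(path) -> "pandas.DataFrame":
    """Optional loader for externally supplied categorization choice data.

    Expects a CSV with columns ``trial, s, sigma, choice`` (stimulus value,
    per-trial sensory noise, 0/1 report of class 1).  Never required by
    the pipeline; raises a clear error on missing or malformed files.
    """
    import pandas as pd
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"behavioral data file {p} not found; this input is optional "
            "and no download is attempted")
    df = pd.read_csv(p)
    required = {"trial", "s", "sigma", "choice"}
    if not required.issubset(df.columns):
        raise ValueError(f"behavioral file must have columns {sorted(required)}")
    return df


def save_behavior(df, path) -> None:
    import pandas as pd  # noqa: F401
    df.to_csv(path, index=False)
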