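"""Optimization loops: Adam mini-batch training, online SGD, modular stages.

Networks are trained on freshly generated trials (streaming regime, the
default), or on a small fixed trial set for the few-shot generalization
experiment.  The online variant updates after every trial with a
``eta0 / (1 + gamma t)`` learning-rate schedule and records the pre-update
choice, mirroring how an animal subject would be scored during learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import networks as nets
from . import tasks as T

#: mini-batch sizes per task
BATCH_SIZES = {"bc": 10, "vs": 500}
DEFAULT_BATCH = 100


@dataclass
class TrainConfig:
    loss: Optional[str] = None          # default: mse (continuous) / xent
    batch_size: Optional[int] = None    # default: per-task standard size
    n_batches: int = 20_000
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    log_every: int = 200


class Adam:
    """Standard Adam accumulator over a dict of parameter arrays."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def default_loss(task: str) -> str:
    return "mse" if task in T.CONTINUOUS_TASKS else "cross_entropy"


def net_target(batch: T.TrialBatch) -> np.ndarray:
    """Supervised target array shaped for the network output."""
    t = np.asarray(batch.target, float)
    if batch.task == "kf":
        return t[:, :, None]
    if t.ndim == 1:
        return t[:, None]
    return t


def recurrent_inputs(batch: T.TrialBatch, steps: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Spread a feedforward batch over ``steps`` presentation steps.

    Total input information is equated with the single-shot presentation
    by drawing each step's counts at gain g / steps, so expected summed
    counts match the feedforward budget.
    """
    n = batch.n
    cols = []
    for i, sl in enumerate(batch.pops):
        spec = batch.specs[i]
        g = batch.gains[:, i] if batch.gains.ndim > 1 else batch.gains
        s = batch.stimuli[:, i] if batch.stimuli.ndim > 1 else batch.stimuli
        lam = T.mean_rates(spec, s, np.asarray(g, float) / steps)
        cols.append(rng.poisson(lam[:, None, :], size=(n, steps, spec.n)))
    return np.concatenate(cols, axis=2)


def train(net: nets.NetworkSpec, task: str, regime, cfg: TrainConfig,
          mixing: Optional[T.MixingModel] = None,
          tuning_overrides: Optional[dict] = None,
          pop_size: Optional[int] = None,
          callback: Optional[Callable] = None):
    """Seeded mini-batch Adam on freshly generated trials.

    Returns ``(net, history)`` where history maps batch index to training
    loss at the logging checkpoints.  EI networks are projected back onto
    the Dale constraint after every update.
    """
    loss = cfg.loss or default_loss(task)
    bs = cfg.batch_size or BATCH_SIZES.get(task, DEFAULT_BATCH)
    opt = Adam(net.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.eps)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(max(cfg.n_batches, 1))
    step_rng = np.random.default_rng(ss.spawn(1)[0])
    history = {"batch": [], "loss": []}
    recurrent_presentation = net.arch == "recurrent_ei" and task != "kf"
    for i in range(cfg.n_batches):
        batch = T.generate_trials(task, regime, bs, int(seeds[i]),
                                  tuning_overrides=tuning_overrides,
                                  pop_size=pop_size, mixing=mixing)
        X = batch.inputs.astype(float)
        if recurrent_presentation:
            X = recurrent_inputs(batch, net.T, step_rng).astype(float)
        tgt = net_target(batch)
        if net.arch in ("recurrent", "recurrent_ei") and net.loss_steps == "last":
            tgt = tgt[:, -1] if tgt.ndim == 3 else tgt
        grads = nets.backward(net, X, tgt, loss)
        opt.step(net.params(), grads)
        nets.project_dale(net)
        if i % cfg.log_every == 0 or i == cfg.n_batches - 1:
            history["batch"].append(i)
            history["loss"].append(nets.loss_value(net, X, tgt, loss))
            if not np.isfinite(history["loss"][-1]):
                raise FloatingPointError(f"training diverged at batch {i}")
            if callback is not None:
                callback(net, i)
    return net, history


def train_fixed(net: nets.NetworkSpec, X: np.ndarray, target: np.ndarray,
                cfg: TrainConfig, n_epochs: int = 2000,
                loss: str = "mse"):
    """Adam over a small fixed trial set (few-shot training regime).

    Each epoch shuffles the set into mini-batches of ``cfg.batch_size``
    (full batch if larger than the set).
    """
    opt = Adam(net.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.eps)
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    bs = min(cfg.batch_size or n, n)
    history = {"epoch": [], "loss": []}
    for e in range(n_epochs):
        order = rng.permutation(n)
        for k in range(0, n, bs):
            idx = order[k:k + bs]
            grads = nets.backward(net, X[idx], target[idx], loss)
            opt.step(net.params(), grads)
            nets.project_dale(net)
        if e % 50 == 0 or e == n_epochs - 1:
            history["epoch"].append(e)
            history["loss"].append(nets.loss_value(net, X, target, loss))
    return net, history


def train_online(net: nets.NetworkSpec, X: np.ndarray, target: np.ndarray,
                 eta0: float, gamma_lr: float, loss: str = "cross_entropy"):
    """Fully online vanilla SGD with learning rate ``eta0 / (1 + gamma t)``.

    Parameters update after every trial; the pre-update choice on each
    trial is recorded.  Returns ``(choices, cumulative_accuracy)`` where
    cumulative accuracy at trial t is the accuracy over trials 1..t.
    """
    n = len(X)
    choices = np.empty(n)
    tgt = np.asarray(target, float).reshape(n, -1)
    for t in range(n):
        x = X[t:t + 1]
        y, _ = nets.forward(net, x)
        choices[t] = float(y.ravel()[0] > 0.5)
        if eta0 > 0:
            grads = nets.backward(net, x, tgt[t:t + 1], loss)
            lr = eta0 / (1.0 + gamma_lr * t)
            for k, p in net.params().items():
                p -= lr * grads[k]
    correct = (choices == tgt[:, 0]).astype(float)
    cum_acc = np.cumsum(correct) / np.arange(1, n + 1)
    return choices, cum_acc


def fit_learning_curve(reference: np.ndarray, X: np.ndarray,
                       target: np.ndarray, net0: nets.NetworkSpec,
                       eta0_grid, gamma_grid, loss: str = "cross_entropy"):
    """Grid search of the online schedule against a reference learning curve.

    Minimizes the mean squared deviation between the network's cumulative
    accuracy trace and ``reference`` over the (eta0, gamma) grid, restarting
    from a copy of ``net0`` for each candidate.  Returns
    ``(best_eta0, best_gamma, best_dev, table)``.
    """
    if len(list(eta0_grid)) == 0 or len(list(gamma_grid)) == 0:
        raise ValueError("empty schedule grid")
    rows = []
    best = (None, None, np.inf)
    for eta0 in eta0_grid:
        for gam in gamma_grid:
            _, trace = train_online(net0.copy(), X, target, eta0, gam, loss)
            dev = float(np.mean((trace - reference) ** 2))
            rows.append((eta0, gam, dev))
            if dev < best[2]:
                best = (eta0, gam, dev)
    return best[0], best[1], best[2], rows


def train_modular(stage1_task: str, cfg1: TrainConfig, cfg2: TrainConfig,
                  n_hid_new: int = 200, n_hid: int = 200, seed: int = 0):
    """Freeze-and-extend protocol for the three-cue combination task.

    Stage 1 trains a feedforward network on cue combination or coordinate
    transformation (two input populations).  Its input-to-hidden weights
    and biases are then frozen and a third input population, feeding
    ``n_hid_new`` fresh hidden units, is bolted on; only the new hidden
    parameters and the readout are trained on the three-cue task.
    Returns ``(combined_net, stage1_net, history2)``.
    """
    if stage1_task not in ("cc", "ct"):
        raise ValueError("stage-1 task must be cc or ct")
    m = T._POP_SIZE["cc"]
    net1 = nets.init("feedforward", 2 * m, n_hid, 1, seed=seed)
    net1, hist1 = train(net1, stage1_task, "all_g", cfg1)
    if hist1["loss"][-1] > 0.9 * hist1["loss"][0]:
        import warnings
        warnings.warn("stage-1 network may not have converged")

    rng = np.random.default_rng(seed + 1)
    n_tot = n_hid + n_hid_new
    W_in = np.zeros((n_tot, 3 * m))
    W_in[:n_hid, :2 * m] = net1.W_in
    W_in[n_hid:, 2 * m:] = rng.normal(
        0.0, np.sqrt(2.0 / (n_hid_new + m)), (n_hid_new, m))
    b = np.concatenate([net1.b, rng.normal(0.0, 0.1, n_hid_new)])
    w_out = rng.normal(0.0, np.sqrt(2.0 / (1 + n_tot)), (1, n_tot))
    net2 = nets.NetworkSpec("feedforward", 3 * m, n_tot, 1, W_in, b, w_out,
                            np.zeros(1), output="linear")
    mask_W = np.zeros_like(W_in, dtype=bool)
    mask_W[n_hid:, 2 * m:] = True
    mask_b = np.zeros(n_tot, dtype=bool)
    mask_b[n_hid:] = True
    net2.trainable = {"W_in": mask_W, "b": mask_b, "w_out": True, "b_out": True}
    net2, hist2 = train(net2, "cc3", "all_g", cfg2)
    return net2, net1, hist2
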