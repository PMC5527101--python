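"""Generic ReLU networks: forward passes, exact gradients, initialization.

Architectures
-------------
``feedforward``   r_hid = [W_in r_in + b]_+ , linear or sigmoidal readout
``recurrent``     r_hid,t+1 = [W_in r_in,t+1 + W_rec r_hid,t + b]_+
``recurrent_ei``  recurrent with separate excitatory/inhibitory populations
                  (Dale's law, 4:1 E:I ratio in input and hidden layers)
``random_ff``     feedforward with frozen random hidden parameters; only
                  the readout is trainable

Gradients are computed analytically (backpropagation, and backpropagation
through time for the recurrent variants) for mean squared error,
cross-entropy and absolute-error losses.  Everything is plain NumPy;
parameters live in a :class:`NetworkSpec` dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ARCHS = ("feedforward", "recurrent", "recurrent_ei", "random_ff")
LOSSES = ("mse", "cross_entropy", "absolute_error")

PARAM_NAMES = ("W_in", "b", "W_rec", "w_out", "b_out")


@dataclass
class NetworkSpec:
    """Architecture, parameters and trainability flags of one network."""

    arch: str
    n_in: int
    n_hid: int
    n_out: int
    W_in: np.ndarray
    b: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    W_rec: Optional[np.ndarray] = None
    output: str = "linear"            # linear | sigmoid
    sign_in: Optional[np.ndarray] = None   # +-1 per input unit (EI only)
    sign_hid: Optional[np.ndarray] = None  # +-1 per hidden unit (EI only)
    trainable: dict = field(default_factory=dict)  # name -> bool or bool mask
    T: int = 10                        # presentation steps (EI networks)
    loss_steps: str = "last"           # recurrent loss on "all" or "last" step

    def params(self) -> dict:
        out = {"W_in": self.W_in, "b": self.b, "w_out": self.w_out,
               "b_out": self.b_out}
        if self.W_rec is not None:
            out["W_rec"] = self.W_rec
        return out

    def copy(self) -> "NetworkSpec":
        import copy
        return copy.deepcopy(self)


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init(arch: str, n_in: int, n_hid: int = 200, n_out: int = 1,
         seed: int = 0, output: str = "linear", T: int = 10,
         loss_steps: str = "last") -> NetworkSpec:
    """Seeded initialization.

    Weights are drawn at SD ``sqrt(2 / (fan_in + fan_out))`` and biases at
    SD 0.1 for every architecture (the scale used for the random-network
    controls).  ``random_ff`` freezes the hidden parameters; EI networks
    get 4:1 excitatory/inhibitory sign masks and magnitudes respecting
    them.
    """
    if arch not in ARCHS:
        raise ValueError(f"unknown architecture {arch!r}")
    rng = np.random.default_rng(seed)
    W_in = rng.normal(0.0, np.sqrt(2.0 / (n_hid + n_in)), (n_hid, n_in))
    b = rng.normal(0.0, 0.1, n_hid)
    w_out = rng.normal(0.0, np.sqrt(2.0 / (n_out + n_hid)), (n_out, n_hid))
    b_out = np.zeros(n_out)
    spec = NetworkSpec(arch, n_in, n_hid, n_out, W_in, b, w_out, b_out,
                       output=output, T=T, loss_steps=loss_steps)
    spec.trainable = {k: True for k in ("W_in", "b", "w_out", "b_out")}
    if arch in ("recurrent", "recurrent_ei"):
        spec.W_rec = rng.normal(0.0, np.sqrt(1.0 / n_hid), (n_hid, n_hid))
        spec.trainable["W_rec"] = True
    if arch == "random_ff":
        spec.trainable["W_in"] = False
        spec.trainable["b"] = False
    if arch == "recurrent_ei":
        spec.sign_in = _dale_mask(n_in)
        spec.sign_hid = _dale_mask(n_hid)
        np.fill_diagonal(spec.W_rec, 0.0)
        project_dale(spec, init=True)
        # Dale-signed magnitudes have a large positive leading eigenvalue;
        # rescale to spectral radius 0.8 so 10-step dynamics stay stable
        rho = np.max(np.abs(np.linalg.eigvals(spec.W_rec)))
        if rho > 0:
            spec.W_rec *= 0.8 / rho
    return spec


def _dale_mask(n: int) -> np.ndarray:
    """+1 for the first 80% (excitatory), -1 for the rest (inhibitory)."""
    n_exc = int(round(0.8 * n))
    return np.concatenate([np.ones(n_exc), -np.ones(n - n_exc)])


def project_dale(net: NetworkSpec, init: bool = False) -> None:
    """Project weights onto the Dale constraint (in place).

    Columns of W_in / W_rec carry the sign of the presynaptic unit; at
    initialization magnitudes are taken, afterwards violating entries are
    clipped to 0 (projected gradient).
    """
    if net.sign_in is None:
        return
    for W, sign in ((net.W_in, net.sign_in), (net.W_rec, net.sign_hid)):
        if W is None:
            continue
        if init:
            W[:] = np.abs(W) * sign[None, :]
        else:
            bad = W * sign[None, :] < 0
            W[bad] = 0.0


def forward(net: NetworkSpec, X: np.ndarray):
    """Forward pass.

    Feedforward: ``X`` is (n, d); returns ``(Y, H)`` with Y (n, n_out) and
    H (n, n_hid).  Recurrent: ``X`` is (n, T, d); returns ``(Y, H)`` with
    per-step outputs Y (n, T, n_out) and hidden states H (n, T, n_hid);
    the final-step output is ``Y[:, -1]``.
    """
    if net.arch in ("feedforward", "random_ff"):
        Z = X @ net.W_in.T + net.b
        H = np.maximum(Z, 0.0)
        Y = H @ net.w_out.T + net.b_out
    else:
        n, steps, _ = X.shape
        H = np.empty((n, steps, net.n_hid))
        h = np.zeros((n, net.n_hid))
        for t in range(steps):
            z = X[:, t] @ net.W_in.T + h @ net.W_rec.T + net.b
            h = np.maximum(z, 0.0)
            H[:, t] = h
        Y = H @ net.w_out.T + net.b_out
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("non-finite network output")
    if net.output == "sigmoid":
        Y = _sigmoid(Y)
    return Y, H


def _delta_out(Y, target, loss, output):
    """dLoss/d(pre-activation of output), averaged over the batch."""
    n = Y.shape[0] if Y.ndim == 2 else Y.shape[0] * Y.shape[1]
    target = np.asarray(target, float).reshape(Y.shape)
    if loss == "cross_entropy":
        if output != "sigmoid":
            raise ValueError("cross-entropy needs sigmoid outputs")
        return (Y - target) / n
    if output == "sigmoid":  # mse / absolute on sigmoid outputs
        base = (2.0 * (Y - target) if loss == "mse" else np.sign(Y - target))
        return base * Y * (1.0 - Y) / n
    if loss == "mse":
        return 2.0 * (Y - target) / n
    if loss == "absolute_error":
        return np.sign(Y - target) / n
    raise ValueError(f"unknown loss {loss!r}")


def loss_value(net: NetworkSpec, X, target, loss: str) -> float:
    Y, _ = forward(net, X)
    if net.arch in ("recurrent", "recurrent_ei") and net.loss_steps == "last":
        Y = Y[:, -1]
        target = np.asarray(target, float).reshape(Y.shape)
    else:
        target = np.asarray(target, float).reshape(Y.shape)
    if loss == "mse":
        per = (Y - target) ** 2
    elif loss == "absolute_error":
        per = np.abs(Y - target)
    elif loss == "cross_entropy":
        eps = 1e-12
        Yc = np.clip(Y, eps, 1 - eps)
        per = -(target * np.log(Yc) + (1 - target) * np.log(1 - Yc))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    # sum over output units, mean over trials (and time steps)
    return float(per.sum(axis=-1).mean())


def backward(net: NetworkSpec, X, target, loss: str) -> dict:
    """Exact batch-loss gradients for all trainable parameters.

    Frozen parameters get zero gradients.  The loss is the mean over
    trials (and, for ``loss_steps="all"``, over time steps) of the
    per-output summed loss.
    """
    grads = {k: np.zeros_like(v) for k, v in net.params().items()}
    if net.arch in ("feedforward", "random_ff"):
        Z = X @ net.W_in.T + net.b
        H = np.maximum(Z, 0.0)
        Ylin = H @ net.w_out.T + net.b_out
        Y = _sigmoid(Ylin) if net.output == "sigmoid" else Ylin
        dZo = _delta_out(Y, target, loss, net.output)       # (n, n_out)
        grads["w_out"] = dZo.T @ H
        grads["b_out"] = dZo.sum(axis=0)
        dH = (dZo @ net.w_out) * (Z > 0)
        grads["W_in"] = dH.T @ X
        grads["b"] = dH.sum(axis=0)
    else:
        n, steps, _ = X.shape
        H = np.empty((n, steps, net.n_hid))
        Zpos = np.empty((n, steps, net.n_hid), dtype=bool)
        h = np.zeros((n, net.n_hid))
        for t in range(steps):
            z = X[:, t] @ net.W_in.T + h @ net.W_rec.T + net.b
            h = np.maximum(z, 0.0)
            H[:, t], Zpos[:, t] = h, z > 0
        Ylin = H @ net.w_out.T + net.b_out
        Y = _sigmoid(Ylin) if net.output == "sigmoid" else Ylin
        if net.loss_steps == "last":
            dZo = np.zeros_like(Y)
            dZo[:, -1] = _delta_out(Y[:, -1], np.asarray(target, float)
                                    .reshape(Y[:, -1].shape), loss, net.output)
        else:
            dZo = _delta_out(Y, target, loss, net.output)
        grads["w_out"] = np.einsum("nto,nth->oh", dZo, H)
        grads["b_out"] = dZo.sum(axis=(0, 1))
        dh_next = np.zeros((n, net.n_hid))
        for t in range(steps - 1, -1, -1):
            dh = dZo[:, t] @ net.w_out + dh_next
            dz = dh * Zpos[:, t]
            grads["W_in"] += dz.T @ X[:, t]
            grads["b"] += dz.sum(axis=0)
            if t > 0:
                grads["W_rec"] += dz.T @ H[:, t - 1]
            dh_next = dz @ net.W_rec
    for name, flag in net.trainable.items():
        if name in grads and flag is False:
            grads[name][:] = 0.0
        elif name in grads and isinstance(flag, np.ndarray):
            grads[name][~flag] = 0.0
    return grads


def readout_normalized(net: NetworkSpec, X):
    """Activity-normalized linear readout ``w' r_hid / 1' r_hid``.

    Returns ``(estimate, defined)``; trials with silent hidden layers are
    flagged undefined.
    """
    if net.output != "linear":
        raise ValueError("normalized readout applies to continuous outputs")
    _, H = forward(net, X)
    if H.ndim == 3:
        H = H[:, -1]
    total = H.sum(axis=1)
    defined = total > 0
    est = np.zeros((len(H), net.n_out))
    est[defined] = (H[defined] @ net.w_out.T) / total[defined, None]
    return np.squeeze(est, -1) if net.n_out == 1 else est, defined
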