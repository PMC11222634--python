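"""Loss, surrogate-gradient BPTT, and the bi-level architecture update.

The network is input channels -> one SC-ML recurrent hidden layer -> a
purely feedforward LIF output layer. Classification targets are expressed at
the PSC level: the target class's desired output is the PSC of an
all-ones spike train, other classes are silenced, and the loss is the summed
squared PSC error over all timesteps,

    L = sum_t sum_o 1/2 (d_o[t] - a_o[t])^2 .

Backpropagation through time is exact over the full horizon (no truncation)
and is implemented here directly: the spike nonlinearity's derivative is a
pluggable surrogate kernel, and in ``spike_mode="smooth"`` the forward pass
itself uses the matching differentiable soft spike so that the computed
gradients are the exact gradients of that relaxed graph — which is how they
are validated against finite-difference and complex-step oracles.

The architecture logits are trained on validation data with a one-step
look-ahead (bi-level) update: the inner weight step is simulated, and the
second-order correction term is estimated with a symmetric finite difference
around weight perturbations along the validation weight gradient.

Adam is used for both weights and architecture logits, with a separate
(smaller) learning rate for the logits. Gradients are averaged over the
batch. Feedforward weights are He-Normal initialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import scml
from .scml import ArchParams, SCMLSpec

__all__ = [
    "target_psc",
    "loss",
    "Network",
    "Adam",
    "weight_step",
    "bilevel_arch_step",
]


def target_psc(label: int, n_out: int, T: int, tau_syn: float) -> np.ndarray:
    """Desired output-PSC sequence for one sample, shape (n_out, T).

    The target neuron should fire at every timestep; its desired PSC is the
    filtered all-ones train ``d[t] = tau_syn * (1 - (1 - 1/tau_syn)**(t+1))``
    (saturating at ``tau_syn``). Non-target rows are zero.
    """
    if not 0 <= label < n_out:
        raise ValueError(f"label {label} out of range for {n_out} outputs")
    d = np.zeros((n_out, T))
    t = np.arange(1, T + 1)
    d[label] = tau_syn * (1.0 - (1.0 - 1.0 / tau_syn) ** t)
    return d


def loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean-over-batch summed squared PSC error. Shapes (B, n_out, T)."""
    outputs = np.asarray(outputs)
    targets = np.asarray(targets)
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch {outputs.shape} vs {targets.shape}")
    B = outputs.shape[0]
    return 0.5 * np.sum((targets - outputs) ** 2) / B


@dataclass
class NetConfig:
    n_in: int
    n_hidden: int
    n_out: int
    motif_sizes: tuple[int, ...]
    T: int
    tau_m: float = 16.0
    tau_syn: float = 8.0
    v_th: float = 0.3
    tying: str = "shared_topology"
    w_inh: float = -2.0
    include_inter: bool = True
    recurrent: bool = True  # False = "no motif" ablation (feedforward SNN)
    surrogate_kind: str = "sigmoid"
    surrogate_width: float = 0.2


class Network:
    """An RSNN with one SC-ML hidden layer and a feedforward readout.

    Owns the trainable weights (``W_in``, ``W_exc``, ``W_out``), the
    architecture logits, and optionally a per-neuron intrinsic-parameter
    state adapted by the IP rule. A frozen discrete architecture may be
    substituted for the relaxed mixture via ``fixed_arch``.
    """

    def __init__(
        self,
        cfg: NetConfig,
        rng: np.random.Generator,
        fixed_arch: scml.DiscreteArchitecture | None = None,
    ):
        self.cfg = cfg
        self.spec = SCMLSpec(
            n=cfg.n_hidden,
            motif_sizes=cfg.motif_sizes,
            tying=cfg.tying,
            w_inh=cfg.w_inh,
            include_inter=cfg.include_inter,
        )
        self.masks = scml.build_candidate_masks(
            cfg.n_hidden, self.spec.motif_sizes, cfg.tying, cfg.include_inter
        )
        self.arch = ArchParams(self.spec, self.masks)
        self.fixed_arch = fixed_arch
        self.ip = None  # set by attach_ip()
        self.weights = self._init_weights(rng)

    def _init_weights(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.cfg
        w = {
            "W_in": rng.normal(0.0, np.sqrt(2.0 / cfg.n_in), (cfg.n_hidden, cfg.n_in)),
            "W_out": rng.normal(
                0.0, np.sqrt(2.0 / cfg.n_hidden), (cfg.n_out, cfg.n_hidden)
            ),
            "W_exc": np.full((cfg.n_hidden, cfg.n_hidden), self.spec.w_exc_init),
        }
        if self.fixed_arch is not None:
            # start exc slots of a committed architecture at the init value
            w["W_exc"] = np.where(
                self.fixed_arch.types == scml.EXC, self.spec.w_exc_init, 0.0
            )
        return w

    def reinitialize_weights(self, rng: np.random.Generator) -> None:
        """Fresh He-Normal feedforward weights, 0.2 excitatory recurrent."""
        self.weights = self._init_weights(rng)

    def attach_ip(self, ip_state) -> None:
        self.ip = ip_state

    # ------------------------------------------------------------------ fwd
    def _hidden_params(self):
        if self.ip is not None:
            return self.ip.tau, self.ip.R
        return self.cfg.tau_m, 1.0

    def recurrent_matrix(self):
        """(W_rec, cache) for the current architecture; cache is None when
        the architecture is discrete/absent."""
        if not self.cfg.recurrent:
            return None, None
        if self.fixed_arch is not None:
            W = np.where(
                self.fixed_arch.types == scml.EXC,
                self.weights["W_exc"],
                self.fixed_arch.W,
            )
            W = np.where(self.fixed_arch.types == scml.NONE, 0.0, W)
            return W, None
        return scml.effective_recurrent_matrix(self.arch, self.weights["W_exc"])

    def forward(
        self, X: np.ndarray, spike_mode: str = "hard", adapt_ip: bool = False
    ) -> dict:
        """Run the network on a spike batch X of shape (B, n_in, T)."""
        cfg = self.cfg
        B, n_in, T = X.shape
        k_s = 1.0 - 1.0 / cfg.tau_syn
        a_in = np.zeros((B, n_in, T))
        acc = np.zeros((B, n_in))
        for t in range(T):
            acc = k_s * acc + X[:, :, t]
            a_in[:, :, t] = acc
        drive_h = np.einsum("hj,bjt->bht", self.weights["W_in"], a_in)
        W_rec, rec_cache = self.recurrent_matrix()
        tau_h, R_h = self._hidden_params()
        hid = scml.recurrent_layer_forward(
            drive_h, W_rec, tau_h, cfg.tau_syn, R_h, cfg.v_th,
            spike_mode, cfg.surrogate_kind, cfg.surrogate_width,
            ip=self.ip if adapt_ip else None,
        )
        drive_o = np.einsum("oh,bht->bot", self.weights["W_out"], hid["a"])
        out = scml.recurrent_layer_forward(
            drive_o, None, cfg.tau_m, cfg.tau_syn, 1.0, cfg.v_th,
            spike_mode, cfg.surrogate_kind, cfg.surrogate_width,
        )
        return {
            "a_in": a_in, "hidden": hid, "out": out,
            "W_rec": W_rec, "rec_cache": rec_cache,
        }

    def targets(self, y: np.ndarray, T: int) -> np.ndarray:
        return np.stack(
            [target_psc(int(c), self.cfg.n_out, T, self.cfg.tau_syn) for c in y]
        )

    def batch_loss(self, fwd: dict, y: np.ndarray) -> float:
        d = self.targets(y, fwd["out"]["a"].shape[-1])
        return loss(fwd["out"]["a"], d)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class = argmax of per-class accumulated output PSC."""
        fwd = self.forward(X)
        return np.argmax(np.sum(fwd["out"]["a"].real, axis=-1), axis=-1)

    def accuracy(self, X: np.ndarray, y: np.ndarray, batch: int = 100) -> float:
        hits = 0
        for lo in range(0, len(y), batch):
            hits += int(np.sum(self.predict(X[lo : lo + batch]) == y[lo : lo + batch]))
        return hits / len(y)

    # ------------------------------------------------------------------ bwd
    def backward(self, fwd: dict, y: np.ndarray) -> dict:
        """Gradients of the batch loss w.r.t. weights and architecture logits.

        Zero-loss batches yield exactly zero gradients. Architecture-logit
        gradients are present only when the relaxed mixture is active.
        """
        B = fwd["a_in"].shape[0]
        T = fwd["out"]["a"].shape[-1]
        d = self.targets(y, T)
        g_a_out = (fwd["out"]["a"] - d) / B
        g_drive_o, _ = scml.recurrent_layer_backward(fwd["out"], g_a_out, None)
        gW_out = np.einsum("bot,bht->oh", g_drive_o, fwd["hidden"]["a"])
        g_a_h = np.einsum("bot,oh->bht", g_drive_o, self.weights["W_out"])
        g_drive_h, gW_rec = scml.recurrent_layer_backward(
            fwd["hidden"], g_a_h, fwd["W_rec"]
        )
        gW_in = np.einsum("bht,bjt->hj", g_drive_h, fwd["a_in"])
        grads = {"W_in": gW_in, "W_out": gW_out}
        if fwd["rec_cache"] is not None:
            arch_g = scml.recurrent_matrix_backward(
                self.arch, self.weights["W_exc"], gW_rec, fwd["rec_cache"]
            )
            grads["W_exc"] = arch_g["W_exc"]
            grads["alpha_v"] = arch_g["alpha_v"]
            grads["type_logits"] = arch_g["type_logits"]
        elif gW_rec is not None:
            # discrete architecture: only excitatory slots are trainable
            grads["W_exc"] = np.where(
                self.fixed_arch.types == scml.EXC, gW_rec, 0.0
            )
        return grads

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, spike_mode: str = "hard"
    ) -> tuple[float, dict]:
        fwd = self.forward(X, spike_mode=spike_mode)
        return self.batch_loss(fwd, y), self.backward(fwd, y)

    # ------------------------------------------------------- parameter views
    def weight_items(self):
        keys = ["W_in", "W_out"]
        if self.cfg.recurrent:
            keys.append("W_exc")
        return {k: self.weights[k] for k in keys}

    def arch_items(self):
        items = {}
        if self.arch.frozen_v is None:
            items["alpha_v"] = self.arch.alpha_v
        for v, tab in self.arch.type_logits.items():
            if self.arch.frozen_v is None or v == self.arch.frozen_v:
                items[f"types:{v}"] = tab
        return items

    def arch_grad_items(self, grads: dict):
        items = {}
        if self.arch.frozen_v is None:
            items["alpha_v"] = grads["alpha_v"]
        for v, g in grads["type_logits"].items():
            if self.arch.frozen_v is None or v == self.arch.frozen_v:
                items[f"types:{v}"] = g
        return items


class Adam:
    """Minimal Adam over a named dict of parameter arrays (updated in place)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = np.asarray(grads[k]).real
            if k not in self.m:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weight_step(net: Network, opt: Adam, X: np.ndarray, y: np.ndarray) -> float:
    """One Adam update of all trainable weights on a training batch."""
    L, grads = net.loss_and_grads(X, y)
    if not np.isfinite(L) or any(
        not np.all(np.isfinite(grads[k])) for k in net.weight_items()
    ):
        raise FloatingPointError("training diverged (non-finite loss or gradient)")
    opt.step(net.weight_items(), {k: grads[k] for k in net.weight_items()})
    return L


def _arch_grads_at(net: Network, X, y, weights: dict, spike_mode="hard") -> dict:
    """Architecture-logit gradients of the loss evaluated at given weights."""
    saved = {k: net.weights[k] for k in weights}
    net.weights.update(weights)
    try:
        _, grads = net.loss_and_grads(X, y, spike_mode=spike_mode)
    finally:
        net.weights.update(saved)
    return net.arch_grad_items(grads)


def bilevel_arch_step(
    net: Network,
    arch_opt: Adam,
    train_batch: tuple[np.ndarray, np.ndarray],
    valid_batch: tuple[np.ndarray, np.ndarray],
    eta: float,
    epsilon: float,
    spike_mode: str = "hard",
    apply: bool = True,
) -> dict:
    """One architecture-logit update with one-step look-ahead.

    Computes ``w' = w - eta * grad_w L_train``, takes the architecture
    gradient of the validation loss at ``w'``, and subtracts the
    second-order correction ``eta/(2 eps) * [g_a L_train(w+) - g_a
    L_train(w-)]`` with ``w+- = w +- eps * grad_w L_valid(w')``. With
    ``eta = 0`` this reduces exactly to the first-order validation gradient.
    Returns the gradient dict (and applies one optimizer step to the logits
    unless ``apply=False``).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(train_batch[1]) == 0 or len(valid_batch[1]) == 0:
        raise ValueError("train and validation batches must be nonempty")
    Xt, yt = train_batch
    Xv, yv = valid_batch
    wkeys = list(net.weight_items())
    if eta == 0.0:
        _, gv = net.loss_and_grads(Xv, yv, spike_mode=spike_mode)
        g_arch = net.arch_grad_items(gv)
    else:
        _, gt = net.loss_and_grads(Xt, yt, spike_mode=spike_mode)
        w_prime = {k: net.weights[k] - eta * gt[k].real for k in wkeys}
        saved = {k: net.weights[k] for k in wkeys}
        net.weights.update(w_prime)
        try:
            _, gv = net.loss_and_grads(Xv, yv, spike_mode=spike_mode)
        finally:
            net.weights.update(saved)
        g_arch = net.arch_grad_items(gv)
        gw_valid = {k: gv[k].real for k in wkeys}
        w_plus = {k: net.weights[k] + epsilon * gw_valid[k] for k in wkeys}
        w_minus = {k: net.weights[k] - epsilon * gw_valid[k] for k in wkeys}
        g_plus = _arch_grads_at(net, Xt, yt, w_plus, spike_mode)
        g_minus = _arch_grads_at(net, Xt, yt, w_minus, spike_mode)
        scale = eta / (2.0 * epsilon)
        g_arch = {
            k: g_arch[k] - scale * (g_plus[k] - g_minus[k]) for k in g_arch
        }
    if apply:
        arch_opt.step(net.arch_items(), g_arch)
    return g_arch
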