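"""Sparsely-Connected Recurrent Motif Layer (SC-ML).

A recurrent layer of ``n`` neurons tiled by identical motifs of size ``v``
(``v`` divides ``n``). Candidate recurrent connections are

* **intra-motif**: all directed pairs within a motif, self-loops included —
  ``(n/v) * v**2`` slots;
* **inter-motif**: mutual links between *corresponding* neurons of adjacent
  motifs (``r = i - v`` or ``r = i + v``, truncated at the layer edges) —
  ``2 * (n - v)`` slots.

Every candidate slot carries a categorical *connection type*: excitatory
(trainable positive weight, initialized to 0.2), inhibitory (fixed weight
-2.0), or non-existent (zero). Architecture search relaxes both the motif
size choice and the per-slot type choice with softmax distributions so that
the mixed recurrent drive

    drive_i = sum_v  a_v * sum_{r in I_i^v} sum_c  p_irc * w_irc * a_r[t-1]

is differentiable in the architecture logits. Discretization commits to the
argmax choices and yields a band-sparse recurrent weight matrix (zero outside
``|i - r| < 2v``).

With ``tying="shared_topology"`` (default) type logits are shared across
motifs by relative position ``(i mod v, r mod v)`` for intra slots and by
direction (+-v) for inter slots, so the searched object is one motif
template; ``tying="untied"`` gives every slot its own logits. Synaptic
weights are untied per connection in both modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

EXC, INH, NONE = 0, 1, 2
TYPE_CHARS = ("E", "I", "N")

__all__ = [
    "EXC",
    "INH",
    "NONE",
    "SCMLSpec",
    "CandidateMask",
    "ArchParams",
    "DiscreteArchitecture",
    "build_candidate_masks",
    "relax",
    "softmax",
    "softmax_backward",
    "effective_recurrent_matrix",
    "recurrent_matrix_backward",
    "recurrent_drive",
    "recurrent_layer_forward",
    "recurrent_layer_backward",
    "discretize",
    "parameter_count",
]


@dataclass
class SCMLSpec:
    """Static description of an SC-ML layer and its search space."""

    n: int
    motif_sizes: tuple[int, ...]
    tying: str = "shared_topology"
    w_exc_init: float = 0.2
    w_inh: float = -2.0
    include_inter: bool = True  # False = "no inter-motif connections" ablation

    def __post_init__(self) -> None:
        self.motif_sizes = tuple(int(v) for v in self.motif_sizes)
        if not self.motif_sizes:
            raise ValueError("need at least one motif-size option")
        for v in self.motif_sizes:
            if v < 1 or self.n % v != 0:
                raise ValueError(f"motif size {v} must divide layer size {self.n}")
        if self.tying not in ("shared_topology", "untied"):
            raise ValueError(f"unknown tying mode {self.tying!r}")
        if self.w_inh >= 0:
            raise ValueError("inhibitory weight must be negative")


@dataclass
class CandidateMask:
    """Candidate slots for one motif-size option.

    ``post``/``pre`` enumerate directed pairs (connection from ``pre`` into
    ``post``); ``slot_id`` maps each pair to a row of the type-logit table
    (shared across motifs when tied). Intra pairs come first, then inter.
    """

    v: int
    n: int
    post: np.ndarray
    pre: np.ndarray
    slot_id: np.ndarray
    is_inter: np.ndarray
    n_table_rows: int
    n_intra: int
    n_inter: int

    def intra_pairs(self) -> set[tuple[int, int]]:
        m = ~self.is_inter
        return set(zip(self.post[m].tolist(), self.pre[m].tolist()))

    def inter_pairs(self) -> set[tuple[int, int]]:
        m = self.is_inter
        return set(zip(self.post[m].tolist(), self.pre[m].tolist()))


def build_candidate_masks(
    n: int,
    motif_sizes: tuple[int, ...],
    tying: str = "shared_topology",
    include_inter: bool = True,
) -> dict[int, CandidateMask]:
    """Enumerate candidate intra/inter slots for every motif-size option."""
    masks: dict[int, CandidateMask] = {}
    for v in motif_sizes:
        if n % v != 0:
            raise ValueError(f"motif size {v} does not divide layer size {n}")
        idx = np.arange(n)
        # intra: all (i, r) with floor(i/v) == floor(r/v), self-loops included
        motif_of = idx // v
        post_i, pre_r = np.meshgrid(idx, idx, indexing="ij")
        intra = motif_of[post_i] == motif_of[pre_r]
        ip, ir = post_i[intra], pre_r[intra]
        # inter: corresponding neurons of adjacent motifs, r = i +- v
        if include_inter and n > v:
            left = idx[idx - v >= 0]
            right = idx[idx + v < n]
            ep = np.concatenate([left, right])
            er = np.concatenate([left - v, right + v])
            e_dir = np.concatenate([np.zeros(len(left), int), np.ones(len(right), int)])
        else:
            ep = er = e_dir = np.zeros(0, dtype=int)
        if tying == "shared_topology":
            intra_slot = (ip % v) * v + (ir % v)
            inter_slot = v * v + e_dir
            n_rows = v * v + (2 if len(ep) else 0)
        else:
            intra_slot = np.arange(len(ip))
            inter_slot = len(ip) + np.arange(len(ep))
            n_rows = len(ip) + len(ep)
        masks[v] = CandidateMask(
            v=v,
            n=n,
            post=np.concatenate([ip, ep]),
            pre=np.concatenate([ir, er]),
            slot_id=np.concatenate([intra_slot, inter_slot]),
            is_inter=np.concatenate(
                [np.zeros(len(ip), bool), np.ones(len(ep), bool)]
            ),
            n_table_rows=n_rows,
            n_intra=len(ip),
            n_inter=len(ep),
        )
    return masks


def parameter_count(spec: SCMLSpec, v: int) -> tuple[int, int, int]:
    """Candidate-slot counts ``(intra, inter, total)`` for motif size ``v``.

    ``total = (n/v) * v**2 + 2*(n - v)``, linear in ``n`` at fixed ``v`` —
    versus ``n**2`` for a fully connected recurrent layer.
    """
    if v not in spec.motif_sizes:
        raise ValueError(f"{v} is not a motif-size option of this layer")
    intra = (spec.n // v) * v * v
    inter = 2 * (spec.n - v) if spec.include_inter else 0
    return intra, inter, intra + inter


class ArchParams:
    """Raw architecture logits: motif-size logits plus per-slot type logits.

    Each motif-size option carries its own type-logit table (its slot layout
    depends on ``v``); after the motif size is frozen only that table keeps
    training.
    """

    def __init__(self, spec: SCMLSpec, masks: dict[int, CandidateMask]):
        self.spec = spec
        self.masks = masks
        self.alpha_v = np.zeros(len(spec.motif_sizes))
        self.type_logits: dict[int, np.ndarray] = {
            v: np.zeros((m.n_table_rows, 3)) for v, m in masks.items()
        }
        self.frozen_v: int | None = None

    def freeze_motif_size(self, v: int | None = None) -> int:
        """Irreversibly commit the motif size (argmax of the relaxed choice)."""
        if v is None:
            v = self.spec.motif_sizes[int(np.argmax(self.alpha_v))]
        if v not in self.spec.motif_sizes:
            raise ValueError(f"{v} not in motif-size options")
        self.frozen_v = int(v)
        return self.frozen_v

    def alpha_v_hat(self) -> np.ndarray:
        if self.frozen_v is not None:
            out = np.zeros(len(self.spec.motif_sizes))
            out[self.spec.motif_sizes.index(self.frozen_v)] = 1.0
            return out
        return softmax(self.alpha_v)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits.real, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, g_p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities ``p`` and dL/dp."""
    inner = np.sum(p * g_p, axis=axis, keepdims=True)
    return p * (g_p - inner)


def relax(arch: ArchParams) -> dict:
    """Softmax-relaxed selection probabilities for all architecture choices."""
    for v, tab in arch.type_logits.items():
        # -inf is a legal logit (exactly-excluded option, used by one-hot
        # architectures); NaN and +inf are not
        if np.any(np.isnan(tab.real)) or np.any(tab.real == np.inf):
            raise ValueError("architecture logits must not be NaN or +inf")
    return {
        "alpha_v": arch.alpha_v_hat(),
        "types": {v: softmax(tab) for v, tab in arch.type_logits.items()},
    }


def effective_recurrent_matrix(
    arch: ArchParams, W_exc: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Mixture recurrent weight matrix under the relaxed architecture.

    ``W[i, r] = sum_v  a_v * (p_exc * W_exc[i, r] + p_inh * w_inh)`` over the
    candidate slots of each motif-size option. Returns the dense matrix and a
    cache for :func:`recurrent_matrix_backward`.
    """
    spec = arch.spec
    relaxed = relax(arch)
    dtype = np.result_type(W_exc, arch.alpha_v, *arch.type_logits.values())
    W = np.zeros((spec.n, spec.n), dtype=dtype)
    per_v = {}
    a_hat = relaxed["alpha_v"]
    for k, v in enumerate(spec.motif_sizes):
        m = arch.masks[v]
        P_tab = relaxed["types"][v]
        P = P_tab[m.slot_id]  # (S, 3)
        w_slot = P[:, EXC] * W_exc[m.post, m.pre] + P[:, INH] * spec.w_inh
        np.add.at(W, (m.post, m.pre), a_hat[k] * w_slot)
        per_v[v] = {"P_tab": P_tab, "w_slot": w_slot, "a_hat": a_hat[k]}
    return W, {"per_v": per_v, "alpha_v_hat": a_hat}


def recurrent_matrix_backward(
    arch: ArchParams, W_exc: np.ndarray, gW: np.ndarray, cache: dict
) -> dict:
    """Chain dL/dW_rec to excitatory weights and architecture logits.

    Returns ``{"W_exc": ..., "alpha_v": ..., "type_logits": {v: ...}}``; the
    motif-size gradient is zero once the size is frozen.
    """
    spec = arch.spec
    gW_exc = np.zeros_like(W_exc, dtype=gW.dtype)
    g_alpha_hat = np.zeros(len(spec.motif_sizes), dtype=gW.dtype)
    g_tables = {}
    for k, v in enumerate(spec.motif_sizes):
        m = arch.masks[v]
        cv = cache["per_v"][v]
        P_tab = cv["P_tab"]
        P = P_tab[m.slot_id]
        g_slot = gW[m.post, m.pre]  # dL/dW at candidate slots
        g_alpha_hat[k] = np.sum(g_slot * cv["w_slot"])
        a_k = cv["a_hat"]
        np.add.at(gW_exc, (m.post, m.pre), a_k * P[:, EXC] * g_slot)
        gP = np.zeros((len(g_slot), 3), dtype=gW.dtype)
        gP[:, EXC] = a_k * g_slot * W_exc[m.post, m.pre]
        gP[:, INH] = a_k * g_slot * spec.w_inh
        g_tab = np.zeros_like(P_tab, dtype=gW.dtype)
        np.add.at(g_tab, m.slot_id, gP)
        g_tables[v] = softmax_backward(P_tab, g_tab)
    if arch.frozen_v is not None:
        g_alpha_v = np.zeros_like(arch.alpha_v)
    else:
        g_alpha_v = softmax_backward(cache["alpha_v_hat"], g_alpha_hat)
    return {"W_exc": gW_exc, "alpha_v": g_alpha_v, "type_logits": g_tables}


def recurrent_drive(
    arch: ArchParams, W_exc: np.ndarray, a_prev: np.ndarray
) -> np.ndarray:
    """Relaxed recurrent input for one step given the layer PSC at t-1."""
    W, _ = effective_recurrent_matrix(arch, W_exc)
    return a_prev @ W.T


def _spike_fns(mode: str, v_th: float, kind: str, width: float):
    from .dynamics import soft_spike, spike_pseudo_grad

    if mode == "hard":
        fwd = lambda u: (u.real >= v_th).astype(float)
    elif mode == "smooth":
        fwd = lambda u: soft_spike(u, v_th, width)
    else:
        raise ValueError(f"unknown spike mode {mode!r}")
    sg = lambda u: spike_pseudo_grad(u, v_th, kind, width)
    return fwd, sg


def recurrent_layer_forward(
    drive_ff: np.ndarray,
    W_rec: np.ndarray | None,
    tau_m,
    tau_syn: float,
    R,
    v_th: float,
    spike_mode: str = "hard",
    surrogate_kind: str = "sigmoid",
    surrogate_width: float = 0.2,
    ip=None,
) -> dict:
    """Run a (recurrent) LIF layer over T steps, keeping BPTT histories.

    ``drive_ff``: already-weighted feedforward drive, shape (B, n, T); the
    feedforward path has zero delay while recurrent links carry a one-step
    delay (``W_rec @ a[t-1]``). ``W_rec=None`` gives a plain feedforward
    layer (the output layer). ``tau_m``/``R`` may be per-neuron arrays; if
    ``ip`` (an :class:`~hrmas.ip.IPState`) is given, intrinsic parameters are
    adapted online every timestep and their per-step values recorded.
    """
    B, n, T = drive_ff.shape
    spike_fwd, _ = _spike_fns(spike_mode, v_th, surrogate_kind, surrogate_width)
    dtype = np.result_type(drive_ff, W_rec if W_rec is not None else np.float64)
    u = np.zeros((B, n), dtype=dtype)
    a = np.zeros((B, n), dtype=dtype)
    u_minus_h = np.zeros((B, n, T), dtype=dtype)
    s_h = np.zeros((B, n, T), dtype=dtype)
    a_h = np.zeros((B, n, T), dtype=dtype)
    k_s = 1.0 - 1.0 / tau_syn
    tau_t = np.zeros((T, n)) if ip is not None else None
    R_t = np.zeros((T, n)) if ip is not None else None
    for t in range(T):
        if ip is not None:
            tau_cur, R_cur = ip.tau, ip.R
            tau_t[t], R_t[t] = tau_cur, R_cur
        else:
            tau_cur, R_cur = tau_m, R
        I = drive_ff[:, :, t]
        if W_rec is not None:
            I = I + a @ W_rec.T
        u_minus = (1.0 - 1.0 / tau_cur) * u + (R_cur / tau_cur) * I
        s = spike_fwd(u_minus)
        u = u_minus * (1.0 - s)
        a = k_s * a + s
        u_minus_h[:, :, t] = u_minus
        s_h[:, :, t] = s
        a_h[:, :, t] = a
        if ip is not None:
            ip.observe(np.mean(s.real, axis=0))
            ip.adapt(v_th)
    return {
        "u_minus": u_minus_h,
        "s": s_h,
        "a": a_h,
        "drive_ff": drive_ff,
        "tau_t": tau_t,
        "R_t": R_t,
        "tau_m": tau_m,
        "tau_syn": tau_syn,
        "R": R,
        "v_th": v_th,
        "spike_mode": spike_mode,
        "surrogate_kind": surrogate_kind,
        "surrogate_width": surrogate_width,
    }


def recurrent_layer_backward(
    cache: dict, g_a_ext: np.ndarray, W_rec: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray | None]:
    """BPTT through one layer.

    ``g_a_ext[:, :, t]`` is dL/da[t] accumulated from outside the layer
    (readout or next layer). The recursion adds the within-layer paths: the
    PSC decay chain, the recurrent drive at t+1, and the membrane leak/reset
    chain with the surrogate spike derivative. Returns dL/d(drive_ff) with
    the same shape, and dL/dW_rec (None for a feedforward layer).
    """
    u_minus_h, s_h, a_h = cache["u_minus"], cache["s"], cache["a"]
    B, n, T = u_minus_h.shape
    _, sg_fn = _spike_fns(
        cache["spike_mode"], cache["v_th"], cache["surrogate_kind"],
        cache["surrogate_width"],
    )
    k_s = 1.0 - 1.0 / cache["tau_syn"]
    dtype = np.result_type(u_minus_h, g_a_ext)
    g_drive = np.zeros((B, n, T), dtype=dtype)
    gW_rec = np.zeros_like(W_rec, dtype=dtype) if W_rec is not None else None
    ga_next = np.zeros((B, n), dtype=dtype)
    gu_minus_next = np.zeros((B, n), dtype=dtype)
    gd_next = np.zeros((B, n), dtype=dtype)
    for t in range(T - 1, -1, -1):
        if cache["tau_t"] is not None:
            tau_cur, R_cur = cache["tau_t"][t], cache["R_t"][t]
            tau_next = cache["tau_t"][t + 1] if t + 1 < T else tau_cur
        else:
            tau_cur = tau_next = cache["tau_m"]
            R_cur = cache["R"]
        ga = g_a_ext[:, :, t] + k_s * ga_next
        if W_rec is not None:
            ga = ga + gd_next @ W_rec
        sg = sg_fn(u_minus_h[:, :, t])
        gu = (1.0 - 1.0 / tau_next) * gu_minus_next
        gu_minus = ga * sg + gu * ((1.0 - s_h[:, :, t]) - u_minus_h[:, :, t] * sg)
        gd = (R_cur / tau_cur) * gu_minus
        g_drive[:, :, t] = gd
        if W_rec is not None and t >= 1:
            gW_rec += gd.T @ a_h[:, :, t - 1]
        ga_next, gu_minus_next, gd_next = ga, gu_minus, gd
    return g_drive, gW_rec


@dataclass
class DiscreteArchitecture:
    """A committed SC-ML architecture: one motif size, one type per slot."""

    n: int
    motif_size: int
    tying: str
    types: np.ndarray  # (n, n) int8, NONE off-candidate
    W: np.ndarray  # (n, n) float, band-sparse

    def to_json(self) -> str:
        v = self.motif_size
        doc: dict = {
            "n": self.n,
            "motif_size": v,
            "tying": self.tying,
            "type_triplets": [
                [int(i), int(r), TYPE_CHARS[self.types[i, r]]]
                for i, r in zip(*np.nonzero(self.types != NONE))
            ],
            "weight_matrix": [
                [int(i), int(r), float(self.W[i, r])]
                for i, r in zip(*np.nonzero(self.types != NONE))
            ],
        }
        if self.tying == "shared_topology":
            tmpl = self.types[:v, :v]
            doc["intra_type_matrix"] = [
                [TYPE_CHARS[tmpl[i, r]] for r in range(v)] for i in range(v)
            ]
            if self.n > v:
                doc["inter_type_assignments"] = {
                    "from_left": TYPE_CHARS[self.types[v, 0]],
                    "from_right": TYPE_CHARS[self.types[0, v]],
                }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteArchitecture":
        doc = json.loads(text)
        n = int(doc["n"])
        types = np.full((n, n), NONE, dtype=np.int8)
        W = np.zeros((n, n))
        for i, r, ch in doc["type_triplets"]:
            types[i, r] = TYPE_CHARS.index(ch)
        for i, r, w in doc["weight_matrix"]:
            W[i, r] = w
        return cls(
            n=n, motif_size=int(doc["motif_size"]), tying=doc.get("tying", "shared_topology"),
            types=types, W=W,
        )


def discretize(arch: ArchParams, W_exc: np.ndarray | None = None) -> DiscreteArchitecture:
    """Commit the relaxed architecture to its argmax choices.

    Motif size: ``frozen_v`` if set, else argmax of the relaxed motif-size
    probabilities; per-slot types: argmax over type probabilities. Exact ties
    resolve to the lowest index (numpy argmax convention). Excitatory entries
    take their current trained weight (or the init value if none given).
    """
    spec = arch.spec
    relaxed = relax(arch)
    v = arch.frozen_v
    if v is None:
        v = spec.motif_sizes[int(np.argmax(relaxed["alpha_v"]))]
    m = arch.masks[v]
    slot_types = np.argmax(relaxed["types"][v], axis=-1)[m.slot_id]
    types = np.full((spec.n, spec.n), NONE, dtype=np.int8)
    types[m.post, m.pre] = slot_types
    if W_exc is None:
        W_exc = np.full((spec.n, spec.n), spec.w_exc_init)
    W = np.zeros((spec.n, spec.n))
    W[types == EXC] = W_exc[types == EXC]
    W[types == INH] = spec.w_inh
    return DiscreteArchitecture(
        n=spec.n, motif_size=v, tying=spec.tying, types=types, W=W
    )
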