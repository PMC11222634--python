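"""Synthetic labeled spike-train tasks.

Two generators keep every part of the library exercisable without external
data:

* :func:`make_pattern_task` — one random spatiotemporal spike template per
  class; samples are the template with Gaussian timing jitter (clipped to
  the simulation window) plus optional background Poisson spikes. Jitter
  controls difficulty: at zero jitter every sample equals its class template.
* :func:`make_teacher_task` — a "teacher" RSNN with a *known planted motif
  size* labels random Poisson input; recovering the planted size from the
  data is the closed-loop test of architecture search. Degenerate draws
  (any class below 10% prevalence) are rejected and redrawn.
* :func:`make_order_task` — classes differ only in the *temporal order* of
  spatial bursts separated by gaps longer than the synaptic memory, so the
  accumulated-PSC readout of a purely feedforward spiking network is nearly
  order-blind and recurrent memory genuinely pays off. This is the
  benchmark used to compare search variants and ablations.

All generators are fully determined by their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import scml
from .scml import EXC, INH, NONE

__all__ = ["SpikeDataset", "make_pattern_task", "make_teacher_task", "make_order_task"]


@dataclass
class SpikeDataset:
    """Dense binary spike tensors with labels: X (S, n_in, T), y (S,)."""

    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)
    access_count: int = 0  # incremented by tensors(); protocol-hygiene probe

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (samples, channels, T) matching y")
        if not np.all((self.X == 0) | (self.X == 1)):
            raise ValueError("spike tensor must be binary")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_in(self) -> int:
        return self.X.shape[1]

    @property
    def T(self) -> int:
        return self.X.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if len(self.y) else 0

    def tensors(self) -> tuple[np.ndarray, np.ndarray]:
        """Hand out (X, y) for compute; counts accesses so the protocol test
        can assert the held-out set is touched exactly once."""
        self.access_count += 1
        return self.X.astype(float), self.y

    def subset(self, idx: np.ndarray) -> "SpikeDataset":
        return SpikeDataset(self.X[idx], self.y[idx], dict(self.meta))

    def batches(self, batch_size: int, rng: np.random.Generator):
        order = rng.permutation(len(self.y))
        for lo in range(0, len(order), batch_size):
            sel = order[lo : lo + batch_size]
            yield self.X[sel].astype(float), self.y[sel]


def make_pattern_task(
    n_classes: int = 2,
    n_in: int = 16,
    T: int = 50,
    spikes_per_template: int = 40,
    jitter_std: float = 1.0,
    n_per_class: int = 100,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> SpikeDataset:
    """Jittered-template classification task with balanced classes."""
    if min(n_classes, n_in, T, spikes_per_template, n_per_class) <= 0:
        raise ValueError("all counts must be positive")
    if jitter_std < 0:
        raise ValueError("jitter_std must be >= 0")
    if spikes_per_template > n_in * T:
        raise ValueError("spikes_per_template exceeds channel-time capacity")
    rng = np.random.default_rng(seed)
    templates = []
    for _ in range(n_classes):
        flat = rng.choice(n_in * T, size=spikes_per_template, replace=False)
        templates.append((flat // T, flat % T))  # (channels, times)
    X = np.zeros((n_classes * n_per_class, n_in, T), dtype=np.uint8)
    y = np.repeat(np.arange(n_classes), n_per_class)
    for s, c in enumerate(y):
        ch, tt = templates[c]
        t_jit = tt + np.round(rng.normal(0.0, jitter_std, size=len(tt))).astype(int)
        t_jit = np.clip(t_jit, 0, T - 1)
        X[s, ch, t_jit] = 1
        if noise_rate > 0:
            X[s] |= (rng.random((n_in, T)) < noise_rate).astype(np.uint8)
    perm = rng.permutation(len(y))
    return SpikeDataset(
        X[perm], y[perm],
        meta={
            "generator": "pattern", "n_classes": n_classes, "n_in": n_in,
            "T": T, "spikes_per_template": spikes_per_template,
            "jitter_std": jitter_std, "n_per_class": n_per_class,
            "noise_rate": noise_rate, "seed": seed,
        },
    )


def make_order_task(
    n_in: int = 18,
    T: int = 60,
    n_classes: int = 4,
    burst_len: int = 6,
    burst_rate: float = 0.4,
    gap: int = 18,
    n_per_class: int = 75,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> SpikeDataset:
    """Temporal-order classification: which sequence the input populations
    fired in.

    The input channels are divided into three equal populations; each class
    is one permutation of their firing order, with bursts ``gap`` timesteps
    apart (several synaptic time constants, so the low-pass input trace has
    largely forgotten one burst before the next). Summed over the trial the
    spike counts per channel are class-independent, which is what defeats a
    feedforward accumulated-PSC readout.
    """
    if n_classes < 2 or n_classes > 6:
        raise ValueError("n_classes must be 2..6 (permutations of 3 populations)")
    if n_in % 3 != 0:
        raise ValueError("n_in must be divisible by 3")
    rng = np.random.default_rng(seed)
    third = n_in // 3
    pops = [slice(0, third), slice(third, 2 * third), slice(2 * third, n_in)]
    orders = [(0, 1, 2), (2, 1, 0), (1, 0, 2), (0, 2, 1), (1, 2, 0), (2, 0, 1)]
    if 2 * gap + burst_len > T - 4:
        raise ValueError("three bursts with this gap do not fit in T")
    n = n_classes * n_per_class
    X = np.zeros((n, n_in, T), np.uint8)
    y = np.repeat(np.arange(n_classes), n_per_class)
    for s, c in enumerate(y):
        t0 = rng.integers(0, 4)
        for k, p in enumerate(orders[c]):
            t = t0 + k * gap
            X[s, pops[p], t : t + burst_len] = (
                rng.random((third, burst_len)) < burst_rate
            )
        if noise_rate > 0:
            X[s] |= (rng.random((n_in, T)) < noise_rate).astype(np.uint8)
    perm = rng.permutation(n)
    return SpikeDataset(
        X[perm], y[perm],
        meta={
            "generator": "order", "n_in": n_in, "T": T, "n_classes": n_classes,
            "burst_len": burst_len, "burst_rate": burst_rate, "gap": gap,
            "n_per_class": n_per_class, "noise_rate": noise_rate, "seed": seed,
        },
    )


def _random_teacher(
    n_in: int, n_hidden: int, v: int, n_classes: int, rng: np.random.Generator
):
    """A discrete SC-ML network with planted motif size ``v``.

    Intra-motif slots draw types (exc/inh/none) at random; the corresponding-
    neuron inter-motif links are excitatory, so adjacent-motif coupling at
    lag ``v`` is a real feature of the data-generating process.
    """
    from .training import NetConfig, Network

    spec = scml.SCMLSpec(n=n_hidden, motif_sizes=(v,))
    masks = scml.build_candidate_masks(n_hidden, (v,), "shared_topology")
    m = masks[v]
    types = np.full((n_hidden, n_hidden), NONE, dtype=np.int8)
    tmpl = rng.choice([EXC, INH, NONE], size=(v, v), p=[0.5, 0.2, 0.3])
    intra = ~m.is_inter
    types[m.post[intra], m.pre[intra]] = tmpl[
        m.post[intra] % v, m.pre[intra] % v
    ]
    types[m.post[m.is_inter], m.pre[m.is_inter]] = EXC
    W = np.zeros((n_hidden, n_hidden))
    W[types == EXC] = rng.uniform(0.3, 0.8, size=int(np.sum(types == EXC)))
    W[types == INH] = spec.w_inh
    arch = scml.DiscreteArchitecture(
        n=n_hidden, motif_size=v, tying="shared_topology", types=types, W=W
    )
    cfg = NetConfig(
        n_in=n_in, n_hidden=n_hidden, n_out=n_classes, motif_sizes=(v,), T=1
    )
    net = Network(cfg, rng, fixed_arch=arch)
    net.weights["W_exc"] = W.copy()
    net.weights["W_out"] = rng.normal(0.0, np.sqrt(2.0 / n_hidden), (n_classes, n_hidden))
    return net, arch


def make_teacher_task(
    n_in: int = 16,
    n_hidden: int = 16,
    motif_size_star: int = 2,
    T: int = 50,
    n_classes: int = 2,
    n_samples: int = 200,
    input_rate: float = 0.15,
    seed: int = 0,
    max_redraws: int = 20,
    return_teacher: bool = False,
):
    """Dataset labeled by a planted-motif teacher RSNN.

    Inputs are homogeneous Poisson spike trains; each label is the teacher's
    readout argmax (accumulated output PSC), so the teacher itself scores
    accuracy 1.0 on its own dataset by construction.
    """
    if n_hidden % motif_size_star != 0:
        raise ValueError("planted motif size must divide n_hidden")
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws):
        teacher, arch = _random_teacher(n_in, n_hidden, motif_size_star, n_classes, rng)
        X = (rng.random((n_samples, n_in, T)) < input_rate).astype(np.uint8)
        y = np.zeros(n_samples, dtype=np.int64)
        for lo in range(0, n_samples, 100):
            y[lo : lo + 100] = teacher.predict(X[lo : lo + 100].astype(float))
        prev = np.bincount(y, minlength=n_classes) / n_samples
        if np.all(prev >= 0.1):
            ds = SpikeDataset(
                X, y,
                meta={
                    "generator": "teacher", "n_in": n_in, "n_hidden": n_hidden,
                    "motif_size_star": motif_size_star, "T": T,
                    "n_classes": n_classes, "n_samples": n_samples,
                    "input_rate": input_rate, "seed": seed,
                    "redraws": attempt,
                },
            )
            return (ds, teacher) if return_teacher else ds
    raise RuntimeError(
        f"teacher labeling degenerate after {max_redraws} redraws"
    )
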