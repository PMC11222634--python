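"""Alternating two-step architecture search and the search/retrain protocol.

Each search iteration performs:

1. **Gradient step** — one bi-level architecture-logit update (validation
   loss, one-step look-ahead with a finite-difference second-order term)
   followed by one Adam update of the synaptic weights on the training
   subset;
2. **Intrinsic plasticity window** — one mini-batch is presented with the
   SpiKL-IP rule adapting each recurrent neuron's R and tau online,
   stabilizing activity against the structural changes of step 1. The
   adapted parameters are the ones the next iteration's gradients see.

The schedule is staged: stage 1 searches motif size and connection types
jointly; at the boundary the motif size is frozen by argmax (irreversibly)
and stage 2 continues on connection types only. Afterwards the architecture
is discretized and — in a second phase — all weights are reinitialized and
retrained on the full training set; accuracy is measured once on the
held-out test set.

Ablation switches mirror the method's components: ``no_ip`` skips step 2,
``no_motif`` removes recurrence entirely (feedforward SNN), ``no_inter_motif``
drops the lateral inter-motif slots, ``fully_connected`` trains a fixed dense
recurrent layer with no search, and ``random_search`` replaces the gradient
search by uniform sampling of discrete architectures on an equal budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import scml
from .ip import IPState
from .tasks import SpikeDataset
from .training import Adam, NetConfig, Network, bilevel_arch_step, weight_step

__all__ = [
    "SearchSchedule",
    "SearchResult",
    "split_train_valid",
    "search",
    "retrain_and_eval",
    "random_search",
]


@dataclass
class SearchSchedule:
    stage1_iters: int = 120
    stage2_iters: int = 120
    finetune_epochs: int = 25
    batch_size: int = 20
    lr_w: float = 5e-3
    # scaled so architecture logits traverse O(1) within a desk-scale stage
    lr_alpha: float = 1e-2
    eta_inner: float = 5e-3
    epsilon_fd: float = 1e-2
    eval_every: int = 10
    ip_enabled: bool = True
    ip_mu: float = 0.1
    ip_tau_cal: float = 16.0
    ip_gamma: float = 0.4
    no_motif: bool = False
    no_inter_motif: bool = False
    fully_connected: bool = False
    random_search: bool = False
    random_candidates: int = 6
    random_train_iters: int = 100

    def __post_init__(self) -> None:
        for name in ("stage1_iters", "stage2_iters", "finetune_epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SearchResult:
    architecture: scml.DiscreteArchitecture | None
    chosen_motif_size: int | None
    trace: list  # (iteration, train_loss, valid_loss, valid_acc)
    test_accuracy: float | None
    seed: int
    meta: dict = field(default_factory=dict)


def split_train_valid(
    dataset: SpikeDataset, seed: int
) -> tuple[SpikeDataset, SpikeDataset]:
    """Deterministic stratified 50/50 split of a dataset."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples to split")
    counts = np.bincount(dataset.y)
    if np.any(counts[counts > 0] < 2):
        raise ValueError("every class needs >= 2 samples for stratification")
    idx = np.arange(len(dataset))
    tr, va = train_test_split(
        idx, test_size=0.5, random_state=seed, stratify=dataset.y, shuffle=True
    )
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(va))


def _batch_stream(ds: SpikeDataset, batch_size: int, rng: np.random.Generator):
    """Endless shuffled mini-batches."""
    while True:
        yield from ds.batches(batch_size, rng)


def _net_config(dataset: SpikeDataset, motif_sizes, n_hidden: int, sched, **kw):
    return NetConfig(
        n_in=dataset.n_in,
        n_hidden=n_hidden,
        n_out=dataset.n_classes,
        motif_sizes=tuple(motif_sizes),
        T=dataset.T,
        include_inter=not sched.no_inter_motif,
        recurrent=not sched.no_motif,
        **kw,
    )


def search(
    dataset: SpikeDataset,
    motif_sizes: tuple[int, ...],
    n_hidden: int,
    schedule: SearchSchedule | None = None,
    seed: int = 0,
    test_set: SpikeDataset | None = None,
    net_kwargs: dict | None = None,
) -> SearchResult:
    """Run the full two-phase protocol on ``dataset``.

    ``dataset`` is split 50/50 into training and validation subsets for the
    search phase. If ``test_set`` is given, the discretized architecture is
    retrained from scratch on the *full* ``dataset`` and evaluated once on
    ``test_set``.
    """
    sched = schedule or SearchSchedule()
    rng = np.random.default_rng(seed)
    if sched.random_search:
        return random_search(dataset, motif_sizes, n_hidden, sched, seed, test_set,
                             net_kwargs)
    train_ds, valid_ds = split_train_valid(dataset, seed)
    cfg = _net_config(dataset, motif_sizes, n_hidden, sched, **(net_kwargs or {}))
    if sched.fully_connected:
        # fixed dense recurrent layer, trainable excitatory everywhere; no search
        arch = scml.DiscreteArchitecture(
            n=n_hidden, motif_size=n_hidden, tying="shared_topology",
            types=np.full((n_hidden, n_hidden), scml.EXC, dtype=np.int8),
            W=np.full((n_hidden, n_hidden), 0.2),
        )
        acc = retrain_and_eval(arch, dataset, test_set, sched, seed, cfg_base=cfg) \
            if test_set is not None else None
        return SearchResult(arch, n_hidden, [], acc, seed, {"mode": "fully_connected"})

    net = Network(cfg, rng)
    if sched.ip_enabled and not sched.no_motif:
        net.attach_ip(IPState(
            n=n_hidden, mu=sched.ip_mu, tau_cal=sched.ip_tau_cal,
            gamma=sched.ip_gamma, tau0=cfg.tau_m,
        ))
    w_opt = Adam(sched.lr_w)
    a_opt = Adam(sched.lr_alpha)
    train_stream = _batch_stream(train_ds, sched.batch_size, rng)
    valid_stream = _batch_stream(valid_ds, sched.batch_size, rng)
    ip_stream = _batch_stream(train_ds, sched.batch_size, rng)
    trace = []
    total = sched.stage1_iters + sched.stage2_iters
    searching = not sched.no_motif
    for it in range(total):
        if searching and it == sched.stage1_iters:
            net.arch.freeze_motif_size()
        Xt, yt = next(train_stream)
        Xv, yv = next(valid_stream)
        # step 1: architecture then weights
        if searching:
            bilevel_arch_step(
                net, a_opt, (Xt, yt), (Xv, yv), sched.eta_inner, sched.epsilon_fd
            )
        train_loss = weight_step(net, w_opt, Xt, yt)
        # step 2: unsupervised IP adaptation over one mini-batch window
        if net.ip is not None:
            Xi, _ = next(ip_stream)
            net.forward(Xi, adapt_ip=True)
        if it % sched.eval_every == 0 or it == total - 1:
            fwd = net.forward(Xv)
            v_loss = net.batch_loss(fwd, yv)
            v_acc = float(np.mean(
                np.argmax(np.sum(fwd["out"]["a"], axis=-1), axis=-1) == yv
            ))
            trace.append((it, float(train_loss), float(v_loss), v_acc))
    if searching:
        if net.arch.frozen_v is None:
            net.arch.freeze_motif_size()
        arch = scml.discretize(net.arch, net.weights["W_exc"])
        chosen = arch.motif_size
    else:
        arch, chosen = None, None
    acc = None
    if test_set is not None:
        acc = retrain_and_eval(arch, dataset, test_set, sched, seed, cfg_base=cfg)
    return SearchResult(arch, chosen, trace, acc, seed, {"mode": "hrmas"})


def retrain_and_eval(
    architecture: scml.DiscreteArchitecture | None,
    train_ds: SpikeDataset,
    test_ds: SpikeDataset,
    schedule: SearchSchedule | None = None,
    seed: int = 0,
    cfg_base: NetConfig | None = None,
) -> float:
    """Phase 2: reinitialize all weights, train on the full training set,
    and score accuracy on the held-out test set (touched exactly once)."""
    sched = schedule or SearchSchedule()
    rng = np.random.default_rng(seed + 10_000)
    if cfg_base is None:
        cfg_base = _net_config(
            train_ds,
            (architecture.motif_size,) if architecture is not None else (1,),
            architecture.n if architecture is not None else 16,
            sched,
        )
    if architecture is not None and architecture.n != cfg_base.n_hidden:
        raise ValueError("architecture size does not match layer size")
    cfg = cfg_base
    net = Network(cfg, rng, fixed_arch=architecture)
    opt = Adam(sched.lr_w)
    for _ in range(sched.finetune_epochs):
        for Xb, yb in train_ds.batches(sched.batch_size, rng):
            weight_step(net, opt, Xb, yb)
    X_test, y_test = test_ds.tensors()
    return net.accuracy(X_test, y_test)


def random_search(
    dataset: SpikeDataset,
    motif_sizes: tuple[int, ...],
    n_hidden: int,
    sched: SearchSchedule,
    seed: int = 0,
    test_set: SpikeDataset | None = None,
    net_kwargs: dict | None = None,
) -> SearchResult:
    """Uniformly sample discrete architectures; train each briefly on the
    training subset; keep the best by validation accuracy."""
    rng = np.random.default_rng(seed)
    train_ds, valid_ds = split_train_valid(dataset, seed)
    cfg = _net_config(dataset, motif_sizes, n_hidden, sched, **(net_kwargs or {}))
    best, best_acc = None, -1.0
    Xv, yv = valid_ds.X.astype(float), valid_ds.y
    for _ in range(sched.random_candidates):
        v = int(rng.choice(motif_sizes))
        masks = scml.build_candidate_masks(n_hidden, (v,), cfg.tying,
                                           cfg.include_inter)
        m = masks[v]
        types = np.full((n_hidden, n_hidden), scml.NONE, dtype=np.int8)
        tab = rng.integers(0, 3, size=m.n_table_rows)
        types[m.post, m.pre] = tab[m.slot_id]
        W = np.zeros((n_hidden, n_hidden))
        W[types == scml.EXC] = 0.2
        W[types == scml.INH] = cfg.w_inh
        arch = scml.DiscreteArchitecture(
            n=n_hidden, motif_size=v, tying=cfg.tying, types=types, W=W
        )
        net = Network(cfg, rng, fixed_arch=arch)
        opt = Adam(sched.lr_w)
        stream = _batch_stream(train_ds, sched.batch_size, rng)
        for _ in range(sched.random_train_iters):
            Xt, yt = next(stream)
            weight_step(net, opt, Xt, yt)
        acc = net.accuracy(Xv, yv)
        if acc > best_acc:
            best, best_acc = arch, acc
    test_acc = None
    if test_set is not None:
        test_acc = retrain_and_eval(best, dataset, test_set, sched, seed,
                                    cfg_base=cfg)
    return SearchResult(best, best.motif_size, [], test_acc, seed,
                        {"mode": "random_search", "valid_acc": best_acc})
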