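import numpy as np
import pytest

from hrmas.training import NetConfig, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_net(
    n_in=3, n_hidden=4, n_out=2, motif_sizes=(2, 4), T=8, seed=0, **kw
):
    """Small network with symmetry-broken logits, for gradient checks."""
    rng = np.random.default_rng(seed)
    cfg = NetConfig(
        n_in=n_in, n_hidden=n_hidden, n_out=n_out, motif_sizes=motif_sizes,
        T=T, tau_m=4.0, tau_syn=3.0, surrogate_width=0.5, **kw
    )
    net = Network(cfg, rng)
    net.arch.alpha_v += rng.normal(0, 0.3, net.arch.alpha_v.shape)
    for v in net.arch.type_logits:
        net.arch.type_logits[v] += rng.normal(0, 0.3, net.arch.type_logits[v].shape)
    net.weights["W_exc"] += rng.normal(0, 0.1, net.weights["W_exc"].shape)
    X = (rng.random((2, n_in, T)) < 0.4).astype(float)
    y = np.arange(2) % n_out
    return net, X, y


@pytest.fixture
def toy_net():
    return make_toy_net()
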