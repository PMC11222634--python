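"""Loss targets, BPTT gradient oracles, and the bi-level architecture step."""

import numpy as np
import pytest

from hrmas.dynamics import soft_spike, spike_pseudo_grad
from hrmas.training import Adam, Network, NetConfig, bilevel_arch_step, loss, target_psc, weight_step

from conftest import make_toy_net


class TestTargetPsc:
    def test_first_steps_match_filter_iteration(self):
        d = target_psc(0, 2, 5, 8.0)
        assert d[0, 0] == pytest.approx(1.0)
        assert d[0, 1] == pytest.approx(1.875)
        assert np.all(d[1] == 0)  # silenced class

    def test_saturates_at_tau_syn(self):
        d = target_psc(1, 2, 500, 8.0)
        assert d[1, -1] == pytest.approx(8.0, rel=1e-8)

    def test_matches_repeated_psc_step(self):
        from hrmas.dynamics import psc_step

        a, trace = np.zeros(1), []
        for _ in range(20):
            a = psc_step(a, np.ones(1), 8.0)
            trace.append(a.item())
        np.testing.assert_allclose(target_psc(0, 1, 20, 8.0)[0], trace, rtol=1e-12)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            target_psc(3, 3, 10, 8.0)


class TestLoss:
    def test_perfect_output_gives_zero(self):
        d = np.random.default_rng(0).random((2, 3, 7))
        assert loss(d, d) == 0.0

    def test_unit_gap_counts_half_per_step(self):
        out = np.zeros((1, 1, 10))
        tgt = np.ones((1, 1, 10))
        assert loss(out, tgt) == pytest.approx(5.0)

    def test_hand_computed_two_neuron_three_step(self):
        out = np.array([[[0.0, 0.5, 1.0], [1.0, 1.0, 0.0]]])
        tgt = np.array([[[1.0, 1.875, 2.64], [0.0, 0.0, 0.0]]])
        expected = 0.5 * sum(
            (t - o) ** 2
            for o, t in zip(out.ravel(), tgt.ravel())
        )
        assert loss(out, tgt) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss(np.zeros((1, 2, 3)), np.zeros((1, 2, 4)))


def flatten(groups):
    return np.concatenate([np.ravel(g) for _, g in sorted(groups.items())])


def all_param_views(net):
    views = dict(net.weights)
    views["alpha_v"] = net.arch.alpha_v
    for v, tab in net.arch.type_logits.items():
        views[f"types:{v}"] = tab
    return views


def all_grad_views(net, grads):
    views = {k: grads[k] for k in ("W_in", "W_out", "W_exc")}
    views["alpha_v"] = grads["alpha_v"]
    for v, g in grads["type_logits"].items():
        views[f"types:{v}"] = g
    return views


class TestGradientOracle:
    def test_bptt_matches_central_differences(self):
        """Analytic weight AND architecture-logit gradients agree with
        central finite differences of the relaxed graph (rel err < 1e-4)."""
        net, X, y = make_toy_net(n_in=3, n_hidden=4, n_out=2, T=8)
        _, grads = net.loss_and_grads(X, y, spike_mode="smooth")
        params = all_param_views(net)
        gviews = all_grad_views(net, grads)
        h = 1e-5
        rng = np.random.default_rng(0)
        for name, arr in params.items():
            idxs = list(np.ndindex(arr.shape))
            picks = rng.choice(len(idxs), min(8, len(idxs)), replace=False)
            for idx in [idxs[i] for i in picks]:
                old = arr[idx]
                arr[idx] = old + h
                Lp = net.loss_and_grads(X, y, spike_mode="smooth")[0]
                arr[idx] = old - h
                Lm = net.loss_and_grads(X, y, spike_mode="smooth")[0]
                arr[idx] = old
                fd = (Lp - Lm) / (2 * h)
                an = gviews[name][idx]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-4, (name, idx, fd, an)

    def test_zero_upstream_error_gives_zero_gradients(self):
        from hrmas.scml import recurrent_layer_backward, recurrent_layer_forward

        rng = np.random.default_rng(1)
        drive = rng.normal(0, 0.5, (2, 3, 6))
        W = rng.normal(0, 0.2, (3, 3))
        cache = recurrent_layer_forward(drive, W, 4.0, 3.0, 1.0, 0.5)
        g_drive, gW = recurrent_layer_backward(cache, np.zeros((2, 3, 6)), W)
        assert np.all(g_drive == 0) and np.all(gW == 0)

    def test_single_step_reduces_to_feedforward_delta_rule(self):
        """T=1: no recurrence is reachable; gradients equal the explicit
        one-layer-at-a-time chain rule computed by hand."""
        net, X, y = make_toy_net(T=1)
        cfg = net.cfg
        L, grads = net.loss_and_grads(X, y, spike_mode="smooth")
        B = X.shape[0]
        g = cfg.tau_m  # shorthand
        W_in, W_out = net.weights["W_in"], net.weights["W_out"]
        W_rec, _ = net.recurrent_matrix()
        a_in = X[:, :, 0]
        gain = 1.0 / cfg.tau_m  # R / tau_m with R = 1
        u_h = gain * a_in @ W_in.T
        s_h = soft_spike(u_h, cfg.v_th, cfg.surrogate_width)
        u_o = gain * s_h @ W_out.T
        a_o = soft_spike(u_o, cfg.v_th, cfg.surrogate_width)
        d = net.targets(y, 1)[:, :, 0]
        sg = lambda u: spike_pseudo_grad(u, cfg.v_th, "sigmoid", cfg.surrogate_width)
        g_uo = (a_o - d) / B * sg(u_o)
        gW_out = gain * g_uo.T @ s_h
        g_uh = gain * (g_uo @ W_out) * sg(u_h)
        gW_in = gain * g_uh.T @ a_in
        np.testing.assert_allclose(grads["W_out"], gW_out, atol=1e-12)
        np.testing.assert_allclose(grads["W_in"], gW_in, atol=1e-12)

    def test_all_none_types_make_a_feedforward_network(self):
        """One-hot "none" everywhere: recurrent weight gradients vanish and
        the forward pass equals the recurrence-free model."""
        net, X, y = make_toy_net(T=6)
        for v in net.arch.type_logits:
            t = np.full_like(net.arch.type_logits[v], -np.inf)
            t[:, 2] = 0.0
            net.arch.type_logits[v] = t
        _, grads = net.loss_and_grads(X, y)
        assert np.all(grads["W_exc"] == 0)
        ff_net, _, _ = make_toy_net(T=6, recurrent=False)
        ff_net.weights["W_in"] = net.weights["W_in"]
        ff_net.weights["W_out"] = net.weights["W_out"]
        f_rec = net.forward(X)
        f_ff = ff_net.forward(X)
        np.testing.assert_array_equal(f_rec["out"]["a"], f_ff["out"]["a"])


class TestTrainingLoop:
    def test_loss_decreases_on_separable_task(self):
        """Weight-only training on a noiseless pattern task: the loss trends
        down over the first 50 steps (smoke property, fixed seed)."""
        from hrmas.tasks import make_pattern_task

        ds = make_pattern_task(n_classes=2, n_in=16, T=40, jitter_std=0.0,
                               n_per_class=30, seed=7)
        rng = np.random.default_rng(0)
        net = Network(NetConfig(n_in=16, n_hidden=16, n_out=2,
                                motif_sizes=(2, 4), T=40), rng)
        opt = Adam(5e-3)
        losses = []
        stream = ds.batches(20, rng)
        for _ in range(50):
            try:
                X, y = next(stream)
            except StopIteration:
                stream = ds.batches(20, rng)
                X, y = next(stream)
            losses.append(weight_step(net, opt, X, y))
        assert losses[-1] < losses[0]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_divergent_loss_aborts(self):
        net, X, y = make_toy_net()
        net.weights["W_in"][:] = np.nan
        with pytest.raises(FloatingPointError):
            weight_step(net, Adam(1e-3), X, y)


class TestBilevel:
    def test_eta_zero_is_plain_validation_gradient(self):
        net, X, y = make_toy_net()
        Xv, yv = X[::-1].copy(), y[::-1].copy()
        _, gv = net.loss_and_grads(Xv, yv, spike_mode="smooth")
        expected = net.arch_grad_items(gv)
        got = bilevel_arch_step(net, Adam(0.0), (X, y), (Xv, yv), eta=0.0,
                                epsilon=1e-2, spike_mode="smooth", apply=False)
        for k in expected:
            np.testing.assert_array_equal(got[k], expected[k])

    def test_finite_difference_term_converges_to_exact_second_order(self):
        """The symmetric FD estimate of the mixed second-order term converges
        at O(eps^2) to the forward-over-reverse (complex-step) value."""
        net, X, y = make_toy_net(n_in=2, n_hidden=2, n_out=2, motif_sizes=(1, 2), T=6)
        Xv, yv = X[::-1].copy(), y[::-1].copy()
        wkeys = list(net.weight_items())
        eta = 0.01
        _, gt = net.loss_and_grads(X, y, spike_mode="smooth")
        saved = {k: net.weights[k].copy() for k in wkeys}
        net.weights.update({k: saved[k] - eta * gt[k] for k in wkeys})
        _, gv = net.loss_and_grads(Xv, yv, spike_mode="smooth")
        net.weights.update(saved)
        g_dir = {k: gv[k] for k in wkeys}

        def arch_grads_at(ws):
            back = {k: net.weights[k] for k in wkeys}
            net.weights.update(ws)
            _, g = net.loss_and_grads(X, y, spike_mode="smooth")
            net.weights.update(back)
            return flatten(net.arch_grad_items(g))

        h = 1e-30
        oracle = arch_grads_at(
            {k: saved[k] + 1j * h * g_dir[k] for k in wkeys}
        ).imag / h
        errs = []
        for eps in (1e-1, 1e-2, 1e-3, 1e-4):
            gp = arch_grads_at({k: saved[k] + eps * g_dir[k] for k in wkeys})
            gm = arch_grads_at({k: saved[k] - eps * g_dir[k] for k in wkeys})
            fd = (gp - gm).real / (2 * eps)
            errs.append(np.linalg.norm(fd - oracle) / np.linalg.norm(oracle))
        assert all(b < a for a, b in zip(errs, errs[1:]))  # monotone in eps
        assert errs[-1] < 1e-6

    def test_matches_unrolled_lookahead_gradient(self):
        """With identical train/valid batches, the update approximates the
        brute-force gradient of L(alpha, w - eta*grad_w L(alpha, w)); the
        discrepancy shrinks with eta."""
        net, X, y = make_toy_net(n_in=2, n_hidden=2, n_out=2, motif_sizes=(2,), T=5)
        wkeys = list(net.weight_items())
        saved = {k: net.weights[k].copy() for k in wkeys}

        def lookahead_loss(eta):
            _, g = net.loss_and_grads(X, y, spike_mode="smooth")
            net.weights.update({k: saved[k] - eta * g[k] for k in wkeys})
            L = net.loss_and_grads(X, y, spike_mode="smooth")[0]
            net.weights.update(saved)
            return L

        rel_errs = []
        for eta in (1e-2, 1e-3):
            update = flatten(bilevel_arch_step(
                net, Adam(0.0), (X, y), (X, y), eta=eta, epsilon=1e-4,
                spike_mode="smooth", apply=False,
            ))
            # brute force: central differences of the unrolled scalar in the
            # architecture logits
            brute = []
            h = 1e-5
            for name, arr in sorted(net.arch_items().items()):
                g = np.zeros_like(arr)
                for idx in np.ndindex(arr.shape):
                    old = arr[idx]
                    arr[idx] = old + h
                    Lp = lookahead_loss(eta)
                    arr[idx] = old - h
                    Lm = lookahead_loss(eta)
                    arr[idx] = old
                    g[idx] = (Lp - Lm) / (2 * h)
                brute.append(g.ravel())
            brute = np.concatenate(brute)
            rel_errs.append(
                np.linalg.norm(update - brute) / max(np.linalg.norm(brute), 1e-12)
            )
        assert rel_errs[1] < rel_errs[0]
        assert rel_errs[1] < 5e-2

    def test_parameter_validation(self):
        net, X, y = make_toy_net()
        with pytest.raises(ValueError):
            bilevel_arch_step(net, Adam(1e-3), (X, y), (X, y), 0.01, epsilon=0.0)
        with pytest.raises(ValueError):
            bilevel_arch_step(net, Adam(1e-3), (X[:0], y[:0]), (X, y), 0.01, 1e-2)
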