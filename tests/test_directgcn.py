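"""DirectGCN layer and model against an independent loop-based oracle."""

import numpy as np
import pytest

import protgram as pg
from protgram.directgcn import DirectGCNParams, layer_backward


def oracle_path(h, a, w_main, b_main, w_shared, b_shared):
    """Triple-loop dense message: A (H W_main) + b_main + H W_shared + b_shared."""
    n, f_in = h.shape
    f_out = w_main.shape[1]
    hw = [[sum(h[i][k] * w_main[k][j] for k in range(f_in)) for j in range(f_out)] for i in range(n)]
    ahw = [[sum(a[i][k] * hw[k][j] for k in range(n)) for j in range(f_out)] for i in range(n)]
    hs = [[sum(h[i][k] * w_shared[k][j] for k in range(f_in)) for j in range(f_out)] for i in range(n)]
    return np.array([[ahw[i][j] + b_main[j] + hs[i][j] + b_shared[j]
                      for j in range(f_out)] for i in range(n)])


def oracle_layer(h, propset, p: DirectGCNParams, slope):
    """Straight-line reimplementation of the gated three-path layer."""
    h_in = oracle_path(h, propset.a_in, p.w_main_in, p.b_main_in, p.w_shared, p.b_shared_in)
    h_out = oracle_path(h, propset.a_out, p.w_main_out, p.b_main_out, p.w_shared, p.b_shared_out)
    h_und = oracle_path(h, propset.a_undir, p.w_main_undir, p.b_main_undir, p.w_shared, p.b_shared_undir)
    n, f_out = h_in.shape
    pre = np.empty((n, f_out))
    for i in range(n):
        gi = p.gate_in[i if p.gate_in.shape[0] > 1 else 0, 0]
        go = p.gate_out[i if p.gate_out.shape[0] > 1 else 0, 0]
        gu = p.gate_undir[i if p.gate_undir.shape[0] > 1 else 0, 0]
        for j in range(f_out):
            pre[i, j] = gu * h_und[i, j] + gi * h_in[i, j] + go * h_out[i, j] + p.b_const[i, j]
    res = h if p.w_res is None else h @ p.w_res
    z = pre + res
    return np.where(z >= 0, z, slope * z)


def random_instance(rng, n=8, f_in=5, f_out=5, gating="vector"):
    a_raw = rng.random((n, n)) * (rng.random((n, n)) > 0.4)
    propset = pg.build_propagation_set(a_raw)
    p = DirectGCNParams.init(rng, n, f_in, f_out, gating)
    for name, arr in p.trainable().items():
        arr += rng.normal(scale=0.3, size=arr.shape)
    h = rng.normal(size=(n, f_in))
    return h, propset, p


class TestPathMessage:
    def test_zero_parameters_give_zero(self, rng):
        h = rng.normal(size=(4, 3))
        a = rng.random((4, 4))
        z = np.zeros((3, 2))
        out = pg.path_message(h, a, z, np.zeros(2), z, np.zeros(2))
        np.testing.assert_array_equal(out, np.zeros((4, 2)))

    def test_identity_propagation(self, rng):
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 2))
        out = pg.path_message(h, np.eye(4), w, np.zeros(2), np.zeros((3, 2)), np.zeros(2))
        np.testing.assert_allclose(out, h @ w, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        h = rng.normal(size=(5, 4))
        a = rng.random((5, 5))
        w_main, w_shared = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        b_main, b_shared = rng.normal(size=3), rng.normal(size=3)
        out = pg.path_message(h, a, w_main, b_main, w_shared, b_shared)
        np.testing.assert_allclose(out, oracle_path(h, a, w_main, b_main, w_shared, b_shared), atol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(pg.ConfigurationError):
            pg.path_message(np.zeros((4, 3)), np.eye(5), np.zeros((3, 2)),
                            np.zeros(2), np.zeros((3, 2)), np.zeros(2))


class TestLayerForward:
    def test_residual_passthrough_with_zero_parameters(self, rng):
        n, f = 6, 6
        p = DirectGCNParams.init(rng, n, f, f, "vector")
        for name, arr in p.trainable().items():
            if not name.startswith("gate"):
                arr[...] = 0.0
        h = np.abs(rng.normal(size=(n, f)))  # non-negative: LeakyReLU is identity
        propset = pg.build_propagation_set(rng.random((n, n)))
        out = pg.layer_forward(h, propset, p)
        np.testing.assert_allclose(out, h, atol=1e-12)

    def test_gating_annihilation(self, rng):
        n, f = 5, 5
        p = DirectGCNParams.init(rng, n, f, f, "vector")
        p.gate_in[...] = 0.0
        p.gate_out[...] = 0.0
        p.gate_undir[...] = 0.0
        h = rng.normal(size=(n, f))
        propset = pg.build_propagation_set(rng.random((n, n)))
        out = pg.layer_forward(h, propset, p, leaky_slope=0.01)
        expected = np.where(h >= 0, h, 0.01 * h)  # w_res is identity here
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_twenty_random_instances_match_oracle(self):
        rng = np.random.default_rng(77)
        for i in range(20):
            gating = ("vector", "scalar", "none")[i % 3]
            f_out = int(rng.integers(3, 7))
            h, propset, p = random_instance(rng, f_in=int(rng.integers(3, 7)), f_out=f_out, gating=gating)
            out = pg.layer_forward(h, propset, p, leaky_slope=0.01)
            assert np.abs(out - oracle_layer(h, propset, p, 0.01)).max() <= 1e-6

    def test_scalar_equals_constant_vector_gating(self, rng):
        h, propset, p_vec = random_instance(rng, gating="vector")
        p_sca = DirectGCNParams.init(np.random.default_rng(0), 8, 5, 5, "scalar")
        # copy non-gate parameters, then set constant gates
        for name, arr in p_vec.trainable().items():
            if not name.startswith("gate"):
                getattr(p_sca, name)[...] = arr
        g = {"gate_in": 1.7, "gate_out": -0.4, "gate_undir": 0.9}
        for name, val in g.items():
            getattr(p_vec, name)[...] = val
            getattr(p_sca, name)[...] = val
        out_v = pg.layer_forward(h, propset, p_vec)
        out_s = pg.layer_forward(h, propset, p_sca)
        np.testing.assert_array_equal(out_v, out_s)

    def test_none_mode_equals_gates_frozen_at_one(self, rng):
        h, propset, p_vec = random_instance(rng, gating="vector")
        for name in ("gate_in", "gate_out", "gate_undir"):
            getattr(p_vec, name)[...] = 1.0
        p_none = DirectGCNParams.init(np.random.default_rng(0), 8, 5, 5, "none")
        for name, arr in p_vec.trainable().items():
            if not name.startswith("gate"):
                getattr(p_none, name)[...] = arr
        np.testing.assert_array_equal(
            pg.layer_forward(h, propset, p_vec), pg.layer_forward(h, propset, p_none)
        )
        assert "gate_in" not in p_none.trainable()

    def test_bad_gate_shape_is_configuration_error(self, rng):
        p = DirectGCNParams.init(rng, 4, 3, 3, "vector")
        with pytest.raises(pg.ConfigurationError):
            DirectGCNParams(**{**{f: getattr(p, f) for f in (
                "w_main_in", "w_main_out", "w_main_undir", "w_shared",
                "b_main_in", "b_main_out", "b_main_undir",
                "b_shared_in", "b_shared_out", "b_shared_undir",
                "b_const")},
                "gate_in": np.ones((2, 1)), "gate_out": np.ones((4, 1)),
                "gate_undir": np.ones((4, 1)), "gating_mode": "vector"})


class TestModel:
    def test_single_layer_equals_layer_forward(self, rng):
        model = pg.DirectGCNModel.init(n_nodes=6, f_in=4, hidden_dims=[5],
                                       n_classes=3, dropout=0.0, seed=3)
        h0 = rng.normal(size=(6, 4))
        propset = pg.build_propagation_set(rng.random((6, 6)))
        z = model.forward(h0, propset)
        direct = pg.layer_forward(h0, propset, model.layers[0], leaky_slope=model.leaky_slope)
        np.testing.assert_array_equal(z, direct)

    def test_deterministic_without_dropout(self, rng):
        model = pg.DirectGCNModel.init(n_nodes=7, f_in=7, hidden_dims=[6, 6],
                                       n_classes=4, dropout=0.0, seed=5)
        h0 = rng.normal(size=(7, 7))
        propset = pg.build_propagation_set(rng.random((7, 7)))
        np.testing.assert_array_equal(model.forward(h0, propset, training=True),
                                      model.forward(h0, propset, training=True))

    def test_three_layer_stack_matches_chained_oracle(self):
        rng = np.random.default_rng(9)
        model = pg.DirectGCNModel.init(n_nodes=6, f_in=4, hidden_dims=[5, 5, 3],
                                       n_classes=3, dropout=0.0, seed=13)
        h0 = rng.normal(size=(6, 4))
        propset = pg.build_propagation_set(rng.random((6, 6)))
        expected = h0
        for layer in model.layers:
            expected = oracle_layer(expected, propset, layer, model.leaky_slope)
        assert np.abs(model.forward(h0, propset) - expected).max() <= 1e-6

    def test_inconsistent_dims_raise(self):
        with pytest.raises(pg.ConfigurationError):
            pg.DirectGCNModel.init(n_nodes=5, f_in=4, hidden_dims=[], n_classes=3)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = pg.DirectGCNModel.init(n_nodes=5, f_in=5, hidden_dims=[4],
                                       n_classes=3, dropout=0.0, seed=2)
        path = tmp_path / "model.npz"
        model.save(path)
        back = pg.DirectGCNModel.load(path)
        h0 = rng.normal(size=(5, 5))
        propset = pg.build_propagation_set(rng.random((5, 5)))
        np.testing.assert_array_equal(model.forward(h0, propset), back.forward(h0, propset))


class TestDecoder:
    def test_uniform_for_zero_logits(self):
        logp = pg.log_softmax(np.zeros((3, 4)))
        np.testing.assert_allclose(logp, np.log(0.25), atol=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(5, 6))
        shifted = logits + rng.normal(size=(5, 1))
        np.testing.assert_allclose(pg.log_softmax(logits), pg.log_softmax(shifted), atol=1e-12)

    def test_matches_scalar_exp_sum_log_oracle(self, rng):
        logits = rng.normal(size=(4, 5)) * 3
        logp = pg.log_softmax(logits)
        for i in range(4):
            denom = sum(np.exp(x) for x in logits[i])
            for j in range(5):
                assert logp[i, j] == pytest.approx(np.log(np.exp(logits[i, j]) / denom), abs=1e-12)
        np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, atol=1e-9)


class TestGradients:
    def test_finite_difference_matches_analytic(self):
        """Spot-check autodiff on a 5-node instance, every parameter family."""
        rng = np.random.default_rng(21)
        model = pg.DirectGCNModel.init(n_nodes=5, f_in=4, hidden_dims=[4, 3],
                                       n_classes=3, dropout=0.0, seed=8)
        h0 = rng.normal(size=(5, 4))
        propset = pg.build_propagation_set(rng.random((5, 5)))
        labels = rng.integers(0, 3, size=5)
        mask = np.array([True, True, False, True, True])
        _, grads = model.loss_and_grads(h0, propset, labels, mask, training=False)
        eps = 1e-6
        params = model.trainable()
        for name in ("layer0/w_main_in", "layer0/w_shared", "layer0/gate_in",
                     "layer0/b_const", "layer1/b_main_undir", "layer1/w_res",
                     "decoder/w"):
            p = params[name]
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            lp, _ = model.loss_and_grads(h0, propset, labels, mask, training=False)
            p[idx] -= 2 * eps
            lm, _ = model.loss_and_grads(h0, propset, labels, mask, training=False)
            p[idx] += eps
            fd = (lp - lm) / (2 * eps)
            analytic = grads[name][idx]
            denom = max(abs(fd), abs(analytic), 1e-8)
            assert abs(fd - analytic) / denom <= 1e-4, name

    def test_subgraph_gradients_match_full_layer_rows(self, rng):
        """Backward through a node subset scatters into the right rows."""
        h, propset, p = random_instance(rng, n=6, f_in=5, f_out=5)
        cache = {}
        idx = np.array([0, 2, 5])
        sub_a = propset.a_in[np.ix_(idx, idx)]
        sub_ps = pg.PropagationSet(a_in=sub_a, a_out=propset.a_out[np.ix_(idx, idx)],
                                   a_undir=propset.a_undir[np.ix_(idx, idx)])
        out = pg.layer_forward(h[idx], sub_ps, p, node_idx=idx, cache=cache)
        grads, _ = layer_backward(cache, np.ones_like(out))
        assert grads["b_const"].shape == p.b_const.shape
        untouched = np.setdiff1d(np.arange(6), idx)
        np.testing.assert_array_equal(grads["b_const"][untouched], 0.0)
        np.testing.assert_array_equal(grads["gate_in"][untouched], 0.0)
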