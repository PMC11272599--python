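"""Architecture tests: GRU gate math against scalar oracles, layer gradients
against finite differences and scipy, and closed-form parameter accounting."""

import numpy as np
import pytest
from scipy.signal import correlate

from shockscale import _layers
from shockscale.net import (
    GRUParams,
    ModelConfig,
    build_model,
    count_parameters,
    gru_step,
    spatial_sizes,
)


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


class TestGRUStep:
    def test_zero_weights(self):
        p = GRUParams(W_z=np.zeros((1, 2)), W_r=np.zeros((1, 2)), W=np.zeros((1, 2)))
        z, r, h_tilde, h = gru_step(p, np.array([0.4]), np.array([1.0]))
        assert z == pytest.approx(0.5) and r == pytest.approx(0.5)
        assert h_tilde == pytest.approx(0.0)
        assert h == pytest.approx(0.2)  # (1 - 0.5)*0.4 + 0.5*0

    def test_saturated_update_gate_forgets_state(self):
        p = GRUParams(
            W_z=np.full((1, 2), 1e3), W_r=np.zeros((1, 2)), W=np.ones((1, 2))
        )
        z, r, h_tilde, h = gru_step(p, np.array([0.9]), np.array([0.3]))
        assert z == pytest.approx(1.0)
        assert h == pytest.approx(h_tilde)

    def test_matches_handwritten_scalar_evaluation(self):
        # independent scalar-by-scalar oracle for u=2, d=1
        rng = np.random.default_rng(42)
        Wz, Wr, W = (rng.normal(scale=0.5, size=(2, 3)) for _ in range(3))
        h_prev = np.array([0.1, -0.2])
        x = np.array([0.7])
        p = GRUParams(W_z=Wz, W_r=Wr, W=W)
        _, _, _, h = gru_step(p, h_prev, x)

        hx = [h_prev[0], h_prev[1], x[0]]
        z0 = _sigmoid(Wz[0][0] * hx[0] + Wz[0][1] * hx[1] + Wz[0][2] * hx[2])
        z1 = _sigmoid(Wz[1][0] * hx[0] + Wz[1][1] * hx[1] + Wz[1][2] * hx[2])
        r0 = _sigmoid(Wr[0][0] * hx[0] + Wr[0][1] * hx[1] + Wr[0][2] * hx[2])
        r1 = _sigmoid(Wr[1][0] * hx[0] + Wr[1][1] * hx[1] + Wr[1][2] * hx[2])
        rh = [r0 * h_prev[0], r1 * h_prev[1], x[0]]
        t0 = np.tanh(W[0][0] * rh[0] + W[0][1] * rh[1] + W[0][2] * rh[2])
        t1 = np.tanh(W[1][0] * rh[0] + W[1][1] * rh[1] + W[1][2] * rh[2])
        h0 = (1 - z0) * h_prev[0] + z0 * t0
        h1 = (1 - z1) * h_prev[1] + z1 * t1
        assert abs(h[0] - h0) < 1e-10 and abs(h[1] - h1) < 1e-10

    def test_dimension_mismatch_rejected(self):
        p = GRUParams(W_z=np.zeros((2, 3)), W_r=np.zeros((2, 3)), W=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="shape"):
            gru_step(p, np.zeros(3), np.zeros(1))

    def test_trainable_layer_matches_reference_with_biases_zeroed(self):
        rng = np.random.default_rng(3)
        u, d, T = 6, 2, 4
        layer = _layers.GRU(d, u, rng, bias=True)
        for k in ("bz", "br", "bh"):
            layer.params[k][:] = 0
        x = rng.normal(size=(1, T, d)).astype(np.float32)
        h_layer = layer.forward(x, train=False)[0]
        p = GRUParams(
            W_z=layer.params["Wz"].T.astype(float),
            W_r=layer.params["Wr"].T.astype(float),
            W=layer.params["Wh"].T.astype(float),
        )
        h = np.zeros(u)
        for t in range(T):
            _, _, _, h = gru_step(p, h, x[0, t].astype(float))
        assert np.max(np.abs(h_layer - h)) < 1e-5


class TestBuildModel:
    def test_spatial_size_chain_from_227(self):
        assert spatial_sizes(227) == [113, 56, 28, 14, 7]

    def test_softmax_normalized(self, tiny_model_cfg, rng):
        model = build_model(tiny_model_cfg, seed=0)
        x = rng.random((3, 32, 32, 3), dtype=np.float32)
        probs = model.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_cnn_only_differs_only_by_gru_block(self, tiny_model_cfg):
        from dataclasses import replace

        full = build_model(tiny_model_cfg, seed=0).layer_names()
        cnn = build_model(replace(tiny_model_cfg, variant="cnn_only"), seed=0).layer_names()
        assert [n for n in full if n not in ("reshape", "gru")] == cnn

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 32"):
            build_model(ModelConfig(input_size=31))

    @pytest.mark.parametrize("fill", [0.0, 1.0])
    def test_forward_finite_on_extreme_inputs(self, tiny_model_cfg, fill):
        model = build_model(tiny_model_cfg, seed=0)
        x = np.full((2, 32, 32, 3), fill, dtype=np.float32)
        assert np.all(np.isfinite(model.forward(x)))

    def test_gru_only_variant_runs(self):
        cfg = ModelConfig(variant="gru_only", input_size=16, gru_units=8, dense_units=8)
        model = build_model(cfg, seed=0)
        out = model.forward(np.zeros((2, 16, 16, 3), dtype=np.float32))
        assert out.shape == (2, 4)


class TestCountParameters:
    def test_default_config_closed_form(self):
        # independent arithmetic: conv (9*c_in+1)*f chained over
        # 3->16->32->64->64->128, GRU 3*(128*129+128), dense 128*128+128
        # and 128*4+4
        conv = 28 * 16 + 145 * 32 + 289 * 64 + 577 * 64 + 577 * 128
        gru = 3 * (128 * 129 + 128)
        dense = (128 * 128 + 128) + (128 * 4 + 4)
        assert conv == 134368 and gru == 49920 and dense == 17028
        assert count_parameters(ModelConfig()) == conv + gru + dense == 201316

    def test_within_published_budget(self):
        assert count_parameters(ModelConfig()) <= 208_000

    @pytest.mark.parametrize("variant", ["full", "cnn_only", "gru_only"])
    def test_equals_model_weight_tally(self, variant):
        cfg = ModelConfig(
            input_size=32, conv_filters=(4, 6, 8, 8, 12), gru_units=9,
            dense_units=11, variant=variant,
        )
        assert count_parameters(cfg) == build_model(cfg, seed=0).n_params()

    def test_doubling_filters_increases_conv_total(self):
        base = ModelConfig()
        doubled = ModelConfig(conv_filters=tuple(2 * f for f in base.conv_filters))
        assert count_parameters(doubled) > count_parameters(base)

    def test_bias_free_convention(self):
        # the gate equations carry no bias terms: 3*u*(u+d) for the GRU
        cfg = ModelConfig()
        diff = count_parameters(cfg) - count_parameters(cfg, include_biases=False)
        assert diff == sum(cfg.conv_filters) + 3 * cfg.gru_units + cfg.dense_units + cfg.n_classes


class TestLayerGradients:
    def test_conv_forward_matches_scipy_correlate(self, rng):
        conv = _layers.Conv2D(3, 4, rng)
        conv.params["b"][:] = 0.25
        x = rng.normal(size=(2, 8, 8, 3)).astype(np.float32)
        out = conv.forward(x, train=False)
        W = conv.params["W"]
        for b in range(2):
            for f in range(4):
                acc = sum(
                    correlate(np.pad(x[b, :, :, c], 1), W[:, :, c, f], mode="valid")
                    for c in range(3)
                )
                ref = np.maximum(acc + 0.25, 0)
                assert np.allclose(out[b, :, :, f], ref, atol=1e-5)

    def test_conv_gradients_exact_in_affine_regime(self, rng):
        # bias pushed past the ReLU kink -> the layer is affine and finite
        # differences are exact up to float32 rounding
        conv = _layers.Conv2D(2, 3, rng)
        conv.params["b"][:] = 5.0
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float32)
        out = conv.forward(x, train=False)
        R = rng.normal(size=out.shape).astype(np.float32)
        dx = conv.backward(R.copy())
        eps = 1e-2
        for k, P in conv.params.items():
            conv.forward(x, train=False)
            conv.backward(R.copy())
            g = conv.grads[k]
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in P.shape)
                old = P[idx]
                P[idx] = old + eps
                lp = float((conv.forward(x, False) * R).sum())
                P[idx] = old - eps
                lm = float((conv.forward(x, False) * R).sum())
                P[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-3 * max(1.0, abs(num))
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            old = x[idx]
            x[idx] = old + eps
            lp = float((conv.forward(x, False) * R).sum())
            x[idx] = old - eps
            lm = float((conv.forward(x, False) * R).sum())
            x[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx[idx]) < 1e-3 * max(1.0, abs(num))

    def test_maxpool_gradient_brute_force(self, rng):
        pool = _layers.MaxPool2x2()
        x = rng.normal(size=(1, 5, 6, 2)).astype(np.float32)
        out = pool.forward(x, train=False)
        R = rng.normal(size=out.shape).astype(np.float32)
        dx = pool.backward(R.copy())
        eps = 1e-3
        num = np.zeros_like(x)
        for idx in np.ndindex(*x.shape):
            old = x[idx]
            x[idx] = old + eps
            lp = float((pool.forward(x, False) * R).sum())
            x[idx] = old - eps
            lm = float((pool.forward(x, False) * R).sum())
            x[idx] = old
            num[idx] = (lp - lm) / (2 * eps)
        assert np.abs(num - dx).max() < 5e-3

    def test_gru_gradient_finite_difference(self, rng):
        layer = _layers.GRU(2, 3, rng)
        x = rng.normal(size=(2, 4, 2)).astype(np.float32)
        out = layer.forward(x, train=True)
        R = rng.normal(size=out.shape).astype(np.float32)
        dx = layer.backward(R.copy())
        eps = 1e-3
        for k, P in layer.params.items():
            layer.forward(x, train=True)
            layer.backward(R.copy())
            g = layer.grads[k]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in P.shape)
                old = P[idx]
                P[idx] = old + eps
                lp = float((layer.forward(x, True) * R).sum())
                P[idx] = old - eps
                lm = float((layer.forward(x, True) * R).sum())
                P[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 5e-3 * max(1.0, abs(num))
        for _ in range(4):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            old = x[idx]
            x[idx] = old + eps
            lp = float((layer.forward(x, True) * R).sum())
            x[idx] = old - eps
            lm = float((layer.forward(x, True) * R).sum())
            x[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx[idx]) < 5e-3 * max(1.0, abs(num))
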