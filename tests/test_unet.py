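"""Backbone: init determinism, parameter inventory, shapes, forward oracle."""

import numpy as np
import pytest

from cafs.errors import ShapeError
from cafs.losses import cross_entropy
from cafs.unet import NetworkConfig, UNet, forward, init_params


class TestInit:
    def test_same_seed_bit_identical(self, toy_net_config):
        a = init_params(toy_net_config, 11)
        b = init_params(toy_net_config, 11)
        assert a.equal(b)

    def test_different_seeds_differ(self, toy_net_config):
        a = init_params(toy_net_config, 11)
        b = init_params(toy_net_config, 12)
        assert not a.equal(b)

    def test_parameter_count_matches_layer_inventory(self):
        """Hand tally for depth 2, base 4, growth 2, 1 input channel,
        2 classes, transposed-conv upsampling, no attention."""
        cfg = NetworkConfig(depth=2, base_channels=4, dtype="float64")
        ps = init_params(cfg, 0)
        conv = lambda cin, cout, k: cout * cin * k * k + cout
        bn = lambda c: 2 * c
        expected = (
            conv(1, 4, 3) + bn(4) + conv(4, 4, 3) + bn(4)        # enc0
            + conv(4, 8, 3) + bn(8) + conv(8, 8, 3) + bn(8)      # enc1
            + 8 * 4 * 2 * 2 + 4                                  # dec0 up
            + conv(8, 4, 3) + bn(4) + conv(4, 4, 3) + bn(4)      # dec0
            + conv(4, 2, 1)                                      # head
        )
        assert ps.n_scalars() == expected

    def test_teacher_student_never_alias(self, toy_net_config):
        t = init_params(toy_net_config, 1, role="teacher")
        s = t.copy(role="student")
        s["head.W"][0, 0, 0, 0] += 1.0
        assert not np.array_equal(t["head.W"], s["head.W"])


class TestForward:
    @pytest.mark.parametrize("depth,hw", [(1, (4, 4)), (2, (8, 12)),
                                          (3, (16, 8))])
    def test_output_shape_contract(self, depth, hw):
        cfg = NetworkConfig(depth=depth, base_channels=2, dtype="float64")
        ps = init_params(cfg, 0)
        x = np.random.default_rng(0).normal(size=(2, 1) + hw)
        logits = UNet(cfg).forward(ps, x)
        assert logits.shape == (2, 2) + hw
        assert np.all(np.isfinite(logits))

    def test_indivisible_input_raises_shape_error(self):
        cfg = NetworkConfig(depth=3, base_channels=2, dtype="float64")
        ps = init_params(cfg, 0)
        with pytest.raises(ShapeError, match="divisible"):
            UNet(cfg).forward(ps, np.zeros((1, 1, 10, 12)))

    def test_zero_output_head_gives_zero_logits(self, toy_net_config):
        ps = init_params(toy_net_config, 0)
        ps["head.W"][:] = 0.0
        ps["head.b"][:] = 0.0
        logits = UNet(toy_net_config).forward(
            ps, np.random.default_rng(1).normal(size=(1, 1, 8, 8)))
        assert np.allclose(logits, 0.0)

    def test_forward_matches_straight_line_oracle(self):
        """Evaluation-mode forward of a depth-2 net reproduced by an
        independent scalar-loop re-evaluation of the same operations."""
        cfg = NetworkConfig(depth=2, base_channels=2, dtype="float64")
        ps = init_params(cfg, 3)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 1, 8, 8))
        got = UNet(cfg).forward(ps, x, train=False)

        def conv(x_, W, b):
            O, C, k, _ = W.shape
            p = (k - 1) // 2
            B, _, H, Wd = x_.shape
            xp = np.pad(x_, ((0, 0), (0, 0), (p, p), (p, p)))
            y = np.zeros((B, O, H, Wd))
            for bi in range(B):
                for o in range(O):
                    for h in range(H):
                        for w in range(Wd):
                            acc = b[o]
                            for c in range(C):
                                for i in range(k):
                                    for j in range(k):
                                        acc += W[o, c, i, j] \
                                            * xp[bi, c, h + i, w + j]
                            y[bi, o, h, w] = acc
            return y

        def bn_eval(x_, name):
            g = ps[f"{name}.gamma"]
            be = ps[f"{name}.beta"]
            rm = ps.buffers[f"{name}.mean"]
            rv = ps.buffers[f"{name}.var"]
            return g[None, :, None, None] \
                * (x_ - rm[None, :, None, None]) \
                / np.sqrt(rv[None, :, None, None] + 1e-5) \
                + be[None, :, None, None]

        def block(x_, name):
            z = np.maximum(bn_eval(conv(x_, ps[f"{name}.conv1.W"],
                                        ps[f"{name}.conv1.b"]),
                                   f"{name}.bn1"), 0.0)
            return np.maximum(bn_eval(conv(z, ps[f"{name}.conv2.W"],
                                           ps[f"{name}.conv2.b"]),
                                      f"{name}.bn2"), 0.0)

        def pool(x_):
            B, C, H, Wd = x_.shape
            y = np.zeros((B, C, H // 2, Wd // 2))
            for bi in range(B):
                for c in range(C):
                    for h in range(H // 2):
                        for w in range(Wd // 2):
                            y[bi, c, h, w] = x_[bi, c, 2 * h:2 * h + 2,
                                                2 * w:2 * w + 2].max()
            return y

        def up(x_, W, b):
            C, O, _, _ = W.shape
            B, _, H, Wd = x_.shape
            y = np.zeros((B, O, 2 * H, 2 * Wd))
            for bi in range(B):
                for o in range(O):
                    for h in range(H):
                        for w in range(Wd):
                            for c in range(C):
                                for i in range(2):
                                    for j in range(2):
                                        y[bi, o, 2 * h + i, 2 * w + j] += \
                                            W[c, o, i, j] * x_[bi, c, h, w]
            y += b[None, :, None, None]
            return y

        e0 = block(x, "enc0")
        e1 = block(pool(e0), "enc1")
        d0 = up(e1, ps["dec0.up.W"], ps["dec0.up.b"])
        d0 = block(np.concatenate([e0, d0], axis=1), "dec0")
        oracle = conv(d0, ps["head.W"], ps["head.b"])
        assert np.allclose(got, oracle, rtol=1e-9, atol=1e-11)

    def test_module_level_forward_accepts_2d_image(self, toy_net_config):
        ps = init_params(toy_net_config, 0)
        logits = forward(ps, np.zeros((8, 8)), toy_net_config)
        assert logits.shape == (1, 2, 8, 8)


class TestBackward:
    @pytest.mark.parametrize("attention,upsample", [
        (False, "transposed"), (True, "transposed"), (False, "nearest")])
    def test_gradients_match_central_differences(self, attention, upsample,
                                                 toy_attention_config):
        """Full-network analytic gradients vs central finite differences,
        sampled over every parameter tensor."""
        cfg = NetworkConfig(depth=2, base_channels=3, dtype="float64",
                            attention_enabled=attention,
                            attention=toy_attention_config,
                            upsample=upsample)
        net = UNet(cfg)
        ps = net.init_params(0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 1, 8, 8))
        t = (rng.random((2, 8, 8)) < 0.4).astype(np.int64)

        logits, caches = net.forward(ps, x, train=True, update_stats=False,
                                     want_cache=True)
        _, dl = cross_entropy(logits, t, with_grad=True)
        grads = net.backward(dl, caches, ps)
        assert set(grads) == set(ps.params)

        for name in ps.params:
            g = grads[name]
            flat = rng.choice(g.size, size=min(4, g.size), replace=False)
            for fi in flat:
                idx = np.unravel_index(fi, g.shape)
                eps = 1e-5
                orig = ps[name][idx]
                ps[name][idx] = orig + eps
                lp = cross_entropy(net.forward(ps, x, train=True,
                                               update_stats=False), t)
                ps[name][idx] = orig - eps
                lm = cross_entropy(net.forward(ps, x, train=True,
                                               update_stats=False), t)
                ps[name][idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= 1e-7 + 1e-4 * max(abs(fd),
                                                             abs(g[idx])), \
                    (name, idx, fd, g[idx])


class TestCheckpoint:
    def test_roundtrip(self, toy_net_config, tmp_path):
        from cafs.params import load_checkpoint, save_checkpoint

        ps = init_params(toy_net_config, 5, role="teacher")
        path = tmp_path / "ck.npz"
        save_checkpoint(path, ps, toy_net_config.to_dict(),
                        rng_state={"step": 3})
        back, cfg_dict, rng_state = load_checkpoint(path)
        assert back.equal(ps)
        assert back.role == "teacher"
        assert NetworkConfig.from_dict(cfg_dict) == toy_net_config
        assert rng_state == {"step": 3}

    def test_wrong_format_rejected(self, tmp_path):
        import json

        import numpy as np

        from cafs.params import load_checkpoint

        path = tmp_path / "bad.npz"
        meta = np.frombuffer(json.dumps({"format": "other"}).encode(),
                             dtype=np.uint8)
        np.savez(path, __meta__=meta)
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(path)
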