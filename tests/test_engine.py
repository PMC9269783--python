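"""Co-training engine: phases, isolation, determinism, gradient oracles."""

from dataclasses import replace

import numpy as np
import pytest

from cafs.data import ImageSample
from cafs.engine import (SGD, TrainConfig, batchify, feedback_gradient,
                         feedback_step, generate_pseudo_masks,
                         pretrain_teacher, student_step, train,
                         train_supervised, predict)
from cafs.errors import ConfigError, DataError
from cafs.losses import cross_entropy, log_softmax
from cafs.phantom import PhantomSpec, generate_cohort
from cafs.unet import NetworkConfig, UNet


TINY_SPEC = PhantomSpec(frame_size=16, tumor_area_fraction_range=(0.1, 0.3),
                        boundary_harmonics=2, boundary_roughness=0.1,
                        contrast_gap=0.1, distractor_count=1, noise_sd=0.03,
                        bias_field_strength=0.1, seed=0)


def tiny_cohort():
    samples = generate_cohort(TINY_SPEC, 6, (2, 2), seed=0)
    labeled = [s for s in samples if s.patient_id in ("P000", "P001")]
    unlabeled = [s for s in samples if s.patient_id in ("P002", "P003")]
    valid = [s for s in samples if s.patient_id in ("P004", "P005")]
    return labeled, unlabeled, valid


def tiny_train_config(**kw):
    base = dict(learning_rate=0.05, momentum=0.0, weight_decay=1e-4,
                pretrain_iterations=3, iterations=4, batch_size=2,
                eval_every=2, feedback_warmup=0, attention_enabled=False,
                seed=0)
    base.update(kw)
    return TrainConfig(**base)


def tiny_net_config(**kw):
    base = dict(depth=2, base_channels=2, dtype="float64")
    base.update(kw)
    return NetworkConfig(**base)


class TestPretrain:
    def test_zero_iterations_returns_initialization(self):
        labeled, _, _ = tiny_cohort()
        cfg = tiny_train_config(pretrain_iterations=0)
        ncfg = tiny_net_config()
        teacher, hist = pretrain_teacher(labeled, cfg, ncfg)
        assert teacher.equal(UNet(ncfg).init_params(cfg.seed + 1,
                                                    role="teacher"))
        assert hist == []

    def test_loss_decreases_when_overfitting_one_sample(self):
        labeled, _, _ = tiny_cohort()
        cfg = tiny_train_config(pretrain_iterations=50, batch_size=1,
                                learning_rate=0.1, momentum=0.9)
        _, hist = pretrain_teacher(labeled[:1], cfg, tiny_net_config())
        losses = [r["teacher_loss"] for r in hist]
        head = np.mean(losses[:10])
        tail = np.mean(losses[-10:])
        assert tail < head
        assert all(np.isfinite(losses))

    def test_fixed_seed_repeat_bitwise_identical(self):
        labeled, _, _ = tiny_cohort()
        cfg = tiny_train_config(pretrain_iterations=5)
        a, _ = pretrain_teacher(labeled, cfg, tiny_net_config())
        b, _ = pretrain_teacher(labeled, cfg, tiny_net_config())
        assert a.equal(b)

    def test_empty_labeled_rejected(self):
        with pytest.raises(ConfigError):
            pretrain_teacher([], tiny_train_config(), tiny_net_config())


class TestPseudoMasks:
    def test_zeroed_head_ties_resolve_to_background(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        teacher["head.W"][:] = 0.0
        teacher["head.b"][:] = 0.0
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        assert np.all(pm.hard == 0)

    def test_soft_masks_sum_to_one(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x, mode="soft")
        assert np.allclose(pm.soft.sum(axis=1), 1.0, atol=1e-12)

    def test_hard_masks_match_forward_argmax_oracle(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(7)
        x = np.random.default_rng(3).random((1, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        logits = net.forward(teacher, x, train=False)
        oracle = np.zeros((1, 16, 16), dtype=np.int8)
        for h in range(16):
            for w in range(16):
                if logits[0, 1, h, w] > logits[0, 0, h, w]:
                    oracle[0, h, w] = 1
        assert np.array_equal(pm.hard, oracle)

    def test_regenerated_masks_identical(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        a = generate_pseudo_masks(net, teacher, x)
        b = generate_pseudo_masks(net, teacher, x)
        assert np.array_equal(a.hard, b.hard)
        assert np.array_equal(a.soft, b.soft)


class TestStudentStep:
    def test_zero_learning_rate_leaves_student_unchanged(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        before = student.copy()
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        cfg = tiny_train_config(learning_rate=1e-300, weight_decay=0.0)
        student_step(net, student, x, pm, cfg)
        for k in before.params:
            assert np.allclose(student[k], before[k], atol=1e-290)

    def test_update_matches_finite_difference_oracle(self):
        """delta == -lr (grad + wd * theta), with grad checked by central
        finite differences of the train-mode loss."""
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        before = student.copy()
        rng = np.random.default_rng(5)
        x = rng.random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        cfg = tiny_train_config(learning_rate=0.01, weight_decay=0.01,
                                momentum=0.0)
        student_step(net, student, x, pm, cfg, opt=SGD(0.0))

        def loss_at(ps):
            logits = net.forward(ps, x, train=True, update_stats=False)
            return cross_entropy(logits, pm.hard.astype(np.int64))

        for name in before.params:
            delta = student[name] - before[name]
            flat = rng.choice(delta.size, size=min(3, delta.size),
                              replace=False)
            for fi in flat:
                idx = np.unravel_index(fi, delta.shape)
                eps = 1e-7
                orig = before[name][idx]
                before[name][idx] = orig + eps
                lp = loss_at(before)
                before[name][idx] = orig - eps
                lm = loss_at(before)
                before[name][idx] = orig
                fd = (lp - lm) / (2 * eps)
                expected = -cfg.learning_rate * (fd + cfg.weight_decay * orig)
                assert delta[idx] == pytest.approx(expected, rel=1e-3,
                                                   abs=1e-9)

    def test_teacher_bitwise_untouched(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        snapshot = teacher.copy()
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        for _ in range(3):
            student_step(net, student, x, pm, tiny_train_config())
        assert teacher.equal(snapshot)

    def test_misaligned_batch_rejected(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        pm = generate_pseudo_masks(net, teacher, x)
        from cafs.errors import ShapeError
        with pytest.raises(ShapeError):
            student_step(net, net.init_params(2), x[:1], pm,
                         tiny_train_config())


class TestFeedback:
    def test_near_stationary_student_leaves_teacher_unchanged(self):
        """A student with (numerically) zero labeled loss produces a
        vanishing feedback gradient."""
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        # force the student to predict background with certainty
        student["head.W"][:] = 0.0
        student["head.b"][:] = np.array([50.0, -50.0])
        x_u = np.random.default_rng(0).random((2, 1, 16, 16))
        x_l = np.random.default_rng(1).random((2, 1, 16, 16))
        y_l = np.zeros((2, 16, 16), dtype=np.int64)  # all background: exact
        cfg = tiny_train_config()
        grads, loss_fb = feedback_gradient(net, teacher, student, x_u, x_l,
                                           y_l, cfg)
        assert loss_fb < 1e-12
        assert max(np.abs(g).max() for g in grads.values()) < 1e-12

    def test_student_untouched_by_feedback_step(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        pre = student.copy()
        snap = student.copy()
        x_u = np.random.default_rng(0).random((2, 1, 16, 16))
        x_l = np.random.default_rng(1).random((2, 1, 16, 16))
        y_l = (np.random.default_rng(2).random((2, 16, 16)) < 0.3
               ).astype(np.int64)
        feedback_step(net, teacher, pre, student, x_u, x_l, y_l,
                      tiny_train_config())
        assert student.equal(snap)

    def test_meta_gradient_matches_unrolled_finite_differences(self):
        """Perturb each teacher parameter, re-run pseudo-masks -> virtual
        student step -> labeled loss, and compare with the analytic
        gradient (one-level net on 4x4 inputs)."""
        ncfg = NetworkConfig(depth=1, base_channels=3, dtype="float64")
        net = UNet(ncfg)
        teacher = net.init_params(0)
        student = net.init_params(1)
        rng = np.random.default_rng(2)
        x_u = rng.normal(size=(2, 1, 4, 4))
        x_l = rng.normal(size=(2, 1, 4, 4))
        y_l = (rng.random((2, 4, 4)) < 0.4).astype(np.int64)
        cfg = tiny_train_config(learning_rate=0.05, weight_decay=0.01)
        grads, _ = feedback_gradient(net, teacher, student, x_u, x_l, y_l,
                                     cfg)

        def unrolled(tp):
            zT = net.forward(tp, x_u, train=False, update_stats=False)
            q = np.exp(log_softmax(zT, axis=1))
            z0, c0 = net.forward(student, x_u, train=False,
                                 update_stats=False, want_cache=True)
            _, dl0 = cross_entropy(z0, q, with_grad=True)
            g_s = net.backward(dl0, c0, student)
            th = student.copy()
            for k in th.params:
                th.params[k] = student[k] - cfg.learning_rate * (
                    g_s[k] + cfg.weight_decay * student[k])
            return cross_entropy(net.forward(th, x_l, train=False,
                                             update_stats=False), y_l)

        for name in teacher.params:
            g = grads[name]
            flat = rng.choice(g.size, size=min(4, g.size), replace=False)
            for fi in flat:
                idx = np.unravel_index(fi, g.shape)
                eps = 1e-5
                orig = teacher[name][idx]
                teacher[name][idx] = orig + eps
                lp = unrolled(teacher)
                teacher[name][idx] = orig - eps
                lm = unrolled(teacher)
                teacher[name][idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[idx]) <= 1e-8 + 1e-2 * max(abs(fd),
                                                             abs(g[idx])), \
                    (name, idx, fd, g[idx])

    def test_feedback_disabled_teacher_frozen_after_pretraining(self):
        labeled, unlabeled, valid = tiny_cohort()
        cfg = tiny_train_config(feedback_enabled=False,
                                teacher_refresh_every=0)
        ncfg = tiny_net_config()
        pretrained, _ = pretrain_teacher(labeled, cfg, ncfg)
        teacher, _, _ = train(labeled, unlabeled, valid, cfg, ncfg,
                              teacher_init=pretrained)
        assert teacher.equal(pretrained)

    def test_feedback_without_student_step_is_protocol_error(self):
        from cafs.errors import ProtocolError

        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        x = np.random.default_rng(0).random((2, 1, 16, 16))
        y = np.zeros((2, 16, 16), dtype=np.int64)
        with pytest.raises(ProtocolError):
            feedback_step(net, teacher, None, student, x, x, y,
                          tiny_train_config())

    def test_scaled_fallback_mode_updates_teacher(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        teacher = net.init_params(1)
        student = net.init_params(2)
        snap = teacher.copy()
        x_u = np.random.default_rng(0).random((2, 1, 16, 16))
        x_l = np.random.default_rng(1).random((2, 1, 16, 16))
        y_l = (np.random.default_rng(2).random((2, 16, 16)) < 0.3
               ).astype(np.int64)
        cfg = tiny_train_config(feedback_mode="scaled")
        feedback_step(net, teacher, student.copy(), student, x_u, x_l, y_l,
                      cfg)
        assert not teacher.equal(snap)


class TestTrainLoop:
    def test_zero_iterations(self):
        labeled, unlabeled, valid = tiny_cohort()
        cfg = tiny_train_config(iterations=0, pretrain_iterations=2)
        ncfg = tiny_net_config()
        teacher, student, hist = train(labeled, unlabeled, valid, cfg, ncfg)
        pre, _ = pretrain_teacher(labeled, cfg, ncfg, valid=valid)
        assert teacher.equal(pre)
        assert student.equal(UNet(ncfg).init_params(cfg.seed + 2,
                                                    role="student"))

    def test_history_bookkeeping(self):
        labeled, unlabeled, valid = tiny_cohort()
        cfg = tiny_train_config(iterations=5, pretrain_iterations=3)
        _, _, hist = train(labeled, unlabeled, valid, cfg, tiny_net_config())
        co = [r for r in hist.records if r.get("phase") == "cotrain"]
        assert [r["step"] for r in co] == [1, 2, 3, 4, 5]
        for r in hist.records:
            for k, v in r.items():
                if isinstance(v, float):
                    assert np.isfinite(v)

    def test_bitwise_reproducibility_of_histories_and_models(self):
        labeled, unlabeled, valid = tiny_cohort()
        cfg = tiny_train_config(iterations=4, pretrain_iterations=2)
        ncfg = tiny_net_config()
        t1, s1, h1 = train(labeled, unlabeled, valid, cfg, ncfg)
        t2, s2, h2 = train(labeled, unlabeled, valid, cfg, ncfg)
        assert h1.jsonl_bytes() == h2.jsonl_bytes()
        assert t1.equal(t2) and s1.equal(s2)

    def test_patient_leakage_detected(self):
        labeled, unlabeled, valid = tiny_cohort()
        with pytest.raises(DataError, match="leakage"):
            train(labeled, unlabeled, valid + labeled[:1],
                  tiny_train_config(), tiny_net_config())

    def test_supervised_baseline_runs_and_is_deterministic(self):
        labeled, _, valid = tiny_cohort()
        cfg = tiny_train_config(iterations=2, pretrain_iterations=2)
        p1, h1 = train_supervised(labeled, valid, cfg, tiny_net_config())
        p2, _ = train_supervised(labeled, valid, cfg, tiny_net_config())
        assert p1.equal(p2)
        assert p1.role == "supervised"


class TestPredict:
    def test_deterministic_and_binary(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        student = net.init_params(3)
        labeled, _, _ = tiny_cohort()
        m1 = predict(net, student, labeled[0])
        m2 = predict(net, student, labeled[0])
        assert np.array_equal(m1, m2)
        assert set(np.unique(m1)) <= {0, 1}

    def test_background_forced_head_gives_empty_mask(self):
        ncfg = tiny_net_config()
        net = UNet(ncfg)
        student = net.init_params(3)
        student["head.W"][:] = 0.0
        student["head.b"][:] = np.array([5.0, -5.0])
        labeled, _, _ = tiny_cohort()
        assert predict(net, student, labeled[0]).sum() == 0
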