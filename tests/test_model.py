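"""Backbone contracts, the freeze/unfreeze schedule, and inference."""

import numpy as np
import pytest

from synemclass import _nn
from synemclass import model as mm
from synemclass.reconstruct_io import Patch

from conftest import make_study


def random_patch(rng, size=64, label="excitatory"):
    return Patch(rng.random((size, size)), (size / 2, size / 2), 0,
                 label, "s0", "c0")


class TestBuildModel:
    def test_unknown_backbone_is_error(self):
        with pytest.raises(ValueError, match="backbone"):
            mm.build_model(mm.ModelConfig(backbone="vgg"))

    def test_head_has_no_bias_term(self):
        net = mm.build_model(mm.ModelConfig())
        assert net.head.b is None

    def test_head_input_dimension_contract(self):
        cfg = mm.ModelConfig(backbone="small_cnn")
        net = mm.build_model(cfg)
        assert net.head.W.shape == (2, cfg.head_in_features)
        assert mm.ModelConfig(backbone="resnext50").head_in_features == 2048

    def test_forward_returns_two_logits(self, rng):
        net = mm.build_model(mm.ModelConfig(input_size=128))
        x = mm.patches_to_array([random_patch(rng, 128)], 128)
        assert net.logits(x).shape == (1, 2)

    def test_n_classes_must_be_two(self):
        with pytest.raises(ValueError, match="n_classes"):
            mm.ModelConfig(n_classes=3)


class TestGradients:
    def test_conv_backward_matches_finite_differences(self, rng):
        """Analytic conv gradients agree with central differences."""
        conv = _nn.Conv2d(2, 3, 3, stride=2, pad=1, rng=rng)
        x = rng.normal(size=(2, 2, 8, 8))
        y = conv.forward(x, train=True)
        dy = rng.normal(size=y.shape)
        dx = conv.backward(dy)
        eps = 1e-6
        for idx in [(0, 1, 3, 4), (1, 0, 0, 0), (1, 1, 7, 7)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (np.sum(conv.forward(xp) * dy) -
                   np.sum(conv.forward(xm) * dy)) / (2 * eps)
            assert num == pytest.approx(dx[idx], rel=1e-5, abs=1e-8)
        for widx in [(0, 0, 0, 0), (2, 1, 2, 2)]:
            orig = conv.W[widx]
            conv.W[widx] = orig + eps
            yp = np.sum(conv.forward(x) * dy)
            conv.W[widx] = orig - eps
            ym = np.sum(conv.forward(x) * dy)
            conv.W[widx] = orig
            conv.forward(x, train=True)
            conv.backward(dy)
            assert (yp - ym) / (2 * eps) == pytest.approx(
                conv.dW[widx], rel=1e-5, abs=1e-8)


class TestTwoPhaseTraining:
    def test_phase1_freezes_body_phase2_updates_it(self, tiny_study):
        train, val, _ = tiny_study
        cfg = mm.ModelConfig(input_size=64, epochs_phase1=2, epochs_phase2=2,
                             seed=1)
        net = mm.build_model(cfg)
        before = mm.parameter_checksum(net.body_params)
        report = mm.train_two_phase(net, train, val, cfg)
        assert report.body_checksum_start == before
        assert report.body_checksum_phase1_end == before   # frozen in phase 1
        assert report.body_checksum_end != before          # tuned in phase 2
        assert set(report.history["phase"]) == {1, 2}

    def test_empty_split_is_error(self, tiny_study):
        train, val, _ = tiny_study
        cfg = mm.ModelConfig(input_size=64, epochs_phase1=1, epochs_phase2=1)
        with pytest.raises(ValueError, match="non-empty"):
            mm.train_two_phase(mm.build_model(cfg), [], val, cfg)

    def test_best_model_is_max_val_accuracy(self, trained_model):
        _, _, report = trained_model
        assert report.best_val_accuracy == report.history["val_acc"].max()
        first_best = int(report.history["val_acc"].idxmax())
        assert report.best_epoch == report.history.loc[first_best, "epoch"]

    def test_monotone_separability_in_effect_size(self):
        """Mean test accuracy never decreases as the class effect grows."""
        from synemclass.synthetic_em import ClassParams, _default_class_params

        def params(level):
            cp = _default_class_params()
            if level == 0:
                cp["excitatory"] = cp["inhibitory"] = ClassParams(
                    (24.0, 6.0), (0.020, 0.005), 0.25)
            elif level == 1:
                cp["excitatory"] = ClassParams((30.0, 6.0), (0.018, 0.004), 0.35)
                cp["inhibitory"] = ClassParams((18.0, 6.0), (0.025, 0.005), 0.15)
            else:
                cp["excitatory"] = ClassParams((40.0, 3.0), (0.018, 0.004), 0.45)
                cp["inhibitory"] = ClassParams((10.0, 3.0), (0.025, 0.005), 0.15)
            return cp

        means = []
        for level in (0, 1, 2):
            accs = []
            tr, va, te = make_study(17, class_params=params(level))
            labs = mm.labels_to_array(te)
            for seed in (0, 1, 2):
                cfg = mm.ModelConfig(input_size=128, epochs_phase1=5,
                                     epochs_phase2=10, seed=seed)
                net = mm.build_model(cfg)
                mm.train_two_phase(net, tr, va, cfg)
                probs = mm.predict_patches(net, te, 128)
                accs.append(float((probs.argmax(1) == labs).mean()))
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05
        assert means[1] <= means[2] + 0.05
        assert means[2] > means[0]


class TestInference:
    def test_probabilities_normalised(self, trained_model, tiny_study):
        net, cfg, _ = trained_model
        _, _, test = tiny_study
        probs = mm.predict_patches(net, test[:10], cfg.input_size)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_patch_identical_probabilities(self, trained_model,
                                                     tiny_study):
        net, cfg, _ = trained_model
        _, _, test = tiny_study
        a = mm.predict_patch(net, test[0], cfg.input_size)
        b = mm.predict_patch(net, test[0], cfg.input_size)
        np.testing.assert_array_equal(a, b)

    def test_probabilities_match_independent_softmax(self, trained_model,
                                                     tiny_study):
        net, cfg, _ = trained_model
        _, _, test = tiny_study
        x = mm.patches_to_array([test[0]], cfg.input_size)
        logits = net.logits(x)[0]
        manual = np.exp(logits - logits.max())
        manual = manual / manual.sum()
        probs = mm.predict_patch(net, test[0], cfg.input_size)
        np.testing.assert_allclose(probs, manual, atol=1e-12)

    def test_checkpoint_round_trip(self, trained_model, tiny_study, tmp_path):
        net, cfg, _ = trained_model
        _, _, test = tiny_study
        path = tmp_path / "ck.npz"
        mm.save_checkpoint(net, path)
        net2 = mm.load_checkpoint(path, cfg)
        a = mm.predict_patches(net, test[:5], cfg.input_size)
        b = mm.predict_patches(net2, test[:5], cfg.input_size)
        np.testing.assert_array_equal(a, b)
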