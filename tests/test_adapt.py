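"""Adaptation losses and the training loop.

The MK-MMD estimator is checked against an independent naive double-sum
oracle, against a hand-evaluated closed form, and for its two-sample
behaviour (zero under equality, monotone under mean shift).
"""

import numpy as np
import pytest

from eegtransfer.adapt import (KernelFamily, TrainConfig, build_model,
                               coral_loss, coral_loss_with_grad,
                               load_checkpoint, make_kernel_family, mk_mmd2,
                               mk_mmd2_with_grad, predict, save_checkpoint,
                               train)
from eegtransfer.encode import EncodedImage
from eegtransfer.errors import InvalidArgumentError


def naive_mk_mmd2(s, t, family, estimator="biased"):
    """O(n²) double-loop oracle evaluating the kernel sums term by term."""
    s, t = np.atleast_2d(s), np.atleast_2d(t)
    n, m = len(s), len(t)

    def k(x, y):
        d2 = float(((x - y) ** 2).sum())
        return sum(b * np.exp(-d2 / g)
                   for b, g in zip(family.beta, family.gammas))

    if estimator == "biased":
        ss = sum(k(s[i], s[j]) for i in range(n) for j in range(n)) / n**2
        tt = sum(k(t[i], t[j]) for i in range(m) for j in range(m)) / m**2
    else:
        ss = sum(k(s[i], s[j]) for i in range(n) for j in range(n) if i != j) \
            / (n * (n - 1))
        tt = sum(k(t[i], t[j]) for i in range(m) for j in range(m) if i != j) \
            / (m * (m - 1))
    st = sum(k(s[i], t[j]) for i in range(n) for j in range(m)) / (n * m)
    return ss + tt - 2 * st


def unit_gaussian_family():
    # k(x, y) = exp(-(x-y)^2 / 2): bandwidth sigma = 1
    return KernelFamily(bandwidths=[1.0], beta=[1.0])


class TestMKMMD:
    def test_singleton_closed_form(self):
        val = mk_mmd2(np.array([[0.0]]), np.array([[1.0]]),
                      unit_gaussian_family())
        assert val == pytest.approx(2.0 - 2.0 * np.exp(-0.5), abs=1e-12)

    def test_identical_sets_give_zero(self, rng):
        x = rng.normal(size=(20, 4))
        fam = make_kernel_family(x, m=5)
        assert mk_mmd2(x, x, fam) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_beta_reduces_to_single_kernel(self, rng):
        s = rng.normal(size=(8, 3))
        t = rng.normal(size=(6, 3)) + 0.3
        multi = KernelFamily(bandwidths=[0.5, 1.0, 2.0], beta=[1.0, 0.0, 0.0])
        single = KernelFamily(bandwidths=[0.5], beta=[1.0])
        assert mk_mmd2(s, t, multi) == pytest.approx(mk_mmd2(s, t, single),
                                                     rel=1e-12)

    @pytest.mark.parametrize("estimator", ["biased", "unbiased"])
    def test_matches_naive_oracle(self, rng, estimator):
        for _ in range(10):
            n, m, d = rng.integers(2, 12, size=3)
            s = rng.normal(size=(n, d))
            t = rng.normal(size=(m, d)) + rng.normal()
            fam = make_kernel_family(np.vstack([s, t]), m=int(rng.integers(1, 6)))
            prod = mk_mmd2(s, t, fam, estimator)
            oracle = naive_mk_mmd2(s, t, fam, estimator)
            assert prod == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_biased_nonnegative_unbiased_centred_under_null(self, rng):
        fam = KernelFamily(bandwidths=[1.0, 2.0], beta=[0.5, 0.5])
        vals = []
        for _ in range(200):
            s = rng.normal(size=(8, 2))
            t = rng.normal(size=(8, 2))
            assert mk_mmd2(s, t, fam, "biased") >= 0.0
            vals.append(mk_mmd2(s, t, fam, "unbiased"))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) <= 2 * se

    def test_monotone_in_mean_shift(self, rng):
        fam = KernelFamily(bandwidths=[1.0], beta=[1.0])
        means = []
        for mu in [0.0, 0.5, 1.0, 2.0]:
            reps = [mk_mmd2(rng.normal(size=(256, 1)),
                            rng.normal(loc=mu, size=(256, 1)), fam)
                    for _ in range(20)]
            means.append(np.mean(reps))
        assert all(b > a - 1e-3 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_gradient_matches_finite_differences(self, rng):
        s = rng.normal(size=(5, 3))
        t = rng.normal(size=(4, 3)) + 0.5
        fam = make_kernel_family(np.vstack([s, t]), m=3)
        _, gs, gt = mk_mmd2_with_grad(s, t, fam)
        eps = 1e-6
        for i in range(5):
            for j in range(3):
                sp = s.copy()
                sp[i, j] += eps
                num = (mk_mmd2(sp, t, fam) - mk_mmd2(s, t, fam)) / eps
                assert num == pytest.approx(gs[i, j], rel=1e-3, abs=1e-6)

    def test_dimension_mismatch_and_empty_rejected(self):
        fam = unit_gaussian_family()
        with pytest.raises(InvalidArgumentError):
            mk_mmd2(np.zeros((3, 2)), np.zeros((3, 3)), fam)
        with pytest.raises(InvalidArgumentError):
            mk_mmd2(np.zeros((0, 2)), np.zeros((3, 2)), fam)
        with pytest.raises(InvalidArgumentError):
            mk_mmd2(np.zeros((1, 2)), np.zeros((3, 2)), fam, "unbiased")


class TestKernelFamily:
    def test_single_kernel_beta_is_one(self):
        fam = make_kernel_family(np.array([[0.0], [1.0]]), m=1)
        assert fam.beta.tolist() == [1.0]

    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_convex_weights(self, rng, m):
        fam = make_kernel_family(rng.normal(size=(10, 2)), m=m)
        assert fam.beta.sum() == pytest.approx(1.0, abs=1e-12)
        assert (fam.beta >= 0).all()

    def test_median_heuristic_two_points(self):
        # only pairwise distance is 2 -> central bandwidth sigma = 2
        fam = make_kernel_family(np.array([[0.0], [2.0]]), m=1)
        assert fam.bandwidths[0] == pytest.approx(2.0)

    def test_geometric_ladder_centred_on_median(self):
        fam = make_kernel_family(np.array([[0.0], [2.0]]), m=5, spacing=2.0)
        assert np.allclose(fam.bandwidths, 2.0 * np.array([0.25, 0.5, 1, 2, 4]))

    def test_identical_features_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            fam = make_kernel_family(np.zeros((4, 2)), m=2)
        assert (fam.bandwidths > 0).all()

    def test_gram_matrices_positive_semidefinite(self, rng):
        x = rng.normal(size=(12, 3))
        fam = make_kernel_family(x, m=5)
        for k in fam.kernels:
            eigs = np.linalg.eigvalsh(k(x, x))
            assert eigs.min() >= -1e-8

    def test_invalid_beta_rejected(self):
        with pytest.raises(InvalidArgumentError):
            KernelFamily(bandwidths=[1.0, 2.0], beta=[0.7, 0.7])


class TestCoral:
    def test_identical_sets_give_zero(self, rng):
        x = rng.normal(size=(10, 4))
        assert coral_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_variance_one_vs_two_closed_form(self):
        s = np.array([[-1.0], [0.0], [1.0]])   # sample variance 1
        t = np.array([[-1.0], [1.0]])          # sample variance 2
        assert coral_loss(s, t) == pytest.approx(0.25, abs=1e-12)

    def test_symmetry(self, rng):
        s = rng.normal(size=(9, 3))
        t = 2 * rng.normal(size=(7, 3))
        assert coral_loss(s, t) == pytest.approx(coral_loss(t, s), rel=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            coral_loss(np.zeros((1, 2)), np.zeros((5, 2)))

    def test_gradient_matches_finite_differences(self, rng):
        s = rng.normal(size=(6, 2))
        t = rng.normal(size=(5, 2)) * 1.5
        _, gs, _ = coral_loss_with_grad(s, t)
        eps = 1e-6
        for i in range(6):
            for j in range(2):
                sp = s.copy()
                sp[i, j] += eps
                num = (coral_loss(sp, t) - coral_loss(s, t)) / eps
                assert num == pytest.approx(gs[i, j], rel=1e-3, abs=1e-8)


def toy_images(n_per_class, size=32, seed=0):
    """Linearly separable toy set: class 0 dark top half, class 1 dark bottom."""
    rng = np.random.default_rng(seed)
    images = []
    for label, name in [(0, "healthy"), (1, "depressed")]:
        for i in range(n_per_class):
            px = np.full((size, size), 255, dtype=np.uint8)
            rows = slice(0, size // 2) if label == 0 else slice(size // 2, size)
            px[rows, :] = (rng.uniform(0, 80, size=(size // 2, size))).astype(np.uint8)
            images.append(EncodedImage(px, "merged_chart", f"{name}{i}",
                                       name, i))
    return images


class TestModelAndTraining:
    def test_source_only_has_no_adaptation_terms(self):
        model = build_model("source_only", input_shape=(1, 32, 32))
        assert model.adaptation_terms() == 0
        assert model.kernel_family is None and model.discriminator is None

    def test_dan_has_one_mmd_term_per_adapted_layer(self):
        model = build_model("dan", input_shape=(1, 32, 32))
        assert model.adaptation_terms() == 3

    def test_dann_has_discriminator_behind_reversal(self):
        model = build_model("dann", input_shape=(1, 32, 32))
        assert model.discriminator is not None
        assert model.discriminator.layers[0] is model.grl

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_model("mmd_net", input_shape=(1, 32, 32))

    def test_frozen_stage_bit_identical_after_training(self):
        imgs = toy_images(6)
        model = build_model("dan", input_shape=(1, 32, 32), seed=1)
        before = model.backbone.frozen_parameter_vector().copy()
        cfg = TrainConfig(epochs=5, batch_size=4, seed=1, lambda_=0.05)
        model, _ = train(model, imgs, imgs[:4], cfg)
        assert np.array_equal(before, model.backbone.frozen_parameter_vector())

    def test_lambda_zero_dan_matches_source_only_trajectory(self):
        imgs = toy_images(4)
        curves = {}
        finals = {}
        for method, lam in [("dan", 0.0), ("source_only", 0.0)]:
            model = build_model(method, input_shape=(1, 32, 32), seed=3)
            cfg = TrainConfig(epochs=4, batch_size=4, seed=3, lambda_=lam)
            model, curve = train(model, imgs, imgs, cfg,
                                 target_labels=[0] * 4 + [1] * 4)
            curves[method] = curve.accuracies
            finals[method] = model.backbone.fc8.params["W"].copy()
        assert curves["dan"] == curves["source_only"]
        assert np.array_equal(finals["dan"], finals["source_only"])

    def test_single_epoch_smoke(self):
        imgs = toy_images(1)
        model = build_model("dan", input_shape=(1, 32, 32))
        cfg = TrainConfig(epochs=1, batch_size=2, seed=0, lambda_=0.05)
        model, curve = train(model, imgs, imgs, cfg, target_labels=[0, 1])
        assert len(curve) == 1

    def test_overfits_linearly_separable_toy_set(self):
        imgs = toy_images(8, seed=4)
        model = build_model("source_only", input_shape=(1, 32, 32), seed=2)
        cfg = TrainConfig(epochs=30, batch_size=8, seed=2, lambda_=0.0)
        model, _ = train(model, imgs, imgs[:4], cfg)
        pred, scores = predict(model, imgs)
        truth = np.array([0] * 8 + [1] * 8)
        assert (pred == truth).mean() == 1.0
        assert scores.shape == (16, 2)

    def test_prediction_tie_breaks_to_lower_index(self):
        model = build_model("source_only", input_shape=(1, 32, 32))
        logits = np.array([[0.7, 0.3], [0.5, 0.5]])
        assert logits.argmax(axis=1).tolist() == [0, 0]

    def test_empty_domain_rejected(self):
        model = build_model("source_only", input_shape=(1, 32, 32))
        with pytest.raises(InvalidArgumentError):
            train(model, [], toy_images(2), TrainConfig(epochs=1))

    def test_wrong_image_shape_rejected(self):
        model = build_model("source_only", input_shape=(1, 32, 32))
        with pytest.raises(InvalidArgumentError):
            predict(model, toy_images(1, size=48))

    @pytest.mark.parametrize("method", ["dan", "dann", "deepcoral"])
    def test_adaptation_methods_run_and_record_curves(self, method):
        imgs = toy_images(4)
        model = build_model(method, input_shape=(1, 32, 32), seed=0)
        cfg = TrainConfig(epochs=3, batch_size=4, seed=0, lambda_=0.1)
        model, curve = train(model, imgs, imgs, cfg,
                             target_labels=[0] * 4 + [1] * 4)
        assert len(curve) == 3
        assert all(0.0 <= a <= 1.0 for a in curve.accuracies)

    def test_training_log_records_losses(self):
        imgs = toy_images(4)
        model = build_model("dan", input_shape=(1, 32, 32), seed=0)
        cfg = TrainConfig(epochs=3, batch_size=4, seed=0, lambda_=0.1,
                          lambda_ramp=False)
        model, curve = train(model, imgs, imgs, cfg)
        assert len(curve.cls_losses) == 3
        assert len(curve.adapt_losses) == 3
        assert all(np.isfinite(curve.cls_losses))
        assert all(v >= 0 for v in curve.adapt_losses)

    @pytest.mark.parametrize("method", ["dan", "dann"])
    def test_checkpoint_roundtrip(self, tmp_path, method):
        imgs = toy_images(4)
        model = build_model(method, input_shape=(1, 32, 32), seed=6)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=6, lambda_=0.1)
        model, _ = train(model, imgs, imgs, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, cfg)
        restored = load_checkpoint(path)
        pred_a, scores_a = predict(model, imgs)
        pred_b, scores_b = predict(restored, imgs)
        assert np.array_equal(pred_a, pred_b)
        assert np.allclose(scores_a, scores_b)

    def test_resnet_backbone_trains(self):
        imgs = toy_images(2)
        model = build_model("dan", backbone="resnet",
                            input_shape=(1, 32, 32), seed=0)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=0, lambda_=0.05,
                          backbone="resnet")
        before = model.backbone.frozen_parameter_vector().copy()
        model, curve = train(model, imgs, imgs, cfg, target_labels=[0, 0, 1, 1])
        assert len(curve) == 2
        assert np.array_equal(before, model.backbone.frozen_parameter_vector())
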