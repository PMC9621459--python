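"""Attribution methods against analytic and finite-difference oracles."""

import numpy as np
import pytest

from skinet import nn
from skinet import saliency as sal
from skinet.metrics import UndefinedMetricError
from skinet.nn import core
from skinet.nn.core import Tensor


class LinearNet(nn.Module):
    """logits = W @ flatten(x): the closed-form case for integrated gradients."""

    def __init__(self, weights):  # weights: (features, n_classes)
        super().__init__()
        self.register_param("weight", np.asarray(weights, dtype=float))

    def forward(self, x: Tensor) -> Tensor:
        flat = core.reshape(x, (x.shape[0], -1))
        return core.matmul(flat, self.weight)


class GradCamToyNet(nn.Module):
    """Class scores are the spatial means of two conv activation maps."""

    def __init__(self, rng):
        super().__init__()
        self.conv = nn.Conv2d(3, 2, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_activations(x)[0]

    def forward_with_activations(self, x: Tensor):
        feat = self.conv(x)
        return core.global_avg_pool(feat), {"feat": feat}


class SimpleReluNet(nn.Module):
    """score_0 = sum(w2 * relu(channel-sum of w1 * x)); hand-differentiable."""

    def __init__(self, w1, w2):
        super().__init__()
        conv = nn.Conv2d(3, 1, 1, np.random.default_rng(0))
        conv.weight.data = np.asarray(w1, dtype=float).reshape(1, 3, 1, 1)
        conv.bias.data = np.zeros(1)
        self.conv = conv
        self.w2 = np.asarray(w2, dtype=float)

    def forward(self, x: Tensor) -> Tensor:
        h = core.relu(self.conv(x))
        weighted = core.mul(h, Tensor(self.w2[None, None]))
        return core.reshape(core.sum_(weighted), (1, 1))


class TestGuidedBackprop:
    def test_constant_output_model_gives_zero_map(self, rng):
        model = LinearNet(np.zeros((2 * 2 * 3, 2)))
        amap = sal.guided_backprop(model, rng.random((2, 2, 3)), 0)
        assert np.all(amap.values == 0)

    def test_hand_derived_masked_gradient_on_2x2_input(self):
        w1 = [1.0, -1.0, 0.5]
        w2 = np.array([[1.0, -2.0], [3.0, -4.0]])
        model = SimpleReluNet(w1, w2)
        x = np.array([[[0.9, 0.1, 0.2], [0.1, 0.9, 0.1]],
                      [[0.5, 0.1, 0.6], [0.2, 0.1, 0.1]]])
        # relu pre-activation: sum_c w1_c * x_c per pixel
        pre = (x * np.array(w1)).sum(axis=-1)
        active = pre > 0
        # guided rule: propagate w2 only where pre>0 AND w2>0
        g = np.where(active & (w2 > 0), w2, 0.0)
        expected = np.abs(g[:, :, None] * np.array(w1)).sum(axis=-1)
        amap = sal.guided_backprop(model, x, 0)
        assert np.allclose(amap.values, expected)

    def test_invariant_to_constant_score_shift(self, rng):
        w = rng.standard_normal((4 * 4 * 3, 2))
        x = rng.random((4, 4, 3))
        a = sal.guided_backprop(LinearNet(w), x, 1).values

        class Shifted(LinearNet):
            def forward(self, t):
                return super().forward(t) + Tensor(np.array([[0.0, 100.0]]))

        b = sal.guided_backprop(Shifted(w), x, 1).values
        assert np.allclose(a, b)


class TestGradCam:
    def test_nonnegative_and_proportional_to_target_activation(self, rng):
        model = GradCamToyNet(rng)
        x = rng.random((6, 6, 3))
        amap = sal.grad_cam(model, x, 0, target_layer="feat")
        assert (amap.values >= 0).all()
        feat = model.conv(Tensor(x.transpose(2, 0, 1)[None])).data[0, 0]
        G = feat.size
        assert np.allclose(amap.values, np.maximum(feat / G, 0.0))

    def test_matches_finite_difference_neuron_importance(self, rng):
        """beta_a from autodiff equals the finite-difference dz/dF pooled."""
        model = GradCamToyNet(rng)
        x = rng.random((4, 4, 3))
        feat = model.conv(Tensor(x.transpose(2, 0, 1)[None])).data[0]
        # z_0(F) = mean of channel 0; numerical dz/dF entries
        eps = 1e-6
        fd = np.zeros_like(feat)
        for a in range(feat.shape[0]):
            for k in range(feat.shape[1]):
                for l in range(feat.shape[2]):
                    up = feat.copy()
                    up[a, k, l] += eps
                    dn = feat.copy()
                    dn[a, k, l] -= eps
                    fd[a, k, l] = (up[0].mean() - dn[0].mean()) / (2 * eps)
        beta_fd = fd.mean(axis=(1, 2))
        cam_fd = np.maximum((beta_fd[:, None, None] * feat).sum(axis=0), 0)
        amap = sal.grad_cam(model, x, 0, target_layer="feat")
        assert np.allclose(amap.values, cam_fd, atol=1e-6)

    def test_zero_gradients_give_zero_map(self, rng):
        class Detached(GradCamToyNet):
            """Logits never depend on the captured activations."""

            def forward_with_activations(self, x):
                feat = self.conv(x)
                return core.matmul(core.global_avg_pool(feat),
                                   Tensor(np.zeros((2, 2)))), {"feat": feat}

        amap = sal.grad_cam(Detached(rng), rng.random((4, 4, 3)), 0,
                            target_layer="feat")
        assert np.all(amap.values == 0)

    def test_model_without_activation_hooks_rejected(self, rng):
        model = LinearNet(np.zeros((4 * 4 * 3, 2)))
        with pytest.raises(sal.CapabilityError):
            sal.grad_cam(model, rng.random((4, 4, 3)), 0)

    def test_unknown_layer_rejected(self, rng):
        model = GradCamToyNet(rng)
        with pytest.raises(ValueError):
            sal.grad_cam(model, rng.random((4, 4, 3)), 0, target_layer="nope")


class TestGuidedGradCam:
    def test_product_of_parents(self, rng):
        model = GradCamToyNet(rng)
        x = rng.random((6, 6, 3))
        gc = sal.grad_cam(model, x, 0, target_layer="feat").values
        gb = sal.guided_backprop(model, x, 0).values
        combined = sal.guided_grad_cam(model, x, 0, target_layer="feat").values
        assert np.allclose(combined, gc * gb)
        # annihilator: anywhere Grad-CAM is zero the product is zero
        assert np.all(combined[gc == 0] == 0)


class TestIntegratedGradients:
    def test_linear_model_closed_form(self, rng):
        w = rng.standard_normal((3 * 3 * 3, 2))
        x = rng.random((3, 3, 3))
        w_e = w[:, 1].reshape(3, 3, 3).transpose(1, 2, 0)  # model flattens CHW
        for steps in (2, 8, 64):
            amap = sal.integrated_gradients(LinearNet(w), x, 1, steps=steps)
            expected = (x * w_e).sum(axis=-1)
            assert np.allclose(amap.values, expected, atol=1e-10)

    def test_input_equal_to_baseline_gives_zero(self, rng):
        w = rng.standard_normal((3 * 3 * 3, 2))
        x = rng.random((3, 3, 3))
        amap = sal.integrated_gradients(LinearNet(w), x, 0, baseline=x.copy())
        assert np.allclose(amap.values, 0)

    def test_completeness_tightens_with_steps(self, tiny_3class, rng):
        model = tiny_3class["model"]
        image = tiny_3class["val"][0].image
        baseline = np.zeros_like(image)
        logits_in = model(Tensor(image.transpose(2, 0, 1)[None])).data[0]
        logits_base = model(Tensor(baseline.transpose(2, 0, 1)[None])).data[0]
        target = int(np.argmax(logits_in))
        delta = logits_in[target] - logits_base[target]
        errs = []
        for steps in (16, 64, 256):
            amap = sal.integrated_gradients(model, image, target, steps=steps)
            errs.append(abs(amap.values.sum() - delta) / abs(delta))
        assert errs[-1] <= errs[0] + 1e-6
        assert errs[1] < 0.01  # within 1% already at 64 steps

    def test_shape_mismatch_and_bad_steps_rejected(self, rng):
        model = LinearNet(rng.standard_normal((12, 2)))
        x = rng.random((2, 2, 3))
        with pytest.raises(ValueError):
            sal.integrated_gradients(model, x, 0, baseline=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            sal.integrated_gradients(model, x, 0, steps=1)


class TestXrai:
    def _segmented_image(self):
        img = np.full((16, 16, 3), 0.2)
        img[4:10, 4:10] = 0.9  # one clearly separable bright square
        return img

    def test_concentrated_attribution_ranks_its_region_first(self):
        img = self._segmented_image()
        attr = np.zeros((16, 16))
        attr[5:9, 5:9] = 1.0
        ranking = sal.rank_regions(img, attr)
        first = ranking.regions[0]
        assert attr[first].sum() > 0
        assert ranking.scores[0] == max(ranking.scores)
        # brute-force: no candidate region has a higher gain per area
        assert ranking.scores[0] == pytest.approx(
            max(attr[r].sum() / r.sum() for r in ranking.regions))

    def test_uniform_zero_attribution_is_deterministic(self):
        img = self._segmented_image()
        a = sal.rank_regions(img, np.zeros((16, 16)))
        b = sal.rank_regions(img, np.zeros((16, 16)))
        assert all(s == 0 for s in a.scores)
        assert len(a.regions) == len(b.regions)
        for ra, rb in zip(a.regions, b.regions):
            assert np.array_equal(ra, rb)

    def test_ranked_regions_cover_every_pixel(self, rng):
        img = self._segmented_image()
        ranking = sal.rank_regions(img, rng.standard_normal((16, 16)))
        union = np.zeros((16, 16), bool)
        for r in ranking.regions:
            union |= r
        assert union.all()

    def test_ranking_invariant_to_monotone_rescaling(self, rng):
        img = self._segmented_image()
        attr = rng.standard_normal((16, 16))
        a = sal.rank_regions(img, attr)
        b = sal.rank_regions(img, 3.7 * attr + 0.4)
        for ra, rb in zip(a.regions, b.regions):
            assert np.array_equal(ra, rb)

    def test_end_to_end_map_orders_pixels_by_rank(self, rng):
        model = LinearNet(rng.standard_normal((16 * 16 * 3, 2)))
        amap, ranking = sal.xrai(model, self._segmented_image(), 0, steps=8)
        assert amap.values.shape == (16, 16)
        first = ranking.regions[0]
        assert amap.values[first].min() == amap.values.max()


class TestBokeh:
    def test_full_restoration_equals_original(self, rng):
        img = rng.random((8, 8, 3))
        out = sal.bokeh_reconstruct(img, rng.random((8, 8)), 1.0, 2.0)
        assert np.array_equal(out, img)

    def test_tiny_blur_approaches_identity(self, rng):
        img = rng.random((8, 8, 3))
        out = sal.bokeh_reconstruct(img, rng.random((8, 8)), 0.1, 1e-6)
        assert np.allclose(out, img, atol=1e-9)

    def test_restored_pixels_match_independent_topk_selection(self, rng):
        img = rng.random((10, 10, 3))
        values = rng.integers(0, 5, size=(10, 10)).astype(float)  # many ties
        frac = 0.3
        out = sal.bokeh_reconstruct(img, values, frac, 3.0)
        k = int(np.ceil(frac * 100))
        order = np.argsort(-values.ravel(), kind="stable")
        keep = np.zeros(100, bool)
        keep[order[:k]] = True
        keep = keep.reshape(10, 10)
        assert np.array_equal(out[keep], img[keep])
        blurred_region = out[~keep]
        assert not np.array_equal(blurred_region, img[~keep])

    def test_invalid_arguments_rejected(self, rng):
        img = rng.random((8, 8, 3))
        with pytest.raises(ValueError):
            sal.bokeh_reconstruct(img, np.zeros((8, 8)), 0.0, 2.0)
        with pytest.raises(ValueError):
            sal.bokeh_reconstruct(img, np.zeros((8, 8)), 0.5, -1.0)


class TestBokehEvaluation:
    def test_full_restoration_reproduces_plain_accuracy(self, tiny_3class):
        model = tiny_3class["model"]
        val = tiny_3class["val"][:30]
        images = np.stack([s.image for s in val])
        labels = np.array([s.label for s in val])
        plain = (model.predict_proba(images).argmax(axis=1) == labels).mean()
        flat = lambda m, s, t: sal.AttributionMap(
            np.zeros(s.image.shape[:2]), "constant", t)
        acc = sal.evaluate_saliency_bokeh(model, val, flat, top_fraction=1.0)
        assert acc == pytest.approx(plain)

    def test_mask_oracle_saliency_beats_random_noise(self, tiny_3class):
        model = tiny_3class["model"]
        val = tiny_3class["val"][:50]
        noise_rng = np.random.default_rng(0)

        def oracle(m, s, t):
            return sal.AttributionMap(s.mask.astype(float), "oracle", t)

        def noise(m, s, t):
            return sal.AttributionMap(
                noise_rng.random(s.image.shape[:2]), "noise", t)

        acc_oracle = sal.evaluate_saliency_bokeh(model, val, oracle,
                                                 top_fraction=0.2, blur_sigma=3.0)
        acc_noise = sal.evaluate_saliency_bokeh(model, val, noise,
                                                top_fraction=0.2, blur_sigma=3.0)
        assert acc_noise <= acc_oracle

    def test_empty_dataset_rejected(self, tiny_3class):
        with pytest.raises(UndefinedMetricError):
            sal.evaluate_saliency_bokeh(tiny_3class["model"], [], "grad_cam")
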