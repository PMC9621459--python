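"""Saliency attribution and the bokeh-effect faithfulness benchmark.

Implements Guided Backpropagation, Grad-CAM, Guided Grad-CAM, integrated
gradients and XRAI for the package's classifiers, plus the bokeh
evaluation: blur an image, restore only the top-salient pixels, and
measure the classifier's accuracy on the reconstruction — a faithful
saliency method preserves the evidence the model actually uses.

Grad-CAM pools the gradient of the class score z_e over the spatial
positions of a conv layer's activation maps F^a to get neuron-importance
weights beta_a = (1/G) sum_kl dz_e/dF^a_kl, then forms
ReLU(sum_a beta_a F^a) and upsamples bilinearly to the input resolution.
XRAI averages integrated gradients over black and white baselines,
over-segments the image with Felzenszwalb's graph-based method at several
scales, and greedily grows a saliency ranking by attribution gain per
unit area.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.segmentation import felzenszwalb
from skimage.transform import resize

from .nn import core
from .nn.core import Tensor, guided_relu
from .nets import CapabilityError, _to_nchw
from .metrics import UndefinedMetricError
from .synthetic import LesionSample

METHODS = ("guided_backprop", "grad_cam", "guided_grad_cam",
           "integrated_gradients", "xrai")


@dataclasses.dataclass
class AttributionMap:
    """Per-pixel importance for one (input, class) pair."""

    values: np.ndarray  # HxW
    method: str
    target_class: int
    input_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise ValueError("attribution map contains non-finite values")


@dataclasses.dataclass
class RegionRanking:
    """XRAI's greedy region ordering (pixel masks and their scores)."""

    regions: list[np.ndarray]  # boolean HxW masks, in rank order
    scores: list[float]        # attribution gain per unit area at inclusion


def _image_of(input_) -> tuple[np.ndarray, str]:
    if isinstance(input_, LesionSample):
        return input_.image, input_.sample_id
    return np.asarray(input_), ""


def _input_gradient(model, image: np.ndarray, target_class: int) -> np.ndarray:
    """d(score of target_class)/d(input), shape HxWx3."""
    x = Tensor(_to_nchw(image), requires_grad=True)
    logits = model(x)
    score = core.select(logits, (np.zeros(1, dtype=int),
                                 np.full(1, target_class, dtype=int)))
    core.sum_(score).backward()
    return x.grad[0].transpose(1, 2, 0)


def guided_backprop(model, input_, target_class: int) -> AttributionMap:
    """Input gradient with the guided-ReLU backward rule.

    At every ReLU the backward signal is zeroed wherever the forward
    input or the incoming gradient is negative; channels are reduced by
    the sum of absolute values.
    """
    if not callable(model):
        raise CapabilityError("model must be a callable network module")
    image, sid = _image_of(input_)
    with guided_relu():
        grad = _input_gradient(model, image, target_class)
    return AttributionMap(values=np.abs(grad).sum(axis=-1),
                          method="guided_backprop",
                          target_class=target_class, input_id=sid)


def grad_cam(model, input_, target_class: int,
             target_layer: str | None = None) -> AttributionMap:
    """Class-activation map from gradient-weighted conv activations."""
    if not hasattr(model, "forward_with_activations"):
        raise CapabilityError("model does not expose conv activations")
    image, sid = _image_of(input_)
    x = Tensor(_to_nchw(image))
    logits, acts = model.forward_with_activations(x)
    if target_layer is None:
        target_layer = list(acts)[-1]  # last conv layer
    if target_layer not in acts:
        raise ValueError(f"unknown layer {target_layer!r}; have {list(acts)}")
    feat = acts[target_layer]
    if feat.data.ndim != 4:
        raise ValueError(f"layer {target_layer!r} has no spatial extent")
    score = core.select(logits, (np.zeros(1, dtype=int),
                                 np.full(1, target_class, dtype=int)))
    core.sum_(score).backward()
    grads = (feat.grad[0] if feat.grad is not None
             else np.zeros_like(feat.data[0]))  # (A, k, l)
    beta = grads.mean(axis=(1, 2))  # global average pooling, 1/G sum_kl
    cam = np.maximum((beta[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    h, w = image.shape[:2]
    cam = resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False)
    return AttributionMap(values=cam, method="grad_cam",
                          target_class=target_class, input_id=sid)


def guided_grad_cam(model, input_, target_class: int,
                    target_layer: str | None = None) -> AttributionMap:
    """Elementwise product of upsampled Grad-CAM and Guided Backprop."""
    gc = grad_cam(model, input_, target_class, target_layer)
    gb = guided_backprop(model, input_, target_class)
    return AttributionMap(values=gc.values * gb.values,
                          method="guided_grad_cam",
                          target_class=target_class, input_id=gc.input_id)


def integrated_gradients(model, input_, target_class: int,
                         baseline: np.ndarray | None = None,
                         steps: int = 64) -> AttributionMap:
    """Path integral of gradients from baseline to input (midpoint rule),
    scaled by (input - baseline); channel-summed (signed), so the map
    satisfies the completeness axiom up to quadrature error."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    image, sid = _image_of(input_)
    if baseline is None:
        baseline = np.zeros_like(image)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != image.shape:
        raise ValueError(f"baseline shape {baseline.shape} != image {image.shape}")
    alphas = (np.arange(steps) + 0.5) / steps
    batch = baseline[None] + alphas[:, None, None, None] * (image - baseline)[None]
    x = Tensor(_to_nchw(batch), requires_grad=True)
    logits = model(x)
    score = core.select(logits, (np.arange(steps),
                                 np.full(steps, target_class, dtype=int)))
    core.sum_(score).backward()
    avg_grad = x.grad.mean(axis=0).transpose(1, 2, 0)
    attr = ((image - baseline) * avg_grad).sum(axis=-1)
    return AttributionMap(values=attr, method="integrated_gradients",
                          target_class=target_class, input_id=sid)


def xrai(model, input_, target_class: int,
         segmentation_scales: tuple[float, ...] = (50.0, 150.0, 400.0),
         steps: int = 64) -> tuple[AttributionMap, RegionRanking]:
    """Region-ranked attribution from black/white-baseline integrated
    gradients and multi-scale Felzenszwalb over-segmentation."""
    image, sid = _image_of(input_)
    attr_black = integrated_gradients(model, input_, target_class,
                                      baseline=np.zeros_like(image), steps=steps)
    attr_white = integrated_gradients(model, input_, target_class,
                                      baseline=np.ones_like(image), steps=steps)
    attr = (attr_black.values + attr_white.values) / 2.0
    ranking = rank_regions(image, attr, segmentation_scales)
    h, w = attr.shape
    out = np.zeros((h, w))
    n = len(ranking.regions)
    for rank, mask in enumerate(ranking.regions):
        out[mask] = n - rank  # higher value = earlier (more salient) region
    amap = AttributionMap(values=out, method="xrai",
                          target_class=target_class, input_id=sid)
    return amap, ranking


def rank_regions(image: np.ndarray, attribution: np.ndarray,
                 segmentation_scales: tuple[float, ...] = (50.0, 150.0, 400.0)
                 ) -> RegionRanking:
    """Greedy merge of over-segmentation regions by summed-attribution
    gain per unit novel area, until the image is covered."""
    candidates: list[np.ndarray] = []
    for scale in segmentation_scales:
        seg = felzenszwalb(np.ascontiguousarray(image), scale=scale,
                           sigma=0.8, min_size=max(4, attribution.size // 400))
        for lab in np.unique(seg):
            candidates.append(seg == lab)
    if len(candidates) == 1:
        warnings.warn("degenerate segmentation: a single region")
    covered = np.zeros(attribution.shape, dtype=bool)
    regions: list[np.ndarray] = []
    gains: list[float] = []
    remaining = list(range(len(candidates)))
    while remaining and not covered.all():
        best_i, best_gain, best_novel = None, -np.inf, None
        for i in remaining:
            novel = candidates[i] & ~covered
            area = novel.sum()
            if area == 0:
                continue
            gain = attribution[novel].sum() / area
            if gain > best_gain:  # strict: ties resolve to lowest index
                best_i, best_gain, best_novel = i, gain, novel
        if best_i is None:
            break
        remaining.remove(best_i)
        covered |= best_novel
        regions.append(best_novel)
        gains.append(float(best_gain))
    return RegionRanking(regions=regions, scores=gains)


def bokeh_reconstruct(image: np.ndarray, saliency: AttributionMap | np.ndarray,
                      top_fraction: float, blur_sigma: float) -> np.ndarray:
    """Blur the image, then restore the top-fraction most-salient pixels.

    Ties in saliency are broken by pixel (raster) index.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    values = saliency.values if isinstance(saliency, AttributionMap) else saliency
    h, w = image.shape[:2]
    blurred = np.stack([ndimage.gaussian_filter(image[:, :, c], blur_sigma)
                        for c in range(image.shape[2])], axis=-1)
    k = int(np.ceil(top_fraction * h * w))
    order = np.argsort(-values.ravel(), kind="stable")
    keep = np.zeros(h * w, dtype=bool)
    keep[order[:k]] = True
    keep = keep.reshape(h, w)
    out = blurred.copy()
    out[keep] = image[keep]
    return out


def evaluate_saliency_bokeh(model, dataset: list[LesionSample], method,
                            top_fraction: float = 0.10,
                            blur_sigma: float | None = None,
                            **method_kwargs) -> float:
    """Accuracy of the classifier on bokeh reconstructions.

    ``method`` is one of METHODS or a callable
    ``(model, sample, target_class) -> AttributionMap``. Saliency is
    computed for the model's *predicted* class; accuracy is measured
    against the ground-truth labels.
    """
    if not dataset:
        raise UndefinedMetricError("bokeh evaluation needs a non-empty dataset")
    if blur_sigma is None:
        h, w = dataset[0].image.shape[:2]
        blur_sigma = 0.05 * min(h, w)
    if callable(method):
        fn = method
    elif method == "xrai":
        fn = lambda m, s, t: xrai(m, s, t, **method_kwargs)[0]
    elif method in METHODS:
        base = globals()[method]
        fn = lambda m, s, t: base(m, s, t, **method_kwargs)
    else:
        raise ValueError(f"unknown method {method!r}")
    correct = 0
    for sample in dataset:
        probs = model.predict_proba(sample.image[None])[0]
        pred = int(np.argmax(probs))
        amap = fn(model, sample, pred)
        recon = bokeh_reconstruct(sample.image, amap, top_fraction, blur_sigma)
        re_pred = int(np.argmax(model.predict_proba(recon[None])[0]))
        correct += int(re_pred == sample.label)
    return correct / len(dataset)


def save_attribution(amap: AttributionMap, path_png: str | Path,
                     path_raw: str | Path | None = None) -> None:
    """8-bit colormapped PNG plus optional raw float32 values (.npy)."""
    import imageio.v3 as iio
    import matplotlib

    v = amap.values
    rng_ = v.max() - v.min()
    norm = (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)
    rgba = (matplotlib.colormaps["inferno"](norm) * 255).astype(np.uint8)
    iio.imwrite(Path(path_png), rgba[:, :, :3])
    if path_raw is not None:
        np.save(Path(path_raw), v.astype(np.float32))


def save_ranking(ranking: RegionRanking, path: str | Path) -> None:
    payload = [{"rank": i, "area": int(m.sum()), "score": s}
               for i, (m, s) in enumerate(zip(ranking.regions, ranking.scores))]
    Path(path).write_text(json.dumps(payload, indent=2))
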