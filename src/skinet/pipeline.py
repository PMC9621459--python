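"""The uncertainty-gated two-stage diagnosis pipeline.

Flow for one image I with segmenter M_s and classifier M_c:

1. resize I to the segmentation input size; draw a posterior of
   segmentation maps; compute the normalized map uncertainty;
2. if that uncertainty is below the segmentation threshold (default
   0.25), hand the lesion-focused image (mask-multiplied, bounding-box
   cropped) to the classifier, otherwise hand over the original;
3. draw a posterior of class-probability vectors; compute the
   normalized predictive entropy;
4. if it is below the classification threshold (default 0.35), emit the
   predicted class, otherwise refer the case for a second opinion;
5. attach a saliency map for the top class on the image actually
   classified.

Batch evaluation records the classifier's prediction for every sample
(including referred ones), tallies the cc/cu/ic/iu categories and
reports diagnostic accuracy A and plain prediction accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import saliency as saliency_mod
from . import uncertainty as unc
from .synthetic import LesionSample

logger = logging.getLogger("skinet.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    phi_T_seg: float = 0.25
    phi_T_cls: float = 0.35
    B: int = 20
    V: int = 20
    M: int = 20
    uncertainty_mode: str = "combined"  # epistemic | aleatoric | combined
    handoff: str = "bbox_crop"          # masked | bbox_crop
    seg_input_size: tuple[int, int] = (224, 224)
    cls_input_size: tuple[int, int] = (450, 600)
    binarize_threshold: float = 0.5
    saliency_method: str = "xrai"       # any saliency.METHODS entry or "none"
    transform_family: unc.TransformFamily = dataclasses.field(
        default_factory=unc.TransformFamily)
    seed: int = 0

    def __post_init__(self):
        for name in ("phi_T_seg", "phi_T_cls"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if min(self.B, self.V, self.M) < 1:
            raise ValueError("sample counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seg_input_size", "cls_input_size"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        if isinstance(raw.get("transform_family"), dict):
            tf = raw["transform_family"]
            if isinstance(tf.get("rotation_range_deg"), list):
                tf["rotation_range_deg"] = tuple(tf["rotation_range_deg"])
            raw["transform_family"] = unc.TransformFamily(**tf)
        return cls(**raw)


@dataclasses.dataclass
class Diagnosis:
    """Terminal record of one pipeline run."""

    input_id: str
    seg_phi_norm: float
    used_segmented_input: bool
    predicted_class: int | None
    cls_phi_norm: float
    decision: str  # "diagnose" | "refer"
    posterior_mean: np.ndarray
    internal_predicted: int
    explanation: saliency_mod.AttributionMap | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_id": self.input_id,
            "seg_phi_norm": self.seg_phi_norm,
            "used_segmented_input": self.used_segmented_input,
            "predicted_class": self.predicted_class,
            "cls_phi_norm": self.cls_phi_norm,
            "decision": self.decision,
            "posterior_mean": np.asarray(self.posterior_mean).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if image.shape[:2] == tuple(size):
        return image
    out = resize(image, size, order=3, mode="edge", anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def handoff_image(image: np.ndarray, mean_mask: np.ndarray,
                  mode: str = "bbox_crop",
                  binarize_threshold: float = 0.5) -> np.ndarray:
    """Lesion-focused image from a probability mask.

    ``masked``: background zeroed. ``bbox_crop``: mask-multiplied image
    cropped to the mask's bounding box dilated by a 10% margin, then
    resized back to the input size. An empty mask degrades gracefully to
    the original image.
    """
    if mean_mask.shape != image.shape[:2]:
        raise ValueError("mask and image sizes differ")
    binary = mean_mask >= binarize_threshold
    if not binary.any():
        warnings.warn("empty segmentation mask; passing the original image")
        return image
    masked = image * binary[:, :, None]
    if mode == "masked":
        return masked
    if mode != "bbox_crop":
        raise ValueError(f"unknown handoff mode {mode!r}")
    rows = np.flatnonzero(binary.any(axis=1))
    cols = np.flatnonzero(binary.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(round(0.1 * (r1 - r0)))
    mc = int(round(0.1 * (c1 - c0)))
    r0, r1 = max(0, r0 - mr), min(image.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(image.shape[1], c1 + mc)
    crop = masked[r0:r1, c0:c1]
    return _resize_image(crop, image.shape[:2])


def _posterior(model, image, mode: str, config: PipelineConfig, seed: int):
    if mode == "epistemic":
        return unc.epistemic_posterior(model, image, config.B, seed=seed)
    if mode == "aleatoric":
        return unc.aleatoric_posterior(model, image, config.V,
                                       config.transform_family, seed=seed)
    if mode == "combined":
        return unc.combined_posterior(model, image, config.M,
                                      config.transform_family, seed=seed)
    raise ValueError(f"unknown uncertainty mode {mode!r}")


def run_skinet(sample: LesionSample | np.ndarray, segmenter, classifier,
               config: PipelineConfig | None = None) -> Diagnosis:
    """Run the full gated two-stage flow on one image."""
    if config is None:
        config = PipelineConfig()
    if isinstance(sample, LesionSample):
        image, sid = sample.image, sample.sample_id
    else:
        image, sid = np.asarray(sample), ""

    # stage 1: Bayesian segmentation + map uncertainty
    seg_in = _resize_image(image, config.seg_input_size)
    seg_post = _posterior(segmenter, seg_in, config.uncertainty_mode,
                          config, seed=config.seed)
    _, seg_phi_norm = unc.segmentation_uncertainty(seg_post)
    use_segmented = seg_phi_norm < config.phi_T_seg
    logger.info("stage=segmentation phi_norm=%.4f gate=%s",
                seg_phi_norm, "segmented" if use_segmented else "original")
    if use_segmented:
        cls_source = handoff_image(seg_in, seg_post.mean, config.handoff,
                                   config.binarize_threshold)
    else:
        cls_source = seg_in

    # stage 2: Bayesian classification + referral gate
    cls_in = _resize_image(cls_source, config.cls_input_size)
    cls_post = _posterior(classifier, cls_in, config.uncertainty_mode,
                          config, seed=config.seed + 1)
    report = unc.classification_report(cls_post, phi_T=config.phi_T_cls)
    decision = "refer" if report.is_uncertain else "diagnose"
    logger.info("stage=classification phi_norm=%.4f gate=%s",
                report.phi_norm, decision)

    explanation = None
    if config.saliency_method != "none":
        if config.saliency_method == "xrai":
            explanation, _ = saliency_mod.xrai(classifier, cls_in,
                                               report.predicted)
        else:
            fn = getattr(saliency_mod, config.saliency_method)
            explanation = fn(classifier, cls_in, report.predicted)

    return Diagnosis(
        input_id=sid,
        seg_phi_norm=float(seg_phi_norm),
        used_segmented_input=bool(use_segmented),
        predicted_class=report.predicted if decision == "diagnose" else None,
        cls_phi_norm=float(report.phi_norm),
        decision=decision,
        posterior_mean=report.posterior_mean,
        internal_predicted=report.predicted,
        explanation=explanation,
    )


@dataclasses.dataclass
class EvaluationReport:
    per_sample: list[tuple[Diagnosis, bool, str]]
    counts: unc.CategoryCounts
    diagnostic_accuracy: float
    prediction_accuracy: float
    prediction_accuracy_diagnosed: float | None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "counts": dataclasses.asdict(self.counts),
            "diagnostic_accuracy": self.diagnostic_accuracy,
            "prediction_accuracy": self.prediction_accuracy,
            "prediction_accuracy_diagnosed": self.prediction_accuracy_diagnosed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_pipeline(dataset: list[LesionSample], segmenter, classifier,
                      config: PipelineConfig | None = None) -> EvaluationReport:
    """Run the pipeline over a labeled dataset and tally cc/cu/ic/iu.

    Referred cases still record the classifier's underlying prediction so
    every sample lands in exactly one category. Two accuracy accountings
    are reported: over all samples (refer cases counted by their internal
    prediction) and over diagnosed samples only.
    """
    from .metrics import UndefinedMetricError
    if not dataset:
        raise UndefinedMetricError("evaluation needs a non-empty dataset")
    if config is None:
        config = PipelineConfig(saliency_method="none")
    per_sample = []
    counts = unc.CategoryCounts()
    n_correct = 0
    n_diag = n_diag_correct = 0
    for i, sample in enumerate(dataset):
        cfg_i = dataclasses.replace(config, seed=(config.seed * 1000003 + 2 * i)
                                    % 2 ** 31)
        diag = run_skinet(sample, segmenter, classifier, cfg_i)
        correct = diag.internal_predicted == sample.label
        cat = unc.categorize(correct, diag.cls_phi_norm, config.phi_T_cls)
        setattr(counts, f"L_{cat}", getattr(counts, f"L_{cat}") + 1)
        n_correct += int(correct)
        if diag.decision == "diagnose":
            n_diag += 1
            n_diag_correct += int(correct)
        per_sample.append((diag, bool(correct), cat))
    return EvaluationReport(
        per_sample=per_sample,
        counts=counts,
        diagnostic_accuracy=unc.diagnostic_accuracy(counts),
        prediction_accuracy=n_correct / len(dataset),
        prediction_accuracy_diagnosed=(n_diag_correct / n_diag) if n_diag else None,
    )


def threshold_sweep(records: list[tuple[bool, float]],
                    thresholds: np.ndarray | list[float],
                    out_csv: str | Path | None = None) -> pd.DataFrame:
    """Diagnostic accuracy A(phi_T) over a grid of thresholds."""
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    for t in thresholds:
        counts = unc.CategoryCounts.from_records(records, t)
        rows.append({"phi_T": float(t), "L_cc": counts.L_cc,
                     "L_cu": counts.L_cu, "L_ic": counts.L_ic,
                     "L_iu": counts.L_iu,
                     "A": unc.diagnostic_accuracy(counts)})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
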