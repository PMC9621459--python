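"""Posterior sampling and uncertainty quantification.

Three posterior-sampling modes over a trained network's predictions:

* epistemic — B Monte-Carlo-dropout forward passes on the unmodified
  input (dropout active at test time, batch-norm frozen);
* aleatoric — V test-time-augmentation passes (flips, rotations) with
  dropout off, segmentation outputs mapped back through the inverse
  geometric transform before averaging;
* combined — M passes each with a fresh augmentation and a fresh dropout
  mask.

The predictive entropy of the averaged probability vector,
phi = -sum_n p_n ln p_n, is normalized to [0, 1] between phi_min and
phi_max (analytic bounds by default: 0 and ln N for classification, ln 2
per pixel for segmentation) and gated at a threshold phi_T: a prediction
is certain iff phi_norm < phi_T. Crossing certainty with correctness
gives the four categories cc/cu/ic/iu whose counts define the diagnostic
accuracy A = (L_cc + L_iu) / (L_cc + L_cu + L_ic + L_iu).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from . import nets
from .metrics import UndefinedMetricError
from .synthetic import LesionSample


# --------------------------------------------------------------------------
# test-time augmentation transforms
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TTATransform:
    """One invertible flip+rotation augmentation."""

    hflip: bool = False
    vflip: bool = False
    angle_deg: float = 0.0

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = image
        if self.hflip:
            out = out[:, ::-1]
        if self.vflip:
            out = out[::-1]
        if self.angle_deg != 0.0:
            out = np.stack([ndimage.rotate(out[:, :, c], self.angle_deg,
                                           reshape=False, order=3, mode="nearest")
                            for c in range(out.shape[2])], axis=-1)
            out = np.clip(out, 0.0, 1.0)
        return np.ascontiguousarray(out)

    def invert_map(self, prob_map: np.ndarray) -> np.ndarray:
        out = prob_map
        if self.angle_deg != 0.0:
            out = ndimage.rotate(out, -self.angle_deg, reshape=False,
                                 order=1, mode="nearest")
            out = np.clip(out, 0.0, 1.0)
        if self.vflip:
            out = out[::-1]
        if self.hflip:
            out = out[:, ::-1]
        return np.ascontiguousarray(out)


@dataclasses.dataclass
class TransformFamily:
    """Distribution of TTA transforms (default = the training family)."""

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range_deg: tuple[float, float] = (-65.0, 65.0)

    def sample(self, rng: np.random.Generator) -> TTATransform:
        lo, hi = self.rotation_range_deg
        return TTATransform(
            hflip=self.horizontal_flip and bool(rng.random() < 0.5),
            vflip=self.vertical_flip and bool(rng.random() < 0.5),
            angle_deg=float(rng.uniform(lo, hi)) if hi > lo else float(lo))

    @classmethod
    def identity(cls) -> "TransformFamily":
        return cls(horizontal_flip=False, vertical_flip=False,
                   rotation_range_deg=(0.0, 0.0))


# --------------------------------------------------------------------------
# posterior sampling
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSamples:
    """Stack of per-pass probability outputs (vectors or maps)."""

    samples: np.ndarray  # (count, N) or (count, H, W)
    mode: str            # epistemic | aleatoric | combined
    source_id: str = ""

    def __post_init__(self):
        if len(self.samples) < 1:
            raise ValueError("need at least one posterior sample")

    @property
    def count(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def is_map(self) -> bool:
        return self.samples.ndim == 3


def _image_of(input_: LesionSample | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(input_, LesionSample):
        return input_.image, input_.sample_id
    return np.asarray(input_), ""


def _set_stochastic(model, enabled: bool, rng: np.random.Generator | None):
    if hasattr(model, "set_stochastic"):
        model.set_stochastic(enabled, rng)
    else:
        nets.set_stochastic_mode(model, enabled, rng)


def epistemic_posterior(model, input_: LesionSample | np.ndarray, B: int,
                        seed: int = 0) -> PosteriorSamples:
    """B MC-dropout passes on the unmodified input; mean is mu_e."""
    if B < 1:
        raise ValueError("B must be >= 1")
    image, sid = _image_of(input_)
    rng = np.random.default_rng(seed)
    _set_stochastic(model, True, rng)
    try:
        batch = np.repeat(image[None], B, axis=0)
        samples = model.predict_proba(batch)
    finally:
        _set_stochastic(model, False, None)
    return PosteriorSamples(samples=samples, mode="epistemic", source_id=sid)


def aleatoric_posterior(model, input_: LesionSample | np.ndarray, V: int,
                        transform_family: TransformFamily | None = None,
                        seed: int = 0) -> PosteriorSamples:
    """V TTA passes with dropout off; segmentation maps are inverse-warped."""
    if V < 1:
        raise ValueError("V must be >= 1")
    if transform_family is None:
        transform_family = TransformFamily()
    image, sid = _image_of(input_)
    rng = np.random.default_rng(seed)
    transforms = [transform_family.sample(rng) for _ in range(V)]
    _set_stochastic(model, False, None)
    batch = np.stack([t.apply(image) for t in transforms])
    out = model.predict_proba(batch)
    if out.ndim == 3:  # segmentation maps: align back to input frame
        out = np.stack([t.invert_map(m) for t, m in zip(transforms, out)])
    return PosteriorSamples(samples=out, mode="aleatoric", source_id=sid)


def combined_posterior(model, input_: LesionSample | np.ndarray, M: int,
                       transform_family: TransformFamily | None = None,
                       seed: int = 0) -> PosteriorSamples:
    """M passes each with a fresh augmentation AND a fresh dropout mask."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if transform_family is None:
        transform_family = TransformFamily()
    image, sid = _image_of(input_)
    rng = np.random.default_rng(seed)
    transforms = [transform_family.sample(rng) for _ in range(M)]
    _set_stochastic(model, True, np.random.default_rng(rng.integers(2 ** 31)))
    try:
        batch = np.stack([t.apply(image) for t in transforms])
        out = model.predict_proba(batch)
    finally:
        _set_stochastic(model, False, None)
    if out.ndim == 3:
        out = np.stack([t.invert_map(m) for t, m in zip(transforms, out)])
    return PosteriorSamples(samples=out, mode="combined", source_id=sid)


# --------------------------------------------------------------------------
# entropy, normalization, categorization
# --------------------------------------------------------------------------

def predictive_entropy(posterior_mean: np.ndarray) -> float:
    """phi = -sum_n p_n ln p_n (nats) of a probability vector."""
    p = np.asarray(posterior_mean, dtype=float)
    if p.ndim != 1 or (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("posterior_mean must be a probability vector")
    p = np.clip(p, 0.0, 1.0)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def normalize_uncertainty(phi: float, phi_min: float = 0.0,
                          phi_max: float | None = None,
                          n_classes: int | None = None) -> float:
    """Linear rescaling of phi to [0, 1] between phi_min and phi_max."""
    if phi_max is None:
        if n_classes is None:
            raise ValueError("give phi_max or n_classes")
        phi_max = float(np.log(n_classes))
    if phi_max <= phi_min:
        raise ValueError(f"phi_max ({phi_max}) must exceed phi_min ({phi_min})")
    if phi < phi_min or phi > phi_max:
        warnings.warn(f"phi={phi} outside [{phi_min}, {phi_max}]; clamping")
        phi = min(max(phi, phi_min), phi_max)
    return (phi - phi_min) / (phi_max - phi_min)


def empirical_bounds(phis: np.ndarray) -> tuple[float, float]:
    """Empirical (min, max) normalization bounds from a calibration batch."""
    phis = np.asarray(phis, dtype=float)
    return float(phis.min()), float(phis.max())


@dataclasses.dataclass
class UncertaintyReport:
    """Per-sample uncertainty summary for one posterior."""

    posterior_mean: np.ndarray
    phi: float
    phi_norm: float
    mode: str
    predicted: int
    is_uncertain: bool
    source_id: str = ""

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {"source_id": self.source_id, "mode": self.mode,
                   "phi": self.phi, "phi_norm": self.phi_norm,
                   "predicted": int(self.predicted),
                   "is_uncertain": self.is_uncertain,
                   "posterior_mean": np.asarray(self.posterior_mean).tolist(),
                   **extra}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def classification_report(posterior: PosteriorSamples, phi_T: float = 0.35,
                          phi_min: float = 0.0,
                          phi_max: float | None = None) -> UncertaintyReport:
    """Entropy, normalized uncertainty and gate status for a class posterior."""
    mean = posterior.mean
    phi = predictive_entropy(mean)
    phi_norm = normalize_uncertainty(phi, phi_min,
                                     phi_max, n_classes=len(mean))
    predicted = int(np.argmax(mean))  # ties resolve to the lowest index
    return UncertaintyReport(posterior_mean=mean, phi=phi, phi_norm=phi_norm,
                             mode=posterior.mode, predicted=predicted,
                             is_uncertain=phi_norm >= phi_T,
                             source_id=posterior.source_id)


def segmentation_uncertainty(posterior: PosteriorSamples,
                             reduction: str = "mean_entropy"
                             ) -> tuple[np.ndarray, float]:
    """Per-pixel binary entropy map and a scalar phi_norm in [0, 1].

    ``reduction``: ``mean_entropy`` (mean per-pixel entropy / ln 2) or
    ``uncertain_fraction`` (fraction of pixels with entropy > 0.5 ln 2).
    """
    if not posterior.is_map:
        raise ValueError("expected a posterior of probability maps")
    p = posterior.mean
    if (p < -1e-9).any() or (p > 1 + 1e-9).any():
        raise ValueError("posterior maps must lie in [0,1]")
    p = np.clip(p, 0.0, 1.0)
    ent = np.zeros_like(p)
    inside = (p > 0) & (p < 1)
    q = p[inside]
    ent[inside] = -(q * np.log(q) + (1 - q) * np.log(1 - q))
    if reduction == "mean_entropy":
        scalar = float(ent.mean() / np.log(2))
    elif reduction == "uncertain_fraction":
        scalar = float((ent > 0.5 * np.log(2)).mean())
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return ent, scalar


def save_entropy_map(entropy_map: np.ndarray, path: str | Path) -> None:
    """16-bit PNG scaled so ln 2 maps to full range."""
    scaled = np.clip(entropy_map / np.log(2), 0, 1)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


@dataclasses.dataclass
class CategoryCounts:
    """The four certainty-correctness tallies."""

    L_cc: int = 0
    L_cu: int = 0
    L_ic: int = 0
    L_iu: int = 0

    def __post_init__(self):
        if min(self.L_cc, self.L_cu, self.L_ic, self.L_iu) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.L_cc + self.L_cu + self.L_ic + self.L_iu

    @classmethod
    def from_records(cls, records, phi_T: float) -> "CategoryCounts":
        counts = cls()
        for correct, phi_norm in records:
            cat = categorize(correct, phi_norm, phi_T)
            setattr(counts, f"L_{cat}", getattr(counts, f"L_{cat}") + 1)
        return counts


def categorize(correct: bool, phi_norm: float, phi_T: float) -> str:
    """One of 'cc', 'cu', 'ic', 'iu'. Certain iff phi_norm < phi_T;
    a value exactly at the threshold counts as uncertain."""
    certain = phi_norm < phi_T
    return ("c" if correct else "i") + ("c" if certain else "u")


def diagnostic_accuracy(counts: CategoryCounts) -> float:
    """A(phi_T) = (L_cc + L_iu) / (L_cc + L_cu + L_ic + L_iu)."""
    if counts.total == 0:
        raise UndefinedMetricError("diagnostic accuracy undefined on zero counts")
    return (counts.L_cc + counts.L_iu) / counts.total


def uncertain_misclassification_rate(n_uncertain: int,
                                     n_misclassified_among_uncertain: int) -> float:
    """Percentage of uncertain predictions that are also misclassified."""
    if n_uncertain <= 0:
        raise UndefinedMetricError("rate undefined with zero uncertain samples")
    if n_misclassified_among_uncertain > n_uncertain:
        raise ValueError("misclassified count exceeds uncertain count")
    return 100.0 * n_misclassified_among_uncertain / n_uncertain
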