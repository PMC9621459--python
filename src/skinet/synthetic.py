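"""Seeded synthetic dermoscopy-like image generator.

Produces skin-tone backgrounds with a single elliptical lesion per image,
class-dependent lesion color/texture, pixel-exact binary masks, and the
two artifact types that dominate real dermoscopy noise — dark curved
hair strokes and bright sweat-droplet highlights. Artifacts are drawn
over the image only, never into the mask, so they act as label-preserving
nuisance structure: exactly the kind of input noise that should raise a
Bayesian model's predictive uncertainty and trigger referral gating.

Every sample is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

# Default 7-class lesion palette: (R, G, B, texture amplitude, texture scale).
# Colors are loosely modeled on pigmented / keratotic / vascular lesion hues;
# pairwise color distances all exceed 3x the default pixel noise so the label
# signal is learnable by construction.
DEFAULT_PALETTE = np.array([
    [0.25, 0.15, 0.10, 0.06, 2.0],   # dark pigmented
    [0.55, 0.35, 0.22, 0.04, 3.0],   # medium brown naevus-like
    [0.85, 0.55, 0.55, 0.03, 4.0],   # pearly pink
    [0.75, 0.35, 0.30, 0.07, 1.5],   # red scaly
    [0.68, 0.53, 0.28, 0.05, 2.5],   # tan waxy
    [0.42, 0.28, 0.38, 0.04, 2.0],   # dusky purple-brown
    [0.60, 0.15, 0.35, 0.03, 3.5],   # red-violet vascular
])

BACKGROUND_RGB = (0.80, 0.62, 0.52)


@dataclasses.dataclass
class SyntheticConfig:
    """Generative parameters for the synthetic lesion imagery."""

    image_height: int = 64
    image_width: int = 64
    n_classes: int = 7
    lesion_radius_range: tuple[float, float] = (0.15, 0.32)
    class_palette: np.ndarray | None = None
    artifact_rate: float = 0.3
    noise_sd: float = 0.06
    seed: int = 0
    background_rgb: tuple[float, float, float] = BACKGROUND_RGB

    def __post_init__(self):
        if self.class_palette is None:
            if self.n_classes > len(DEFAULT_PALETTE):
                raise ValueError(
                    f"default palette has {len(DEFAULT_PALETTE)} classes; "
                    f"supply class_palette for n_classes={self.n_classes}")
            self.class_palette = DEFAULT_PALETTE[: self.n_classes].copy()
        self.class_palette = np.asarray(self.class_palette, dtype=float)
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("lesion_radius_range values must lie in (0, 0.5]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if len(self.class_palette) != self.n_classes:
            raise ValueError("class_palette must have exactly n_classes rows")
        d = self.class_palette[:, None, :3] - self.class_palette[None, :, :3]
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() <= 0:
            raise ValueError("class_palette rows must be pairwise distinct")


@dataclasses.dataclass
class LesionSample:
    """One image flowing through the pipeline: RGB in [0,1], HxWx3."""

    image: np.ndarray
    mask: np.ndarray | None = None
    label: int | None = None
    sample_id: str = ""
    meta: dict = dataclasses.field(default_factory=dict)


def _background(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    yy, xx = np.mgrid[0:h, 0:w]
    # gentle diagonal illumination gradient, +-5%
    grad = 0.05 * ((yy / max(h - 1, 1)) + (xx / max(w - 1, 1)) - 1.0)
    tone = np.array(cfg.background_rgb) * (1.0 + rng.normal(0, 0.02, size=3))
    img = tone[None, None, :] * (1.0 + grad[:, :, None])
    return img


def _ellipse_mask(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    lo, hi = cfg.lesion_radius_range
    r = min(h, w)
    a = rng.uniform(lo, hi) * r
    b = rng.uniform(lo, hi) * r
    theta = rng.uniform(0, np.pi)
    cy = h / 2 + rng.uniform(-0.1, 0.1) * h
    cx = w / 2 + rng.uniform(-0.1, 0.1) * w
    yy, xx = np.mgrid[0:h, 0:w]
    yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
    xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    return ((yr / a) ** 2 + (xr / b) ** 2 <= 1.0).astype(np.uint8)


def _draw_hairs(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    for _ in range(rng.integers(3, 8)):
        # quadratic Bezier stroke across the field of view
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p2 = rng.uniform([0, 0], [h - 1, w - 1])
        p1 = (p0 + p2) / 2 + rng.normal(0, 0.25 * min(h, w), size=2)
        t = np.linspace(0, 1, 4 * max(h, w))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        shade = rng.uniform(0.05, 0.15)
        img[rr, cc] = shade
        # thicken to ~2 px
        rr2 = np.clip(rr + 1, 0, h - 1)
        img[rr2, cc] = shade


def _draw_droplets(img: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(2, 6)):
        cy, cx = rng.uniform([0, 0], [h - 1, w - 1])
        rad = rng.uniform(0.03, 0.08) * min(h, w)
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / rad ** 2
        alpha = np.clip(1.0 - d2, 0.0, 1.0) ** 0.5 * rng.uniform(0.5, 0.8)
        img[:] = img * (1 - alpha[:, :, None]) + alpha[:, :, None] * 0.97


def generate_sample(config: SyntheticConfig, class_index: int,
                    rng: np.random.Generator | None = None,
                    sample_id: str = "") -> LesionSample:
    """Render one lesion image of the given class with its exact mask.

    Raises ``ValueError`` when ``class_index`` is outside
    ``[0, n_classes)``.
    """
    if not 0 <= class_index < config.n_classes:
        raise ValueError(f"class_index {class_index} out of range "
                         f"[0, {config.n_classes})")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = _background(config, rng)
    mask = _ellipse_mask(config, rng)

    r, g, b, amp, scale = config.class_palette[class_index]
    h, w = mask.shape
    texture = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), scale)
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax
    lesion = np.array([r, g, b])[None, None, :] * (1.0 + amp * texture[:, :, None])
    m3 = mask[:, :, None].astype(float)
    img = img * (1 - m3) + lesion * m3

    has_hair = rng.random() < config.artifact_rate
    has_droplet = rng.random() < config.artifact_rate
    if has_hair:
        _draw_hairs(img, rng)
    if has_droplet:
        _draw_droplets(img, rng)

    img = img + rng.normal(0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return LesionSample(image=img, mask=mask, label=int(class_index),
                        sample_id=sample_id,
                        meta={"has_hair": bool(has_hair),
                              "has_droplet": bool(has_droplet),
                              "has_artifact": bool(has_hair or has_droplet)})


def generate_dataset(config: SyntheticConfig, n_per_class: int,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[LesionSample], pd.DataFrame]:
    """Balanced dataset of ``n_classes * n_per_class`` seeded samples.

    When ``out_dir`` is given, images and masks are written as PNG and a
    ``manifest.csv`` (sample_id, label, image_path, mask_path) alongside.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    samples = []
    for i in range(n_per_class):
        for c in range(config.n_classes):
            sid = f"syn_{c}_{i:04d}"
            samples.append(generate_sample(config, c, rng, sample_id=sid))
    rows = [{"sample_id": s.sample_id, "label": s.label} for s in samples]
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        image_paths, mask_paths = [], []
        for s in samples:
            ip = out_dir / f"{s.sample_id}.png"
            mp = out_dir / f"{s.sample_id}_mask.png"
            save_image(s.image, ip)
            iio.imwrite(mp, (s.mask * 255).astype(np.uint8))
            image_paths.append(str(ip))
            mask_paths.append(str(mp))
        manifest["image_path"] = image_paths
        manifest["mask_path"] = mask_paths
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return samples, manifest


def load_dataset(manifest_csv: str | Path) -> list[LesionSample]:
    """Read samples back from a ``generate_dataset`` manifest."""
    df = pd.read_csv(manifest_csv)
    samples = []
    for row in df.itertuples():
        img = load_image(row.image_path)
        mask = None
        if hasattr(row, "mask_path") and isinstance(row.mask_path, str):
            mask = (iio.imread(row.mask_path) > 127).astype(np.uint8)
        samples.append(LesionSample(image=img, mask=mask,
                                    label=int(row.label),
                                    sample_id=str(row.sample_id)))
    return samples


def save_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.clip(image, 0, 1) * 255).astype(np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[:, :, :3].astype(np.float64) / 255.0


def _rotate_pair(image: np.ndarray, mask: np.ndarray | None, angle_deg: float,
                 fill_rgb: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray | None]:
    """Rotate image (bicubic, background fill) and mask (nearest, binary)."""
    chans = [ndimage.rotate(image[:, :, c], angle_deg, reshape=False,
                            order=3, mode="constant", cval=fill_rgb[c])
             for c in range(3)]
    img = np.clip(np.stack(chans, axis=-1), 0.0, 1.0)
    m = None
    if mask is not None:
        m = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=False,
                           order=0, mode="constant", cval=0)
        m = (m > 0).astype(np.uint8)
    return img, m


def offline_augment(samples: list[LesionSample],
                    rotation_range_deg: tuple[float, float] = (-65.0, 65.0),
                    horizontal_flip: bool = True,
                    vertical_flip: bool = True,
                    copies_per_sample: int = 1,
                    rng: np.random.Generator | None = None,
                    fill_rgb: tuple[float, float, float] = BACKGROUND_RGB
                    ) -> list[LesionSample]:
    """Pre-training augmentation: flips plus random rotations.

    Masks are transformed identically to images (nearest-neighbor so they
    stay binary); labels are preserved; rotation fill is the background
    skin tone. Returns originals followed by ``copies_per_sample``
    transformed copies of each, so the output has
    ``len(samples) * (1 + copies_per_sample)`` entries.
    """
    lo, hi = rotation_range_deg
    if not (-180 <= lo <= hi <= 180):
        raise ValueError("rotation_range_deg must lie within [-180, 180]")
    if rng is None:
        rng = np.random.default_rng(0)
    out = list(samples)
    for k in range(copies_per_sample):
        for s in samples:
            img, mask = s.image, s.mask
            if horizontal_flip and rng.random() < 0.5:
                img = img[:, ::-1]
                mask = None if mask is None else mask[:, ::-1]
            if vertical_flip and rng.random() < 0.5:
                img = img[::-1]
                mask = None if mask is None else mask[::-1]
            angle = rng.uniform(lo, hi)
            if angle != 0.0:
                img, mask = _rotate_pair(np.ascontiguousarray(img),
                                         None if mask is None
                                         else np.ascontiguousarray(mask),
                                         angle, fill_rgb)
            out.append(LesionSample(image=np.ascontiguousarray(img),
                                    mask=None if mask is None
                                    else np.ascontiguousarray(mask),
                                    label=s.label,
                                    sample_id=f"{s.sample_id}_aug{k}",
                                    meta=dict(s.meta)))
    return out
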