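"""Evaluation metrics: accuracy, F1, Dice, Jaccard, and binary cross-entropy.

The Jaccard operation returns *similarity* by default. Some sources print
the Jaccard formula with a leading ``1 -`` (the Jaccard distance) while
reporting similarity-scale numbers; the ``as_distance`` flag makes the
complement explicit instead of ambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty."""


@dataclasses.dataclass
class ConfusionCounts:
    Tp: int
    Tn: int
    Fp: int
    Fn: int

    def __post_init__(self):
        if min(self.Tp, self.Tn, self.Fp, self.Fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclasses.dataclass
class MaskOverlap:
    intersection: int
    size_M: int
    size_C: int

    def __post_init__(self):
        if min(self.intersection, self.size_M, self.size_C) < 0:
            raise ValueError("counts must be non-negative")
        if self.intersection > min(self.size_M, self.size_C):
            raise ValueError("intersection exceeds a mask size")

    @classmethod
    def from_masks(cls, M: np.ndarray, C: np.ndarray) -> "MaskOverlap":
        M = np.asarray(M).astype(bool)
        C = np.asarray(C).astype(bool)
        return cls(intersection=int((M & C).sum()),
                   size_M=int(M.sum()), size_C=int(C.sum()))


def accuracy(counts: ConfusionCounts) -> float:
    """(Tp + Tn) / (Tp + Fp + Tn + Fn)."""
    total = counts.Tp + counts.Tn + counts.Fp + counts.Fn
    if total == 0:
        raise UndefinedMetricError("accuracy undefined on zero samples")
    return (counts.Tp + counts.Tn) / total


def f1_score(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when there are no Tp."""
    if counts.Tp + counts.Fp + counts.Fn == 0:
        raise UndefinedMetricError("F1 undefined without positives")
    if counts.Tp == 0:
        return 0.0
    precision = counts.Tp / (counts.Tp + counts.Fp)
    recall = counts.Tp / (counts.Tp + counts.Fn)
    return 2 * precision * recall / (precision + recall)


def dice(overlap: MaskOverlap) -> float:
    """Dice coefficient 2|M∩C| / (|M|+|C|); empty-vs-empty -> 1."""
    denom = overlap.size_M + overlap.size_C
    if denom == 0:
        return 1.0
    return 2 * overlap.intersection / denom


def jaccard(overlap: MaskOverlap, as_distance: bool = False) -> float:
    """Jaccard similarity |M∩C| / |M∪C| (or its complement)."""
    denom = overlap.size_M + overlap.size_C - overlap.intersection
    j = 1.0 if denom == 0 else overlap.intersection / denom
    return 1.0 - j if as_distance else j


def bce_loss(y: np.ndarray, p: np.ndarray, epsilon: float = 1e-12) -> float:
    """Mean binary cross-entropy with probability clipping.

    ``y`` is binary truth, ``p`` the predicted probabilities; both may be
    per-sample vectors or per-pixel maps of any matching shape.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise UndefinedMetricError("BCE undefined on zero samples")
    if not (0 < epsilon <= 1e-6):
        raise ValueError("epsilon must lie in (0, 1e-6]")
    p = np.clip(p, epsilon, 1.0 - epsilon)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def evaluate_mask_batch(manifest_csv: str | Path,
                        out_csv: str | Path | None = None,
                        out_json: str | Path | None = None) -> pd.DataFrame:
    """Score predicted vs ground-truth mask PNG pairs listed in a manifest.

    The manifest needs columns ``sample_id, mask_path, pred_path``. Writes
    per-sample metrics as CSV and aggregates (mean-per-image and
    global-pixel Dice/Jaccard) as JSON when paths are given.
    """
    df = pd.read_csv(manifest_csv)
    rows = []
    tot_inter = tot_m = tot_c = 0
    for row in df.itertuples():
        M = iio.imread(row.mask_path) > 127
        C = iio.imread(row.pred_path) > 127
        ov = MaskOverlap.from_masks(M, C)
        tot_inter += ov.intersection
        tot_m += ov.size_M
        tot_c += ov.size_C
        rows.append({"sample_id": row.sample_id, "dice": dice(ov),
                     "jaccard": jaccard(ov)})
    per_sample = pd.DataFrame(rows)
    glob = MaskOverlap(tot_inter, tot_m, tot_c)
    aggregates = {
        "mean_dice": float(per_sample["dice"].mean()),
        "mean_jaccard": float(per_sample["jaccard"].mean()),
        "global_dice": dice(glob),
        "global_jaccard": jaccard(glob),
    }
    if out_csv is not None:
        per_sample.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(aggregates, indent=2))
    return per_sample
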