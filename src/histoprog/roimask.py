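"""Region-of-interest masks from tumor-probability heatmaps.

The fixed pipeline is: binarize at a threshold calibrated to a pooled
recall target, remove positive connected components smaller than eight
superpixels, then dilate with a discrete Euclidean disc of radius r (r = 0
is the identity; dilation runs after component removal).  Prognostic
patches are the non-overlapping tiles, anchored at the grid origin, whose
footprint is at least half covered by the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "calibrate_threshold",
    "binarize",
    "denoise",
    "dilate",
    "roi_mask",
    "PatchSelection",
    "select_patches",
    "patch_features",
    "train_patch_classifier",
    "compute_heatmap",
]


def calibrate_threshold(heatmaps, pixel_labels, target_recall: float) -> float:
    """Largest threshold whose pooled recall over all heatmaps meets the target.

    Recall is pooled over superpixels of all provided slides (the per-slide
    averaged variant is available through :func:`per_slide_recalls`).
    Binarization uses the >= comparison, so the returned threshold is always
    an attainable positive score.
    """
    if not 0 < target_recall <= 1:
        raise ValueError("target_recall must lie in (0, 1]")
    pos_scores = []
    for h, lab in zip(heatmaps, pixel_labels):
        h = np.asarray(h, dtype=float)
        lab = np.asarray(lab, dtype=bool)
        if h.shape != lab.shape:
            raise ValueError("heatmap and label grids must be aligned")
        pos_scores.append(h[lab])
    pos = np.concatenate(pos_scores) if pos_scores else np.array([])
    if pos.size == 0:
        raise ValueError("no positive superpixels in the provided labels")
    m = pos.size
    k = int(np.ceil(target_recall * m))  # smallest count achieving the target
    t = float(np.sort(pos)[::-1][k - 1])  # k-th largest positive score
    achieved = float((pos >= t).sum() / m)
    if achieved < target_recall:  # unreachable even at threshold 0
        raise ValueError(
            f"recall target {target_recall} unreachable (best {achieved:.4f} at t={t})"
        )
    return t


def per_slide_recalls(heatmaps, pixel_labels, t: float) -> list:
    return [
        float((np.asarray(h)[np.asarray(lab, bool)] >= t).mean())
        for h, lab in zip(heatmaps, pixel_labels)
        if np.asarray(lab, bool).any()
    ]


def binarize(heatmap: np.ndarray, t: float) -> np.ndarray:
    """Positive iff tumor probability >= t."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(heatmap, dtype=float) >= t


def denoise(mask: np.ndarray, min_component: int = 8, connectivity: int = 8) -> np.ndarray:
    """Remove positive connected components with fewer than ``min_component``
    superpixels; components of exactly that size are kept."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=conn)
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0  # background
    keep = sizes >= min_component
    return keep[labeled]


def dilate(mask: np.ndarray, r: int) -> np.ndarray:
    """Dilation by the discrete Euclidean disc {(dy, dx): dy^2 + dx^2 <= r^2}."""
    if r < 0 or int(r) != r:
        raise ValueError("radius must be a nonnegative integer")
    mask = np.asarray(mask, dtype=bool)
    if r == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=morphology.disk(int(r)))


def roi_mask(heatmap, t, r, min_component: int = 8, connectivity: int = 8) -> np.ndarray:
    """The full pipeline in its fixed order: binarize -> denoise -> dilate."""
    return dilate(denoise(binarize(heatmap, t), min_component, connectivity), r)


@dataclass
class PatchSelection:
    """Selected prognostic patches on the tiling anchored at the grid origin.

    ``table`` has columns (row, col, y, x, coverage): (row, col) index the
    patch tiling, (y, x) are the top-left superpixel coordinates (0-based,
    half-open extents), coverage is the positive fraction of the footprint.
    """

    table: pd.DataFrame
    patch_size: int

    def coords(self) -> list:
        return list(zip(self.table["row"].astype(int), self.table["col"].astype(int)))

    def __len__(self) -> int:
        return len(self.table)


def select_patches(mask: np.ndarray, patch_size_superpixels: int) -> PatchSelection:
    """Tiles whose footprint is at least half inside the mask (ties included)."""
    mask = np.asarray(mask, dtype=bool)
    p = int(patch_size_superpixels)
    if p <= 0:
        raise ValueError("patch size must be positive")
    nr, nc = mask.shape[0] // p, mask.shape[1] // p
    if nr == 0 or nc == 0:
        warnings.warn("patch size exceeds grid; empty selection", stacklevel=2)
        return PatchSelection(
            pd.DataFrame(columns=["row", "col", "y", "x", "coverage"]), p
        )
    cov = (
        mask[: nr * p, : nc * p]
        .reshape(nr, p, nc, p)
        .mean(axis=(1, 3))
    )
    rows, cols = np.nonzero(cov >= 0.5)
    table = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "y": rows * p,
            "x": cols * p,
            "coverage": cov[rows, cols],
        }
    )
    return PatchSelection(table, p)


# ---------------------------------------------------------------------------
# desk-scale tumor-vs-non-tumor patch classifier


def patch_features(patches: np.ndarray) -> np.ndarray:
    """Hand-crafted per-patch statistics: channel means/stds plus gradient
    magnitude statistics (sensitive to blob/stripe density)."""
    x = np.asarray(patches, dtype=float) / 255.0
    if x.ndim == 3:
        x = x[None]
    feats = [x.mean(axis=(1, 2)), x.std(axis=(1, 2))]
    gray = x.mean(axis=3)
    gy = np.abs(np.diff(gray, axis=1)).mean(axis=(1, 2))
    gx = np.abs(np.diff(gray, axis=2)).mean(axis=(1, 2))
    feats.append(np.stack([gy, gx], axis=1))
    return np.concatenate(feats, axis=1)


def train_patch_classifier(patches: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Tumor/non-tumor patch classifier: logistic regression on
    :func:`patch_features`.  Raises on single-class labels."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
    )
    clf.fit(patch_features(patches), labels)
    return clf


def compute_heatmap(classifier, slide, classes) -> np.ndarray:
    """Tumor-probability heatmap for a synthetic slide at superpixel
    resolution: the classifier scores each patch and the probability is
    broadcast over the patch's superpixel footprint."""
    from .synthdata import render_slide_patch

    rows, cols = slide.class_grid.shape
    patches = np.stack(
        [render_slide_patch(slide, r, c, classes) for r in range(rows) for c in range(cols)]
    )
    prob = classifier.predict_proba(patch_features(patches))[:, 1].reshape(rows, cols)
    return np.kron(prob, np.ones((slide.sp_per_patch, slide.sp_per_patch)))
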