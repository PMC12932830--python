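"""Grad-CAM heatmaps and quantitative localization scoring.

Grad-CAM weighs each feature map of a convolutional layer by the spatial
mean of the class-score gradient flowing into it, sums, rectifies, and
upsamples to the input size.  Localization quality against a binary
lesion mask is scored two ways: IoU of the binarized heatmap (top-20%
rule by default) and the Pointing Game (does the heatmap's maximum fall
inside the lesion?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)


@dataclass
class Heatmap:
    values: np.ndarray          # 2-D, [0, 1], input spatial size
    source_layer: str = "backbone:last_conv"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap must be 2-D with values in [0, 1]")


def grad_cam(model, image: np.ndarray, target_layer: str | None = None) -> Heatmap:
    """Grad-CAM heatmap for one image.

    Channel weights are the spatial means of d(logit)/d(feature map);
    the weighted sum is rectified, bilinearly upsampled to the input
    size and max-normalized (an all-zero map stays zero).  The target
    layer is the model's designated Grad-CAM stage (last convolutional
    stage of the backbone; the attended fused maps for the
    attention-fusion model).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a single 2-D array")
    maps, grads = model.gradcam_features(image)
    a, da = maps[0], grads[0]                       # (C, h, w)
    weights = da.mean(axis=(1, 2))                  # spatial-mean gradients
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    cam = _sk_resize(cam, image.shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    layer_name = target_layer or getattr(model, "gradcam_layer_name",
                                         "backbone:last_conv")
    return Heatmap(values=cam, source_layer=layer_name)


def binarize_heatmap(h: Heatmap | np.ndarray, q: float = 0.8) -> np.ndarray:
    """Pixels at or above the q-quantile of the positive heatmap values
    (top-20% rule at the default q = 0.8); an all-zero map gives an
    empty mask."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    values = h.values if isinstance(h, Heatmap) else np.asarray(h, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        return np.zeros_like(values, dtype=bool)
    cut = np.quantile(positive, q)
    return values >= cut


def iou_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks; both empty -> 1
    (perfect agreement on absence)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def pointing_game(h: Heatmap | np.ndarray, lesion_mask: np.ndarray) -> int:
    """1 if the heatmap's argmax pixel (row-major first occurrence on
    ties) lies inside the lesion mask, else 0."""
    values = h.values if isinstance(h, Heatmap) else np.asarray(h, dtype=float)
    mask = np.asarray(lesion_mask).astype(bool)
    if values.shape != mask.shape:
        raise ValueError("heatmap and mask shapes differ")
    if not mask.any():
        raise ValueError("lesion mask is empty; image cannot be scored")
    peak = np.unravel_index(int(np.argmax(values)), values.shape)
    return int(mask[peak])


def localization_scores(model, images: np.ndarray, masks: np.ndarray,
                        q: float = 0.8) -> dict:
    """Aggregate Pointing-Game accuracy and mean IoU over a set.

    Images with empty masks are excluded with a warning (they cannot be
    scored)."""
    hits, ious, scored = [], [], 0
    for img, mask in zip(images, masks):
        if not np.asarray(mask).astype(bool).any():
            logger.warning("empty lesion mask: image excluded from scoring")
            continue
        h = grad_cam(model, img)
        hits.append(pointing_game(h, mask))
        ious.append(iou_score(binarize_heatmap(h, q), mask))
        scored += 1
    if scored == 0:
        raise ValueError("no scorable images (all masks empty)")
    return {"pointing_game_accuracy": float(np.mean(hits)),
            "mean_iou": float(np.mean(ious)),
            "n_scored": scored}
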