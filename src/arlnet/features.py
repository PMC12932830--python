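"""Handcrafted + deep feature extraction and 176-dim early fusion.

The fused vector per image is the concatenation, in fixed order, of

* texture (40): 25-bin LBP histogram followed by 15 GLCM statistics
  (contrast, dissimilarity, homogeneity, energy, correlation at each of
  the directions 0, 45 and 90 degrees, distance 1, 32 gray levels),
* shape (3): area, perimeter, compactness of the largest Otsu-threshold
  component,
* intensity (5): mean, standard deviation, median, skewness, excess
  kurtosis of the pixel values,
* deep (128): the global-average-pooled CNN representation, standardized
  and passed through a learned per-dimension sigmoid gate so no deep
  feature can exceed the dynamic range of the standardized handcrafted
  features.

Notes on the texture descriptors.  No standard LBP variant yields
exactly 25 values; here the plain 8-neighbor radius-1 codes (bit set
when neighbor >= center, east-first counter-clockwise bit order) are
binned into a 25-bin equal-width normalized histogram.  Ties count as 1,
which makes the constant image deterministic (all pixels code 255).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops

from .nn import sigmoid

logger = logging.getLogger(__name__)

GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation")
GLCM_ANGLES_DEG = (0, 45, 90)
N_LBP, N_GLCM, N_SHAPE, N_INTENSITY, N_DEEP = 25, 15, 3, 5, 128
N_TEXTURE = N_LBP + N_GLCM
N_FUSED = N_TEXTURE + N_SHAPE + N_INTENSITY + N_DEEP  # 176


# ---------------------------------------------------------------------------
# handcrafted blocks
# ---------------------------------------------------------------------------

def glcm_features(pixels: np.ndarray, levels: int = 32, distance: int = 1,
                  angles_deg: tuple[int, ...] = GLCM_ANGLES_DEG) -> np.ndarray:
    """15 gray-level co-occurrence statistics, angle-major order.

    The co-occurrence matrix is symmetric and normalized; a constant
    image has zero contrast/dissimilarity, unit homogeneity/energy, and
    correlation 1 by the perfectly-self-similar convention.
    """
    pixels = np.asarray(pixels, dtype=float)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if min(pixels.shape) < distance + 1:
        raise ValueError("image smaller than distance + 1")
    q = np.clip((pixels * levels).astype(int), 0, levels - 1).astype(np.uint8)
    angles = [np.deg2rad(a) for a in angles_deg]
    glcm = graycomatrix(q, distances=[distance], angles=angles,
                        levels=levels, symmetric=True, normed=True)
    out = []
    for ai in range(len(angles)):
        for prop in GLCM_PROPS:
            out.append(float(graycoprops(glcm, prop)[0, ai]))
    return np.array(out)


_LBP_OFFSETS = (  # east-first, counter-clockwise; bit k weighs 2**k
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def lbp_codes(pixels: np.ndarray) -> np.ndarray:
    """8-neighbor radius-1 LBP code (0-255) for every interior pixel."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    center = pixels[1:-1, 1:-1]
    codes = np.zeros_like(center, dtype=np.int64)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        neighbor = pixels[1 + dr:pixels.shape[0] - 1 + dr,
                          1 + dc:pixels.shape[1] - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << k
    return codes


def lbp_features(pixels: np.ndarray, n_bins: int = N_LBP) -> np.ndarray:
    """Normalized 25-bin equal-width histogram of the LBP codes."""
    codes = lbp_codes(pixels)
    hist, _ = np.histogram(codes, bins=n_bins, range=(0, 256))
    return hist / hist.sum()


def shape_features(pixels: np.ndarray) -> np.ndarray:
    """(area, perimeter, compactness) of the largest 8-connected
    component of the Otsu-thresholded image; (0, 0, 0) when no foreground
    exists (constant or empty image)."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.max() == pixels.min():
        logger.warning("constant image: no foreground, shape features are 0")
        return np.zeros(3)
    fg = pixels > threshold_otsu(pixels)
    if not fg.any():
        logger.warning("empty foreground, shape features are 0")
        return np.zeros(3)
    labeled = _cc_label(fg, connectivity=2)
    regions = regionprops(labeled)
    largest = max(regions, key=lambda r: r.area)
    area = float(largest.area)
    perimeter = float(largest.perimeter)
    compactness = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    return np.array([area, perimeter, compactness])


def intensity_features(pixels: np.ndarray) -> np.ndarray:
    """(mean, sd, median, skewness, excess kurtosis) over all pixels;
    zero-variance images return 0 for the two moment ratios."""
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("pixels must be non-empty")
    sd = float(x.std())
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        # constant image: moment ratios are 0/0, resolved to 0
        return np.array([float(x.mean()), 0.0, float(np.median(x)), 0.0, 0.0])
    with np.errstate(all="ignore"):
        skew = float(_stats.skew(x))
        kurt = float(_stats.kurtosis(x))
    return np.array([float(x.mean()), sd, float(np.median(x)),
                     np.nan_to_num(skew), np.nan_to_num(kurt)])


def handcrafted_features(pixels: np.ndarray) -> np.ndarray:
    """The 48 handcrafted values: [25 LBP | 15 GLCM | 3 shape | 5 intensity]."""
    return np.concatenate([lbp_features(pixels), glcm_features(pixels),
                           shape_features(pixels), intensity_features(pixels)])


# ---------------------------------------------------------------------------
# deep block, standardization, gating, fusion
# ---------------------------------------------------------------------------

def extract_deep_features(model, pixels: np.ndarray) -> np.ndarray:
    """128-dim pooled CNN representation(s); deterministic (inference mode)."""
    feats = model.pooled_features(pixels)
    if feats.shape[-1] != N_DEEP:
        raise ValueError(f"model pooled layer must be {N_DEEP}-wide")
    return feats


class FeatureScaler:
    """Per-dimension zero-mean/unit-variance scaler, fitted on training
    rows only; zero-variance dimensions are centered and passed through
    (sd treated as 1) with a warning."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, rows: np.ndarray) -> "FeatureScaler":
        rows = np.asarray(rows, dtype=float)
        if rows.ndim != 2 or rows.shape[0] < 2:
            raise ValueError("fit requires >= 2 rows")
        self.mean_ = rows.mean(axis=0)
        sd = rows.std(axis=0)
        if np.any(sd == 0):
            logger.warning("%d zero-variance feature dimension(s); sd set to 1",
                           int((sd == 0).sum()))
            sd = np.where(sd == 0, 1.0, sd)
        self.sd_ = sd
        return self

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler is not fitted")
        return (np.asarray(rows, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, rows: np.ndarray) -> np.ndarray:
        return self.fit(rows).transform(rows)


def fit_scaler(rows: np.ndarray) -> FeatureScaler:
    return FeatureScaler().fit(rows)


def apply_scaler(scaler: FeatureScaler, rows: np.ndarray) -> np.ndarray:
    return scaler.transform(rows)


def attention_gate_deep(deep: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-dimension sigmoid gating: out_i = sigmoid(w_i) * deep_i."""
    deep = np.asarray(deep, dtype=float)
    w = np.asarray(w, dtype=float)
    if deep.shape[-1] != w.shape[-1]:
        raise ValueError("deep and gate parameter lengths differ")
    return sigmoid(w) * deep


def fit_attention_gate(deep_rows: np.ndarray, labels: np.ndarray,
                       epochs: int = 200, lr: float = 0.05,
                       seed: int = 0) -> np.ndarray:
    """Learn the 128 gate parameters jointly with a small logistic head.

    The head p = sigmoid((sigmoid(w) * x) @ v + b) is trained by full-batch
    gradient descent on the training rows; only ``w`` is kept (frozen)
    for feature export.
    """
    X = np.asarray(deep_rows, dtype=float)
    y = np.asarray(labels, dtype=float).reshape(-1)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("deep_rows must be 2-D and match labels")
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    w = np.zeros(d)
    v = rng.normal(0, 1.0 / np.sqrt(d), d)
    b = 0.0
    n = len(X)
    for _ in range(epochs):
        g = sigmoid(w)
        z = (g * X) @ v + b
        p = sigmoid(z)
        dz = (p - y) / n
        dv = (g * X).T @ dz
        dg = (X * v).T @ dz
        dw = dg * g * (1 - g)
        db = dz.sum()
        v -= lr * dv
        w -= lr * dw
        b -= lr * db
    return w


def fuse_features(texture: np.ndarray, shape: np.ndarray,
                  intensity: np.ndarray, gated_deep: np.ndarray) -> np.ndarray:
    """Early fusion: [texture | shape | intensity | gated deep] -> 176."""
    blocks = {"texture": (texture, N_TEXTURE), "shape": (shape, N_SHAPE),
              "intensity": (intensity, N_INTENSITY), "deep": (gated_deep, N_DEEP)}
    arrays = []
    for name, (arr, n) in blocks.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] != n:
            raise ValueError(f"{name} block must have length {n}, got {arr.shape[-1]}")
        arrays.append(arr)
    return np.concatenate(arrays, axis=-1)


FEATURE_COLUMNS = (
    [f"lbp_{i:02d}" for i in range(N_LBP)]
    + [f"glcm_{a:02d}_{p}" for a in GLCM_ANGLES_DEG for p in GLCM_PROPS]
    + ["shape_area", "shape_perimeter", "shape_compactness"]
    + ["int_mean", "int_sd", "int_median", "int_skew", "int_kurtosis"]
    + [f"deep_{i:03d}" for i in range(N_DEEP)]
)


class FusedFeaturePipeline:
    """Fit-on-train / apply-anywhere extractor of the 176-dim vectors.

    ``fit`` computes handcrafted + deep features on the training images,
    fits the standardizing scaler on them, and learns the deep-block
    sigmoid gate against the training labels.  ``transform`` reuses the
    frozen statistics and gate (no refit — the leakage contract).
    """

    def __init__(self, model, seed: int = 0) -> None:
        self.model = model
        self.seed = seed
        self.scaler = FeatureScaler()
        self.gate_w: np.ndarray | None = None

    def _raw(self, images: np.ndarray) -> np.ndarray:
        hand = np.stack([handcrafted_features(img) for img in images])
        deep = extract_deep_features(self.model, images)
        return np.concatenate([hand, deep], axis=1)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "FusedFeaturePipeline":
        raw = self._raw(images)
        z = self.scaler.fit_transform(raw)
        self.gate_w = fit_attention_gate(z[:, -N_DEEP:], labels, seed=self.seed)
        return self

    def transform(self, images: np.ndarray) -> np.ndarray:
        if self.gate_w is None:
            raise ValueError("pipeline is not fitted")
        z = self.scaler.transform(self._raw(images))
        hand, deep = z[:, :-N_DEEP], z[:, -N_DEEP:]
        gated = attention_gate_deep(deep, self.gate_w)
        return fuse_features(hand[:, :N_TEXTURE],
                             hand[:, N_TEXTURE:N_TEXTURE + N_SHAPE],
                             hand[:, N_TEXTURE + N_SHAPE:],
                             gated)

    def fit_transform(self, images: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return self.fit(images, labels).transform(images)

    def to_frame(self, images: np.ndarray, image_ids: list[str]) -> pd.DataFrame:
        fused = self.transform(images)
        return pd.DataFrame(fused, index=pd.Index(image_ids, name="image_id"),
                            columns=FEATURE_COLUMNS)
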