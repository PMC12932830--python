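"""Synthetic CT-phantom cohort generator.

Emulates the structure of a curated lung-CT screening cohort — a fixed
number of patients each contributing the same number of 2-D grayscale
slices, with a patient-level binary label (cancer / non-cancer) — so that
every downstream stage (splitting, feature extraction, model training,
active-reinforcement labeling, Grad-CAM scoring) can be exercised without
any external download.

Each image is a smoothed-noise background with two darker elliptical
"lung fields"; cancer images additionally contain exactly one bright
elliptical nodule whose pixels are recorded in a binary lesion mask.
One nodule per image keeps localization metrics (IoU, Pointing Game)
unambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter


class PhantomConfigError(ValueError):
    """Raised when a :class:`PhantomConfig` field is invalid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom cohort.

    Defaults mirror the reference cohort geometry: 38 images per patient,
    128x128 pixels, balanced classes.
    """

    n_patients: int = 790
    images_per_patient: int = 38
    image_size: int = 128
    cancer_fraction: float = 0.5
    nodule_radius_range: tuple[float, float] = (6.0, 12.0)
    nodule_contrast: float = 0.35
    background_noise_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise PhantomConfigError("n_patients must be >= 2")
        if self.images_per_patient < 1:
            raise PhantomConfigError("images_per_patient must be >= 1")
        if self.image_size < 16:
            raise PhantomConfigError("image_size must be >= 16")
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise PhantomConfigError("cancer_fraction must be in [0, 1]")
        n_cancer = self.cancer_fraction * self.n_patients
        if abs(n_cancer - round(n_cancer)) > 1e-9:
            raise PhantomConfigError(
                "cancer_fraction * n_patients must be an integer "
                f"(got {n_cancer!r})"
            )
        lo, hi = self.nodule_radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("nodule_radius_range must satisfy 0 < min <= max")
        if self.nodule_contrast < 0:
            raise PhantomConfigError("nodule_contrast must be >= 0")
        if self.background_noise_sd < 0:
            raise PhantomConfigError("background_noise_sd must be >= 0")

    @property
    def n_cancer_patients(self) -> int:
        return int(round(self.cancer_fraction * self.n_patients))


@dataclass
class ImageRecord:
    """One grayscale slice with its patient identity, label and lesion mask."""

    patient_id: str
    image_id: str
    pixels: np.ndarray          # float64 in [0, 1], (image_size, image_size)
    label: int                  # 0 = non-cancer, 1 = cancer
    lesion_mask: np.ndarray     # bool, same shape; all-zero when label == 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.pixels.shape != self.lesion_mask.shape:
            raise ValueError("pixels and lesion_mask shapes differ")
        if self.label == 1 and not self.lesion_mask.any():
            raise ValueError("cancer image must have a non-empty lesion mask")


def _lung_fields(size: int, rng: np.random.Generator) -> np.ndarray:
    """Two darker elliptical lung fields, as a multiplicative darkening map."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    darken = np.zeros((size, size))
    for cx_frac in (0.30, 0.70):
        cx = size * (cx_frac + rng.uniform(-0.02, 0.02))
        cy = size * (0.5 + rng.uniform(-0.02, 0.02))
        a = size * rng.uniform(0.16, 0.20)   # semi-axis, x
        b = size * rng.uniform(0.28, 0.34)   # semi-axis, y
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        darken[inside] = 1.0
    return gaussian_filter(darken, sigma=2.0)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def render_image(label: int, rng: np.random.Generator,
                 config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one phantom slice.

    Returns ``(pixels, lesion_mask, meta)``.  The background consumes a
    fixed sequence of random draws before any nodule parameter is sampled,
    so rendering label 0 and label 1 from the same generator state produces
    identical backgrounds.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    size = config.image_size

    noise = rng.normal(0.0, 1.0, (size, size))
    texture = gaussian_filter(noise, sigma=2.0)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    base = 0.55 + config.background_noise_sd * texture
    base -= 0.25 * _lung_fields(size, rng)

    mask = np.zeros((size, size), dtype=bool)
    meta: dict = {}
    if label == 1:
        lo, hi = config.nodule_radius_range
        r = rng.uniform(lo, hi)
        aspect = rng.uniform(0.85, 1.15)
        theta = rng.uniform(0.0, np.pi)
        # keep the nodule inside one of the lung fields
        cx = size * rng.choice([0.30, 0.70]) + rng.uniform(-0.06, 0.06) * size
        cy = size * 0.5 + rng.uniform(-0.18, 0.18) * size
        mask = _ellipse_mask(size, cy, cx, r, r * aspect, theta)
        if not mask.any():  # pragma: no cover - geometry keeps it inside
            mask[int(cy) % size, int(cx) % size] = True
        base = base + config.nodule_contrast * mask
        meta = {"radius": r, "aspect": aspect, "center": (cy, cx), "theta": theta}

    return np.clip(base, 0.0, 1.0), mask, meta


def generate_cohort(config: PhantomConfig) -> list[ImageRecord]:
    """Generate the full phantom cohort, deterministic under ``config.seed``.

    Cancer status is assigned at the patient level (the first
    ``n_cancer_patients`` of a seed-shuffled patient order), and every
    image of a patient carries the patient's label.
    """
    n_cancer = config.n_cancer_patients
    root_ss = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(root_ss.spawn(1)[0])
    labels = np.zeros(config.n_patients, dtype=int)
    labels[order_rng.permutation(config.n_patients)[:n_cancer]] = 1

    records: list[ImageRecord] = []
    patient_seeds = root_ss.spawn(config.n_patients + 1)[1:]
    for p in range(config.n_patients):
        patient_id = f"P{p:04d}"
        image_seeds = patient_seeds[p].spawn(config.images_per_patient)
        for i in range(config.images_per_patient):
            rng = np.random.default_rng(image_seeds[i])
            pixels, mask, meta = render_image(int(labels[p]), rng, config)
            records.append(ImageRecord(
                patient_id=patient_id,
                image_id=f"{patient_id}_I{i:03d}",
                pixels=pixels,
                label=int(labels[p]),
                lesion_mask=mask,
                meta=meta,
            ))
    return records


MANIFEST_COLUMNS = ("patient_id", "image_id", "label", "image_path", "mask_path")


def write_dataset(records: Sequence[ImageRecord], directory: str | Path) -> Path:
    """Write a cohort to disk: 8-bit PNGs for inspection, a lossless float
    archive for exact round-trips, and a CSV manifest.

    Returns the manifest path.  Masks are written only for cancer images;
    non-cancer rows carry an empty ``mask_path``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    directory = Path(directory)
    img_dir = directory / "images"
    mask_dir = directory / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    arrays = {}
    rows = []
    for rec in records:
        png_path = img_dir / f"{rec.image_id}.png"
        iio.imwrite(png_path, (np.clip(rec.pixels, 0, 1) * 255).round().astype(np.uint8))
        arrays[rec.image_id] = rec.pixels
        mask_path = ""
        if rec.label == 1:
            mpath = mask_dir / f"{rec.image_id}.png"
            iio.imwrite(mpath, (rec.lesion_mask.astype(np.uint8) * 255))
            mask_path = str(mpath.relative_to(directory))
        rows.append((rec.patient_id, rec.image_id, rec.label,
                     str(png_path.relative_to(directory)), mask_path))

    np.savez_compressed(directory / "pixels.npz", **arrays)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


def read_dataset(manifest: str | Path) -> list[ImageRecord]:
    """Read a cohort written by :func:`write_dataset` (exact float pixels)."""
    manifest = Path(manifest)
    directory = manifest.parent
    with np.load(directory / "pixels.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = arrays[row["image_id"]]
            if row["mask_path"]:
                mask = iio.imread(directory / row["mask_path"]) > 0
            else:
                mask = np.zeros_like(pixels, dtype=bool)
            records.append(ImageRecord(
                patient_id=row["patient_id"],
                image_id=row["image_id"],
                pixels=pixels,
                label=int(row["label"]),
                lesion_mask=mask,
            ))
    return records


def cohort_arrays(records: Iterable[ImageRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack a cohort into ``(images, labels, patient_ids)`` arrays."""
    recs = list(records)
    X = np.stack([r.pixels for r in recs])
    y = np.array([r.label for r in recs], dtype=int)
    pids = [r.patient_id for r in recs]
    return X, y, pids
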