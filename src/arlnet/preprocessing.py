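"""Resizing, intensity normalization, and leak-free patient-level splitting.

Splitting operates on patients, never on images: all images of a patient
land in the same partition, which is the standard guard against
patient-level information leakage in medical-imaging evaluation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)


class DataIntegrityError(ValueError):
    """Raised when the manifest violates a structural assumption."""


def resize_image(pixels: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of a 2-D image to ``(target, target)``."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("pixels must be non-empty")
    if target < 1:
        raise ValueError("target must be >= 1")
    if pixels.shape == (target, target):
        return pixels.copy()
    out = _sk_resize(pixels, (target, target), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, pixels.min(), pixels.max())


def normalize_intensity(pixels: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1].

    A constant image maps to all zeros (the range contract cannot hold and
    zero is the deterministic degenerate choice).
    """
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    if hi - lo == 0:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def normalize_intensity_global(pixels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min-max normalization against dataset-wide bounds (config switch for
    cohort-level rather than per-image scaling)."""
    pixels = np.asarray(pixels, dtype=float)
    if hi - lo == 0:
        return np.zeros_like(pixels)
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions of patients (defaults 70/15/15)."""

    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    stratify_by_label: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f <= 0 for f in fr):
            raise ValueError("all fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class CohortSplit:
    """Disjoint patient partitions plus the induced image index lists."""

    train_patients: list[str]
    val_patients: list[str]
    test_patients: list[str]
    train_idx: list[int] = field(default_factory=list)
    val_idx: list[int] = field(default_factory=list)
    test_idx: list[int] = field(default_factory=list)

    def patient_sets(self) -> dict[str, set[str]]:
        return {"train": set(self.train_patients),
                "val": set(self.val_patients),
                "test": set(self.test_patients)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"train": sorted(self.train_patients),
                       "val": sorted(self.val_patients),
                       "test": sorted(self.test_patients)}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path, manifest: pd.DataFrame | None = None
                  ) -> "CohortSplit":
        with open(path) as fh:
            d = json.load(fh)
        split = cls(d["train"], d["val"], d["test"])
        if manifest is not None:
            _attach_image_indices(split, manifest)
        return split


def _largest_remainder(total: int, fractions: list[float]) -> list[int]:
    """Floor-then-largest-remainder apportionment; ties broken by list
    order (train before val before test)."""
    ideal = [total * f for f in fractions]
    counts = [int(np.floor(v)) for v in ideal]
    short = total - sum(counts)
    remainders = [v - c for v, c in zip(ideal, counts)]
    # stable sort descending keeps earlier partitions first on ties
    order = sorted(range(len(fractions)), key=lambda i: -remainders[i])
    for i in order[:short]:
        counts[i] += 1
    return counts


def _attach_image_indices(split: CohortSplit, manifest: pd.DataFrame) -> None:
    sets = split.patient_sets()
    idx = {"train": [], "val": [], "test": []}
    for i, pid in enumerate(manifest["patient_id"]):
        for name, pset in sets.items():
            if pid in pset:
                idx[name].append(i)
                break
    split.train_idx, split.val_idx, split.test_idx = idx["train"], idx["val"], idx["test"]


def patient_level_split(manifest: pd.DataFrame, spec: SplitSpec) -> CohortSplit:
    """Partition patients into train/val/test.

    Partition sizes come from floor-then-largest-remainder apportionment on
    the total patient count (ties train > val > test).  Each partition's
    quota is then distributed over the label classes by a second
    largest-remainder round (ties by ascending label, last partition takes
    the per-class remainder), which keeps every partition's class mix
    within one patient of the cohort mix.  Patients are shuffled within
    class by the spec seed, so the split is a pure function of
    (manifest, spec).
    """
    per_patient = manifest.groupby("patient_id")["label"].agg(["nunique", "first"])
    mixed = per_patient.index[per_patient["nunique"] > 1].tolist()
    if mixed:
        raise DataIntegrityError(f"patients with mixed labels: {mixed}")

    patient_label = per_patient["first"]
    patients = sorted(patient_label.index)
    n_total = len(patients)
    fractions = [spec.train_fraction, spec.val_fraction, spec.test_fraction]
    part_sizes = _largest_remainder(n_total, fractions)

    rng = np.random.default_rng(spec.seed)
    if spec.stratify_by_label:
        classes = sorted(set(int(v) for v in patient_label))
        pools = {c: [p for p in patients if int(patient_label[p]) == c] for c in classes}
        for c in classes:
            pools[c] = [pools[c][i] for i in rng.permutation(len(pools[c]))]
        remaining = {c: len(pools[c]) for c in classes}
        cursors = {c: 0 for c in classes}
        parts: list[list[str]] = []
        for k, n_p in enumerate(part_sizes):
            if k == len(part_sizes) - 1:
                take = {c: remaining[c] for c in classes}
            else:
                ideal = {c: n_p * len(pools[c]) / n_total for c in classes}
                take = {c: int(np.floor(ideal[c])) for c in classes}
                short = n_p - sum(take.values())
                order = sorted(classes, key=lambda c: (-(ideal[c] - take[c]), c))
                for c in order[:short]:
                    take[c] += 1
                for c in classes:  # cap by availability
                    take[c] = min(take[c], remaining[c])
            members: list[str] = []
            for c in classes:
                members.extend(pools[c][cursors[c]:cursors[c] + take[c]])
                cursors[c] += take[c]
                remaining[c] -= take[c]
            parts.append(members)
    else:
        shuffled = [patients[i] for i in rng.permutation(n_total)]
        parts = []
        start = 0
        for n_p in part_sizes:
            parts.append(shuffled[start:start + n_p])
            start += n_p

    split = CohortSplit(parts[0], parts[1], parts[2])
    _attach_image_indices(split, manifest)
    return split


@dataclass
class LeakageReport:
    ok: bool
    violating_patients: list[str]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def verify_no_leakage(split: CohortSplit) -> LeakageReport:
    """Check that the three patient sets are pairwise disjoint."""
    sets = split.patient_sets()
    names = list(sets)
    violations: set[str] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            violations |= sets[names[i]] & sets[names[j]]
    for name, s in sets.items():
        if not s:
            logger.warning("partition %r is empty", name)
    return LeakageReport(ok=not violations, violating_patients=sorted(violations))
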