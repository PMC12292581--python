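"""Synthetic labelled image streams with symmetric label noise and disjoint task splits.

The generator produces desk-scale stand-ins for medical image classification
benchmarks (blood-cell / pathology tiles): each class has a distinct parametric
appearance — a base colour drawn from an evenly spaced hue wheel, an oriented
sinusoidal texture and a class-positioned disk — plus per-image jitter and
Gaussian pixel noise.  The ``separability`` knob scales template contrast
against the fixed noise floor; at 1.0 a small CNN separates the classes almost
perfectly, which is the regime in which per-class confidence histograms become
bimodal under label noise.

Images are float32 in [0, 1] in memory and uint8 on disk (NPZ archives using
the ``train_images``/``train_labels``/``test_images``/``test_labels`` key
convention of the MedMNIST family).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LabeledImageDataset",
    "NoiseSpec",
    "TaskSequence",
    "generate_synthetic_dataset",
    "inject_symmetric_noise",
    "split_tasks",
    "read_npz_dataset",
    "write_npz_dataset",
    "export_manifest",
]


@dataclass
class LabeledImageDataset:
    """Images plus true and (possibly corrupted) observed labels.

    ``noisy_labels`` equals ``true_labels`` until noise is injected; training
    code only ever sees ``noisy_labels``, while ``true_labels`` exist so that
    selection purity can be measured in synthetic mode.
    """

    images: np.ndarray  # (N, H, W, C) float32 in [0, 1]
    true_labels: np.ndarray  # (N,) int64
    noisy_labels: np.ndarray  # (N,) int64
    n_classes: int
    split: str = "train"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64).ravel()
        self.noisy_labels = np.asarray(self.noisy_labels, dtype=np.int64).ravel()
        n = len(self.images)
        if not (len(self.true_labels) == len(self.noisy_labels) == n):
            raise ValueError(
                f"image/label count mismatch: {n} images, "
                f"{len(self.true_labels)} true labels, {len(self.noisy_labels)} noisy labels"
            )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        for name, lab in (("true", self.true_labels), ("noisy", self.noisy_labels)):
            if n and (lab.min() < 0 or lab.max() >= self.n_classes):
                raise ValueError(f"{name} labels outside [0, {self.n_classes})")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def noise_fraction(self) -> float:
        """Realised fraction of samples whose observed label is wrong."""
        if len(self) == 0:
            return 0.0
        return float(np.mean(self.noisy_labels != self.true_labels))

    def subset(self, indices: np.ndarray) -> "LabeledImageDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return LabeledImageDataset(
            self.images[idx],
            self.true_labels[idx],
            self.noisy_labels[idx],
            self.n_classes,
            self.split,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Symmetric label-noise specification.

    A fraction ``rate`` of samples (an exact count, round(rate*N)) is selected
    uniformly at random and each selected sample's label is replaced by one of
    the K-1 *other* classes, uniformly.
    """

    rate: float
    seed: int = 0
    model: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"noise rate must be in [0, 1), got {self.rate}")
        if self.model != "symmetric":
            raise ValueError(f"unsupported noise model: {self.model!r}")


@dataclass
class TaskSequence:
    """Ordered disjoint-class tasks with index lists into a parent dataset."""

    class_sets: list[frozenset[int]]
    task_indices: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.class_sets = [frozenset(s) for s in self.class_sets]
        seen: set[int] = set()
        for s in self.class_sets:
            if not s:
                raise ValueError("empty task class set")
            if seen & s:
                raise ValueError(f"overlapping task class sets: {sorted(seen & s)}")
            seen |= s
        if self.task_indices:
            all_idx = np.concatenate([np.asarray(ix) for ix in self.task_indices])
            if len(np.unique(all_idx)) != len(all_idx):
                raise ValueError("a sample index appears in more than one task")

    @property
    def n_tasks(self) -> int:
        return len(self.class_sets)

    def classes_seen(self, upto: int) -> list[int]:
        """Sorted union of class ids over tasks 0..upto inclusive."""
        out: set[int] = set()
        for s in self.class_sets[: upto + 1]:
            out |= s
        return sorted(out)


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb, dtype=np.float64)


def _class_template(k: int, n_classes: int, size: int) -> np.ndarray:
    """Deterministic appearance template for class ``k``: base colour +
    oriented stripes + a complementary-colour disk on a class-specific ring
    position."""
    base = _hsv_to_rgb(k / n_classes, 0.65, 0.70)
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    angle = np.pi * (k + 0.5) / n_classes
    freq = 2.0 + (k % 4)
    stripes = 0.18 * np.sin(2 * np.pi * freq * (xx * np.cos(angle) + yy * np.sin(angle)))
    template = base[None, None, :] + stripes[:, :, None]
    cx = 0.5 + 0.28 * np.cos(2 * np.pi * k / n_classes)
    cy = 0.5 + 0.28 * np.sin(2 * np.pi * k / n_classes)
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 < 0.18**2
    template[disk] = 1.0 - base[None, :]
    return template


def generate_synthetic_dataset(
    n_classes: int,
    n_per_class: int,
    image_size: int = 32,
    separability: float = 1.0,
    seed: int = 0,
    noise_sigma: float = 0.10,
    split: str = "train",
) -> LabeledImageDataset:
    """Generate ``n_classes * n_per_class`` images with distinct per-class
    appearance.

    Parameters
    ----------
    separability : float
        Multiplies template contrast around mid-grey against the fixed pixel
        noise floor ``noise_sigma``; larger is easier.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separability <= 0:
        raise ValueError("separability must be > 0")

    rng = np.random.default_rng(seed)
    templates = [_class_template(k, n_classes, image_size) for k in range(n_classes)]
    images = np.empty((n_classes * n_per_class, image_size, image_size, 3), dtype=np.float32)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    max_shift = max(1, image_size // 16)
    for i, k in enumerate(labels):
        t = templates[k]
        dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
        t = np.roll(np.roll(t, dy, axis=0), dx, axis=1)
        img = 0.5 + separability * (t - 0.5) + rng.normal(0.0, noise_sigma, t.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    # quantise to the uint8 grid so disk round-trips are exact
    images = np.round(images * 255.0).astype(np.uint8).astype(np.float32) / 255.0
    return LabeledImageDataset(images, labels, labels.copy(), n_classes, split)


def inject_symmetric_noise(
    dataset: LabeledImageDataset, spec: NoiseSpec
) -> LabeledImageDataset:
    """Corrupt exactly ``round(rate * N)`` labels, chosen uniformly without
    replacement; each corrupted label is drawn uniformly from the K-1 other
    classes.  True labels are untouched; deterministic for a fixed seed."""
    k = dataset.n_classes
    if k < 2:
        raise ValueError("need at least 2 classes to inject noise")
    n = len(dataset)
    n_flip = int(round(spec.rate * n))
    rng = np.random.default_rng(spec.seed)
    flip_idx = rng.choice(n, size=n_flip, replace=False)
    noisy = dataset.true_labels.copy()
    # uniform over the K-1 other classes: draw from 0..K-2 and skip the truth
    draws = rng.integers(0, k - 1, size=n_flip)
    truth = noisy[flip_idx]
    noisy[flip_idx] = np.where(draws >= truth, draws + 1, draws)
    return replace(dataset, noisy_labels=noisy)


def split_tasks(
    dataset: LabeledImageDataset, class_partition: Sequence[Sequence[int]]
) -> TaskSequence:
    """Split a dataset into disjoint-class incremental tasks.

    Task membership follows the *observed* (noisy) label: a sample mislabelled
    into class c travels with the task that introduces class c, which is how
    noise enters new tasks when corruption precedes the task split.
    """
    sets = [frozenset(int(c) for c in s) for s in class_partition]
    all_classes = set().union(*sets) if sets else set()
    if any(c < 0 or c >= dataset.n_classes for c in all_classes):
        raise ValueError("partition references a class not present in the dataset")
    seq = TaskSequence(class_sets=sets)  # validates disjointness
    indices = []
    for s in sets:
        mask = np.isin(dataset.noisy_labels, sorted(s))
        indices.append(np.flatnonzero(mask))
    seq.task_indices = indices
    seq.__post_init__()  # re-validate with indices attached
    return seq


_NPZ_KEYS = ("train_images", "train_labels", "test_images", "test_labels")


def write_npz_dataset(
    train: LabeledImageDataset, test: LabeledImageDataset, path: str | Path
) -> None:
    """Write a train/test pair as an uncompressed NPZ archive in the MedMNIST
    key dialect; observed labels under ``*_labels`` (column vectors), true
    labels preserved under ``*_true_labels`` when they differ."""
    arrays: dict[str, np.ndarray] = {}
    for tag, ds in (("train", train), ("test", test)):
        arrays[f"{tag}_images"] = np.round(ds.images * 255.0).astype(np.uint8)
        arrays[f"{tag}_labels"] = ds.noisy_labels.reshape(-1, 1).astype(np.int64)
        if np.any(ds.noisy_labels != ds.true_labels):
            arrays[f"{tag}_true_labels"] = ds.true_labels.reshape(-1, 1).astype(np.int64)
    arrays["n_classes"] = np.array([train.n_classes], dtype=np.int64)
    np.savez(path, **arrays)


def read_npz_dataset(path: str | Path) -> tuple[LabeledImageDataset, LabeledImageDataset]:
    """Read a train/test archive written by :func:`write_npz_dataset` (or any
    MedMNIST-dialect NPZ).  uint8 images are mapped to [0, 1] floats."""
    with np.load(path) as z:
        missing = [k for k in _NPZ_KEYS if k not in z]
        if missing:
            raise ValueError(f"NPZ archive missing keys: {missing}")
        out = []
        if "n_classes" in z:
            n_classes = int(np.asarray(z["n_classes"]).ravel()[0])
        else:
            n_classes = int(max(z["train_labels"].max(), z["test_labels"].max())) + 1
        for tag in ("train", "test"):
            images = np.asarray(z[f"{tag}_images"])
            labels = np.asarray(z[f"{tag}_labels"]).ravel().astype(np.int64)
            if len(images) != len(labels):
                raise ValueError(
                    f"{tag} split: {len(images)} images but {len(labels)} labels"
                )
            if images.dtype == np.uint8:
                images = images.astype(np.float32) / 255.0
            key = f"{tag}_true_labels"
            true = np.asarray(z[key]).ravel().astype(np.int64) if key in z else labels.copy()
            out.append(LabeledImageDataset(images, true, labels, n_classes, tag))
    return out[0], out[1]


def export_manifest(
    dataset: LabeledImageDataset, tasks: TaskSequence | None, path: str | Path
) -> None:
    """CSV label manifest: index,true_label,noisy_label,task (-1 if unassigned)."""
    task_of = np.full(len(dataset), -1, dtype=np.int64)
    if tasks is not None:
        for t, idx in enumerate(tasks.task_indices):
            task_of[idx] = t
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "true_label", "noisy_label", "task"])
        for i in range(len(dataset)):
            w.writerow([i, dataset.true_labels[i], dataset.noisy_labels[i], task_of[i]])
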