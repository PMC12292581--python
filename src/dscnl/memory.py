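"""Stage 2 — representative–diverse rehearsal sampling.

Per-sample uncertainty is estimated by test-time augmentation voting: S
stochastically augmented copies of an image are classified, each casts an
argmax vote, and the uncertainty is one minus the modal vote fraction
(U in [0, 1 - 1/S]; 0 means all copies agree).  Low-uncertainty samples sit
near their class centre (representative), high-uncertainty ones near the
boundary (diverse).  A fixed-capacity, class-balanced buffer is then filled
per class by *interval sampling*: evenly spaced ranks over the
uncertainty-sorted candidates, so the stored set spans the whole uncertainty
spectrum, endpoints included.  Random and reservoir baselines are provided
for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .backbone import softmax

__all__ = [
    "AugmentationSpec",
    "UncertaintyEstimate",
    "MemoryBuffer",
    "augment",
    "mc_predict",
    "vote_uncertainty",
    "estimate_uncertainties",
    "interval_sample",
    "update_buffer",
    "reservoir_sample",
    "random_sample",
]


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentationSpec:
    """S stochastic augmentations drawn from a named transform family.

    Families: ``affine`` (rotation <=15 deg, translation <=10%, scale
    0.9-1.1, horizontal flip), ``pixel`` (brightness/contrast jitter <=20%,
    additive Gaussian noise sigma <=0.05, colour jitter) and ``mix``
    (affine + pixel + CutOut of <=25% area).  Each copy applies exactly one
    transform drawn uniformly from the family.
    """

    S: int = 10
    family: str = "mix"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.family not in ("affine", "pixel", "mix", "identity"):
            raise ValueError(f"unknown augmentation family: {self.family!r}")


def _rotate(img, rng):
    angle = rng.uniform(-15.0, 15.0)
    return ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1,
                          mode="nearest")


def _translate(img, rng):
    h, w = img.shape[:2]
    dy = rng.uniform(-0.1, 0.1) * h
    dx = rng.uniform(-0.1, 0.1) * w
    return ndimage.shift(img, (dy, dx, 0), order=1, mode="nearest")


def _scale(img, rng):
    s = rng.uniform(0.9, 1.1)
    h, w = img.shape[:2]
    matrix = np.diag([1.0 / s, 1.0 / s, 1.0])
    offset = np.array([h, w, 0]) * (1 - 1.0 / s) / 2.0
    return ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                    mode="nearest")


def _hflip(img, rng):
    return img[:, ::-1]


def _brightness(img, rng):
    return img + rng.uniform(-0.2, 0.2)


def _contrast(img, rng):
    return (img - 0.5) * (1.0 + rng.uniform(-0.2, 0.2)) + 0.5


def _gauss_noise(img, rng):
    return img + rng.normal(0.0, rng.uniform(0.0, 0.05), img.shape)


def _color_jitter(img, rng):
    return img * (1.0 + rng.uniform(-0.2, 0.2, size=(1, 1, img.shape[2])))


def _cutout(img, rng):
    h, w = img.shape[:2]
    side = int(rng.uniform(0.25, 0.5) * min(h, w))  # area <= 25%
    y = rng.integers(0, h - side + 1)
    x = rng.integers(0, w - side + 1)
    out = img.copy()
    out[y : y + side, x : x + side] = 0.0
    return out


_FAMILIES = {
    "affine": [_rotate, _translate, _scale, _hflip],
    "pixel": [_brightness, _contrast, _gauss_noise, _color_jitter],
    "identity": [lambda img, rng: img],
}
_FAMILIES["mix"] = _FAMILIES["affine"] + _FAMILIES["pixel"] + [_cutout]


def augment(
    image: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Return S independently augmented copies of ``image`` (H, W, C)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    transforms = _FAMILIES[spec.family]
    out = np.empty((spec.S,) + image.shape, dtype=np.float32)
    for j in range(spec.S):
        f = transforms[rng.integers(0, len(transforms))]  # the one-hot draw
        out[j] = np.clip(f(image.astype(np.float64), rng), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# uncertainty

@dataclass
class UncertaintyEstimate:
    votes: np.ndarray  # (K,) argmax vote counts, sums to S
    uncertainty: float  # 1 - max votes / S, in [0, 1 - 1/S]
    mc_probs: np.ndarray  # (K,) Monte-Carlo averaged class probabilities


def mc_predict(model, augmented: np.ndarray, class_mask=None) -> np.ndarray:
    """Monte-Carlo class probabilities: mean softmax over augmented copies."""
    probs = model.predict_proba(augmented, class_mask=class_mask)
    return probs.mean(axis=0)


def vote_uncertainty(per_aug_probs: np.ndarray) -> UncertaintyEstimate:
    """Vote-based uncertainty from (S, K) per-augmentation probabilities."""
    p = np.asarray(per_aug_probs, dtype=np.float64)
    if p.ndim != 2 or len(p) < 1:
        raise ValueError("need an (S, K) probability array with S >= 1")
    s, k = p.shape
    votes = np.bincount(p.argmax(axis=1), minlength=k)
    u = 1.0 - votes.max() / s
    return UncertaintyEstimate(votes=votes, uncertainty=float(u),
                               mc_probs=p.mean(axis=0))


def estimate_uncertainties(
    model,
    images: np.ndarray,
    spec: AugmentationSpec,
    class_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Augmentation-vote uncertainty for each image, under one shared rng."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = len(images)
    if n == 0:
        return np.zeros(0)
    batch = np.concatenate([augment(img, spec, rng) for img in images], axis=0)
    probs = model.predict_proba(batch, class_mask=class_mask)
    probs = probs.reshape(n, spec.S, -1)
    return np.array([vote_uncertainty(p).uncertainty for p in probs])


# ---------------------------------------------------------------------------
# interval sampling and the buffer

def interval_sample(uncertainties: np.ndarray, quota: int) -> np.ndarray:
    """Indices of ``quota`` samples at evenly spaced ranks of the ascending
    uncertainty order (stable tie-break by original index).  For quota >= 2
    the minimum- and maximum-uncertainty samples are always included; a
    quota exceeding the class size selects everything."""
    if quota < 0:
        raise ValueError("quota must be >= 0")
    u = np.asarray(uncertainties, dtype=np.float64)
    n = len(u)
    if quota == 0 or n == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.argsort(u, kind="stable")
    if quota >= n:
        return order
    if quota == 1:
        return order[:1]
    ranks = np.round(np.linspace(0, n - 1, quota)).astype(np.int64)
    return order[ranks]


@dataclass
class _ClassStore:
    images: np.ndarray
    labels: np.ndarray
    uncertainties: np.ndarray  # recorded at insertion; reused when shrinking
    seen: int = 0  # stream length seen (reservoir bookkeeping)


@dataclass
class MemoryBuffer:
    """Fixed-capacity, class-balanced replay store.

    Each entry keeps its label and its uncertainty as recorded at insertion
    time, so that quota shrinkage (when new classes arrive) can re-apply
    interval sampling without a forward pass.  The per-class quota is
    ``capacity // n_classes_seen`` with leftover slots given one each to the
    earliest-seen classes.
    """

    capacity: int
    stores: dict[int, _ClassStore] = field(default_factory=dict)
    class_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    def __len__(self) -> int:
        return sum(len(s.labels) for s in self.stores.values())

    def class_counts(self) -> dict[int, int]:
        return {c: len(self.stores[c].labels) for c in self.class_order}

    def quotas(self, classes_seen: list[int]) -> dict[int, int]:
        k = len(classes_seen)
        base, rem = divmod(self.capacity, k)
        return {c: base + (1 if i < rem else 0) for i, c in enumerate(classes_seen)}

    def get_all(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.stores:
            raise ValueError("buffer is empty")
        imgs = np.concatenate([self.stores[c].images for c in self.class_order])
        labs = np.concatenate([self.stores[c].labels for c in self.class_order])
        unc = np.concatenate([self.stores[c].uncertainties for c in self.class_order])
        return imgs, labs, unc

    # -- persistence -------------------------------------------------------
    def save_npz(self, path: str | Path) -> None:
        imgs, labs, unc = self.get_all()
        np.savez(path, images=np.round(imgs * 255).astype(np.uint8),
                 labels=labs, uncertainties=unc,
                 capacity=np.array([self.capacity]),
                 class_order=np.array(self.class_order))

    @classmethod
    def load_npz(cls, path: str | Path) -> "MemoryBuffer":
        with np.load(path) as z:
            buf = cls(capacity=int(z["capacity"][0]))
            imgs = z["images"].astype(np.float32) / 255.0
            labs, unc = z["labels"], z["uncertainties"]
            for c in z["class_order"]:
                m = labs == c
                buf.stores[int(c)] = _ClassStore(imgs[m], labs[m], unc[m],
                                                 seen=int(m.sum()))
                buf.class_order.append(int(c))
        return buf


def update_buffer(
    buffer: MemoryBuffer,
    images: np.ndarray,
    labels: np.ndarray,
    uncertainties: np.ndarray,
    classes_seen: list[int],
) -> MemoryBuffer:
    """Interval-sampling buffer update after a task.

    Quotas are recomputed as capacity / |classes seen|; already-stored
    classes are shrunk to quota by interval sampling over their recorded
    uncertainties, and each newly seen class is filled by interval sampling
    its candidates.  Classes with fewer candidates than quota keep everything
    (spare slots stay unused)."""
    labels = np.asarray(labels)
    quotas = buffer.quotas(classes_seen)
    for c in list(buffer.class_order):
        store = buffer.stores[c]
        q = quotas.get(c, 0)
        if len(store.labels) > q:
            keep = interval_sample(store.uncertainties, q)
            buffer.stores[c] = _ClassStore(store.images[keep], store.labels[keep],
                                           store.uncertainties[keep], store.seen)
    for c in classes_seen:
        if c in buffer.stores:
            continue
        cand = np.flatnonzero(labels == c)
        if len(cand) == 0:
            continue
        pick = cand[interval_sample(uncertainties[cand], quotas[c])]
        buffer.stores[int(c)] = _ClassStore(
            np.asarray(images)[pick], labels[pick],
            np.asarray(uncertainties)[pick], seen=len(cand))
        buffer.class_order.append(int(c))
    assert len(buffer) <= buffer.capacity
    return buffer


def random_sample(
    buffer: MemoryBuffer,
    images: np.ndarray,
    labels: np.ndarray,
    classes_seen: list[int],
    rng: np.random.Generator,
) -> MemoryBuffer:
    """Ablation baseline: pool stored + candidate samples and keep a uniform
    subset up to capacity, ignoring both uncertainty and class balance."""
    if len(buffer) > 0:
        old_imgs, old_labs, _ = buffer.get_all()
        pool_imgs = np.concatenate([old_imgs, images])
        pool_labs = np.concatenate([old_labs, np.asarray(labels)])
    else:
        pool_imgs, pool_labs = np.asarray(images), np.asarray(labels)
    n = len(pool_labs)
    keep = (rng.choice(n, size=buffer.capacity, replace=False)
            if n > buffer.capacity else np.arange(n))
    buffer.stores.clear()
    buffer.class_order.clear()
    for c in classes_seen:
        m = keep[pool_labs[keep] == c]
        if len(m) == 0:
            continue
        buffer.stores[int(c)] = _ClassStore(pool_imgs[m], pool_labs[m],
                                            np.zeros(len(m)), seen=len(m))
        buffer.class_order.append(int(c))
    return buffer


def reservoir_indices(n_items: int, capacity: int, seed: int) -> np.ndarray:
    """Classic single-pass reservoir over a stream of ``n_items``; every item
    ends up retained with probability capacity / n_items."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: list[int] = []
    for i in range(n_items):
        if len(reservoir) < capacity:
            reservoir.append(i)
        else:
            j = int(rng.integers(0, i + 1))
            if j < capacity:
                reservoir[j] = i
    return np.array(sorted(reservoir), dtype=np.int64)


def reservoir_sample(
    buffer: MemoryBuffer,
    images: np.ndarray,
    labels: np.ndarray,
    classes_seen: list[int],
    rng: np.random.Generator,
) -> MemoryBuffer:
    """Ablation baseline: class-balanced reservoir.  Quotas are recomputed as
    for interval sampling; stored classes shrink by uniform subsampling, and
    each new class runs a classic reservoir over its candidate stream."""
    labels = np.asarray(labels)
    quotas = buffer.quotas(classes_seen)
    for c in list(buffer.class_order):
        store = buffer.stores[c]
        q = quotas.get(c, 0)
        if len(store.labels) > q:
            keep = np.sort(rng.choice(len(store.labels), size=q, replace=False))
            buffer.stores[c] = _ClassStore(store.images[keep], store.labels[keep],
                                           store.uncertainties[keep], store.seen)
    for c in classes_seen:
        if c in buffer.stores:
            continue
        cand = np.flatnonzero(labels == c)
        if len(cand) == 0:
            continue
        q = quotas[c]
        pick = cand[reservoir_indices(len(cand), min(q, len(cand)),
                                      seed=int(rng.integers(2**31)))]
        buffer.stores[int(c)] = _ClassStore(
            np.asarray(images)[pick], labels[pick],
            np.zeros(len(pick)), seen=len(cand))
        buffer.class_order.append(int(c))
    return buffer
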