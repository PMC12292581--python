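"""Stage 3 — experience soft replay.

Joint batches are drawn uniformly from the union of the current task's clean
subset and the memory buffer.  Mixup virtual samples are built from a random
pairing of the batch with a Beta(alpha, alpha) weight folded to
lambda' = max(lambda, 1 - lambda) >= 0.5, so every mixed sample stays
dominated by its anchor and the anchor's label remains meaningful.  The
objective is L = L_ce + beta * L_mix: hard-label cross-entropy on the
un-mixed batch plus soft-label cross-entropy on the mixed batch; beta = 0
reduces to plain experience replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import soft_cross_entropy

__all__ = [
    "LossConfig",
    "MixupDraw",
    "compose_batch",
    "sample_lambda",
    "mixup_pair",
    "mixup_batch",
    "mix_loss",
    "combined_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """beta weighs the mixup term; alpha is the Beta concentration."""

    beta: float = 1.0
    alpha: float = 1.0
    pairing: str = "permutation"  # or "memory-anchored"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.pairing not in ("permutation", "memory-anchored"):
            raise ValueError(f"unknown pairing policy: {self.pairing!r}")


@dataclass
class MixupDraw:
    lam: float
    lam_prime: float
    image: np.ndarray
    soft_label: np.ndarray


def compose_batch(
    clean_images: np.ndarray,
    clean_labels: np.ndarray,
    buffer_images: np.ndarray | None,
    buffer_labels: np.ndarray | None,
    batch_size: int,
    n_classes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a batch uniformly from clean-subset ∪ buffer.

    Returns (images, one-hot labels over the global class space, is_memory
    flags).  With an empty buffer (task 1) the batch is purely current-task.
    """
    if batch_size < 2:
        raise ValueError("batch size must be >= 2")
    n_cur = len(clean_labels)
    n_mem = 0 if buffer_labels is None else len(buffer_labels)
    if n_cur + n_mem == 0:
        raise ValueError("both the clean subset and the buffer are empty")
    idx = rng.integers(0, n_cur + n_mem, size=batch_size)
    from_mem = idx >= n_cur
    images = np.empty((batch_size,) + tuple(clean_images.shape[1:]),
                      dtype=np.float32)
    labels = np.empty(batch_size, dtype=np.int64)
    cur = ~from_mem
    images[cur] = clean_images[idx[cur]]
    labels[cur] = np.asarray(clean_labels)[idx[cur]]
    if from_mem.any():
        images[from_mem] = buffer_images[idx[from_mem] - n_cur]
        labels[from_mem] = np.asarray(buffer_labels)[idx[from_mem] - n_cur]
    one_hot = np.zeros((batch_size, n_classes), dtype=np.float64)
    one_hot[np.arange(batch_size), labels] = 1.0
    return images, one_hot, from_mem


def sample_lambda(alpha: float, rng: np.random.Generator) -> tuple[float, float]:
    """lambda ~ Beta(alpha, alpha); lambda' = max(lambda, 1 - lambda)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    lam = float(rng.beta(alpha, alpha))
    return lam, max(lam, 1.0 - lam)


def mixup_pair(
    x_i: np.ndarray, y_i: np.ndarray, x_j: np.ndarray, y_j: np.ndarray,
    lam_prime: float,
) -> MixupDraw:
    """Convex combination of two samples and their (probability) labels."""
    x_i, x_j = np.asarray(x_i), np.asarray(x_j)
    if x_i.shape != x_j.shape:
        raise ValueError("image shape mismatch")
    y_i, y_j = np.asarray(y_i, dtype=np.float64), np.asarray(y_j, dtype=np.float64)
    if y_i.shape != y_j.shape:
        raise ValueError("label shape mismatch")
    return MixupDraw(
        lam=lam_prime,
        lam_prime=lam_prime,
        image=lam_prime * x_i + (1.0 - lam_prime) * x_j,
        soft_label=lam_prime * y_i + (1.0 - lam_prime) * y_j,
    )


def mixup_batch(
    images: np.ndarray,
    soft_labels: np.ndarray,
    config: LossConfig,
    rng: np.random.Generator,
    is_memory: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mix a batch against a partner assignment.

    ``permutation`` pairing mixes each sample with a random permutation of
    the batch, so memory and current samples fuse naturally;
    ``memory-anchored`` forces every memory sample to draw its partner from
    the current-task part of the batch."""
    n = len(images)
    partner = rng.permutation(n)
    if config.pairing == "memory-anchored" and is_memory is not None:
        cur_idx = np.flatnonzero(~is_memory)
        if len(cur_idx) > 0:
            mem_idx = np.flatnonzero(is_memory)
            partner[mem_idx] = rng.choice(cur_idx, size=len(mem_idx))
    _, lam_prime = sample_lambda(config.alpha, rng)
    mixed_x = lam_prime * images + (1.0 - lam_prime) * images[partner]
    mixed_y = lam_prime * soft_labels + (1.0 - lam_prime) * soft_labels[partner]
    return mixed_x.astype(np.float32), mixed_y, lam_prime


def mix_loss(model_probs: np.ndarray, soft_labels: np.ndarray) -> float:
    """Soft-label cross-entropy, mean over the batch (1e-12 floor)."""
    return soft_cross_entropy(model_probs, soft_labels)


def combined_loss(l_ce: float, l_mix: float, beta: float) -> float:
    """L = L_ce + beta * L_mix; beta = 0 is plain experience replay."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(l_ce + beta * l_mix)
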