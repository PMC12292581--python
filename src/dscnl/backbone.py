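"""Small deterministic numpy classifiers used as desk-scale backbones.

``TinyConvNet`` is a 3-block convolutional network (3x3 conv + ReLU + 2x2
max-pool, channel widths 4/8/16, linear head) trained with Adam.  Everything
is plain numpy with explicit backprop, which keeps runs bit-reproducible on a
single CPU thread and free of framework dependencies; at 32x32 inputs and
desk-scale sample counts a full incremental run takes seconds.

The output dimension is the *total* class count of the benchmark (single
unified head, no task identifier); class-incremental training masks the
logits of classes not yet seen via ``class_mask``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["TinyConvNet", "MLPNet", "make_backbone", "softmax", "soft_cross_entropy"]

_NEG = np.float32(-1e30)


def softmax(logits: np.ndarray, class_mask: np.ndarray | None = None) -> np.ndarray:
    """Row-wise softmax; entries where ``class_mask`` is False get zero mass."""
    z = np.asarray(logits, dtype=np.float64)
    if class_mask is not None:
        z = np.where(class_mask[None, :], z, _NEG)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def soft_cross_entropy(probs: np.ndarray, soft_targets: np.ndarray) -> float:
    """Mean -sum_c y_c log p_c with a 1e-12 probability floor."""
    p = np.clip(probs, 1e-12, None)
    return float(-(soft_targets * np.log(p)).sum(axis=1).mean())


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k), dtype=np.float64)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    # x: (N, H, W, C), 3x3 window, pad 1 -> (N*H*W, C*9)
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, c * 9)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    n, h, w, c = shape
    d6 = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w, :] += d6[:, :, :, :, i, j]
    return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    r = r.reshape(n, h // 2, w // 2, c, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_back(dout: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    n, h, w, c = shape
    dr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dr.reshape(n, h, w, c)


class _Adam:
    def __init__(self, lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class _Net:
    """Shared training loop over subclasses providing forward/backward."""

    n_classes: int
    params: dict[str, np.ndarray]

    def __init__(self, n_classes: int, lr: float, seed: int):
        self.n_classes = int(n_classes)
        self.opt = _Adam(lr)
        self.rng = np.random.default_rng(seed)

    # subclass API -----------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        raise NotImplementedError

    def _backward(self, dlogits: np.ndarray, cache: tuple) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # public API -------------------------------------------------------
    def predict_proba(
        self,
        images: np.ndarray,
        class_mask: np.ndarray | None = None,
        batch_size: int = 512,
    ) -> np.ndarray:
        out = []
        for lo in range(0, len(images), batch_size):
            logits, _ = self._forward(images[lo : lo + batch_size])
            out.append(softmax(logits, class_mask))
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, class_mask: np.ndarray | None = None) -> np.ndarray:
        return self.predict_proba(images, class_mask).argmax(axis=1)

    def loss_and_grads(
        self,
        images: np.ndarray,
        soft_targets: np.ndarray,
        class_mask: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Soft-label cross-entropy loss and parameter gradients for a batch."""
        logits, cache = self._forward(images)
        probs = softmax(logits, class_mask)
        loss = soft_cross_entropy(probs, soft_targets)
        dlogits = (probs - soft_targets) / len(images)
        if class_mask is not None:
            dlogits = dlogits * class_mask[None, :]
        return loss, self._backward(dlogits.astype(np.float32), cache)

    def apply_grads(self, grads: dict[str, np.ndarray]) -> None:
        self.opt.step(self.params, grads)

    def train_epoch(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        batch_size: int = 64,
        class_mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> float:
        """One shuffled epoch of hard-label cross-entropy; returns mean loss."""
        rng = rng if rng is not None else self.rng
        order = rng.permutation(len(images))
        targets = _one_hot(np.asarray(labels), self.n_classes)
        losses = []
        for lo in range(0, len(order), batch_size):
            idx = order[lo : lo + batch_size]
            loss, grads = self.loss_and_grads(images[idx], targets[idx], class_mask)
            self.apply_grads(grads)
            losses.append(loss)
        return float(np.mean(losses))


class TinyConvNet(_Net):
    """3-block CNN: [conv3x3 -> ReLU -> maxpool2] x3 + linear head."""

    def __init__(
        self,
        n_classes: int,
        image_size: int = 32,
        channels: tuple[int, int, int] = (4, 8, 16),
        lr: float = 1e-3,
        seed: int = 0,
    ):
        super().__init__(n_classes, lr, seed)
        if image_size % 8 != 0:
            raise ValueError("image_size must be divisible by 8")
        self.image_size = image_size
        self.channels = channels
        cs = (3,) + tuple(channels)
        self.params = {}
        for b in range(3):
            fan_in = cs[b] * 9
            self.params[f"W{b}"] = (
                self.rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, cs[b + 1]))
            ).astype(np.float32)
            self.params[f"b{b}"] = np.zeros(cs[b + 1], dtype=np.float32)
        feat = channels[2] * (image_size // 8) ** 2
        self.params["Wf"] = (
            self.rng.normal(0, np.sqrt(2.0 / feat), (feat, n_classes))
        ).astype(np.float32)
        self.params["bf"] = np.zeros(n_classes, dtype=np.float32)

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        x = np.asarray(x, dtype=np.float32)
        caches = []
        for b in range(3):
            n, h, w, c = x.shape
            cols = _im2col(x)
            z = cols @ self.params[f"W{b}"] + self.params[f"b{b}"]
            a = np.maximum(z, 0.0)
            amap = a.reshape(n, h, w, -1)
            pooled, idx = _maxpool(amap)
            caches.append((x.shape, cols, z > 0, amap.shape, idx))
            x = pooled
        flat = x.reshape(len(x), -1)
        logits = flat @ self.params["Wf"] + self.params["bf"]
        return logits, (caches, flat, x.shape)

    def _backward(self, dlogits: np.ndarray, cache: tuple) -> dict[str, np.ndarray]:
        caches, flat, pooled_shape = cache
        grads: dict[str, np.ndarray] = {
            "Wf": flat.T @ dlogits,
            "bf": dlogits.sum(axis=0),
        }
        dx = (dlogits @ self.params["Wf"].T).reshape(pooled_shape).astype(np.float32)
        for b in (2, 1, 0):
            xshape, cols, relu_mask, amap_shape, idx = caches[b]
            da = _maxpool_back(dx, idx, amap_shape)
            dz = da.reshape(-1, amap_shape[3]) * relu_mask
            grads[f"W{b}"] = cols.T @ dz
            grads[f"b{b}"] = dz.sum(axis=0)
            dcols = dz @ self.params[f"W{b}"].T
            dx = _col2im(dcols, xshape)
        return grads


class MLPNet(_Net):
    """One-hidden-layer perceptron on flattened pixels; a fast baseline for
    plumbing tests and cross-validated noise-rate estimation."""

    def __init__(self, n_classes: int, image_size: int = 32, hidden: int = 64,
                 lr: float = 1e-3, seed: int = 0):
        super().__init__(n_classes, lr, seed)
        self.image_size = image_size
        d = image_size * image_size * 3
        self.params = {
            "W0": self.rng.normal(0, np.sqrt(2.0 / d), (d, hidden)).astype(np.float32),
            "b0": np.zeros(hidden, dtype=np.float32),
            "W1": self.rng.normal(0, np.sqrt(2.0 / hidden), (hidden, n_classes)).astype(
                np.float32
            ),
            "b1": np.zeros(n_classes, dtype=np.float32),
        }

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        flat = np.asarray(x, dtype=np.float32).reshape(len(x), -1)
        z = flat @ self.params["W0"] + self.params["b0"]
        a = np.maximum(z, 0.0)
        logits = a @ self.params["W1"] + self.params["b1"]
        return logits, (flat, z > 0, a)

    def _backward(self, dlogits: np.ndarray, cache: tuple) -> dict[str, np.ndarray]:
        flat, relu_mask, a = cache
        grads = {"W1": a.T @ dlogits, "b1": dlogits.sum(axis=0)}
        da = (dlogits @ self.params["W1"].T) * relu_mask
        grads["W0"] = flat.T @ da
        grads["b0"] = da.sum(axis=0)
        return grads


def make_backbone(
    n_classes: int,
    image_size: int = 32,
    arch: str = "tiny_cnn",
    lr: float = 1e-3,
    seed: int = 0,
) -> _Net:
    """Factory for fresh backbones (used for both the main and the auxiliary
    expert network, which share an architecture family by default)."""
    if arch == "tiny_cnn":
        return TinyConvNet(n_classes, image_size=image_size, lr=lr, seed=seed)
    if arch == "mlp":
        return MLPNet(n_classes, image_size=image_size, lr=lr, seed=seed)
    raise ValueError(f"unknown backbone architecture: {arch!r}")


BackboneFactory = Callable[[int], _Net]
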