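"""Stage 1 — clean-sample filtering via per-class confidence mixtures.

An auxiliary expert network is warm-up trained on the raw (noisy) task data
while a per-sample history accumulates the softmax probability the network
assigns to each sample's *own* observed label.  Because networks fit clean,
easy structure before memorising label noise, the per-class distribution of
average historical confidence becomes bimodal: a high-mean component of
presumed-clean samples and a low-mean component of mislabelled / hard ones.
A two-component ("binary") Gaussian mixture is fitted per class by EM, and
samples whose posterior responsibility for the high-mean component clears a
dynamic threshold are retained.  The loop (re-fit mixtures -> select -> train
the auxiliary network one epoch on the selection -> refresh the history)
repeats until the selection reaches the expected clean count
``round((1 - rho) * N)``, with rho either user-supplied or estimated by
cross-validated disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

from .backbone import make_backbone
from .datasets import LabeledImageDataset

__all__ = [
    "ConfidenceHistory",
    "BgmmFit",
    "CleanSubset",
    "FilterConfig",
    "update_history",
    "average_confidence",
    "fit_class_bgmm",
    "select_clean",
    "adjust_threshold",
    "expected_clean_count",
    "estimate_noise_rate",
    "run_filtering_loop",
]

_VARIANCE_FLOOR = 1e-4


@dataclass
class ConfidenceHistory:
    """Running per-sample sum of the probability assigned to the observed label."""

    cumulative: np.ndarray
    epochs_recorded: int = 0

    @classmethod
    def empty(cls, n_samples: int) -> "ConfidenceHistory":
        return cls(np.zeros(n_samples, dtype=np.float64), 0)


def update_history(history: ConfidenceHistory, label_probs: np.ndarray) -> ConfidenceHistory:
    """Add one epoch's own-label probabilities to the running sums."""
    p = np.asarray(label_probs, dtype=np.float64)
    if p.shape != history.cumulative.shape:
        raise ValueError(
            f"expected {history.cumulative.shape[0]} probabilities, got {p.shape}"
        )
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("label probabilities must lie in [0, 1]")
    return ConfidenceHistory(history.cumulative + p, history.epochs_recorded + 1)


def average_confidence(history: ConfidenceHistory) -> np.ndarray:
    """Per-sample mean confidence C_i / E in [0, 1]."""
    if history.epochs_recorded < 1:
        raise ValueError("no epochs recorded yet")
    return history.cumulative / history.epochs_recorded


@dataclass
class BgmmFit:
    """Ordered two-component univariate Gaussian mixture for one class."""

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    weight_low: float
    weight_high: float
    resp_high: np.ndarray  # posterior responsibility of the high-mean component
    converged: bool = True
    degenerate: bool = False


def fit_class_bgmm(
    values: np.ndarray, min_samples: int = 10, seed: int = 0
) -> BgmmFit:
    """Fit a 2-component mixture to one class's average confidences by EM.

    EM is initialised from the 25th/75th percentiles with a variance floor of
    1e-4; components are reported ordered so ``mu_low <= mu_high``.  Classes
    with fewer than ``min_samples`` values, or with (near-)constant values,
    yield a degenerate fit that the caller treats as "select everything".
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if len(v) < min_samples or np.std(v) < 1e-6:
        n = len(v)
        mu = float(np.mean(v)) if n else 0.0
        return BgmmFit(mu, mu, _VARIANCE_FLOOR**0.5, _VARIANCE_FLOOR**0.5,
                       0.5, 0.5, np.ones(n), converged=False, degenerate=True)
    init = np.percentile(v, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=_VARIANCE_FLOOR,
        means_init=init,
        weights_init=np.array([0.5, 0.5]),
        precisions_init=np.full((2, 1, 1), 1.0 / max(np.var(v), _VARIANCE_FLOOR)),
        max_iter=200,
        random_state=seed,
    )
    gm.fit(v.reshape(-1, 1))
    means = gm.means_.ravel()
    order = np.argsort(means)
    lo, hi = order[0], order[1]
    resp = gm.predict_proba(v.reshape(-1, 1))
    sig = np.sqrt(gm.covariances_.reshape(2))
    return BgmmFit(
        mu_low=float(means[lo]),
        mu_high=float(means[hi]),
        sigma_low=float(sig[lo]),
        sigma_high=float(sig[hi]),
        weight_low=float(gm.weights_[lo]),
        weight_high=float(gm.weights_[hi]),
        resp_high=resp[:, hi],
        converged=bool(gm.converged_),
        degenerate=False,
    )


def select_clean(fit: BgmmFit, tau: float) -> np.ndarray:
    """Boolean mask of samples whose clean-component posterior >= tau.

    Degenerate fits (tiny or constant classes) select everything: with no
    evidence of bimodality the class is passed through unfiltered.
    """
    if fit.degenerate:
        return np.ones(len(fit.resp_high), dtype=bool)
    return fit.resp_high >= tau


def adjust_threshold(
    tau: float, selected: int, expected: int, gamma: float = 0.8
) -> float:
    """Dynamic amplification: move tau toward 1 (multiply 1-tau by gamma)
    while the selection overshoots the expected clean count, relax it
    (divide 1-tau by gamma) otherwise.  Clipped to (0, 1)."""
    if selected > expected:
        tau = 1.0 - gamma * (1.0 - tau)
    else:
        tau = 1.0 - (1.0 - tau) / gamma
    return float(np.clip(tau, 1e-3, 1.0 - 1e-3))


def expected_clean_count(noise_rate_estimate: float, n_samples: int) -> int:
    if not 0.0 <= noise_rate_estimate < 1.0:
        raise ValueError("noise rate estimate must be in [0, 1)")
    return int(round((1.0 - noise_rate_estimate) * n_samples))


@dataclass
class CleanSubset:
    """Indices (into the task dataset) retained as presumed clean."""

    indices: np.ndarray
    labels: np.ndarray  # retained observed labels, presumed clean
    converged: bool = True

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("clean-subset indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class FilterConfig:
    """Auxiliary-network filtering configuration.

    ``warmup_epochs`` of plain training accumulate the confidence history
    before any selection; the learning rate / batch size are the auxiliary
    network's (desk-scale defaults; the full-scale benchmark setting used
    1e-4 / 128).  ``known_noise_rate`` bypasses cross-validated estimation and
    is the default in benchmark mode, where the injected rate is known.
    """

    warmup_epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 64
    tau0: float = 0.5
    gamma: float = 0.8
    max_iterations: int = 10
    min_class_size: int = 10
    known_noise_rate: float | None = None
    cv_folds: int = 2
    cv_epochs: int = 5

    def __post_init__(self) -> None:
        if self.warmup_epochs < 1:
            raise ValueError("warmup_epochs must be >= 1")
        if not 0.0 < self.tau0 < 1.0:
            raise ValueError("tau0 must be in (0, 1)")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")


def estimate_noise_rate(
    task: LabeledImageDataset,
    backbone_factory: Callable[[int], object],
    folds: int = 2,
    epochs: int = 5,
    seed: int = 0,
    known_rate: float | None = None,
) -> float:
    """Cross-validated noise-rate estimate: mean held-out disagreement
    between fold-model predictions and the observed labels, clipped to
    [0, 0.9].  ``known_rate`` short-circuits estimation."""
    if known_rate is not None:
        return float(known_rate)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    labels = task.noisy_labels
    counts = np.bincount(labels, minlength=task.n_classes)
    present = np.flatnonzero(counts)
    if np.any(counts[present] < folds):
        raise ValueError("every observed class needs at least `folds` samples")
    mask = np.zeros(task.n_classes, dtype=bool)
    mask[present] = True
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    disagreements = []
    for f, (tr, ho) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        net = backbone_factory(seed + 1000 + f)
        for _ in range(epochs):
            net.train_epoch(task.images[tr], labels[tr], class_mask=mask, rng=rng)
        pred = net.predict(task.images[ho], class_mask=mask)
        disagreements.append(np.mean(pred != labels[ho]))
    return float(np.clip(np.mean(disagreements), 0.0, 0.9))


def run_filtering_loop(
    task: LabeledImageDataset,
    backbone_factory: Callable[[int], object] | None = None,
    config: FilterConfig | None = None,
    seed: int = 0,
) -> tuple[CleanSubset, pd.DataFrame]:
    """Warm up an auxiliary network, then iteratively fit per-class mixtures
    on average confidences and select high-posterior samples until the
    selection reaches the expected clean count.

    Returns the final :class:`CleanSubset` and a per-iteration/per-class
    diagnostics frame (component means, threshold, counts and — when true
    labels are available, i.e. in synthetic mode — selection purity).
    """
    if len(task) == 0:
        raise ValueError("empty task dataset")
    config = config or FilterConfig()
    image_size = task.images.shape[1]
    if backbone_factory is None:
        backbone_factory = lambda s: make_backbone(  # noqa: E731
            task.n_classes, image_size, lr=config.learning_rate, seed=s
        )
    rng = np.random.default_rng(seed)
    net = backbone_factory(seed)
    labels = task.noisy_labels
    class_mask = np.zeros(task.n_classes, dtype=bool)
    class_mask[np.unique(labels)] = True

    history = ConfidenceHistory.empty(len(task))
    for _ in range(config.warmup_epochs):
        net.train_epoch(task.images, labels, batch_size=config.batch_size,
                        class_mask=class_mask, rng=rng)
        probs = net.predict_proba(task.images, class_mask=class_mask)
        history = update_history(history, probs[np.arange(len(task)), labels])

    rho = estimate_noise_rate(
        task, backbone_factory, folds=config.cv_folds, epochs=config.cv_epochs,
        seed=seed, known_rate=config.known_noise_rate,
    )
    expected = expected_clean_count(rho, len(task))

    # purity is meaningful only when true labels are genuinely known
    # (synthetic mode); on real data true == observed and it reads 100.
    clean_truth = task.noisy_labels == task.true_labels

    tau = config.tau0
    rows: list[dict] = []
    mask = np.ones(len(task), dtype=bool)
    converged = False
    for it in range(config.max_iterations):
        avg = average_confidence(history)
        mask = np.zeros(len(task), dtype=bool)
        for c in np.flatnonzero(class_mask):
            in_c = np.flatnonzero(labels == c)
            fit = fit_class_bgmm(avg[in_c], min_samples=config.min_class_size,
                                 seed=seed)
            sel = select_clean(fit, tau)
            mask[in_c[sel]] = True
            rows.append({
                "iteration": it,
                "class": int(c),
                "mu_low": fit.mu_low,
                "mu_high": fit.mu_high,
                "tau": tau,
                "selected_count": int(sel.sum()),
                "class_size": len(in_c),
                "degenerate": fit.degenerate,
                "purity": (100.0 * clean_truth[in_c[sel]].mean()
                           if sel.any() else np.nan),
            })
        total = int(mask.sum())
        if total >= expected:
            converged = True
            break
        tau = adjust_threshold(tau, total, expected, config.gamma)
        if total > 0:
            sel_idx = np.flatnonzero(mask)
            net.train_epoch(task.images[sel_idx], labels[sel_idx],
                            batch_size=config.batch_size, class_mask=class_mask,
                            rng=rng)
        probs = net.predict_proba(task.images, class_mask=class_mask)
        history = update_history(history, probs[np.arange(len(task)), labels])

    idx = np.flatnonzero(mask)
    subset = CleanSubset(indices=idx, labels=labels[idx], converged=converged)
    return subset, pd.DataFrame(rows)
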