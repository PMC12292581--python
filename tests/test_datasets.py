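"""Synthetic stream generation, symmetric noise injection and task splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dscnl.backbone import TinyConvNet
from dscnl.datasets import (LabeledImageDataset, NoiseSpec, TaskSequence,
                            export_manifest, generate_synthetic_dataset,
                            inject_symmetric_noise, read_npz_dataset,
                            split_tasks, write_npz_dataset)


class TestGenerator:
    def test_shapes_and_class_counts(self):
        ds = generate_synthetic_dataset(8, 100, 32, 1.0, seed=7)
        assert len(ds) == 800
        assert ds.images.shape == (800, 32, 32, 3)
        assert sorted(np.unique(ds.true_labels)) == list(range(8))
        assert (np.bincount(ds.true_labels) == 100).all()
        assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0

    def test_minimal_case(self):
        ds = generate_synthetic_dataset(2, 1, 8, 1.0, seed=1)
        assert len(ds) == 2 and set(ds.true_labels) == {0, 1}

    @pytest.mark.parametrize("kwargs", [
        dict(n_classes=1, n_per_class=5),
        dict(n_classes=3, n_per_class=5, image_size=4),
        dict(n_classes=3, n_per_class=5, separability=0.0),
        dict(n_classes=3, n_per_class=0),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_synthetic_dataset(**{"image_size": 16,
                                          "separability": 1.0, "seed": 0,
                                          **kwargs})

    def test_deterministic_for_seed(self):
        a = generate_synthetic_dataset(3, 10, 16, 1.0, seed=5)
        b = generate_synthetic_dataset(3, 10, 16, 1.0, seed=5)
        assert np.array_equal(a.images, b.images)

    def test_small_cnn_separates_classes(self, clean_stream):
        """At separability 1.0 the reference backbone reaches >=95% clean
        test accuracy within 10 epochs."""
        train, test = clean_stream
        net = TinyConvNet(8, 32, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            net.train_epoch(train.images, train.true_labels, rng=rng)
        acc = (net.predict(test.images) == test.true_labels).mean()
        assert acc >= 0.95


class TestNoiseInjection:
    def test_zero_rate_is_identity(self):
        ds = generate_synthetic_dataset(4, 20, 16, 1.0, seed=0)
        out = inject_symmetric_noise(ds, NoiseSpec(rate=0.0, seed=3))
        assert np.array_equal(out.noisy_labels, out.true_labels)

    @pytest.mark.parametrize("rate,seed", [(0.1, 0), (0.3, 1), (0.5, 2),
                                           (0.37, 3)])
    def test_exact_corruption_count(self, rate, seed):
        ds = generate_synthetic_dataset(5, 40, 16, 1.0, seed=0)
        out = inject_symmetric_noise(ds, NoiseSpec(rate=rate, seed=seed))
        n_flipped = int((out.noisy_labels != out.true_labels).sum())
        assert n_flipped == round(rate * len(ds))
        assert np.array_equal(out.true_labels, ds.true_labels)

    def test_corrupted_label_never_equals_original(self):
        ds = generate_synthetic_dataset(3, 50, 16, 1.0, seed=0)
        out = inject_symmetric_noise(ds, NoiseSpec(rate=0.9, seed=7))
        flipped = out.noisy_labels != out.true_labels
        assert flipped.sum() == round(0.9 * len(ds))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            NoiseSpec(rate=1.0)

    def test_class_count_conservation(self):
        ds = generate_synthetic_dataset(6, 30, 16, 1.0, seed=0)
        out = inject_symmetric_noise(ds, NoiseSpec(rate=0.4, seed=5))
        assert np.bincount(out.noisy_labels, minlength=6).sum() == len(ds)

    def test_monte_carlo_matches_closed_form(self):
        """Mean post-noise count of a class over repeated seeds matches
        E[A_c] = (1-rho)B_c + rho(N-B_c)/(K-1) within 3 standard errors."""
        k, rho = 5, 0.3
        counts = np.array([30, 80, 20, 50, 40])
        labels = np.repeat(np.arange(k), counts)
        n = len(labels)
        images = np.zeros((n, 1, 1, 3), dtype=np.float32)
        ds = LabeledImageDataset(images, labels, labels.copy(), k)
        sims = []
        for seed in range(200):
            out = inject_symmetric_noise(ds, NoiseSpec(rate=rho, seed=seed))
            sims.append((out.noisy_labels == 1).sum())
        sims = np.asarray(sims, dtype=float)
        expected = (1 - rho) * counts[1] + rho * (n - counts[1]) / (k - 1)
        sem = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(sims.mean() - expected) <= 3 * sem

    def test_transition_matrix_symmetry(self):
        """Empirical label transitions converge to (1-rho) on the diagonal
        and rho/(K-1) off-diagonal."""
        k, rho = 4, 0.4
        labels = np.repeat(np.arange(k), 50)
        images = np.zeros((len(labels), 1, 1, 3), dtype=np.float32)
        ds = LabeledImageDataset(images, labels, labels.copy(), k)
        trans = np.zeros((k, k))
        n_seeds = 300
        for seed in range(n_seeds):
            out = inject_symmetric_noise(ds, NoiseSpec(rate=rho, seed=seed))
            for a, b in zip(out.true_labels, out.noisy_labels):
                trans[a, b] += 1
        trans /= trans.sum(axis=1, keepdims=True)
        target = np.full((k, k), rho / (k - 1))
        np.fill_diagonal(target, 1 - rho)
        assert np.abs(trans - target).max() < 0.02


class TestTaskSplit:
    def test_four_binary_tasks(self, noisy_stream):
        train, _ = noisy_stream
        seq = split_tasks(train, [{0, 1}, {2, 3}, {4, 5}, {6, 7}])
        assert seq.n_tasks == 4
        all_idx = np.concatenate(seq.task_indices)
        assert len(np.unique(all_idx)) == len(all_idx) == len(train)
        # membership follows the observed label
        for s, idx in zip(seq.class_sets, seq.task_indices):
            assert set(train.noisy_labels[idx]) <= s

    def test_single_task_covers_everything(self, clean_stream):
        train, _ = clean_stream
        seq = split_tasks(train, [set(range(8))])
        assert len(seq.task_indices[0]) == len(train)

    def test_overlapping_partition_rejected(self, clean_stream):
        train, _ = clean_stream
        with pytest.raises(ValueError):
            split_tasks(train, [{0, 1}, {1, 2}])

    def test_classes_seen_accumulates(self):
        seq = TaskSequence(class_sets=[{0, 1}, {2, 3}])
        assert seq.classes_seen(0) == [0, 1]
        assert seq.classes_seen(1) == [0, 1, 2, 3]


class TestNpzRoundTrip:
    def test_bitwise_round_trip(self, tmp_path):
        train = generate_synthetic_dataset(3, 10, 16, 1.0, seed=0)
        test = generate_synthetic_dataset(3, 4, 16, 1.0, seed=1, split="test")
        train = inject_symmetric_noise(train, NoiseSpec(rate=0.3, seed=0))
        path = tmp_path / "stream.npz"
        write_npz_dataset(train, test, path)
        tr2, te2 = read_npz_dataset(path)
        assert np.array_equal(tr2.images, train.images)  # uint8-grid images
        assert np.array_equal(tr2.noisy_labels, train.noisy_labels)
        assert np.array_equal(tr2.true_labels, train.true_labels)
        assert np.array_equal(te2.images, test.images)

    def test_uint8_scaling_convention(self, tmp_path):
        imgs = np.full((2, 8, 8, 3), 0.5, dtype=np.float32)
        ds = LabeledImageDataset(imgs, [0, 1], [0, 1], 2)
        path = tmp_path / "s.npz"
        write_npz_dataset(ds, ds, path)
        with np.load(path) as z:
            assert z["train_images"].dtype == np.uint8
            assert z["train_images"].max() == 128  # round(0.5 * 255)
        tr, _ = read_npz_dataset(path)
        assert tr.images.max() == pytest.approx(128 / 255)

    def test_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, train_images=np.zeros((5, 8, 8, 3), np.uint8),
                 train_labels=np.zeros((4, 1), np.int64),
                 test_images=np.zeros((2, 8, 8, 3), np.uint8),
                 test_labels=np.zeros((2, 1), np.int64))
        with pytest.raises(ValueError, match="5 images but 4 labels"):
            read_npz_dataset(path)

    def test_missing_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, train_images=np.zeros((2, 8, 8, 3), np.uint8))
        with pytest.raises(ValueError, match="missing keys"):
            read_npz_dataset(path)

    def test_manifest_export(self, tmp_path):
        import pandas as pd
        ds = generate_synthetic_dataset(4, 5, 16, 1.0, seed=0)
        seq = split_tasks(ds, [{0, 1}, {2, 3}])
        path = tmp_path / "manifest.csv"
        export_manifest(ds, seq, path)
        m = pd.read_csv(path)
        assert list(m.columns) == ["index", "true_label", "noisy_label", "task"]
        assert len(m) == len(ds)
        assert set(m.task) == {0, 1}


@given(rate=st.floats(0.0, 0.95), seed=st.integers(0, 2**16))
@settings(max_examples=25, deadline=None)
def test_noise_fraction_exact_for_any_seed(rate, seed):
    labels = np.arange(60) % 3
    images = np.zeros((60, 1, 1, 3), dtype=np.float32)
    ds = LabeledImageDataset(images, labels, labels.copy(), 3)
    out = inject_symmetric_noise(ds, NoiseSpec(rate=rate, seed=seed))
    assert (out.noisy_labels != out.true_labels).sum() == round(rate * 60)
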