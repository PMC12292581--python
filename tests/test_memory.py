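"""Augmentation-vote uncertainty and the class-balanced replay buffer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dscnl.backbone import TinyConvNet, make_backbone
from dscnl.datasets import NoiseSpec, generate_synthetic_dataset, \
    inject_symmetric_noise
from dscnl.memory import (AugmentationSpec, MemoryBuffer, augment,
                          estimate_uncertainties, interval_sample, mc_predict,
                          random_sample, reservoir_indices, update_buffer,
                          vote_uncertainty)


class TestAugment:
    def test_identity_family_returns_input(self):
        img = np.random.default_rng(0).random((16, 16, 3)).astype(np.float32)
        out = augment(img, AugmentationSpec(S=1, family="identity", seed=0))
        assert np.allclose(out[0], img)

    def test_fixed_seed_reproducible(self):
        img = np.random.default_rng(1).random((16, 16, 3)).astype(np.float32)
        spec = AugmentationSpec(S=5, family="mix", seed=7)
        assert np.array_equal(augment(img, spec), augment(img, spec))

    @pytest.mark.parametrize("family", ["affine", "pixel", "mix"])
    def test_output_shape_and_range(self, family):
        img = np.random.default_rng(2).random((16, 16, 3)).astype(np.float32)
        out = augment(img, AugmentationSpec(S=8, family=family, seed=3))
        assert out.shape == (8, 16, 16, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(S=2, family="quantum")

    def test_mix_family_includes_cutout(self):
        """Over many draws the mix family produces zeroed squares."""
        img = np.full((16, 16, 3), 0.9, dtype=np.float32)
        out = augment(img, AugmentationSpec(S=50, family="mix", seed=0))
        assert any((copy == 0.0).mean() > 0.05 for copy in out)


class TestVoteUncertainty:
    def test_unanimous_votes_zero_uncertainty(self):
        probs = np.tile([0.9, 0.05, 0.05], (10, 1))
        est = vote_uncertainty(probs)
        assert est.uncertainty == 0.0
        assert est.votes.tolist() == [10, 0, 0]

    def test_split_7_2_1(self):
        probs = np.zeros((10, 3))
        probs[:7, 0] = 1.0
        probs[7:9, 1] = 1.0
        probs[9, 2] = 1.0
        assert vote_uncertainty(probs).uncertainty == pytest.approx(0.3)

    def test_five_way_even_split_is_maximal(self):
        probs = np.zeros((10, 5))
        for j in range(10):
            probs[j, j // 2] = 1.0
        assert vote_uncertainty(probs).uncertainty == pytest.approx(0.8)

    @given(s=st.integers(1, 12), k=st.integers(2, 6),
           seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_identities_against_brute_force(self, s, k, seed):
        """Sum of votes is S and U = 1 - max votes / S, checked against a
        direct per-row argmax count."""
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(k), size=s)
        est = vote_uncertainty(probs)
        brute = np.zeros(k, dtype=int)
        for row in probs:
            brute[int(np.argmax(row))] += 1
        assert est.votes.tolist() == brute.tolist()
        assert est.votes.sum() == s
        assert est.uncertainty == pytest.approx(1 - brute.max() / s)
        assert 0 <= est.uncertainty <= 1 - 1 / s
        assert est.mc_probs.sum() == pytest.approx(1.0)

    def test_mc_predict_averages_predictions(self):
        class Const:
            def predict_proba(self, x, class_mask=None):
                out = np.zeros((len(x), 2))
                out[: len(x) // 2, 0] = 1.0
                out[len(x) // 2:, 1] = 1.0
                return out

        avg = mc_predict(Const(), np.zeros((2, 4, 4, 3)))
        assert np.allclose(avg, [0.5, 0.5])


class TestIntervalSample:
    def test_full_quota_selects_all(self):
        u = np.random.default_rng(0).random(100)
        assert len(interval_sample(u, 100)) == 100

    def test_quota_two_selects_spectrum_endpoints(self):
        u = np.random.default_rng(1).permutation(10).astype(float)
        picked = interval_sample(u, 2)
        assert {u[i] for i in picked} == {0.0, 9.0}

    def test_even_spacing_gaps_differ_by_at_most_one(self):
        u = np.arange(12, dtype=float)
        picked = np.sort(interval_sample(u, 4))
        gaps = np.diff(picked)
        assert gaps.max() - gaps.min() <= 1
        assert picked[0] == 0 and picked[-1] == 11

    def test_quota_exceeding_size_selects_all(self):
        assert len(interval_sample(np.ones(5), 20)) == 5

    def test_stable_tie_break(self):
        u = np.zeros(6)
        assert interval_sample(u, 3).tolist() == [0, 2, 5]


class TestBuffer:
    def test_quota_arithmetic(self):
        buf = MemoryBuffer(capacity=500)
        assert buf.quotas([0, 1]) == {0: 250, 1: 250}
        assert buf.quotas([0, 1, 2, 3]) == {0: 125, 1: 125, 2: 125, 3: 125}
        buf200 = MemoryBuffer(capacity=200)
        assert set(buf200.quotas(list(range(8))).values()) == {25}

    def test_remainder_goes_to_earliest_classes(self):
        buf = MemoryBuffer(capacity=10)
        q = buf.quotas([4, 2, 7])
        assert q == {4: 4, 2: 3, 7: 3}

    def test_shortfall_class_keeps_all(self):
        buf = MemoryBuffer(capacity=100)
        imgs = np.zeros((5, 4, 4, 3), np.float32)
        update_buffer(buf, imgs, np.zeros(5, int), np.arange(5.0), [0, 1])
        assert buf.class_counts() == {0: 5}

    def test_quota_shrink_preserves_endpoints(self):
        """After a quota reduction the stored samples still span the
        recorded uncertainty spectrum of the original selection."""
        rng = np.random.default_rng(0)
        buf = MemoryBuffer(capacity=20)
        imgs = rng.random((40, 4, 4, 3)).astype(np.float32)
        u = rng.random(40)
        update_buffer(buf, imgs, np.zeros(40, int), u, [0])
        lo, hi = buf.stores[0].uncertainties.min(), buf.stores[0].uncertainties.max()
        assert lo == u.min() and hi == u.max()
        update_buffer(buf, imgs, np.ones(40, int), u, [0, 1])
        assert buf.stores[0].uncertainties.min() == u.min()
        assert buf.stores[0].uncertainties.max() == u.max()
        assert len(buf) <= 20

    @given(capacity=st.integers(4, 60), seed=st.integers(0, 5000),
           n_tasks=st.integers(1, 4))
    @settings(max_examples=40, deadline=None)
    def test_capacity_and_balance_over_random_sequences(self, capacity, seed,
                                                        n_tasks):
        """Occupancy never exceeds capacity and filled classes differ by at
        most one from their quota across arbitrary task sequences."""
        rng = np.random.default_rng(seed)
        buf = MemoryBuffer(capacity=capacity)
        seen: list[int] = []
        for t in range(n_tasks):
            new_classes = [2 * t, 2 * t + 1]
            seen += new_classes
            n = int(rng.integers(10, 80))
            labels = rng.choice(new_classes, size=n)
            imgs = np.zeros((n, 2, 2, 3), np.float32)
            update_buffer(buf, imgs, labels, rng.random(n), seen)
            assert len(buf) <= capacity
            quotas = buf.quotas(seen)
            for c, cnt in buf.class_counts().items():
                assert cnt <= quotas[c]

    def test_npz_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        buf = MemoryBuffer(capacity=12)
        imgs = np.round(rng.random((30, 4, 4, 3)) * 255).astype(np.uint8)
        imgs = imgs.astype(np.float32) / 255.0
        labels = rng.integers(0, 2, 30)
        update_buffer(buf, imgs, labels, rng.random(30), [0, 1])
        path = tmp_path / "buffer.npz"
        buf.save_npz(path)
        loaded = MemoryBuffer.load_npz(path)
        assert loaded.capacity == 12
        assert loaded.class_counts() == buf.class_counts()
        a, _, _ = buf.get_all()
        b, _, _ = loaded.get_all()
        assert np.allclose(a, b)


class TestBaselineSamplers:
    def test_reservoir_capacity_covers_stream(self):
        idx = reservoir_indices(50, 100, seed=0)
        assert len(idx) == 50

    def test_reservoir_retention_is_uniform(self):
        """Each item of a 2000-long stream is retained with probability
        capacity/n; chi-square over 300 seeds."""
        from scipy.stats import chisquare
        n, cap = 2000, 50
        counts = np.zeros(n)
        n_seeds = 300
        for seed in range(n_seeds):
            counts[reservoir_indices(n, cap, seed)] += 1
        # bin items into 20 groups to keep expected counts large
        binned = counts.reshape(20, -1).sum(axis=1)
        expected = np.full(20, n_seeds * cap / 20)
        assert chisquare(binned, expected).pvalue > 1e-3

    def test_random_sampler_ignores_uncertainty(self):
        rng_imgs = np.random.default_rng(0)
        imgs = rng_imgs.random((60, 2, 2, 3)).astype(np.float32)
        labels = np.repeat([0, 1], 30)
        a = random_sample(MemoryBuffer(20), imgs, labels, [0, 1],
                          np.random.default_rng(5))
        b = random_sample(MemoryBuffer(20), imgs, labels, [0, 1],
                          np.random.default_rng(5))
        assert a.class_counts() == b.class_counts()
        ia, la, _ = a.get_all()
        ib, lb, _ = b.get_all()
        assert np.allclose(ia, ib) and np.array_equal(la, lb)


def test_mislabeled_samples_are_more_uncertain():
    """After training on a noisy task, augmentation-vote uncertainty is on
    average higher for mislabeled samples than for clean ones (averaged over
    seeds) — the premise behind spectrum-covering replay selection."""
    diffs = []
    for seed in range(5):
        ds = generate_synthetic_dataset(8, 60, 32, 1.0, seed=seed)
        ds = inject_symmetric_noise(ds, NoiseSpec(rate=0.3, seed=seed))
        net = make_backbone(8, 32, arch="tiny_cnn", seed=seed)
        rng = np.random.default_rng(seed)
        for _ in range(8):
            net.train_epoch(ds.images, ds.noisy_labels, rng=rng)
        u = estimate_uncertainties(net, ds.images,
                                   AugmentationSpec(S=10, family="mix"),
                                   rng=np.random.default_rng(seed + 1))
        assert np.all((u >= 0) & (u <= 1 - 1 / 10))
        noisy = ds.noisy_labels != ds.true_labels
        diffs.append(u[noisy].mean() - u[~noisy].mean())
    assert np.mean(diffs) > 0
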