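"""SSL relabeler: augmentations, contrastive losses, clustering, alignment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ripplelabel import nn
from ripplelabel.autodiff import Tensor
from ripplelabel.relabel import (
    AugmentationConfig,
    EncoderConfig,
    SSLEncoder,
    align_and_compose,
    contextual_contrast_loss,
    embed,
    relabel_kmeans,
    strong_augment,
    temporal_contrast_loss,
    train_ssl,
    weak_augment,
)
from ripplelabel.simulate import ObservedLabel, generate_dataset, SimConfig


SMALL_CFG = EncoderConfig(epochs=2, batch_size=32, seed=0)


@pytest.fixture(scope="module")
def separable_training():
    """SSL model trained on 512 clean windows (256 per class)."""
    dataset = generate_dataset(256, config=SimConfig(seed=13))
    cfg = EncoderConfig(epochs=40, batch_size=64, seed=13)
    model, history = train_ssl(dataset, cfg)
    return dataset, model, history


class TestWeakAugment:
    def test_identity_when_degenerate(self):
        cfg = AugmentationConfig(weak_scale_range=(1.0, 1.0), weak_jitter_sd=0.0)
        x = np.random.default_rng(0).normal(size=512).astype(np.float32)
        assert np.allclose(weak_augment(x, cfg, np.random.default_rng(1)), x)

    def test_pure_scaling_has_constant_ratio(self):
        cfg = AugmentationConfig(weak_scale_range=(0.5, 2.0), weak_jitter_sd=0.0)
        x = np.full(512, 3.0, np.float32)
        out = weak_augment(x, cfg, np.random.default_rng(2))
        ratios = out / x
        assert np.allclose(ratios, ratios[0])
        assert 0.5 <= ratios[0] <= 2.0

    def test_jitter_is_zero_mean(self):
        """Sample-mean oracle: residual after descaling averages to ~0."""
        cfg = AugmentationConfig(weak_scale_range=(1.0, 1.0), weak_jitter_sd=0.05)
        x = np.zeros((20, 512), np.float32)
        out = weak_augment(x, cfg, np.random.default_rng(3))
        se = 0.05 / np.sqrt(out.size)
        assert abs(out.mean()) < 3 * se


class TestStrongAugment:
    def test_single_segment_is_identity(self):
        cfg = AugmentationConfig(strong_num_segments_range=(1, 1), strong_jitter_sd=0.0)
        x = np.random.default_rng(0).normal(size=512).astype(np.float32)
        assert np.allclose(strong_augment(x, cfg, np.random.default_rng(1)), x)

    def test_sample_multiset_conserved_without_jitter(self):
        cfg = AugmentationConfig(strong_num_segments_range=(4, 8), strong_jitter_sd=0.0)
        x = np.random.default_rng(2).normal(size=512).astype(np.float32)
        out = strong_augment(x, cfg, np.random.default_rng(3))
        assert np.allclose(np.sort(out), np.sort(x))

    def test_two_segments_are_contiguous_rotation(self):
        """Enumeration oracle: a 2-segment permutation is either the identity
        or a swap of two contiguous blocks, i.e. one of the 511 rotations."""
        cfg = AugmentationConfig(strong_num_segments_range=(2, 2), strong_jitter_sd=0.0)
        x = np.arange(512, dtype=np.float32)
        out = strong_augment(x, cfg, np.random.default_rng(4))
        candidates = [x] + [np.r_[x[c:], x[:c]] for c in range(1, 512)]
        assert any(np.array_equal(out, c) for c in candidates)

    def test_too_many_segments_rejected(self):
        cfg = AugmentationConfig(strong_num_segments_range=(600, 600))
        with pytest.raises(ValueError):
            strong_augment(np.zeros(512, np.float32), cfg, np.random.default_rng(0))


class TestEncoder:
    def test_encode_is_deterministic_in_eval_mode(self):
        model = SSLEncoder(SMALL_CFG, np.random.default_rng(0))
        model.eval()
        x = np.random.default_rng(1).normal(size=(4, 512)).astype(np.float32)
        assert np.array_equal(model.encode(x).numpy(), model.encode(x).numpy())

    def test_batch_dimension_preserved(self):
        model = SSLEncoder(SMALL_CFG, np.random.default_rng(0))
        x = np.zeros((7, 512), np.float32)
        z = model.encode(x)
        assert z.shape == (7, SMALL_CFG.latent_timesteps, SMALL_CFG.latent_dim)

    def test_distinct_inputs_give_distinct_latents(self):
        model = SSLEncoder(SMALL_CFG, np.random.default_rng(0))
        model.eval()
        quiet = np.zeros((1, 512), np.float32)
        loud = np.full((1, 512), 5.0, np.float32)
        assert not np.allclose(
            model.encode(quiet).numpy(), model.encode(loud).numpy()
        )

    def test_wrong_length_rejected(self):
        model = SSLEncoder(SMALL_CFG, np.random.default_rng(0))
        with pytest.raises(ValueError):
            model.encode(np.zeros((2, 256), np.float32))


class TestTemporalContrastLoss:
    def test_uniform_similarities_give_log_n(self):
        """With zeroed prediction heads every candidate scores equally."""
        model = SSLEncoder(SMALL_CFG, np.random.default_rng(0))
        for head in model.predict_heads:
            head.weight.data[:] = 0.0
            head.bias.data[:] = 0.0
        n = 6
        rng = np.random.default_rng(1)
        z_s = model.encode(rng.normal(size=(n, 512)).astype(np.float32))
        z_w = model.encode(rng.normal(size=(n, 512)).astype(np.float32))
        loss = temporal_contrast_loss(model, z_s, z_w, t=3)
        assert loss.item() == pytest.approx(np.log(n), rel=1e-5)

    def test_matches_handrolled_softmax_cross_entropy(self):
        """Brute-force oracle on batch 3 recomputed outside the graph."""
        cfg = SMALL_CFG
        model = SSLEncoder(cfg, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        z_s = model.encode(rng.normal(size=(3, 512)).astype(np.float32))
        z_w = model.encode(rng.normal(size=(3, 512)).astype(np.float32))
        t = 2
        loss = temporal_contrast_loss(model, z_s, z_w, t=t)

        def direction(ctx_latents, future_latents):
            c = model.ar(Tensor(ctx_latents[:, : t + 1, :])).numpy()
            total = 0.0
            for k in range(1, cfg.prediction_horizon + 1):
                head = model.predict_heads[k - 1]
                pred = c @ head.weight.numpy() + head.bias.numpy()
                scores = pred @ future_latents[:, t + k, :].T
                scores -= scores.max(axis=1, keepdims=True)
                log_probs = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
                total += -np.diag(log_probs).mean()
            return total

        expected = (
            direction(z_s.numpy(), z_w.numpy())
            + direction(z_w.numpy(), z_s.numpy())
        ) / (2 * cfg.prediction_horizon)
        assert loss.item() == pytest.approx(expected, rel=1e-4)

    def test_horizon_must_fit(self):
        cfg = SMALL_CFG
        model = SSLEncoder(cfg, np.random.default_rng(0))
        short = Tensor(np.zeros((2, cfg.prediction_horizon, cfg.latent_dim), np.float32))
        with pytest.raises(ValueError):
            temporal_contrast_loss(model, short, short, t=0)


class TestContextualContrastLoss:
    def test_identical_projections_give_log_2n_minus_1(self):
        n = 4
        same = Tensor(np.ones((n, 8), np.float32))
        loss = contextual_contrast_loss(same, same, temperature=0.2)
        assert loss.item() == pytest.approx(np.log(2 * n - 1), rel=1e-4)

    def test_orthogonal_negatives_closed_form(self):
        """N=2, siblings identical, cross-pairs orthogonal: the softmax has
        one positive at cosine 1 and two negatives at cosine 0."""
        tau = 0.2
        a = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]], np.float32))
        loss = contextual_contrast_loss(a, a, temperature=tau)
        expected = -np.log(np.exp(1 / tau) / (np.exp(1 / tau) + 2 * np.exp(0.0)))
        assert loss.item() == pytest.approx(expected, rel=1e-4)

    def test_infinite_temperature_limit(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(5, 8)).astype(np.float32))
        b = Tensor(rng.normal(size=(5, 8)).astype(np.float32))
        loss = contextual_contrast_loss(a, b, temperature=1e6)
        assert loss.item() == pytest.approx(np.log(9), rel=1e-3)

    def test_single_sample_rejected(self):
        a = Tensor(np.ones((1, 4), np.float32))
        with pytest.raises(ValueError):
            contextual_contrast_loss(a, a, temperature=0.2)


class TestTrainSSL:
    def test_history_bookkeeping(self, tiny_dataset):
        model, history = train_ssl(tiny_dataset, SMALL_CFG)
        assert len(history) == SMALL_CFG.epochs
        assert all(np.isfinite(history))

    def test_same_seed_reproduces_losses(self, tiny_dataset):
        _, h1 = train_ssl(tiny_dataset, SMALL_CFG)
        _, h2 = train_ssl(tiny_dataset, SMALL_CFG)
        assert h1 == h2

    def test_observed_labels_never_consumed(self, tiny_dataset):
        """Permuting the label vector cannot change a label-blind training."""
        import dataclasses

        shuffled = dataclasses.replace(
            tiny_dataset,
            observed_label=np.random.default_rng(0).permutation(
                tiny_dataset.observed_label
            ),
        )
        _, h1 = train_ssl(tiny_dataset, SMALL_CFG)
        _, h2 = train_ssl(shuffled, SMALL_CFG)
        assert h1 == h2

    def test_oversized_batch_rejected(self, tiny_dataset):
        cfg = EncoderConfig(epochs=1, batch_size=10_000, seed=0)
        with pytest.raises(ValueError):
            train_ssl(tiny_dataset, cfg)

    def test_loss_decreases_on_separable_data(self, separable_training):
        _, _, history = separable_training
        assert history[-1] < history[0]

    def test_frozen_embeddings_beat_chance(self, separable_training):
        """Downstream-probe oracle: a linear probe on the SSL features
        separates the classes far better than coin flipping (p < 0.01)."""
        from sklearn.linear_model import LogisticRegression

        dataset, model, _ = separable_training
        emb = embed(model, dataset)
        half = len(emb) // 2
        rng = np.random.default_rng(0)
        order = rng.permutation(len(emb))
        train, test = order[:half], order[half:]
        clf = LogisticRegression(max_iter=2000).fit(emb[train], dataset.true_class[train])
        correct = int((clf.predict(emb[test]) == dataset.true_class[test]).sum())
        p = stats.binomtest(correct, len(test), 0.5, alternative="greater").pvalue
        assert p < 0.01

    def test_between_class_distance_exceeds_within(self, separable_training):
        dataset, model, _ = separable_training
        emb = embed(model, dataset)
        emb = emb / (np.linalg.norm(emb, axis=1, keepdims=True) + 1e-12)
        c1 = emb[dataset.true_class == 0]
        c2 = emb[dataset.true_class == 1]
        within = 1 - (c1[:50] @ c1[50:100].T).mean()
        between = 1 - (c1[:50] @ c2[:50].T).mean()
        assert between > within


class TestRelabelKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, size=(40, 4))
        b = rng.normal(10.0, 0.01, size=(40, 4))
        emb = np.concatenate([a, b])
        group = relabel_kmeans(emb, seed=0)
        assert len(set(group[:40])) == 1 and len(set(group[40:])) == 1
        assert group[0] != group[-1]

    def test_square_corners_match_min_inertia_partition(self):
        """Brute force over all 2-partitions of 4 points."""
        pts = np.array([[0, 0], [0, 1.2], [5, 0], [5, 1.2]], dtype=float)
        group = relabel_kmeans(pts, seed=0, whiten_components=None)

        def inertia(mask):
            total = 0.0
            for side in (mask, ~mask):
                cluster = pts[side]
                total += ((cluster - cluster.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (
                np.array([i in subset for i in range(4)])
                for subset in itertools.chain.from_iterable(
                    itertools.combinations(range(4), r) for r in (1, 2)
                )
            ),
            key=inertia,
        )
        same_as_best = np.array_equal(group.astype(bool), best) or np.array_equal(
            ~group.astype(bool), best
        )
        assert same_as_best

    def test_two_points_split(self):
        group = relabel_kmeans(np.array([[0.0], [1.0]]), seed=0)
        assert set(group) == {0, 1}

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            relabel_kmeans(np.zeros((1, 3)))


class TestAlignAndCompose:
    def test_perfect_agreement(self):
        group = np.array([0, 0, 1, 1])
        observed = np.array([ObservedLabel.BL] * 2 + [ObservedLabel.AL] * 2)
        result = align_and_compose(group, observed)
        assert result.alignment == {0: 0, 1: 1}
        assert np.array_equal(result.composition, [[2, 0], [0, 2]])
        assert result.intersection_mask.all()

    def test_inverted_clusters_realigned(self):
        group = np.array([1, 1, 0, 0])
        observed = np.array([ObservedLabel.BL] * 2 + [ObservedLabel.AL] * 2)
        result = align_and_compose(group, observed)
        assert result.alignment == {1: 0, 0: 1}
        assert result.intersection_mask.all()

    def test_uninformative_split(self):
        group = np.array([0, 1, 0, 1])
        observed = np.array([ObservedLabel.BL] * 2 + [ObservedLabel.AL] * 2)
        result = align_and_compose(group, observed)
        assert np.array_equal(result.composition, [[1, 1], [1, 1]])
        assert result.intersection_mask.sum() == 2
        assert np.allclose(result.composition_within_group, 0.5)

    def test_partition_conserved(self):
        rng = np.random.default_rng(0)
        group = rng.integers(0, 2, 100)
        observed = rng.integers(0, 2, 100)
        result = align_and_compose(group, observed)
        assert result.composition.sum() == 100
        assert np.bincount(result.group, minlength=2).sum() == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_and_compose(np.zeros(3), np.zeros(4))
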