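"""Dual-head scoring, the combined loss, negative sampling, and training."""

import numpy as np
import pytest

from cgardp import _autodiff as ad
from cgardp.local_encoder import ConvConfig
from cgardp.path_encoder import GruConfig
from cgardp.trainer import (
    TrainConfig,
    combined_loss,
    init_model_params,
    pair_score,
    sample_training_pairs,
    train,
)


@pytest.fixture
def small_params(tiny_net):
    return init_model_params(
        tiny_net.n_drugs,
        tiny_net.n_diseases,
        ConvConfig(n_filters_per_layer=(2,), fc_out_dim=4),
        GruConfig(hidden_dim=3, attention_dim=3),
        np.random.default_rng(0),
    )


class TestPairScore:
    def test_alpha_one_is_cnn_head(self, small_params, rng):
        c, g = rng.random(4), rng.normal(size=6)
        score, score_c, score_g = pair_score(c, g, small_params, alpha1=1.0)
        np.testing.assert_allclose(score, score_c)

    def test_alpha_zero_is_path_head(self, small_params, rng):
        c, g = rng.random(4), rng.normal(size=6)
        score, _, score_g = pair_score(c, g, small_params, alpha1=0.0)
        np.testing.assert_allclose(score, score_g)

    @pytest.mark.parametrize("alpha1", [0.0, 0.3, 0.5, 0.9, 1.0])
    def test_scores_stay_on_simplex(self, small_params, rng, alpha1):
        for _ in range(5):
            score, sc, sg = pair_score(rng.random(4), rng.normal(size=6), small_params, alpha1)
            for s in (score, sc, sg):
                assert s.sum() == pytest.approx(1.0, abs=1e-12)
                assert (s >= 0).all()

    def test_missing_paths_fall_back_to_cnn(self, small_params, rng):
        score, score_c, score_g = pair_score(rng.random(4), None, small_params, alpha1=0.3)
        assert score_g is None
        np.testing.assert_allclose(score, score_c)


class TestCombinedLoss:
    def test_perfect_prediction_zero_loss(self):
        assert combined_loss(np.array([0.0, 1.0]), np.array([0.5, 0.5]), 1, 1.0) == 0.0

    def test_uniform_scores_give_ln2(self):
        half = np.array([0.5, 0.5])
        for y in (0, 1):
            assert combined_loss(half, half, y, 0.5) == pytest.approx(np.log(2))

    def test_nonnegative(self, rng):
        for _ in range(20):
            p = rng.random()
            q = rng.random()
            loss = combined_loss(
                np.array([1 - p, p]), np.array([1 - q, q]), int(rng.random() < 0.5),
                rng.random(),
            )
            assert loss >= 0.0

    def test_tied_heads_equal_single_head(self, rng):
        p = rng.random()
        score = np.array([1 - p, p])
        tied = combined_loss(score, score, 1, 0.5)
        assert tied == pytest.approx(combined_loss(score, None, 1, 1.0))

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.array([0.5, 0.5]), None, 2, 0.5)

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(combined_loss(np.array([1.0, 0.0]), None, 1, 1.0))


class TestSampleTrainingPairs:
    def test_matching_negative_count(self, tiny_net):
        pos = np.argwhere(tiny_net.A == 1)[:10]
        pairs, labels = sample_training_pairs(tiny_net, pos, neg_ratio=1.0, seed=0)
        assert len(pairs) == 20
        assert labels.sum() == 10

    def test_deterministic_given_seed(self, tiny_net):
        pos = np.argwhere(tiny_net.A == 1)
        a = sample_training_pairs(tiny_net, pos, 1.0, seed=42)
        b = sample_training_pairs(tiny_net, pos, 1.0, seed=42)
        np.testing.assert_array_equal(a[0], b[0])

    def test_negatives_are_unknown_pairs(self, tiny_net):
        pos = np.argwhere(tiny_net.A == 1)
        pairs, labels = sample_training_pairs(tiny_net, pos, 1.5, seed=7)
        for (i, j), y in zip(pairs, labels):
            if y == 0:
                assert tiny_net.A[i, j] == 0

    def test_forbidden_pairs_excluded(self, tiny_net):
        pos = np.argwhere(tiny_net.A == 1)
        unknown = np.argwhere(tiny_net.A == 0)
        forbidden = unknown[:30]
        pairs, labels = sample_training_pairs(tiny_net, pos, 1.0, seed=3, forbidden=forbidden)
        forb = {tuple(p) for p in forbidden}
        for (i, j), y in zip(pairs, labels):
            if y == 0:
                assert (i, j) not in forb

    def test_impossible_request_rejected(self, worked_example):
        pos = np.argwhere(worked_example.A == 1)
        with pytest.raises(ValueError):
            sample_training_pairs(worked_example, pos, neg_ratio=100.0, seed=0)


class TestTrain:
    tiny_arch = dict(
        fc_out_dim=4, n_filters=(2,), hidden_dim=3, attention_dim=3,
    )

    def test_zero_epochs_returns_initialized_params(self, tiny_net):
        cfg = TrainConfig(epochs=0, seed=1)
        params = train(tiny_net, cfg, **self.tiny_arch)
        ref = init_model_params(
            tiny_net.n_drugs, tiny_net.n_diseases,
            ConvConfig(n_filters_per_layer=(2,), fc_out_dim=4),
            GruConfig(3, 3), np.random.default_rng(1),
        )
        for (k1, t1), (k2, t2) in zip(
            sorted(params.named_tensors().items()), sorted(ref.named_tensors().items())
        ):
            assert k1 == k2
            np.testing.assert_array_equal(t1.value, t2.value)

    def test_loss_trends_downward(self, tiny_net):
        # full-batch, dropout off: the optimizer itself should descend
        cfg = TrainConfig(
            epochs=50, seed=0, learning_rate=1e-3, dropout_rate=0.0, batch_size=64
        )
        params = train(tiny_net, cfg, **self.tiny_arch)
        hist = params.loss_history
        assert len(hist) == 50
        assert hist[-1] < hist[0]
        increases = sum(b > a for a, b in zip(hist, hist[1:]))
        assert increases <= 0.1 * len(hist)

    def test_identical_seed_identical_final_loss(self, tiny_net):
        cfg = TrainConfig(epochs=5, seed=9)
        a = train(tiny_net, cfg, **self.tiny_arch)
        b = train(tiny_net, cfg, **self.tiny_arch)
        assert a.loss_history[-1] == pytest.approx(b.loss_history[-1], abs=1e-6)
        np.testing.assert_array_equal(a.W_l.value, b.W_l.value)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(alpha1=2.0).validate()
        with pytest.raises(ValueError):
            TrainConfig(dropout_rate=1.0).validate()


def test_dropout_disabled_makes_training_forward_match_inference(tiny_net):
    """With dropout off, the training-time forward equals the scoring pass."""
    from cgardp.estimator import CGARDPClassifier

    pos = np.argwhere(tiny_net.A == 1)
    pairs, labels = sample_training_pairs(tiny_net, pos, 1.0, seed=0)
    clf = CGARDPClassifier(
        epochs=2, dropout_rate=0.0, random_state=0, **TestTrain.tiny_arch
    )
    clf.fit(pairs, labels, network=tiny_net)
    rng = np.random.default_rng(0)
    sc_train, sg_train, wp = clf._forward_batch(
        clf.builder_, clf.params_, pairs[:8], clf.plans_, rng=rng
    )
    sc_eval, sg_eval, wp2 = clf._forward_batch(
        clf.builder_, clf.params_, pairs[:8], clf.plans_, rng=None
    )
    assert wp == wp2
    np.testing.assert_array_equal(sc_train.value, sc_eval.value)
    if sg_train is not None:
        np.testing.assert_array_equal(sg_train.value, sg_eval.value)


def test_checkpoint_round_trip(tmp_path, fitted_tiny):
    from cgardp.trainer import ModelParams

    path = tmp_path / "model.npz"
    fitted_tiny.params_.save(path)
    again = ModelParams.load(path)
    for (k1, t1), (k2, t2) in zip(
        sorted(again.named_tensors().items()),
        sorted(fitted_tiny.params_.named_tensors().items()),
    ):
        assert k1 == k2
        np.testing.assert_array_equal(t1.value, t2.value)
    assert again.input_shape == fitted_tiny.params_.input_shape
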