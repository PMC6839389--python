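"""Network training, prediction and evaluation.

AUC checks use a brute-force pairwise (Mann-Whitney) oracle; training
checks use data whose difficulty is known by construction.
"""

import numpy as np
import pytest

from sonocad.classifier import (
    LabeledDataset,
    NetworkModel,
    TrainingConfig,
    TrainingError,
    evaluate,
    load_model,
    predict,
    save_model,
    train,
)
from sonocad.features import FeatureStats


def gaussian_clusters(n_per_class, d=8, sep=6.0, seed=0):
    """Two well-separated Gaussian blobs -> linearly separable."""
    rng = np.random.default_rng(seed)
    a = rng.normal(loc=0.0, size=(n_per_class, d))
    b = rng.normal(loc=sep / np.sqrt(d), size=(n_per_class, d))
    x = np.vstack([a, b])
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return LabeledDataset.from_labels(x, y, ("neg", "pos"))


def pairwise_auc(y_true, scores):
    """Mann-Whitney statistic normalised: P(score_pos > score_neg) + ties/2."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestTrain:
    def test_separable_clusters_fit(self):
        data = gaussian_clusters(100)
        model = train(data, seed=0)
        p = predict(model, data.features)
        assert (p.argmax(1) == data.labels).mean() >= 0.99

    def test_constant_features_hit_entropy_floor(self):
        x = np.ones((40, 4))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        data = LabeledDataset.from_labels(x, y, ("a", "b"))
        model = train(data, TrainingConfig(regularization=0.0), seed=1)
        p = predict(model, data.features)
        acc = (p.argmax(1) == y).mean()
        assert abs(acc - 0.5) <= 0.15
        ce = -np.log(p[np.arange(40), y]).mean()
        assert ce == pytest.approx(np.log(2), abs=0.05)

    def test_deterministic_given_seed(self):
        data = gaussian_clusters(50)
        m1 = train(data, seed=9)
        m2 = train(data, seed=9)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        assert m1.training_loss == m2.training_loss
        assert m1.validation_loss == m2.validation_loss

    def test_absent_class_named_in_error(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        t = np.zeros((10, 2))
        t[:, 0] = 1.0
        data = LabeledDataset(x, t, ("healthy", "lesion"))
        with pytest.raises(TrainingError, match="lesion"):
            train(data, seed=0)

    def test_gd_fallback_also_fits(self):
        data = gaussian_clusters(100)
        cfg = TrainingConfig(optimizer="gd", learning_rate=0.5, max_epochs=300)
        model = train(data, cfg, seed=0)
        p = predict(model, data.features)
        assert (p.argmax(1) == data.labels).mean() >= 0.95

    def test_scg_training_loss_decreases_overall(self):
        data = gaussian_clusters(100)
        model = train(data, seed=3)
        losses = model.training_loss
        assert losses[-1] < losses[0]


class TestPredict:
    def test_simplex_contract(self, rng):
        data = gaussian_clusters(30)
        model = train(data, seed=0)
        p = predict(model, rng.normal(size=(7, 8)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all() and (p <= 1).all()

    def test_cluster_center_high_posterior(self):
        data = gaussian_clusters(100, sep=6.0)
        model = train(data, seed=0)
        center_pos = data.features[data.labels == 1].mean(axis=0)
        assert predict(model, center_pos)[1] >= 0.95

    def test_zero_weight_model_uniform_posterior(self):
        sizes = (4, 3, 2)
        model = NetworkModel(
            layer_sizes=sizes,
            weights=[np.zeros((4, 3)), np.zeros((3, 2))],
            biases=[np.zeros(3), np.zeros(2)],
            feature_stats=FeatureStats.identity(4),
            class_names=("a", "b"),
        )
        np.testing.assert_allclose(predict(model, np.ones(4)), 0.5)

    def test_dimension_mismatch(self):
        data = gaussian_clusters(20)
        model = train(data, seed=0)
        with pytest.raises(ValueError, match="input_dim"):
            predict(model, np.zeros(5))


class TestEvaluate:
    def test_perfect_predictor(self):
        data = gaussian_clusters(100, sep=10.0)
        model = train(data, seed=0)
        rep = evaluate(model, data)
        assert rep.auc == pytest.approx(1.0, abs=1e-9)
        assert rep.confusion[0, 1] == 0 and rep.confusion[1, 0] == 0
        assert rep.accuracy == 1.0

    def test_auc_equals_pairwise_oracle(self):
        data = gaussian_clusters(40, sep=2.0, seed=5)
        model = train(data, seed=5)
        scores = predict(model, data.features)[:, 1]
        rep = evaluate(model, data)
        assert rep.auc == pytest.approx(
            pairwise_auc(data.labels, scores), abs=1e-10
        )

    def test_hand_built_four_sample_auc(self):
        # labels (1,1,0,0), scores (0.9,0.8,0.3,0.1): all thresholds
        # rank positives above negatives -> AUC 1 by enumeration
        assert pairwise_auc(
            np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.3, 0.1])
        ) == 1.0

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(4)
        n = 400
        x = rng.normal(size=(n, 6))
        y = rng.integers(0, 2, size=n)
        data = LabeledDataset.from_labels(x, y, ("a", "b"))
        model = train(data, TrainingConfig(max_epochs=30), seed=4)
        rep = evaluate(model, data)
        assert abs(rep.auc - 0.5) <= 0.2  # no signal beyond overfit noise

    def test_per_class_percentages_sum(self):
        data = gaussian_clusters(50, sep=3.0)
        model = train(data, seed=2)
        rep = evaluate(model, data)
        for d in rep.per_class.values():
            total = d["tp_pct"] + d["fp_pct"] + d["tn_pct"] + d["fn_pct"]
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_single_class_auc_undefined(self):
        data = gaussian_clusters(20)
        model = train(data, seed=0)
        x = data.features[data.labels == 0]
        t = np.zeros((len(x), 2))
        t[:, 0] = 1.0
        single = LabeledDataset(x, t, ("neg", "pos"))
        with pytest.raises(ValueError, match="single class"):
            evaluate(model, single)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        data = gaussian_clusters(30)
        model = train(data, seed=0)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(
            predict(back, data.features), predict(model, data.features)
        )
        assert back.class_names == model.class_names
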