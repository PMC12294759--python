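"""Masked network: preprocessing, forward contract, training, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from frbinn.hierarchy import MaskStack, build_hierarchy, build_masks
from frbinn.model import (
    CLASSES,
    BinnModel,
    Preprocessor,
    TrainConfig,
    crossval_evaluate,
    evaluate,
    load_model,
    save_model,
    train,
)
from frbinn.synthetic import SyntheticSpec, simulate


class TestPreprocessor:
    def test_log_then_zscale(self):
        x = np.array([[0.0, 1.0], [3.0, 7.0]])
        pre = Preprocessor().fit(x)
        out = pre.transform(x)
        logged = np.log2(x + 1)
        expected = (logged - logged.mean(0)) / logged.std(0)
        np.testing.assert_allclose(out, expected)

    def test_constant_gene_gets_unit_scale(self):
        x = np.array([[5.0, 1.0], [5.0, 3.0]])
        pre = Preprocessor().fit(x)
        assert pre.scale_[0] == 1.0
        assert np.all(pre.transform(x)[:, 0] == 0.0)

    def test_all_zero_matrix_maps_to_zero(self):
        x = np.zeros((3, 2))
        assert np.all(Preprocessor().fit_transform(x) == 0.0)

    def test_negative_input_rejected(self):
        pre = Preprocessor().fit(np.ones((2, 2)))
        with pytest.raises(ValueError, match="non-negative"):
            pre.transform(np.array([[-1.0, 0.0]]))


class TestForward:
    def test_zero_weights_give_uniform_probabilities(self, toy_masks):
        model = BinnModel.initialize(toy_masks, seed=0)
        for w in model.weights:
            w[:] = 0.0
        model.w_out[:] = 0.0
        p = model.predict_proba(np.ones((1, 3)))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_hand_computed_identity_network(self, toy_masks):
        """Two masked matrix products, checked against direct arithmetic."""
        model = BinnModel.initialize(toy_masks, activation="identity", seed=1)
        x = np.array([[0.5, -1.0, 2.0]])
        s0, s1 = toy_masks.arrays()
        h1 = x @ (s0 * model.weights[0]).T + model.biases[0]
        h2 = h1 @ (s1 * model.weights[1]).T + model.biases[1]
        expected = h2 @ model.w_out.T + model.b_out
        np.testing.assert_allclose(model.logits(x), expected, rtol=1e-12)

    def test_masked_weight_perturbation_is_noop(self, toy_masks):
        model = BinnModel.initialize(toy_masks, seed=2)
        x = np.random.default_rng(0).normal(size=(4, 3))
        before = model.logits(x)
        mask = toy_masks.arrays()[0]
        model.weights[0][mask == 0] = 123.0
        np.testing.assert_array_equal(model.logits(x), before)

    def test_all_ones_mask_equals_dense_reference(self):
        h = build_hierarchy({"P1": ["g1", "g2"], "P2": ["g1", "g2"]})
        ms = build_masks(h)
        model = BinnModel.initialize(ms, activation="tanh", seed=3)
        x = np.random.default_rng(1).normal(size=(5, 2))
        # dense reference: plain matrix products with the same weights
        h1 = np.tanh(x @ model.weights[0].T + model.biases[0])
        h2 = np.tanh(h1 @ model.weights[1].T + model.biases[1])
        ref = h2 @ model.w_out.T + model.b_out
        np.testing.assert_allclose(model.logits(x), ref, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, toy_masks):
        model = BinnModel.initialize(toy_masks)
        with pytest.raises(ValueError, match="features"):
            model.logits(np.ones((1, 5)))

    def test_probability_rows_sum_to_one(self, toy_masks):
        model = BinnModel.initialize(toy_masks, seed=4)
        p = model.predict_proba(np.random.default_rng(2).normal(size=(8, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


@pytest.fixture(scope="module")
def separable():
    spec = SyntheticSpec(
        n_genes=12, n_pathways=12, n_superpathways=6, genes_per_pathway=2,
        pathway_overlap=1, samples_per_class=20, planted_per_class=3,
        effect_size=3.0, noise_sd=0.3, seed=42,
    )
    ds = simulate(spec)
    return ds, build_masks(ds.hierarchy)


class TestTrain:
    def test_separable_toy_reaches_perfect_training_f1(self, separable):
        ds, masks = separable
        # independent separability oracle: a linear classifier on the
        # log-transformed matrix must achieve training accuracy 1.0
        logged = np.log2(ds.expression.to_numpy() + 1)
        oracle = LogisticRegression(max_iter=2000).fit(logged, ds.labels)
        assert oracle.score(logged, ds.labels) == 1.0

        model, report = train(
            ds.expression, ds.labels, masks,
            TrainConfig(epochs=200, batch_size=16, seed=0),
        )
        assert evaluate(model, ds.expression, ds.labels)["f1"] == 1.0
        assert report.epoch_losses[-1] < report.epoch_losses[0]

    def test_zero_epochs_returns_initial_model(self, separable):
        ds, masks = separable
        model, report = train(ds.expression, ds.labels, masks, TrainConfig(epochs=0))
        assert report.epoch_losses == []
        assert model.predict_proba(np.zeros((1, 12))).shape == (1, 4)

    def test_same_seed_identical_weights_and_losses(self, separable):
        ds, masks = separable
        cfg = TrainConfig(epochs=5, seed=7)
        m1, r1 = train(ds.expression, ds.labels, masks, cfg)
        m2, r2 = train(ds.expression, ds.labels, masks, cfg)
        assert r1.epoch_losses == r2.epoch_losses
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_single_class_rejected(self, separable):
        ds, masks = separable
        y = pd.Series("normal", index=ds.expression.index)
        with pytest.raises(ValueError, match="two classes"):
            train(ds.expression, y, masks, TrainConfig(epochs=1))

    def test_mask_positions_stay_zero_after_training(self, separable):
        ds, masks = separable
        model, _ = train(ds.expression, ds.labels, masks, TrainConfig(epochs=10))
        for w, s in zip(model.weights, masks.arrays()):
            assert np.all(w[s == 0] == 0.0)


class TestCrossval:
    def test_stratified_folds_and_metrics(self, separable):
        ds, masks = separable
        report = crossval_evaluate(
            ds.expression, ds.labels, masks,
            TrainConfig(epochs=200, batch_size=16, seed=3), k_folds=4,
        )
        assert len(report.fold_metrics) == 4
        # stratification: each fold holds 5 samples of each class (20/4)
        y = ds.labels.to_numpy()
        for fold in range(4):
            held = y[report.fold_assignments == fold]
            counts = pd.Series(held).value_counts()
            assert set(counts) == {5}
        assert 0.0 <= report.pooled_metrics["f1"] <= 1.0
        # the separable cohort should generalize near-perfectly
        assert report.pooled_metrics["f1"] > 0.9

    def test_too_small_class_suggests_smaller_k(self, separable):
        ds, masks = separable
        x = ds.expression.iloc[:63]
        y = ds.labels.iloc[:63]  # last class truncated to 3 < 4 samples
        with pytest.raises(ValueError, match="smaller k"):
            crossval_evaluate(x, y, masks, TrainConfig(epochs=1), k_folds=4)


def test_save_load_round_trip(tmp_path, separable):
    ds, masks = separable
    model, _ = train(ds.expression, ds.labels, masks, TrainConfig(epochs=3, seed=1))
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    x = ds.expression.iloc[:5][model.gene_names].to_numpy()
    xt = model.preprocessor.transform(x)
    np.testing.assert_array_equal(loaded.logits(xt), model.logits(xt))
    assert loaded.classes == CLASSES
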