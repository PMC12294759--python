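"""Integrated Gradients, conductance and Kernel SHAP against independent oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from frbinn.attribution import (
    AttributionConfig,
    attribute_dataset,
    conductance,
    integrated_gradients,
    kernel_shap,
)
from frbinn.hierarchy import MaskStack
from frbinn.model import BinnModel, Preprocessor, TrainConfig

from conftest import make_linear_model


def riemann_oracle(model, x, target, steps=100_000, baseline=None):
    """High-resolution right-endpoint path integral, chunked."""
    x = np.asarray(x, float).ravel()
    baseline = np.zeros_like(x) if baseline is None else baseline
    delta = x - baseline
    acc = np.zeros_like(x)
    for start in range(0, steps, 5000):
        t = (np.arange(start, min(start + 5000, steps)) + 1) / steps
        points = baseline + t[:, None] * delta
        _, grads = model.output_scalar_and_input_grad(points, target)
        acc += grads.sum(axis=0)
    return delta * acc / steps


def brute_force_shapley(f, x, background):
    """Average marginal contribution over all orderings (exact definition)."""
    n = len(x)
    phi = np.zeros(n)
    for order in permutations(range(n)):
        current = np.array(background, float)
        prev = f(current)
        for i in order:
            current[i] = x[i]
            now = f(current)
            phi[i] += now - prev
            prev = now
    import math

    return phi / math.factorial(n)


class TestIntegratedGradients:
    @pytest.mark.parametrize("m", [1, 3, 800])
    @pytest.mark.parametrize("scheme", ["riemann-right", "gauss-legendre"])
    def test_exact_on_linear_model(self, linear_model, m, scheme):
        cfg = AttributionConfig(m_ig=m, scheme=scheme)
        ig = integrated_gradients(linear_model, np.array([1.0, 1.0]), 0, cfg)
        np.testing.assert_allclose(ig, [3.0, 2.0], rtol=1e-12)

    def test_zero_at_baseline(self, linear_model):
        cfg = AttributionConfig(baseline=np.array([0.3, -0.2]))
        ig = integrated_gradients(linear_model, np.array([0.3, -0.2]), 0, cfg)
        np.testing.assert_array_equal(ig, 0.0)

    def test_matches_high_resolution_oracle_on_trained_net(self, small_trained):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[7]
        cfg = AttributionConfig(m_ig=800, scheme="riemann-right")
        ig = integrated_gradients(model, xt, 1, cfg)
        oracle = riemann_oracle(model, xt, 1)
        assert np.max(np.abs(ig - oracle)) <= 1e-3

    def test_completeness_on_trained_net(self, small_trained):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[3]
        ig = integrated_gradients(model, xt, 2, AttributionConfig(m_ig=800))
        f = lambda v: model.logits(v[None, :])[0, 2]
        span = f(xt) - f(np.zeros_like(xt))
        assert abs(ig.sum() - span) <= 1e-3 * max(1.0, abs(span))

    def test_schemes_agree_at_large_m(self, small_trained):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[0]
        a = integrated_gradients(model, xt, 0, AttributionConfig(m_ig=800, scheme="riemann-right"))
        b = integrated_gradients(model, xt, 0, AttributionConfig(m_ig=800, scheme="gauss-legendre"))
        np.testing.assert_allclose(a, b, atol=5e-3)

    def test_zero_weight_gene_gets_zero_score(self, linear_model):
        # the second output row is all-zero: no path from any gene
        ig = integrated_gradients(linear_model, np.array([1.0, 2.0]), 1)
        np.testing.assert_array_equal(ig, 0.0)


class TestConductance:
    def test_single_path_chain_equals_output_span(self):
        """x -> y -> F with weights w1, w2: Cond_y = w2 w1 x = F(x) - F(0)."""
        w1, w2, xval = 1.7, -0.6, 2.0
        genes = ["g0"]
        mask = pd.DataFrame([[1]], index=["y"], columns=genes)
        model = BinnModel(
            mask_stack=MaskStack(masks=(mask,)),
            weights=[np.array([[w1]])],
            biases=[np.zeros(1)],
            w_out=np.array([[w2], [0.0]]),
            b_out=np.zeros(2),
            activation="identity",
            preprocessor=Preprocessor(mean_=np.zeros(1), scale_=np.ones(1)),
            config=TrainConfig(),
        )
        prof = conductance(model, np.array([xval]), layer=1, target=0)
        np.testing.assert_allclose(prof.values.to_numpy(), [w2 * w1 * xval], rtol=1e-12)

    @pytest.mark.parametrize("layer", [1, 2])
    def test_layer_completeness_on_trained_net(self, small_trained, layer):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[11]
        prof = conductance(model, xt, layer, 1, AttributionConfig(m_con=800))
        f = lambda v: model.logits(v[None, :])[0, 1]
        span = f(xt) - f(np.zeros_like(xt))
        assert abs(prof.values.sum() - span) <= 1e-3 * max(1.0, abs(span))

    def test_dead_neuron_zero_conductance(self, toy_masks):
        model = BinnModel.initialize(toy_masks, activation="identity", seed=0)
        model.weights[0][0, :] = 0.0  # neuron P1 receives nothing
        prof = conductance(model, np.array([1.0, 2.0, 3.0]), 1, 0)
        assert prof.values["P1"] == 0.0

    def test_output_layer_request_rejected(self, small_trained):
        model, dataset, _ = small_trained
        with pytest.raises(ValueError, match="hidden layer"):
            conductance(model, np.zeros(len(model.gene_names)), model.n_hidden_layers + 1, 0)

    def test_set_aggregation_is_exact_sum(self, small_trained):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[2]
        prof = conductance(model, xt, 1, 0, AttributionConfig(m_con=50))
        names = list(prof.values.index)
        agg = prof.aggregate({"first_two": names[:2], "rest": names[2:]})
        assert agg["first_two"] == pytest.approx(prof.values[names[:2]].sum(), abs=0)
        assert agg.sum() == pytest.approx(prof.values.sum())


class TestKernelShap:
    def test_linear_model_closed_form_under_enumeration(self):
        model = make_linear_model([3.0, 2.0, -1.0])
        x = np.array([1.0, 0.5, 2.0])
        bg = np.array([0.2, 0.0, -0.5])
        cfg = AttributionConfig(background=bg, shap_enumerate="always")
        phi = kernel_shap(model, x, 0, cfg)
        np.testing.assert_allclose(phi, np.array([3.0, 2.0, -1.0]) * (x - bg), atol=1e-9)

    def test_interaction_model_matches_brute_force(self, small_trained):
        """3-feature slice of a trained nonlinear net vs the permutation oracle."""
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[5]
        frozen = xt.copy()
        free = [0, 1, 2]

        def f3(v3):
            full = frozen.copy()
            full[free] = v3
            return model.logits(full[None, :])[0, 0]

        x3 = xt[free]
        bg3 = np.zeros(3)

        def f_full(vec):
            full = frozen.copy()
            full[free] = vec
            return model.logits(full[None, :])[0, 0]

        oracle = brute_force_shapley(f_full, x3, bg3)

        # restrict the model's view: features beyond the three are fixed at x
        class Slice:
            def logits(self, pts):
                full = np.tile(frozen, (pts.shape[0], 1))
                full[:, free] = pts
                return model.logits(full)

            def predict_proba(self, pts):
                raise NotImplementedError

        phi = kernel_shap(Slice(), x3, 0, AttributionConfig(background=bg3, shap_enumerate="always"))
        np.testing.assert_allclose(phi, oracle, atol=1e-6)

    def test_exchangeable_features_get_equal_scores(self):
        model = make_linear_model([2.0, 2.0, 5.0])
        phi = kernel_shap(
            model, np.array([1.0, 1.0, 0.0]), 0,
            AttributionConfig(shap_enumerate="always"),
        )
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)

    @pytest.mark.parametrize("enumerate_mode", ["always", "never"])
    def test_efficiency_constraint_always_holds(self, small_trained, enumerate_mode):
        model, dataset, _ = small_trained
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )[9]
        cfg = AttributionConfig(m_shapley=300, shap_enumerate=enumerate_mode, seed=4)
        phi = kernel_shap(model, xt, 3, cfg)
        f = lambda v: model.logits(v[None, :])[0, 3]
        np.testing.assert_allclose(phi.sum(), f(xt) - f(np.zeros_like(xt)), atol=1e-8)


class TestAttributeDataset:
    def test_filters_misclassified_and_matches_single_calls(self, small_trained):
        model, dataset, _ = small_trained
        res = attribute_dataset(
            model, dataset.expression, dataset.labels, "IG",
            AttributionConfig(m_ig=50),
        )
        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )
        pred = model.predict(xt)
        truth = dataset.labels.map(
            {"cancer": 0, "CP-CID": 1, "NCP-CID": 2, "normal": 3}
        ).to_numpy()
        correct_ids = dataset.expression.index[pred == truth]
        assert list(res.scores.index) == list(correct_ids)
        # batching equivalence: row equals a direct single-sample call
        sid = res.scores.index[0]
        pos = dataset.expression.index.get_loc(sid)
        single = integrated_gradients(
            model, xt[pos], int(truth[pos]), AttributionConfig(m_ig=50)
        )
        np.testing.assert_allclose(res.scores.loc[sid].to_numpy(), single)

    def test_class_restriction(self, small_trained):
        model, dataset, _ = small_trained
        res = attribute_dataset(
            model, dataset.expression, dataset.labels, "IG",
            AttributionConfig(m_ig=20), target_class="CP-CID",
        )
        assert set(dataset.labels.loc[res.scores.index]) == {"CP-CID"}

    def test_no_correct_samples_is_error(self, small_trained):
        model, dataset, _ = small_trained
        from frbinn.model import CLASSES

        xt = model.preprocessor.transform(
            dataset.expression[model.gene_names].to_numpy()
        )
        pred = model.predict(xt)
        # labels guaranteed to disagree with every prediction
        wrong = pd.Series(
            [CLASSES[(p + 1) % 4] for p in pred], index=dataset.expression.index
        )
        with pytest.raises(ValueError, match="no correctly predicted"):
            attribute_dataset(model, dataset.expression, wrong, "IG", AttributionConfig(m_ig=5))

    def test_conductance_dataset_scores_pathways(self, small_trained):
        model, dataset, _ = small_trained
        res = attribute_dataset(
            model, dataset.expression, dataset.labels, "conductance",
            AttributionConfig(m_con=50), target_class="cancer",
        )
        assert list(res.scores.columns) == model.hidden_layer_names(1)
        assert res.entity_layer == "hidden-1"
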