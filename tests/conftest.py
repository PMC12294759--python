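"""Shared fixtures: toy hierarchies, hand-built models, small trained nets."""

import numpy as np
import pandas as pd
import pytest

from frbinn.hierarchy import MaskStack, build_hierarchy, build_masks
from frbinn.model import BinnModel, Preprocessor, TrainConfig, train
from frbinn.synthetic import SyntheticSpec, simulate


@pytest.fixture
def toy_hierarchy():
    """3 genes, 2 overlapping pathways, 1 superpathway."""
    return build_hierarchy(
        {"P1": ["g1", "g2"], "P2": ["g2", "g3"]},
        [("P1", "SP1"), ("P2", "SP1")],
    )


@pytest.fixture
def toy_masks(toy_hierarchy):
    return build_masks(toy_hierarchy)


def make_linear_model(weights_per_feature, n_classes: int = 2) -> BinnModel:
    """A network computing logit_0(x) = w · x exactly.

    Identity activation, one all-ones gene→pathway layer wide enough to pass
    each feature through its own neuron, identity-like output head.
    """
    w = np.asarray(weights_per_feature, dtype=float)
    n = w.size
    genes = [f"g{i}" for i in range(n)]
    units = [f"u{i}" for i in range(n)]
    mask = pd.DataFrame(np.eye(n, dtype=np.int8), index=units, columns=genes)
    ms = MaskStack(masks=(mask,))
    model = BinnModel(
        mask_stack=ms,
        weights=[np.eye(n)],
        biases=[np.zeros(n)],
        w_out=np.vstack([w, np.zeros((n_classes - 1, n))]),
        b_out=np.zeros(n_classes),
        activation="identity",
        preprocessor=Preprocessor(mean_=np.zeros(n), scale_=np.ones(n)),
        config=TrainConfig(),
    )
    return model


@pytest.fixture
def linear_model():
    """F_0(x) = 3 x1 + 2 x2."""
    return make_linear_model([3.0, 2.0])


@pytest.fixture(scope="session")
def small_trained():
    """A nonlinear toy net trained on a small separable cohort.

    12 genes / 4 pathways / 2 superpathways, 25 samples per class, tanh
    hidden units so gradients are smooth for quadrature comparisons.
    """
    spec = SyntheticSpec(
        n_genes=12,
        n_pathways=4,
        n_superpathways=2,
        genes_per_pathway=3,
        samples_per_class=25,
        planted_per_class=3,
        effect_size=2.0,
        noise_sd=0.5,
        seed=11,
    )
    dataset = simulate(spec)
    masks = build_masks(dataset.hierarchy)
    model, report = train(
        dataset.expression,
        dataset.labels,
        masks,
        TrainConfig(epochs=150, batch_size=16, activation="tanh", seed=5),
    )
    return model, dataset, report
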