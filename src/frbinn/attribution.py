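"""Feature and neuron attribution for the masked classifier.

Three methods, all explaining the same scalar — a chosen class's
pre-softmax logit (probability via a flag):

* **Integrated Gradients** — the path integral of the input gradient from a
  baseline ``x'`` (zero by default) to the input, approximated either by the
  right-endpoint Riemann sum ``IG_i = (x_i − x'_i) Σ_k ∂F(x' + k/m (x−x'))/∂x_i
  · 1/m`` or by Gauss–Legendre quadrature on the same path.  Satisfies
  completeness: attributions sum to ``F(x) − F(x')``.
* **Conductance** — IG pushed onto hidden neurons: the part of the
  input-to-output attribution flowing through neuron ``y``,
  ``Cond_y = Σ_i (x_i − x'_i) ∫ ∂F/∂y · ∂y/∂x_i dα``, computed per step as
  the product of the output-side gradient ``∂F/∂y`` and the input-side
  directional derivative of ``y`` along ``x − x'``.  Summing over one hidden
  layer recovers ``F(x) − F(x')``; summing over a named neuron set (a
  pathway group) gives that set's conductance.
* **Kernel SHAP** — Shapley values approximated by Shapley-kernel-weighted
  linear regression over feature coalitions, with off-coalition features
  pinned to a background vector and the efficiency constraint
  ``Σ φ_i = F(x) − F(background)`` enforced exactly.  Small problems are
  solved over all coalitions, which yields the exact Shapley values.

Attributions are computed in the model's input space, i.e. after the
log/z-scale preprocessing; the zero baseline is therefore the training-set
mean expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .model import CLASSES, BinnModel, encode_labels, validate_expression

METHODS = ("IG", "SV", "conductance")


@dataclass
class AttributionConfig:
    """Shared knobs for the three attribution methods.

    ``m_ig``, ``m_con`` and ``m_shapley`` are the paths-integral step counts
    and the surrogate-model query budget; all default to 800.  ``baseline``
    (IG/conductance) and ``background`` (SHAP) default to the zero vector in
    preprocessed space.  ``scheme`` selects the integral approximation.
    """

    baseline: np.ndarray | None = None
    background: np.ndarray | None = None
    m_ig: int = 800
    m_con: int = 800
    m_shapley: int = 800
    scheme: str = "gauss-legendre"
    use_probability: bool = False
    shap_enumerate: str = "auto"  # "auto" | "always" | "never"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m_ig, self.m_con, self.m_shapley) < 1:
            raise ValueError("step counts m_* must be >= 1")
        if self.scheme not in ("riemann-right", "gauss-legendre"):
            raise ValueError(f"unknown integration scheme {self.scheme!r}")
        if self.shap_enumerate not in ("auto", "always", "never"):
            raise ValueError("shap_enumerate must be auto, always or never")


@dataclass
class AttributionResult:
    """Per-sample signed attribution scores for one method.

    ``scores`` is samples × entities (genes for IG/SV, hidden-layer neurons
    for conductance); ``targets`` records the class index each row was
    attributed against.
    """

    method: str
    scores: pd.DataFrame
    targets: pd.Series
    entity_layer: str = "gene"
    target_class: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("attribution scores contain non-finite values")


@dataclass
class ConductanceProfile:
    """Total conductance per hidden neuron, with exact set aggregation."""

    layer: int
    values: pd.Series  # index = neuron names

    def aggregate(self, sets: dict[str, list[str]]) -> pd.Series:
        """Sum member-neuron conductances for each named neuron set."""
        out = {}
        for name, members in sets.items():
            missing = set(members) - set(self.values.index)
            if missing:
                raise KeyError(f"set {name!r} references unknown neurons {sorted(missing)}")
            out[name] = float(self.values[members].sum())
        return pd.Series(out)


def _path(scheme: str, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for ∫₀¹ g(α) dα."""
    if scheme == "riemann-right":
        t = np.arange(1, m + 1) / m
        w = np.full(m, 1.0 / m)
    else:
        nodes, weights = np.polynomial.legendre.leggauss(m)
        t = (nodes + 1.0) / 2.0
        w = weights / 2.0
    return t, w


def _resolve_vec(vec, n, name):
    if vec is None:
        return np.zeros(n)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {vec.shape}")
    return vec


def integrated_gradients(
    model: BinnModel,
    x: np.ndarray,
    target: int,
    config: AttributionConfig | None = None,
) -> np.ndarray:
    """Integrated Gradients of the target logit for one preprocessed sample.

    Exact on linear models for any ``m_ig``; at the input equal to the
    baseline the result is all-zero by construction.
    """
    config = config or AttributionConfig()
    x = np.asarray(x, dtype=float).ravel()
    baseline = _resolve_vec(config.baseline, x.size, "baseline")
    delta = x - baseline
    if not np.any(delta):
        return np.zeros_like(x)
    t, w = _path(config.scheme, config.m_ig)
    points = baseline + t[:, None] * delta
    _, grads = model.output_scalar_and_input_grad(
        points, target, use_probability=config.use_probability
    )
    return delta * (w @ grads)


def conductance(
    model: BinnModel,
    x: np.ndarray,
    layer: int,
    target: int,
    config: AttributionConfig | None = None,
) -> ConductanceProfile:
    """Total conductance of every neuron in a hidden layer (1 = pathways).

    Each quadrature step multiplies the output-side gradient ``∂F/∂y`` by the
    input-side directional derivative of ``y`` along ``x − x'``; the weighted
    sum over steps approximates the path integral.  Requesting the output
    layer is an error — conductance is defined for hidden neurons.
    """
    config = config or AttributionConfig()
    x = np.asarray(x, dtype=float).ravel()
    baseline = _resolve_vec(config.baseline, x.size, "baseline")
    delta = x - baseline
    names = model.hidden_layer_names(layer)
    t, w = _path(config.scheme, config.m_con)
    points = baseline + t[:, None] * delta
    g, jvp = model.hidden_grad_and_jvp(points, delta, layer, target)
    values = w @ (g * jvp)
    return ConductanceProfile(layer=layer, values=pd.Series(values, index=names))


# ---------------------------------------------------------------------------
# Kernel SHAP


def _shapley_kernel_weights(n: int, sizes: np.ndarray) -> np.ndarray:
    return np.array([(n - 1) / (comb(n, s) * s * (n - s)) for s in sizes])


def _enumerate_coalitions(n: int) -> np.ndarray:
    rows = []
    for size in range(1, n):
        for subset in combinations(range(n), size):
            z = np.zeros(n)
            z[list(subset)] = 1.0
            rows.append(z)
    return np.array(rows)


def _sample_coalitions(n: int, budget: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.arange(1, n)
    p = (n - 1) / (sizes * (n - sizes))
    p = p / p.sum()
    rows = []
    while len(rows) < budget:
        s = int(rng.choice(sizes, p=p))
        members = rng.choice(n, size=s, replace=False)
        z = np.zeros(n)
        z[members] = 1.0
        rows.append(z)
        if len(rows) < budget:
            rows.append(1.0 - z)  # paired complement
    return np.array(rows[:budget])


def kernel_shap(
    model: BinnModel,
    x: np.ndarray,
    target: int,
    config: AttributionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shapley-value attribution of the target logit by weighted regression.

    Coalition members take their value from ``x``; the rest are pinned to the
    background vector.  The efficiency constraint — scores summing exactly to
    ``F(x) − F(background)`` — is imposed by eliminating one feature from the
    least-squares system.  When ``2^n − 2`` coalitions fit within
    ``m_shapley`` (and enumeration is not disabled) all coalitions are used
    with exact Shapley-kernel weights, which recovers the exact Shapley
    values; otherwise coalitions are drawn in complementary pairs with sizes
    following the kernel-weight distribution.
    """
    config = config or AttributionConfig()
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    background = _resolve_vec(config.background, n, "background")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5AAB]))

    def f(points: np.ndarray) -> np.ndarray:
        if config.use_probability:
            return model.predict_proba(points)[:, target]
        return model.logits(points)[:, target]

    fx = float(f(x[None, :])[0])
    f0 = float(f(background[None, :])[0])
    if n == 1:
        return np.array([fx - f0])

    full = 2 ** n - 2 if n <= 30 else np.inf
    enumerate_all = config.shap_enumerate == "always" or (
        config.shap_enumerate == "auto" and full <= max(config.m_shapley, 2)
    )
    if enumerate_all:
        z = _enumerate_coalitions(n)
        w = _shapley_kernel_weights(n, z.sum(axis=1).astype(int))
    else:
        z = _sample_coalitions(n, config.m_shapley, rng)
        w = np.ones(z.shape[0])

    if np.all(z == z[0], axis=None):
        raise ValueError("degenerate coalition design: all sampled coalitions identical")

    points = z * x + (1.0 - z) * background
    fz = f(points)

    # eliminate the last feature to enforce efficiency exactly
    span = fx - f0
    design = z[:, :-1] - z[:, [-1]]
    response = fz - f0 - z[:, -1] * span
    sw = np.sqrt(w)
    phi_head, *_ = np.linalg.lstsq(design * sw[:, None], response * sw, rcond=None)
    phi = np.empty(n)
    phi[:-1] = phi_head
    phi[-1] = span - phi_head.sum()
    return phi


# ---------------------------------------------------------------------------
# Dataset-level attribution


def attribute_dataset(
    model: BinnModel,
    x: pd.DataFrame,
    y: pd.Series,
    method: str,
    config: AttributionConfig | None = None,
    target_class: str | None = None,
    conductance_layer: int = 1,
) -> AttributionResult:
    """Attribute every correctly predicted sample against its true class.

    Samples whose argmax prediction disagrees with the label are dropped;
    with ``target_class`` the retained set is further restricted to that
    class.  ``method`` is ``"IG"``, ``"SV"`` or ``"conductance"`` (the latter
    scores hidden-layer neurons, pathways by default).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    config = config or AttributionConfig()
    validate_expression(x)
    truth = encode_labels(y)
    xt = model.preprocessor.transform(x[model.gene_names].to_numpy(dtype=float))
    pred = model.predict(xt)
    keep = pred == truth
    if target_class is not None:
        if target_class not in CLASSES:
            raise ValueError(f"unknown class {target_class!r}")
        keep &= truth == CLASSES.index(target_class)
    if not keep.any():
        raise ValueError("no correctly predicted samples to attribute")

    idx = np.flatnonzero(keep)
    sample_ids = x.index[idx]
    if method == "conductance":
        entity_names = model.hidden_layer_names(conductance_layer)
        entity_layer = f"hidden-{conductance_layer}"
    else:
        entity_names = model.gene_names
        entity_layer = "gene"

    rows = np.empty((len(idx), len(entity_names)))
    for row, i in enumerate(idx):
        tgt = int(truth[i])
        if method == "IG":
            rows[row] = integrated_gradients(model, xt[i], tgt, config)
        elif method == "SV":
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x5AAB, int(i)])
            )
            rows[row] = kernel_shap(model, xt[i], tgt, config, rng=rng)
        else:
            rows[row] = conductance(
                model, xt[i], conductance_layer, tgt, config
            ).values.to_numpy()

    return AttributionResult(
        method=method,
        scores=pd.DataFrame(rows, index=sample_ids, columns=entity_names),
        targets=pd.Series(truth[idx], index=sample_ids),
        entity_layer=entity_layer,
        target_class=target_class,
    )
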