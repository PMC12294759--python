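"""Masked sparse neural classifier over a pathway hierarchy.

The network is an MLP whose hidden connectivity is restricted by binary
masks: layer ``l`` computes ``h^{l+1} = f((S^l ⊙ W^l) h^l + b^l)`` where
``S^l`` is the 0/1 mask from the pathway hierarchy, so a weight can only be
learned where the prior says a relation exists.  The output head is dense
followed by softmax over the four cohort classes.  Training minimises mean
cross-entropy with Adam.

Everything is plain NumPy: the forward pass caches activations, and the
module provides reverse-mode gradients (for training and for input/hidden
attributions) and forward-mode directional derivatives (for conductance).
All randomness flows through explicitly passed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .hierarchy import MaskStack

CLASSES = ("cancer", "CP-CID", "NCP-CID", "normal")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def validate_expression(x: pd.DataFrame) -> pd.DataFrame:
    """Check a samples × genes expression frame: non-negative, unique ids."""
    if x.index.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    if x.columns.has_duplicates:
        raise ValueError("duplicate gene identifiers")
    values = x.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative (TPM-like)")
    return x


def encode_labels(y: pd.Series) -> np.ndarray:
    """Map class strings to fixed indices (cancer=0, CP-CID=1, NCP-CID=2, normal=3)."""
    unknown = set(y.unique()) - set(CLASSES)
    if unknown:
        raise ValueError(
            f"unknown class labels {sorted(unknown)}; allowed: {list(CLASSES)}"
        )
    return y.map(CLASS_INDEX).to_numpy(dtype=int)


@dataclass
class Preprocessor:
    """log2(v+1) then per-gene z-scaling with training-fold statistics.

    A gene constant across the training fold gets unit scale so held-out
    samples stay finite.
    """

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Preprocessor":
        logged = np.log2(x + 1.0)
        self.mean_ = logged.mean(axis=0)
        sd = logged.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Preprocessor not fitted")
        if (x < 0).any():
            raise ValueError("expression values must be non-negative")
        return (np.log2(x + 1.0) - self.mean_) / self.scale_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: 500 epochs, batch 32, lr 1e-3)."""

    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainReport:
    epoch_losses: list[float]
    seed: int
    fold_metrics: list[dict] = field(default_factory=list)
    fold_assignments: np.ndarray | None = None
    pooled_metrics: dict | None = None


@dataclass
class BinnModel:
    """The trained masked classifier.

    ``weights[l]`` has the same shape as ``mask_stack.masks[l]`` (out × in);
    the effective weight at any time is ``mask * weight``, applied in every
    forward pass, so masked positions can never influence the output.
    """

    mask_stack: MaskStack
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    w_out: np.ndarray
    b_out: np.ndarray
    activation: str
    preprocessor: Preprocessor
    config: TrainConfig
    classes: tuple[str, ...] = CLASSES

    # -- construction ---------------------------------------------------

    @classmethod
    def initialize(
        cls,
        mask_stack: MaskStack,
        n_classes: int = len(CLASSES),
        activation: str = "relu",
        seed: int = 0,
        config: TrainConfig | None = None,
    ) -> "BinnModel":
        """Glorot-uniform init on unmasked entries, zero elsewhere."""
        rng = np.random.default_rng(seed)
        masks = mask_stack.arrays()
        # narrow ReLU layers can start entirely dead with zero biases; a
        # small positive bias keeps every hidden unit initially active
        bias0 = 0.01 if activation == "relu" else 0.0
        weights, biases = [], []
        for s in masks:
            n_out, n_in = s.shape
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=s.shape) * s
            weights.append(w)
            biases.append(np.full(n_out, bias0))
        n_last = masks[-1].shape[0]
        limit = np.sqrt(6.0 / (n_last + n_classes))
        w_out = rng.uniform(-limit, limit, size=(n_classes, n_last))
        return cls(
            mask_stack=mask_stack,
            weights=weights,
            biases=biases,
            w_out=w_out,
            b_out=np.zeros(n_classes),
            activation=activation,
            preprocessor=Preprocessor(),
            config=config or TrainConfig(activation=activation, seed=seed),
        )

    # -- forward / autodiff ---------------------------------------------

    @property
    def gene_names(self) -> list[str]:
        return self.mask_stack.gene_names

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights)

    def hidden_layer_names(self, layer: int) -> list[str]:
        """Entity names of hidden layer ``layer`` (1-based: 1 = pathways)."""
        if not 1 <= layer <= self.n_hidden_layers:
            raise ValueError(f"hidden layer index must be in [1, {self.n_hidden_layers}]")
        return list(self.mask_stack.masks[layer - 1].index)

    def _effective(self) -> list[np.ndarray]:
        return [s * w for s, w in zip(self.mask_stack.arrays(), self.weights)]

    def _forward_cache(self, x: np.ndarray):
        """Forward pass on preprocessed input, caching pre-activations."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.gene_names):
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {len(self.gene_names)}"
            )
        f, _ = _ACTIVATIONS[self.activation]
        hs, zs = [x], []
        h = x
        for w_eff, b in zip(self._effective(), self.biases):
            z = h @ w_eff.T + b
            h = f(z)
            zs.append(z)
            hs.append(h)
        logits = h @ self.w_out.T + self.b_out
        return hs, zs, logits

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward_cache(x)[2]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        # np.argmax takes the lowest index on ties
        return np.argmax(self.logits(x), axis=1)

    def output_scalar_and_input_grad(
        self, x: np.ndarray, target: int, use_probability: bool = False
    ):
        """Target-class output and its gradient w.r.t. every input row.

        ``target`` is a class index; the scalar is its pre-softmax logit by
        default (softmax probability with ``use_probability``).  Reverse-mode
        through the cached forward pass.
        """
        hs, zs, logits = self._forward_cache(x)
        _, fprime = _ACTIVATIONS[self.activation]
        if use_probability:
            p = _softmax(logits)
            value = p[:, target]
            # d p_t / d logits = p_t * (e_t - p)
            dlogits = p[:, [target]] * (np.eye(logits.shape[1])[target] - p)
        else:
            value = logits[:, target]
            dlogits = np.zeros_like(logits)
            dlogits[:, target] = 1.0
        dh = dlogits @ self.w_out
        for w_eff, z in zip(reversed(self._effective()), reversed(zs)):
            dz = dh * fprime(z)
            dh = dz @ w_eff
        return value, dh

    def hidden_grad_and_jvp(self, x: np.ndarray, tangent: np.ndarray, layer: int, target: int):
        """For conductance: ∂F/∂h^layer and the directional derivative J·v.

        Returns ``(g, t)`` where ``g[i, y] = ∂ logit_target / ∂ h^layer_y``
        (reverse-mode from the output down to the chosen hidden layer) and
        ``t[i, y] = Σ_j ∂ h^layer_y / ∂ x_j · tangent[i, j]`` (forward-mode
        from the input up), both evaluated at input rows ``x``.
        """
        if not 1 <= layer <= self.n_hidden_layers:
            raise ValueError(
                f"conductance is defined for hidden layers 1..{self.n_hidden_layers}"
            )
        hs, zs, logits = self._forward_cache(x)
        _, fprime = _ACTIVATIONS[self.activation]
        effective = self._effective()

        # forward-mode tangent up to `layer`
        t = np.atleast_2d(np.asarray(tangent, dtype=float))
        t = np.broadcast_to(t, hs[0].shape).copy()
        for l in range(layer):
            t = (t @ effective[l].T) * fprime(zs[l])

        # reverse-mode from output down to `layer`
        dlogits = np.zeros_like(logits)
        dlogits[:, target] = 1.0
        dh = dlogits @ self.w_out
        for l in range(self.n_hidden_layers - 1, layer - 1, -1):
            dz = dh * fprime(zs[l])
            dh = dz @ effective[l]
        return dh, t

    # -- training -------------------------------------------------------

    def _loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray):
        hs, zs, logits = self._forward_cache(x)
        _, fprime = _ACTIVATIONS[self.activation]
        p = _softmax(logits)
        n = x.shape[0]
        loss = -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n
        dlogits = (p - y_onehot) / n
        g_wout = dlogits.T @ hs[-1]
        g_bout = dlogits.sum(axis=0)
        dh = dlogits @ self.w_out
        g_w, g_b = [], []
        masks = self.mask_stack.arrays()
        effective = self._effective()
        for l in range(self.n_hidden_layers - 1, -1, -1):
            dz = dh * fprime(zs[l])
            g_w.append((dz.T @ hs[l]) * masks[l])  # masked positions stay frozen
            g_b.append(dz.sum(axis=0))
            dh = dz @ effective[l]
        return loss, list(reversed(g_w)), list(reversed(g_b)), g_wout, g_bout


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    """Adam over a flat list of parameter arrays."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    x: pd.DataFrame,
    y: pd.Series,
    mask_stack: MaskStack,
    config: TrainConfig | None = None,
) -> tuple[BinnModel, TrainReport]:
    """Fit the masked classifier with Adam on mean cross-entropy.

    ``x`` is raw (TPM-like) samples × genes; it is aligned to the mask's gene
    order, log2(v+1)-transformed and z-scaled with statistics fitted here and
    stored on the model for reuse on held-out data.  Fully deterministic
    given ``config.seed``.
    """
    config = config or TrainConfig()
    validate_expression(x)
    y_idx = encode_labels(y)
    if len(y_idx) != x.shape[0]:
        raise ValueError("label vector length does not match sample count")
    if np.unique(y_idx).size < 2:
        raise ValueError("training requires at least two classes present")

    genes = mask_stack.gene_names
    missing = set(genes) - set(x.columns)
    if missing:
        raise ValueError(f"expression matrix lacks {len(missing)} mask genes, e.g. {sorted(missing)[:3]}")
    x_aligned = x[genes].to_numpy(dtype=float)

    model = BinnModel.initialize(
        mask_stack, activation=config.activation, seed=config.seed, config=config
    )
    xt = model.preprocessor.fit_transform(x_aligned)
    y_onehot = np.eye(len(CLASSES))[y_idx]

    params = model.weights + model.biases + [model.w_out, model.b_out]
    opt = _Adam([p.shape for p in params], lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5AD]))

    n = xt.shape[0]
    losses: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, g_w, g_b, g_wout, g_bout = model._loss_and_grads(
                xt[idx], y_onehot[idx]
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "lower the learning rate or check the input scale"
                )
            opt.step(params, g_w + g_b + [g_wout, g_bout])
            batch_losses.append(loss)
        losses.append(float(np.mean(batch_losses)))

    return model, TrainReport(epoch_losses=losses, seed=config.seed)


def evaluate(model: BinnModel, x: pd.DataFrame, y: pd.Series) -> dict:
    """Weighted precision / recall / F1 of ``model`` on raw expression."""
    xt = model.preprocessor.transform(x[model.gene_names].to_numpy(dtype=float))
    pred = model.predict(xt)
    truth = encode_labels(y)
    p, r, f1, _ = precision_recall_fscore_support(
        truth, pred, average="weighted", zero_division=0
    )
    return {"precision": float(p), "recall": float(r), "f1": float(f1)}


def crossval_evaluate(
    x: pd.DataFrame,
    y: pd.Series,
    mask_stack: MaskStack,
    config: TrainConfig | None = None,
    k_folds: int = 5,
) -> TrainReport:
    """Stratified k-fold cross-validation with weighted P/R/F1.

    Folds preserve per-class proportions.  Metrics are reported per fold and
    pooled over all held-out predictions.
    """
    config = config or TrainConfig()
    y_idx = encode_labels(y)
    counts = np.bincount(y_idx, minlength=len(CLASSES))
    thin = [CLASSES[i] for i in range(len(CLASSES)) if 0 < counts[i] < k_folds]
    if thin:
        raise ValueError(
            f"classes {thin} have fewer than {k_folds} samples; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=config.seed)
    assignments = np.empty(len(y_idx), dtype=int)
    fold_metrics = []
    pooled_truth, pooled_pred = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y_idx)), y_idx)):
        assignments[te] = fold
        model, _ = train(x.iloc[tr], y.iloc[tr], mask_stack, config)
        xt = model.preprocessor.transform(
            x.iloc[te][model.gene_names].to_numpy(dtype=float)
        )
        pred = model.predict(xt)
        p, r, f1, _ = precision_recall_fscore_support(
            y_idx[te], pred, average="weighted", zero_division=0
        )
        fold_metrics.append(
            {"fold": fold, "precision": float(p), "recall": float(r), "f1": float(f1)}
        )
        pooled_truth.append(y_idx[te])
        pooled_pred.append(pred)
    truth = np.concatenate(pooled_truth)
    pred = np.concatenate(pooled_pred)
    p, r, f1, _ = precision_recall_fscore_support(
        truth, pred, average="weighted", zero_division=0
    )
    return TrainReport(
        epoch_losses=[],
        seed=config.seed,
        fold_metrics=fold_metrics,
        fold_assignments=assignments,
        pooled_metrics={"precision": float(p), "recall": float(r), "f1": float(f1)},
    )


def save_model(model: BinnModel, path) -> None:
    """Serialise model + masks + preprocessing stats to one ``.npz`` archive."""
    payload = {
        "activation": np.array(model.activation),
        "classes": np.array(model.classes),
        "w_out": model.w_out,
        "b_out": model.b_out,
        "pre_mean": model.preprocessor.mean_,
        "pre_scale": model.preprocessor.scale_,
        "n_hidden": np.array(model.n_hidden_layers),
        "cfg": np.array(
            [model.config.epochs, model.config.batch_size, model.config.seed]
        ),
        "lr": np.array(model.config.learning_rate),
    }
    for l, (w, b, m) in enumerate(
        zip(model.weights, model.biases, model.mask_stack.masks)
    ):
        payload[f"w{l}"] = w
        payload[f"b{l}"] = b
        payload[f"mask{l}"] = m.to_numpy()
        payload[f"rows{l}"] = np.array(list(m.index))
        payload[f"cols{l}"] = np.array(list(m.columns))
    np.savez(path, **payload)


def load_model(path) -> BinnModel:
    with np.load(path, allow_pickle=False) as data:
        n_hidden = int(data["n_hidden"])
        masks = tuple(
            pd.DataFrame(
                data[f"mask{l}"],
                index=list(data[f"rows{l}"]),
                columns=list(data[f"cols{l}"]),
            )
            for l in range(n_hidden)
        )
        pre = Preprocessor(mean_=data["pre_mean"], scale_=data["pre_scale"])
        epochs, batch, seed = (int(v) for v in data["cfg"])
        cfg = TrainConfig(
            epochs=epochs,
            batch_size=batch,
            learning_rate=float(data["lr"]),
            activation=str(data["activation"]),
            seed=seed,
        )
        return BinnModel(
            mask_stack=MaskStack(masks=masks),
            weights=[data[f"w{l}"] for l in range(n_hidden)],
            biases=[data[f"b{l}"] for l in range(n_hidden)],
            w_out=data["w_out"],
            b_out=data["b_out"],
            activation=cfg.activation,
            preprocessor=pre,
            config=cfg,
            classes=tuple(data["classes"]),
        )
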