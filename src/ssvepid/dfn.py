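"""Deep feedforward network (DFN) classifier.

Three hidden blocks, each a fully connected layer followed by batch
normalization and a ReLU, then a linear classification layer with softmax.
The layer widths follow an expand-then-contract schedule: the first block
projects the FBCSP feature vector into a much larger dimension (a kernel-
trick-style lift), and subsequent blocks contract it —

    D0 = I (input),  D1 >> D0,  D2 < D1,  D3 < D2,  D3 > C,  D4 = C.

Training minimizes softmax cross-entropy with Adam; after every epoch the
validation loss is evaluated (batch norm in inference mode, running
statistics), and the parameter snapshot with the lowest validation loss is
the returned model.  Ablation variants drop leading blocks (keep {B2,B3} or
{B3} only).

Everything is plain NumPy; gradients are hand-derived (the batch-norm
backward pass uses the standard compact form).  All randomness flows from a
single seeded Generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .errors import (
    InvalidArchitectureError,
    InvalidConfigError,
    InvalidInputError,
    StratificationError,
)
from .fbcsp import FeatureVector, feature_matrix

__all__ = ["DFNConfig", "DFNModel", "TrainHistory", "build_dfn", "train_dfn", "predict"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_ADAM_BETAS = (0.9, 0.999)
_ADAM_EPS = 1e-8
_BLOCK_NAMES = ("B1", "B2", "B3")


@dataclass
class DFNConfig:
    """Architecture and training hyperparameters (defaults per the reference
    configuration: widths 500/100/50, lr 1e-3, batch 32, 200 epochs, keep the
    lowest-validation-loss snapshot)."""

    hidden_dims: tuple[int, int, int] = (500, 100, 50)
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    validation_fraction: float | str = 0.2  # or "one-block"
    blocks_kept: tuple[str, ...] = ("B1", "B2", "B3")

    def __post_init__(self) -> None:
        if isinstance(self.validation_fraction, str):
            if self.validation_fraction != "one-block":
                raise InvalidConfigError(
                    "validation_fraction must be a fraction in (0,1) or 'one-block'"
                )
        elif not 0.0 < self.validation_fraction < 1.0:
            raise InvalidConfigError("validation_fraction must lie in (0, 1)")
        if any(b not in _BLOCK_NAMES for b in self.blocks_kept) or not self.blocks_kept:
            raise InvalidConfigError(f"blocks_kept must be a non-empty subset of {_BLOCK_NAMES}")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidConfigError("epochs and batch_size must be >= 1")

    def kept_dims(self) -> tuple[int, ...]:
        return tuple(
            d for name, d in zip(_BLOCK_NAMES, self.hidden_dims) if name in self.blocks_kept
        )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    selected_epoch: int = -1


@dataclass
class DFNModel:
    """Parameter container; use :func:`train_dfn` / :func:`predict` to operate it.

    ``weights[j]`` has shape (D_j, D_{j-1}); hidden layers carry batch-norm
    state (scale ``gamma``, shift ``beta``, running mean/var).  ``classes``
    maps output index to subject label.
    """

    input_dim: int
    class_count: int
    hidden_dims: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    classes: list[int] = field(default_factory=list)
    config: DFNConfig | None = None

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, *self.bn_gamma, *self.bn_beta]

    def snapshot(self) -> dict:
        return {
            "weights": [w.copy() for w in self.weights],
            "biases": [b.copy() for b in self.biases],
            "bn_gamma": [g.copy() for g in self.bn_gamma],
            "bn_beta": [b.copy() for b in self.bn_beta],
            "bn_mean": [m.copy() for m in self.bn_mean],
            "bn_var": [v.copy() for v in self.bn_var],
        }

    def restore(self, snap: dict) -> None:
        for name, vals in snap.items():
            setattr(self, name, [v.copy() for v in vals])

    def save(self, path: str | Path) -> None:
        meta = {
            "input_dim": self.input_dim,
            "class_count": self.class_count,
            "hidden_dims": list(self.hidden_dims),
            "classes": self.classes,
            "format_version": "1",
        }
        arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for name in ("weights", "biases", "bn_gamma", "bn_beta", "bn_mean", "bn_var"):
            for i, a in enumerate(getattr(self, name)):
                arrays[f"{name}_{i}"] = a
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DFNModel":
        with np.load(path) as arrays:
            meta = json.loads(bytes(arrays["_meta"]).decode())
            lists: dict[str, list[np.ndarray]] = {
                n: [] for n in ("weights", "biases", "bn_gamma", "bn_beta", "bn_mean", "bn_var")
            }
            for name in lists:
                i = 0
                while f"{name}_{i}" in arrays.files:
                    lists[name].append(arrays[f"{name}_{i}"])
                    i += 1
        return cls(
            input_dim=meta["input_dim"],
            class_count=meta["class_count"],
            hidden_dims=tuple(meta["hidden_dims"]),
            classes=list(meta["classes"]),
            **lists,
        )


def build_dfn(input_dim: int, n_classes: int, config: DFNConfig | None = None) -> DFNModel:
    """Build an initialized network; validates the dimension schedule.

    Weight init is He (fan-in-scaled normal), biases zero, batch norm in its
    identity state — so a zero input maps to uniform softmax at init.
    """
    config = config or DFNConfig()
    hidden = config.kept_dims()
    if n_classes < 2:
        raise InvalidArchitectureError("need at least two classes")
    if hidden[-1] <= n_classes:
        raise InvalidArchitectureError(
            f"last hidden width {hidden[-1]} must exceed class count {n_classes}"
        )
    if "B1" in config.blocks_kept and hidden[0] <= input_dim:
        raise InvalidArchitectureError(
            f"first block must expand: D1={hidden[0]} <= input dim {input_dim}"
        )
    if any(a <= b for a, b in zip(hidden[1:], hidden[2:])):
        raise InvalidArchitectureError("hidden widths must contract after the first block")

    rng = np.random.default_rng(config.seed)
    dims = [input_dim, *hidden, n_classes]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in))
        biases.append(np.zeros(d_out))
    return DFNModel(
        input_dim=input_dim,
        class_count=n_classes,
        hidden_dims=hidden,
        weights=weights,
        biases=biases,
        bn_gamma=[np.ones(d) for d in hidden],
        bn_beta=[np.zeros(d) for d in hidden],
        bn_mean=[np.zeros(d) for d in hidden],
        bn_var=[np.ones(d) for d in hidden],
        config=config,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: DFNModel, x: np.ndarray, training: bool):
    """Forward pass; returns (probs, cache) — cache only when training."""
    n_hidden = len(model.hidden_dims)
    o = x
    cache = []
    for j in range(n_hidden):
        z = o @ model.weights[j].T + model.biases[j]
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            n = z.shape[0]
            # running stats track the unbiased variance (identity state = 1)
            run_var = var * n / (n - 1) if n > 1 else var
            model.bn_mean[j] = (1 - _BN_MOMENTUM) * model.bn_mean[j] + _BN_MOMENTUM * mu
            model.bn_var[j] = (1 - _BN_MOMENTUM) * model.bn_var[j] + _BN_MOMENTUM * run_var
        else:
            mu, var = model.bn_mean[j], model.bn_var[j]
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (z - mu) * ivar
        y = model.bn_gamma[j] * xhat + model.bn_beta[j]
        a = np.maximum(y, 0.0)
        if training:
            cache.append((o, xhat, ivar, y))
        o = a
    logits = o @ model.weights[-1].T + model.biases[-1]
    probs = _softmax(logits)
    if training:
        cache.append(o)
    return probs, cache


def _backward(model: DFNModel, cache, probs: np.ndarray, y_onehot: np.ndarray):
    """Gradients of mean cross-entropy wrt all parameters."""
    n_hidden = len(model.hidden_dims)
    n = probs.shape[0]
    grads_w = [None] * (n_hidden + 1)
    grads_b = [None] * (n_hidden + 1)
    grads_g = [None] * n_hidden
    grads_be = [None] * n_hidden

    last_input = cache[-1]
    dz = (probs - y_onehot) / n
    grads_w[-1] = dz.T @ last_input
    grads_b[-1] = dz.sum(axis=0)
    do = dz @ model.weights[-1]

    for j in range(n_hidden - 1, -1, -1):
        o_prev, xhat, ivar, y = cache[j]
        dy = do * (y > 0)  # ReLU
        grads_g[j] = (dy * xhat).sum(axis=0)
        grads_be[j] = dy.sum(axis=0)
        dxhat = dy * model.bn_gamma[j]
        m = dy.shape[0]
        dz = (ivar / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        grads_w[j] = dz.T @ o_prev
        grads_b[j] = dz.sum(axis=0)
        do = dz @ model.weights[j]
    return [*grads_w, *grads_b, *grads_g, *grads_be]


def _cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    return float(-np.mean(np.sum(y_onehot * np.log(np.clip(probs, 1e-300, None)), axis=1)))


def _split_validation(
    x: np.ndarray, y: np.ndarray, blocks: np.ndarray, config: DFNConfig, rng: np.random.Generator
):
    """Stratified-per-class (or one-whole-block) train/validation split."""
    if config.validation_fraction == "one-block":
        uniq = np.unique(blocks)
        if len(uniq) < 3:
            raise StratificationError("one-block validation needs >= 3 training blocks")
        held = uniq[-1]
        val_mask = blocks == held
    else:
        val_mask = np.zeros(len(y), dtype=bool)
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_val = max(1, int(round(config.validation_fraction * len(idx))))
            if n_val >= len(idx):
                raise StratificationError(
                    f"class {c} has too few samples ({len(idx)}) for a validation split"
                )
            val_mask[idx[:n_val]] = True
    for c in np.unique(y):
        if not np.any((y == c) & ~val_mask) or not np.any((y == c) & val_mask):
            raise StratificationError(f"class {c} missing from a split")
    return ~val_mask, val_mask


def train_dfn(
    model: DFNModel,
    features: list[FeatureVector] | tuple[np.ndarray, np.ndarray],
    config: DFNConfig | None = None,
) -> tuple[DFNModel, TrainHistory]:
    """Adam training with per-epoch validation and lowest-val-loss selection.

    ``features`` is either a list of :class:`FeatureVector` or a pre-built
    ``(X, y)`` pair; features are assumed already standardized.  Returns the
    model restored to its best epoch plus the full history.
    """
    config = config or model.config or DFNConfig()
    if isinstance(features, tuple):
        x, y = features
        blocks = np.zeros(len(y), dtype=int)
    else:
        x, y = feature_matrix(features)
        blocks = np.array([f.block_index for f in features])
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] != model.input_dim:
        raise InvalidInputError(f"feature dim {x.shape[1]} != model input dim {model.input_dim}")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise StratificationError("need >= 2 classes to train")
    if len(classes) != model.class_count:
        raise InvalidInputError(
            f"{len(classes)} classes in data, model built for {model.class_count}"
        )
    model.classes = [int(c) for c in classes]
    class_to_idx = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_to_idx[v] for v in y])
    onehot = np.eye(model.class_count)[yi]

    rng = np.random.default_rng(config.seed)
    train_mask, val_mask = _split_validation(x, yi, blocks, config, rng)
    x_tr, y_tr = x[train_mask], onehot[train_mask]
    x_val, y_val = x[val_mask], onehot[val_mask]
    yi_val = yi[val_mask]

    params = model.parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    b1, b2 = _ADAM_BETAS
    step = 0

    history = TrainHistory()
    best_loss = np.inf
    best_snap = model.snapshot()
    best_epoch = -1

    n_tr = x_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = _forward(model, x_tr[idx], training=True)
            loss = _cross_entropy(probs, y_tr[idx])
            epoch_loss += loss * len(idx)
            grads = _backward(model, cache, probs, y_tr[idx])
            step += 1
            params = model.parameters()
            for p, g, ms, vs in zip(params, grads, m_state, v_state):
                ms *= b1
                ms += (1 - b1) * g
                vs *= b2
                vs += (1 - b2) * g**2
                mhat = ms / (1 - b1**step)
                vhat = vs / (1 - b2**step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        history.train_loss.append(epoch_loss / n_tr)

        val_probs, _ = _forward(model, x_val, training=False)
        val_loss = _cross_entropy(val_probs, y_val)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == yi_val))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_snap = model.snapshot()
            best_epoch = epoch
    model.restore(best_snap)
    history.selected_epoch = best_epoch
    return model, history


def predict(
    model: DFNModel, features: list[FeatureVector] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inference: batch-norm running statistics, softmax probabilities, argmax labels."""
    if isinstance(features, np.ndarray):
        x = np.atleast_2d(features)
    else:
        x, _ = feature_matrix(features)
    if x.shape[1] != model.input_dim:
        raise InvalidInputError(f"feature dim {x.shape[1]} != model input dim {model.input_dim}")
    probs, _ = _forward(model, x, training=False)
    label_map = np.array(model.classes if model.classes else range(model.class_count))
    labels = label_map[probs.argmax(axis=1)]
    return labels, probs


class DFNClassifier:
    """fit/predict facade matching the baselines' interface."""

    def __init__(self, config: DFNConfig | None = None):
        self.config = config or DFNConfig()
        self.model: DFNModel | None = None
        self.history: TrainHistory | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, blocks: np.ndarray | None = None):
        classes = sorted(np.unique(y).tolist())
        model = build_dfn(x.shape[1], len(classes), self.config)
        if blocks is None:
            feats = (np.asarray(x), np.asarray(y))
        else:
            feats = [
                FeatureVector(values=xi, subject_label=int(yi_), block_index=int(bi))
                for xi, yi_, bi in zip(x, y, blocks)
            ]
        self.model, self.history = train_dfn(model, feats, self.config)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        labels, _ = predict(self.model, np.asarray(x))
        return labels

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        _, probs = predict(self.model, np.asarray(x))
        return probs
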