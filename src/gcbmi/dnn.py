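"""Dense binary classifier for paired multi-omics examples, plus baselines.

The network is a plain feed-forward architecture: an input layer whose
vector is the expression block concatenated with the methylation block,
six ReLU hidden layers of 100 units each (with per-unit biases), inverted
dropout after every hidden layer during training, and a single sigmoid
output unit. The loss is the binary cross-entropy

    L(ŷ, y) = −y·log(ŷ) − (1−y)·log(1−ŷ)

with cost J = mean of L over the minibatch, minimized by Adam. All
randomness — weight initialization, minibatch shuffling, dropout masks —
flows from one integer seed, so training is exactly reproducible.

Implemented as a self-contained numpy minibatch trainer: the model is a few
small dense matrices and the whole forward/backward pass is a handful of
GEMMs, so no deep-learning framework is involved.

``baseline_classifiers`` exposes the comparison classifiers (k-nearest
neighbors with K=5, an RBF support vector machine, Gaussian naive Bayes)
behind the same fit/score contract so the evaluator can swap them in.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .integration import PairedDataset

_EPS = 1e-7  # sigmoid output clip for the cross-entropy
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass(frozen=True)
class DNNConfig:
    """Architecture and optimization settings.

    The architecture (6 × 100 ReLU, sigmoid output) is fixed by design;
    dropout rate, learning rate, epochs and batch size are conventional
    defaults and freely configurable.
    """

    n_hidden_layers: int = 6
    units_per_layer: int = 100
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 128
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.n_hidden_layers < 1 or self.units_per_layer < 1:
            raise ValueError("need at least one hidden layer and one unit")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedModel:
    """Layer weights/biases plus the per-epoch mean training loss."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    history: list[float]
    config: DNNConfig
    n_features: int

    def save(self, path: str | Path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps(
                    {"config": asdict(self.config), "n_features": self.n_features,
                     "history": self.history}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            n_layers = meta["config"]["n_hidden_layers"] + 1
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
        return cls(
            weights=weights,
            biases=biases,
            history=list(meta["history"]),
            config=DNNConfig(**meta["config"]),
            n_features=int(meta["n_features"]),
        )


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy (natural log), predictions clipped to [ε, 1−ε]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), _EPS, 1.0 - _EPS)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log1p(-p)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(n_features: int, cfg: DNNConfig, rng: np.random.Generator):
    sizes = [n_features] + [cfg.units_per_layer] * cfg.n_hidden_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        # He initialization for the ReLU stack; the final sigmoid layer is
        # small enough that the same scale works fine
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(X, weights, biases, cfg, rng=None):
    """Forward pass; with an rng, applies inverted dropout and keeps caches."""
    acts = [X]
    masks = []
    h = X
    keep = 1.0 - cfg.dropout_rate
    for i in range(cfg.n_hidden_layers):
        h = np.maximum(h @ weights[i] + biases[i], 0.0)
        if rng is not None and cfg.dropout_rate > 0.0:
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    z = h @ weights[-1] + biases[-1]
    p = _sigmoid(z)
    return p.ravel(), acts, masks


def train(dataset: PairedDataset, config: DNNConfig = DNNConfig()) -> TrainedModel:
    """Minibatch-Adam training on a paired dataset.

    Dropout is active only here; prediction is deterministic. Raises on an
    empty or single-class dataset.
    """
    X = np.asarray(dataset.features, dtype=float)
    y = np.asarray(dataset.labels, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty dataset")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(X.shape[1], config, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    step = 0
    history: list[float] = []

    for _ in range(config.epochs):
        order = rng.permutation(X.shape[0])
        epoch_losses = []
        for start in range(0, X.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            p, acts, masks = _forward(xb, weights, biases, config, rng=rng)
            epoch_losses.append(bce_loss(yb, p) * len(idx))

            # backward: d(BCE∘sigmoid)/dz = p − y
            delta = ((p - yb) / len(idx))[:, None]
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            grads_w[-1] = acts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            d = delta @ weights[-1].T
            for i in range(config.n_hidden_layers - 1, -1, -1):
                if masks[i] is not None:
                    d = d * masks[i]
                d = d * (acts[i + 1] > 0)
                grads_w[i] = acts[i].T @ d
                grads_b[i] = d.sum(axis=0)
                if i > 0:
                    d = d @ weights[i].T

            step += 1
            corr1 = 1.0 - _ADAM_B1**step
            corr2 = 1.0 - _ADAM_B2**step
            for i in range(len(weights)):
                m_w[i] = _ADAM_B1 * m_w[i] + (1 - _ADAM_B1) * grads_w[i]
                v_w[i] = _ADAM_B2 * v_w[i] + (1 - _ADAM_B2) * grads_w[i] ** 2
                weights[i] -= config.learning_rate * (m_w[i] / corr1) / (
                    np.sqrt(v_w[i] / corr2) + _ADAM_EPS
                )
                m_b[i] = _ADAM_B1 * m_b[i] + (1 - _ADAM_B1) * grads_b[i]
                v_b[i] = _ADAM_B2 * v_b[i] + (1 - _ADAM_B2) * grads_b[i] ** 2
                biases[i] -= config.learning_rate * (m_b[i] / corr1) / (
                    np.sqrt(v_b[i] / corr2) + _ADAM_EPS
                )
        history.append(float(np.sum(epoch_losses) / X.shape[0]))

    return TrainedModel(weights=weights, biases=biases, history=history,
                        config=config, n_features=X.shape[1])


def predict_scores(model: TrainedModel, features: np.ndarray | PairedDataset) -> np.ndarray:
    """Per-row sigmoid scores in (0, 1); dropout off, fully deterministic."""
    X = features.features if isinstance(features, PairedDataset) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length mismatch: model expects {model.n_features}, got {X.shape}"
        )
    p, _, _ = _forward(X, model.weights, model.biases, model.config, rng=None)
    return p


def predict(model: TrainedModel, features: np.ndarray | PairedDataset) -> tuple[np.ndarray, np.ndarray]:
    """Scores and hard labels via the configured decision threshold."""
    scores = predict_scores(model, features)
    return scores, (scores >= model.config.decision_threshold).astype(np.intp)


# ---------------------------------------------------------------------------
# Baseline classifier adapters
# ---------------------------------------------------------------------------

class BaselineAdapter:
    """Uniform fit/score wrapper around a scikit-learn classifier."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaselineAdapter":
        self.estimator.fit(X, y)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        # map decision_function output through a sigmoid to (0, 1)
        return _sigmoid(est.decision_function(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        scores = self.predict_scores(X)
        return scores, (scores >= threshold).astype(np.intp)


BASELINE_NAMES = ("knn", "svm", "nb")


def baseline_classifiers(name: str) -> BaselineAdapter:
    """Comparison classifiers: ``knn`` (K=5), ``svm`` (RBF, gamma=auto, degree=3), ``nb``."""
    if name == "knn":
        return BaselineAdapter("knn", KNeighborsClassifier(n_neighbors=5))
    if name == "svm":
        return BaselineAdapter(
            "svm", SVC(kernel="rbf", degree=3, gamma="auto", cache_size=200)
        )
    if name == "nb":
        return BaselineAdapter("nb", GaussianNB())
    raise ValueError(f"unknown baseline classifier {name!r}; choose from {BASELINE_NAMES}")
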