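"""Baseline models.

A gradient-boosted tree ensemble (XGBoost) serves as the reference model
and supplies its internal feature-importance ranking. A fully-connected
neural network — ReLU hidden layers, sigmoid output, binary cross-entropy,
Adam — is the shared backbone that the adversarial and reinforcement-
learning debiasing variants build on. Every trained model satisfies the
same predictor contract: ``score(rows) -> P(label = 1)`` per row.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from ._nn import Adam, DenseNet, sigmoid
from .synthetic_cohort import feature_columns

__all__ = [
    "NNConfig",
    "Predictor",
    "NNPredictor",
    "GBPredictor",
    "train_gb_baseline",
    "feature_importance",
    "train_nn",
    "design_matrix",
]


def design_matrix(table: pd.DataFrame, features: Sequence[str], allow_nan: bool = False):
    """Extract (X, y) arrays for the given feature order; reject NaNs unless allowed."""
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns: {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if not allow_nan and np.isnan(X).any():
        raise ValueError("features contain NaNs; impute before training/scoring")
    y = table["label"].to_numpy(dtype=int) if "label" in table.columns else None
    return X, y


class Predictor:
    """Contract shared by all model families: a probability scorer on rows."""

    feature_names: tuple[str, ...]
    metadata: dict

    def score(self, rows) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def _matrix(self, rows) -> np.ndarray:
        if isinstance(rows, pd.DataFrame):
            X, _ = design_matrix(rows, self.feature_names)
            return X
        X = np.asarray(rows, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        if np.isnan(X).any():
            raise ValueError("features contain NaNs; impute before scoring")
        return X


@dataclass(frozen=True)
class NNConfig:
    """Feedforward-network training configuration.

    Defaults (two hidden layers of 32 and 16 units, 50 epochs, batch 256,
    Adam at 1e-3) are desk-scale stand-ins exposed in full; nothing is
    hard-coded in the training loop.
    """

    hidden_sizes: tuple[int, ...] = (32, 16)
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    excluded_features: tuple[str, ...] = ()

    def validate(self, schema: Sequence[str]) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must contain at least one positive width")
        unknown = [f for f in self.excluded_features if f not in schema]
        if unknown:
            raise ValueError(f"excluded features not in schema: {unknown}")


class NNPredictor(Predictor):
    def __init__(self, net: DenseNet, feature_names: Sequence[str], metadata: dict):
        self.net = net
        self.feature_names = tuple(feature_names)
        self.metadata = metadata

    def score(self, rows) -> np.ndarray:
        X = self._matrix(rows)
        return sigmoid(self.net.predict(X)[:, 0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "nn",
                "feature_names": list(self.feature_names),
                "metadata": self.metadata,
                "weights": [w.tolist() for w in self.net.weights],
                "biases": [b.tolist() for b in self.net.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NNPredictor":
        d = json.loads(text)
        weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        net = DenseNet.__new__(DenseNet)
        net.weights = weights
        net.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return cls(net, d["feature_names"], d["metadata"])


class GBPredictor(Predictor):
    def __init__(self, model: XGBClassifier, feature_names: Sequence[str], metadata: dict):
        self.model = model
        self.feature_names = tuple(feature_names)
        self.metadata = metadata

    def score(self, rows) -> np.ndarray:
        X = self._matrix(rows)
        return self.model.predict_proba(X)[:, 1].astype(float)


_GB_DEFAULTS = dict(
    n_estimators=200,
    max_depth=4,
    learning_rate=0.1,
    tree_method="hist",
    n_jobs=1,
    eval_metric="logloss",
)


def train_gb_baseline(train: pd.DataFrame, params: dict | None = None, seed: int = 0) -> GBPredictor:
    """Train the gradient-boosted reference model (seeded, single-threaded)."""
    features = feature_columns(train)
    X, y = design_matrix(train, features, allow_nan=True)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    kwargs = {**_GB_DEFAULTS, **(params or {}), "random_state": int(seed)}
    model = XGBClassifier(**kwargs)
    model.fit(X, y)
    return GBPredictor(model, features, {"params": kwargs, "seed": int(seed)})


def feature_importance(predictor: GBPredictor) -> list[tuple[str, float]]:
    """The ensemble's internal importance scores, normalised to sum 1, descending."""
    if not isinstance(predictor, GBPredictor):
        raise TypeError("feature_importance is defined for the gradient-boosting baseline")
    try:
        raw = np.asarray(predictor.model.feature_importances_, dtype=float)
    except Exception as exc:  # untrained model
        raise ValueError("model has no importance scores (untrained?)") from exc
    total = raw.sum()
    if total <= 0:
        raise ValueError("ensemble assigned no importance (empty or untrained)")
    scores = raw / total
    order = np.argsort(-scores, kind="stable")
    return [(predictor.feature_names[i], float(scores[i])) for i in order]


def train_nn(train: pd.DataFrame, config: NNConfig = NNConfig()) -> NNPredictor:
    """Train the fully-connected baseline by binary cross-entropy.

    Excluded features are removed before training; imputation must have run
    already (NaNs are rejected). Deterministic given the config seed.
    """
    schema = feature_columns(train)
    config.validate(schema)
    features = [f for f in schema if f not in config.excluded_features]
    X, y = design_matrix(train, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    net = DenseNet(X.shape[1], config.hidden_sizes, 1, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    yv = y.reshape(-1, 1).astype(float)

    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, acts = net.forward(X[idx])
            p = sigmoid(logits)
            d_logits = (p - yv[idx]) / len(idx)  # BCE gradient wrt logit
            grads, _ = net.backward(acts, d_logits)
            opt.step(net.parameters(), grads)

    meta = {"config": asdict(config), "features": features}
    return NNPredictor(net, features, meta)
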