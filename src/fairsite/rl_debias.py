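"""Reinforcement-learning debiasing.

Classification is cast as a one-step contextual bandit: a policy network
reads a presentation's features, samples an action in {predict negative,
predict positive}, and receives an immediate reward — positive for a
correct call, negative otherwise. Updates follow REINFORCE with a
moving-average baseline, backpropagating only through the action actually
taken. Fairness shaping multiplies each sample's reward by the inverse
frequency of its (site, label) group, normalised to mean 1 over the
training set, so sparse minority-site rows carry as much total learning
signal as the majority sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, DenseNet, softmax
from .classifiers import NNConfig, design_matrix
from .synthetic_cohort import feature_columns

__all__ = ["RLConfig", "PolicyPredictor", "group_weights", "train_rl_classifier"]


@dataclass(frozen=True)
class RLConfig:
    """Policy-gradient training configuration.

    ``episodes`` counts full passes over the training set. The policy head
    has two actions; its returned score is the probability of the positive
    action. ``fairness_weighting`` is ``"none"`` or
    ``"inverse_group_frequency"``.
    """

    policy: NNConfig = field(default_factory=NNConfig)
    reward_correct: float = 1.0
    reward_incorrect: float = -1.0
    fairness_weighting: str = "none"
    episodes: int = 200
    batch_size: int = 256
    seed: int = 0
    baseline_momentum: float = 0.9

    def validate(self) -> None:
        if self.reward_correct <= self.reward_incorrect:
            raise ValueError("reward_correct must exceed reward_incorrect")
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")
        if self.fairness_weighting not in ("none", "inverse_group_frequency"):
            raise ValueError("fairness_weighting must be 'none' or 'inverse_group_frequency'")
        if not (np.isfinite(self.reward_correct) and np.isfinite(self.reward_incorrect)):
            raise ValueError("rewards must be finite")


def group_weights(sites: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample inverse (site, label) group-frequency weights.

    w_g = N / (G * n_g) for a sample in group g, with N samples and G
    distinct non-empty groups — proportional to 1/n_g and averaging exactly
    1 over the training set.
    """
    sites = np.asarray(sites)
    labels = np.asarray(labels)
    keys = [(s, int(l)) for s, l in zip(sites, labels)]
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    if any(c == 0 for c in counts.values()):  # defensive; cannot occur for seen groups
        raise ValueError("degenerate (site, label) group with zero frequency")
    N, G = len(keys), len(counts)
    return np.array([N / (G * counts[k]) for k in keys], dtype=float)


class PolicyPredictor:
    """Predictor contract over the trained policy: score = P(action = positive)."""

    def __init__(self, net: DenseNet, feature_names, metadata: dict):
        self.net = net
        self.feature_names = tuple(feature_names)
        self.metadata = metadata

    def score(self, rows) -> np.ndarray:
        if isinstance(rows, pd.DataFrame):
            X, _ = design_matrix(rows, self.feature_names)
        else:
            X = np.asarray(rows, dtype=float)
            if np.isnan(X).any():
                raise ValueError("features contain NaNs; impute before scoring")
        return softmax(self.net.predict(X))[:, 1]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "kind": "policy",
                "feature_names": list(self.feature_names),
                "metadata": self.metadata,
                "weights": [w.tolist() for w in self.net.weights],
                "biases": [b.tolist() for b in self.net.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PolicyPredictor":
        import json

        d = json.loads(text)
        net = DenseNet.__new__(DenseNet)
        net.weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return cls(net, d["feature_names"], d["metadata"])


def train_rl_classifier(train: pd.DataFrame, config: RLConfig = RLConfig()) -> PolicyPredictor:
    """Train the bandit policy; returns a scorer with a per-episode reward log.

    The REINFORCE update uses advantage = reward - moving-average baseline
    and the log-policy gradient of the sampled action only. The mean shaped
    reward per episode is stored in ``metadata["reward_log"]``.
    """
    config.validate()
    schema = feature_columns(train)
    config.policy.validate(schema)
    features = [f for f in schema if f not in config.policy.excluded_features]
    X, y = design_matrix(train, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if config.fairness_weighting != "none":
        if "site" not in train.columns or len(set(train["site"])) < 2:
            raise ValueError("fairness weighting requires at least two sites")
        w = group_weights(train["site"].to_numpy(), y)
    else:
        w = np.ones(len(y))

    rng = np.random.default_rng([int(config.seed) % 2**31, int(config.policy.seed) % 2**31])
    net = DenseNet(X.shape[1], config.policy.hidden_sizes, 2, rng)
    opt = Adam(net.parameters(), lr=config.policy.learning_rate)

    n = len(X)
    baseline = 0.0
    reward_log = []
    for _ in range(config.episodes):
        order = rng.permutation(n)
        ep_reward = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            B = len(idx)
            logits, acts = net.forward(X[idx])
            p = softmax(logits)
            a = (rng.random(B) < p[:, 1]).astype(int)
            r = np.where(a == y[idx], config.reward_correct, config.reward_incorrect) * w[idx]
            if not np.all(np.isfinite(r)):
                raise FloatingPointError("non-finite reward encountered")
            advantage = r - baseline
            # d(-advantage * log pi(a|x)) / d logits, sampled action only
            d_logits = -(np.eye(2)[a] - p) * advantage[:, None] / B
            grads, _ = net.backward(acts, d_logits)
            opt.step(net.parameters(), grads)
            m = config.baseline_momentum
            baseline = m * baseline + (1.0 - m) * float(r.mean())
            ep_reward += float(r.sum())
        reward_log.append(ep_reward / n)

    meta = {"config": asdict(config), "features": features, "reward_log": reward_log}
    return PolicyPredictor(net, features, meta)
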