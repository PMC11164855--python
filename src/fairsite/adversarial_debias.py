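"""Adversarial debiasing.

A primary classifier (the feedforward backbone) is trained jointly with an
adversary that tries to recover the hospital site from the classifier's
output score, optionally concatenated with the true label. Conditioning the
adversary on the label targets equalized odds — score distributions must
match across sites *within* each label class — rather than demographic
parity. The classifier descends its own cross-entropy while ascending the
adversary's (gradient reversal), weighted by ``lambda_adv``.

Because the minority site contributes only a few percent of the rows, an
unweighted adversary barely registers it; its cross-entropy is therefore
class-weighted by inverse site frequency, and the adversary takes extra
catch-up steps at a higher learning rate so it tracks the classifier
through training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nn import Adam, DenseNet, sigmoid, softmax
from .classifiers import NNConfig, NNPredictor, design_matrix
from .synthetic_cohort import feature_columns

__all__ = ["AdversarialConfig", "train_adversarial", "sweep_lambda"]


@dataclass(frozen=True)
class AdversarialConfig:
    """Configuration for the classifier/adversary pair.

    ``lambda_adv`` weights the reversed adversary gradient in the classifier
    update (0 decouples the adversary entirely). ``adversary_inputs`` is
    ``"score+label"`` (equalized-odds target, default) or ``"score"``
    (demographic-parity-like). ``adversary_steps`` counts adversary updates
    per classifier update. ``mode`` selects joint single-pass updates
    (default) or strictly alternating classifier/adversary batches. The
    adversarial dynamic converges more slowly than plain supervised
    training, hence the longer default epoch budget of the base network.
    """

    base: NNConfig = field(default_factory=lambda: NNConfig(epochs=150))
    adversary_hidden_sizes: tuple[int, ...] = (16,)
    lambda_adv: float = 2.0
    adversary_inputs: str = "score+label"
    adversary_lr: float = 5e-3
    adversary_steps: int = 3
    class_weighted_adversary: bool = True
    mode: str = "joint"
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be non-negative")
        if self.adversary_inputs not in ("score", "score+label"):
            raise ValueError("adversary_inputs must be 'score' or 'score+label'")
        if self.mode not in ("joint", "alternating"):
            raise ValueError("mode must be 'joint' or 'alternating'")
        if self.adversary_steps < 1:
            raise ValueError("adversary_steps must be >= 1")


def train_adversarial(
    train: pd.DataFrame, config: AdversarialConfig = AdversarialConfig()
) -> tuple[NNPredictor, dict]:
    """Train the debiased classifier; return it with adversary diagnostics.

    Diagnostics include per-epoch classifier and adversary losses and the
    adversary's final site-prediction accuracy (raw and balanced across
    sites) on the training rows — lower balanced accuracy at fixed lambda
    means less site information leaks through the score.
    """
    config.validate()
    schema = feature_columns(train)
    config.base.validate(schema)
    features = [f for f in schema if f not in config.base.excluded_features]
    X, y = design_matrix(train, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    site_ids = sorted(set(train["site"]))
    if len(site_ids) < 2:
        raise ValueError("adversarial debiasing requires at least two sites")
    z = np.array([site_ids.index(s) for s in train["site"]])
    K = len(site_ids)

    base = config.base
    rng = np.random.default_rng([int(config.seed) % 2**31, int(base.seed) % 2**31])
    clf = DenseNet(X.shape[1], base.hidden_sizes, 1, rng)
    adv_in_dim = 2 if config.adversary_inputs == "score+label" else 1
    adv = DenseNet(adv_in_dim, config.adversary_hidden_sizes, K, rng)
    opt_c = Adam(clf.parameters(), lr=base.learning_rate)
    opt_a = Adam(adv.parameters(), lr=config.adversary_lr)

    yv = y.reshape(-1, 1).astype(float)
    onehot_z = np.eye(K)[z]
    counts = np.bincount(z, minlength=K)
    if config.class_weighted_adversary:
        site_w = len(z) / (K * np.maximum(counts, 1))
    else:
        site_w = np.ones(K)
    w = site_w[z]

    def adversary_pass(s_det: np.ndarray, idx: np.ndarray):
        """One adversary forward/backward on detached scores."""
        adv_in = np.hstack([s_det, yv[idx]]) if adv_in_dim == 2 else s_det
        alogits, acts_a = adv.forward(adv_in)
        pa = softmax(alogits)
        d_alogits = (pa - onehot_z[idx]) * w[idx][:, None] / len(idx)
        grads_a, d_adv_in = adv.backward(acts_a, d_alogits)
        return pa, grads_a, d_adv_in

    n = len(X)
    history = {"clf_loss": [], "adv_loss": []}
    batch_counter = 0
    for _ in range(base.epochs):
        order = rng.permutation(n)
        ep_closs, ep_aloss, ep_batches = 0.0, 0.0, 0
        for start in range(0, n, base.batch_size):
            idx = order[start : start + base.batch_size]
            B = len(idx)
            update_adv = update_clf = True
            if config.mode == "alternating":
                update_adv = batch_counter % 2 == 0
                update_clf = not update_adv
            batch_counter += 1

            if update_adv:  # catch-up steps on the current classifier
                for _k in range(config.adversary_steps - 1):
                    s_det = sigmoid(clf.predict(X[idx]))
                    _, grads_a, _ = adversary_pass(s_det, idx)
                    opt_a.step(adv.parameters(), grads_a)

            logits, acts_c = clf.forward(X[idx])
            s = sigmoid(logits)
            pa, grads_a, d_adv_in = adversary_pass(s, idx)
            if update_adv:
                opt_a.step(adv.parameters(), grads_a)
            if update_clf:
                # classifier gradient: BCE minus lambda * adversary loss,
                # the adversary term flowing back through the sigmoid score
                d_s = -config.lambda_adv * d_adv_in[:, :1]
                d_logits = (s - yv[idx]) / B + d_s * s * (1.0 - s)
                grads_c, _ = clf.backward(acts_c, d_logits)
                opt_c.step(clf.parameters(), grads_c)

            eps = 1e-12
            ep_closs += float(-np.mean(yv[idx] * np.log(s + eps) + (1 - yv[idx]) * np.log(1 - s + eps)))
            ep_aloss += float(-np.mean(np.log(pa[np.arange(B), z[idx]] + eps)))
            ep_batches += 1
        history["clf_loss"].append(ep_closs / ep_batches)
        history["adv_loss"].append(ep_aloss / ep_batches)
        if not np.isfinite(history["clf_loss"][-1]):
            raise FloatingPointError("non-finite classifier loss during adversarial training")

    # final adversary site-prediction accuracy on training rows
    s_all = sigmoid(clf.predict(X))
    adv_in = np.hstack([s_all, yv]) if adv_in_dim == 2 else s_all
    pred_site = np.argmax(adv.predict(adv_in), axis=1)
    adv_accuracy = float(np.mean(pred_site == z))
    per_site_acc = [float(np.mean(pred_site[z == k] == k)) for k in range(K) if counts[k]]
    balanced_accuracy = float(np.mean(per_site_acc))

    meta = {"config": asdict(config), "features": features, "sites": site_ids}
    diagnostics = {
        "adversary_accuracy": adv_accuracy,
        "adversary_balanced_accuracy": balanced_accuracy,
        "history": history,
        "site_ids": site_ids,
    }
    return NNPredictor(clf, features, meta), diagnostics


def sweep_lambda(train: pd.DataFrame, lambdas, config: AdversarialConfig = AdversarialConfig()) -> pd.DataFrame:
    """Train at each lambda and tabulate the adversary's residual site signal.

    A small utility for choosing the adversary weight: larger lambda should
    drive the adversary's balanced site-prediction accuracy down toward
    chance (1 / n_sites).
    """
    rows = []
    for lam in lambdas:
        cfg = AdversarialConfig(**{**asdict(config), "lambda_adv": float(lam), "base": config.base})
        _, diag = train_adversarial(train, cfg)
        rows.append(
            {
                "lambda_adv": float(lam),
                "adversary_accuracy": diag["adversary_accuracy"],
                "adversary_balanced_accuracy": diag["adversary_balanced_accuracy"],
            }
        )
    return pd.DataFrame(rows)
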