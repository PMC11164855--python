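"""Operating-point calibration and classification metrics with bootstrap
uncertainty.

The operating threshold is chosen on the continuous-validation split by a
grid search over all achievable operating points, targeting a sensitivity
of 0.9 (±0.05) and maximising specificity among the feasible candidates.
Test-set metrics (AUROC, AUPRC, sensitivity, specificity, PPV, NPV) carry
95% percentile confidence intervals over 1000 whole-set bootstrap
resamples; model comparison uses a paired bootstrap sharing resample
indices across models. PPV and NPV are computed at the evaluated set's own
prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ThresholdChoice",
    "MetricReport",
    "calibrate_threshold",
    "classification_metrics",
    "metric_report",
    "bootstrap_ci",
    "paired_bootstrap_pvalue",
    "per_site_eval",
    "auroc",
]


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    sensitivity: float
    specificity: float
    feasible: bool


@dataclass
class MetricReport:
    auroc: float | None
    auprc: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    prevalence: float
    n: int
    threshold: float | None = None
    ci: dict = field(default_factory=dict)  # metric name -> (lower, upper)


def _sens_spec(scores, labels, threshold):
    pred = scores >= threshold
    pos = labels == 1
    sens = np.mean(pred[pos]) if pos.any() else None
    spec = np.mean(~pred[~pos]) if (~pos).any() else None
    return sens, spec


def calibrate_threshold(scores, labels, target_sens: float = 0.9, tol: float = 0.05) -> ThresholdChoice:
    """Grid-search the threshold for a target sensitivity, maximising specificity.

    Candidates are 0, 1 and every midpoint between adjacent sorted unique
    scores (the complete set of achievable operating points under the rule
    score >= t -> positive). Among candidates within ``tol`` of the target
    sensitivity the one with highest specificity is returned; if none is
    feasible, the candidate minimising |sensitivity - target| is returned
    with ``feasible=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (labels == 1).any():
        raise ValueError("calibration requires positive validation labels")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2.0, [1.0]])

    best_feasible = None  # (spec, threshold)
    best_any = None  # (-|sens-target|, spec, threshold, sens)
    for t in candidates:
        sens, spec = _sens_spec(scores, labels, t)
        spec = 0.0 if spec is None else spec
        key = (-abs(sens - target_sens), spec, t)
        if best_any is None or key > best_any[:3]:
            best_any = (*key, sens)
        if abs(sens - target_sens) <= tol:
            if best_feasible is None or (spec, t) > best_feasible[:2]:
                best_feasible = (spec, t, sens)

    if best_feasible is not None:
        spec, t, sens = best_feasible
        return ThresholdChoice(float(t), float(sens), float(spec), True)
    _, spec, t, sens = best_any
    return ThresholdChoice(float(t), float(sens), float(spec), False)


def auroc(scores, labels) -> float | None:
    """AUROC (probability a random positive outscores a random negative, ties 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def _auprc(scores, labels) -> float | None:
    labels = np.asarray(labels)
    if not (labels == 1).any():
        return None
    # step-wise integral of the precision-recall curve
    return float(average_precision_score(labels, scores))


def classification_metrics(scores, labels, threshold: float) -> MetricReport:
    """Point estimates of all six metrics on one set at one threshold.

    Metrics whose denominator is empty (e.g. specificity with no negatives)
    are reported as ``None``, never as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = len(labels)
    return MetricReport(
        auroc=auroc(scores, labels),
        auprc=_auprc(scores, labels),
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
        prevalence=float(np.mean(labels == 1)),
        n=n,
        threshold=float(threshold),
    )


_METRIC_NAMES = ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv")


def _resample_indices(n, B, rng, labels=None, stratified=False):
    if not stratified:
        return rng.integers(0, n, size=(B, n))
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    idx = np.empty((B, n), dtype=int)
    for b in range(B):
        idx[b, : len(pos)] = rng.choice(pos, size=len(pos), replace=True)
        idx[b, len(pos) :] = rng.choice(neg, size=len(neg), replace=True)
    return idx


def metric_report(
    scores,
    labels,
    threshold: float,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = False,
) -> MetricReport:
    """Full metric report with percentile bootstrap CIs (shared resamples)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    report = classification_metrics(scores, labels, threshold)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(len(labels), B, rng, labels, stratified)
    samples = {m: [] for m in _METRIC_NAMES}
    for b in range(B):
        rep = classification_metrics(scores[idx[b]], labels[idx[b]], threshold)
        for m in _METRIC_NAMES:
            v = getattr(rep, m)
            if v is not None:
                samples[m].append(v)
    q = (1.0 - level) / 2.0
    for m in _METRIC_NAMES:
        if samples[m]:
            lo, hi = np.quantile(samples[m], [q, 1.0 - q])
            report.ci[m] = (float(lo), float(hi))
    return report


def bootstrap_ci(scores, labels, metric, B: int = 1000, level: float = 0.95, seed: int = 0,
                 stratified: bool = False) -> tuple[float, float]:
    """Percentile CI of ``metric(scores, labels)`` over B whole-set resamples."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(len(labels), B, rng, labels, stratified)
    vals = []
    for b in range(B):
        v = metric(scores[idx[b]], labels[idx[b]])
        if v is not None:
            vals.append(v)
    if not vals:
        raise ValueError("metric undefined on every bootstrap resample")
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [q, 1.0 - q])
    return float(lo), float(hi)


def paired_bootstrap_pvalue(scores_a, scores_b, labels, metric, B: int = 1000, seed: int = 0) -> float:
    """One-sided paired-bootstrap p-value that model A outperforms model B.

    The same resample indices are applied to both score vectors; p is the
    fraction of iterations in which A's metric does not exceed B's, exact
    ties counting one half (so two identical models give p = 0.5).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(len(labels), B, rng)
    wins_b, valid = 0.0, 0
    for b in range(B):
        va = metric(scores_a[idx[b]], labels[idx[b]])
        vb = metric(scores_b[idx[b]], labels[idx[b]])
        if va is None or vb is None:
            continue
        valid += 1
        wins_b += 1.0 if va < vb else (0.5 if va == vb else 0.0)
    if valid == 0:
        raise ValueError("metric undefined on every bootstrap resample")
    return wins_b / valid


def per_site_eval(scores, labels, sites, threshold: float, B: int = 0, seed: int = 0) -> dict:
    """Metric reports within each site's rows (PPV/NPV at that site's prevalence)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    sites = np.asarray(sites)
    out = {}
    for z in sorted(set(sites.tolist())):
        m = sites == z
        if B > 0:
            out[z] = metric_report(scores[m], labels[m], threshold, B=B, seed=seed)
        else:
            out[z] = classification_metrics(scores[m], labels[m], threshold)
    return out
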