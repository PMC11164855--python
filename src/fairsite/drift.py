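"""Between-site covariate-shift screening.

Two-sample Kolmogorov-Smirnov tests per feature between each reference site
and a target site (plus all reference-site pairs), Bonferroni-corrected
over every test performed, and a descriptive Kruskal-Wallis scan of
per-feature medians across all sites. The KS statistic is invariant to
monotone transforms, so the scan may run on raw or standardised features
interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import feature_columns

__all__ = [
    "DriftReport",
    "ks_two_sample",
    "covariate_shift_scan",
    "select_drifted_features",
    "kruskal_scan",
]


@dataclass
class DriftReport:
    """KS scan results (one row per feature x site pair) plus Kruskal entries."""

    ks: pd.DataFrame
    target_site: str | None = None
    stat_threshold: float = 0.5
    alpha: float = 1e-4
    kruskal: pd.DataFrame = field(default_factory=pd.DataFrame)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS statistic (exact sup of ECDF differences) and asymptotic p.

    Missing entries are dropped; empty samples are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ks_two_sample requires non-empty samples after dropping missing values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def covariate_shift_scan(
    cohort: pd.DataFrame,
    reference_sites: list[str],
    target_site: str,
    stat_threshold: float = 0.5,
    alpha: float = 1e-4,
) -> DriftReport:
    """KS-test every feature between each reference site and the target site.

    Reference-site pairs among themselves are also tested (the within-group
    comparison that contextualises the target shift). The Bonferroni factor
    m counts every test performed: #features x #site pairs.
    """
    sites = set(cohort["site"])
    for s in [*reference_sites, target_site]:
        if s not in sites:
            raise ValueError(f"site {s!r} not present in cohort")
    pairs = [(ref, target_site) for ref in reference_sites]
    pairs += list(combinations(reference_sites, 2))
    features = feature_columns(cohort)
    m = len(features) * len(pairs)

    rows = []
    grouped = {s: cohort[cohort["site"] == s] for s in sites}
    for f in features:
        for ref, tgt in pairs:
            stat, p = ks_two_sample(grouped[ref][f], grouped[tgt][f])
            p_bonf = min(1.0, p * m)
            rows.append(
                {
                    "feature": f,
                    "reference_site": ref,
                    "target_site": tgt,
                    "ks_statistic": stat,
                    "p_value": p,
                    "p_bonferroni": p_bonf,
                    "flagged": bool(stat > stat_threshold and p_bonf < alpha),
                }
            )
    return DriftReport(
        ks=pd.DataFrame(rows),
        target_site=target_site,
        stat_threshold=stat_threshold,
        alpha=alpha,
    )


def select_drifted_features(report: DriftReport, stat_threshold: float | None = None) -> list[str]:
    """Features showing a material shift against the target in *every* pair.

    A feature qualifies when its minimum KS statistic over all
    reference-target pairs exceeds the threshold and its Bonferroni-corrected
    p-value is below the report's alpha in each of those pairs. The returned
    list is ordered by descending mean statistic.
    """
    if stat_threshold is None:
        stat_threshold = report.stat_threshold
    if report.target_site is None:
        raise ValueError("report has no target site")
    ks = report.ks[report.ks["target_site"] == report.target_site]
    out = []
    for f, sub in ks.groupby("feature"):
        if sub["ks_statistic"].min() > stat_threshold and (sub["p_bonferroni"] < report.alpha).all():
            out.append((f, sub["ks_statistic"].mean()))
    out.sort(key=lambda t: -t[1])
    return [f for f, _ in out]


def kruskal_scan(cohort: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis test of each feature's distribution across all sites.

    Descriptive only — it informs no exclusion decision.
    """
    site_ids = sorted(set(cohort["site"]))
    if len(site_ids) < 2:
        raise ValueError("kruskal_scan requires at least two sites")
    rows = []
    for f in feature_columns(cohort):
        groups = []
        for s in site_ids:
            vals = cohort.loc[cohort["site"] == s, f].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                groups.append(vals)
        H, p = stats.kruskal(*groups)
        rows.append({"feature": f, "H": float(H), "p_value": float(p)})
    return pd.DataFrame(rows)
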