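"""Equalized-odds fairness over hospital sites.

A thresholded classifier satisfies equalized odds when its true-positive
and false-positive rates are equal across every class of the sensitive
attribute (here, the site of care). With more than two sites the departure
from equality is summarised by the standard deviation of the per-site rates:
SD_TP over {TP_z / (TP_z + FN_z)} and SD_FP over the per-site false-positive
rates. Zero means perfect equalized odds; every site contributes equally
regardless of its size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

__all__ = ["SiteConfusion", "FairnessReport", "site_confusions", "equalized_odds_sd"]


class SiteConfusion(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class FairnessReport:
    tpr: dict
    fpr: dict
    sd_tp: float
    sd_fp: float
    n_sites: int
    #: |rate_A - rate_B| pair, populated only in the two-site case
    tpr_gap: float | None = None
    fpr_gap: float | None = None


def site_confusions(scores, labels, sites, threshold: float) -> dict[object, SiteConfusion]:
    """Per-site confusion counts at a threshold (score >= threshold -> positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    sites = np.asarray(sites)
    pred = scores >= threshold
    out = {}
    for z in sorted(set(sites.tolist())):
        m = sites == z
        y, p = labels[m], pred[m]
        out[z] = SiteConfusion(
            tp=int(np.sum(p & (y == 1))),
            fp=int(np.sum(p & (y == 0))),
            tn=int(np.sum(~p & (y == 0))),
            fn=int(np.sum(~p & (y == 1))),
        )
    return out


def equalized_odds_sd(
    confusions: Mapping[object, SiteConfusion],
    ddof: int = 0,
    fpr_denominator: str = "standard",
) -> FairnessReport:
    """Equalized-odds SD scores from per-site confusion counts.

    The SD is the population SD by default (``ddof=0``): the site set is the
    full population of interest, not a sample. ``fpr_denominator`` selects
    the standard false-positive rate FP/(FP+TN) (default) or the
    ``"as_printed"`` audit variant FP/(TP+FN).
    """
    if fpr_denominator not in ("standard", "as_printed"):
        raise ValueError("fpr_denominator must be 'standard' or 'as_printed'")
    if not confusions:
        raise ValueError("no site confusions supplied")
    tpr, fpr = {}, {}
    for z, c in confusions.items():
        if c.tp + c.fn == 0:
            raise ValueError(f"site {z!r} has no positives; TPR undefined")
        tpr[z] = c.tp / (c.tp + c.fn)
        if fpr_denominator == "standard":
            if c.fp + c.tn == 0:
                raise ValueError(f"site {z!r} has no negatives; FPR undefined")
            fpr[z] = c.fp / (c.fp + c.tn)
        else:
            fpr[z] = c.fp / (c.tp + c.fn)
    tpr_vals = np.array(list(tpr.values()))
    fpr_vals = np.array(list(fpr.values()))
    report = FairnessReport(
        tpr=tpr,
        fpr=fpr,
        sd_tp=float(np.std(tpr_vals, ddof=ddof)),
        sd_fp=float(np.std(fpr_vals, ddof=ddof)),
        n_sites=len(confusions),
    )
    if len(confusions) == 2:
        report.tpr_gap = float(abs(tpr_vals[0] - tpr_vals[1]))
        report.fpr_gap = float(abs(fpr_vals[0] - fpr_vals[1]))
    return report
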