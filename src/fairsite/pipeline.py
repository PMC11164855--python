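"""End-to-end experiment orchestration.

Runs the full comparison on a configured scenario: generate the multi-site
cohort, split each site stratified by label, fit preprocessing on the
training rows, screen covariate shift, train the model roster (gradient
boosting, the all-features network, reduced-feature networks derived from
the drift scan, the RL and adversarial debiasing models), calibrate each
model's threshold on the continuous-validation split, and evaluate
classification performance and equalized-odds fairness on the test split —
overall and within each site.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adversarial_debias import AdversarialConfig, train_adversarial
from .classifiers import NNConfig, train_gb_baseline, train_nn
from .cohort_prep import SplitPlan, apply_preprocess, filter_missingness, fit_preprocess, split_extract
from .drift import DriftReport, covariate_shift_scan, select_drifted_features
from .evaluation import calibrate_threshold, metric_report, per_site_eval
from .fairness import equalized_odds_sd, site_confusions
from .rl_debias import RLConfig, train_rl_classifier
from .synthetic_cohort import GeneratorConfig, default_generator_config, generate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "reduced_feature_roster", "split_per_site", "prepare_cohort"]

log = logging.getLogger("fairsite")

DEFAULT_ROSTER = ("gb", "nn", "rl", "adversarial")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the full comparison experiment."""

    generator: GeneratorConfig = field(default_factory=default_generator_config)
    split: SplitPlan = field(default_factory=SplitPlan)
    target_site: str = "site_E"
    roster: tuple[str, ...] = DEFAULT_ROSTER
    include_reduced: bool = True
    nn: NNConfig = field(default_factory=NNConfig)
    adversarial: AdversarialConfig = field(default_factory=AdversarialConfig)
    rl: RLConfig = field(default_factory=lambda: RLConfig(fairness_weighting="inverse_group_frequency"))
    target_sensitivity: float = 0.9
    sensitivity_tol: float = 0.05
    bootstrap_B: int = 1000
    seeds: tuple[int, ...] = (0,)

    def validate(self) -> None:
        if not self.roster:
            raise ValueError("model roster must not be empty")
        unknown = [m for m in self.roster if m not in DEFAULT_ROSTER]
        if unknown:
            raise ValueError(f"unknown roster entries: {unknown}")


def split_per_site(cohort: pd.DataFrame, plan: SplitPlan) -> pd.DataFrame:
    """Apply the stratified split independently within every site.

    Each site gets its own deterministic stream derived from the plan seed
    and a stable hash of the site id.
    """
    parts = []
    for site_id, group in cohort.groupby("site", sort=True):
        site_seed = np.random.SeedSequence(
            [int(plan.seed) % 2**31, zlib.crc32(str(site_id).encode())]
        ).generate_state(1)[0] % 2**31
        parts.append(split_extract(group, SplitPlan(plan.fractions, int(site_seed))))
    return pd.concat(parts).sort_index()


def prepare_cohort(config: "ExperimentConfig"):
    """Generate, split, missingness-filter and standardise the cohort.

    Returns (prepared table, preprocess state, dropped features).
    """
    cohort = generate_cohort(config.generator)
    cohort = split_per_site(cohort, config.split)
    cohort, dropped = filter_missingness(cohort)
    state = fit_preprocess(cohort[cohort["split"] == "train"])
    return apply_preprocess(cohort, state), state, dropped


def reduced_feature_roster(drifted: list[str] | DriftReport) -> list[tuple[str, tuple[str, ...]]]:
    """NN exclusion sets from the drift scan: top-1, top-2, and both jointly.

    Returns (model name, excluded features) pairs; duplicates collapse when
    fewer than two features were flagged, and an empty scan yields an empty
    roster with a warning.
    """
    if isinstance(drifted, DriftReport):
        drifted = select_drifted_features(drifted)
    if not drifted:
        warnings.warn("drift scan flagged no features; reduced-feature roster is empty")
        return []
    combos = [(f"nn_minus_{drifted[0]}", (drifted[0],))]
    if len(drifted) > 1:
        combos.append((f"nn_minus_{drifted[1]}", (drifted[1],)))
        combos.append(("nn_minus_both", tuple(drifted[:2])))
    return combos


def _train_model(name: str, train_rows: pd.DataFrame, config: ExperimentConfig, seed: int,
                 excluded: tuple[str, ...] = ()):
    if name == "gb":
        return train_gb_baseline(train_rows, seed=seed)
    if name.startswith("nn"):
        cfg = NNConfig(**{**asdict(config.nn), "seed": seed, "excluded_features": excluded})
        return train_nn(train_rows, cfg)
    if name == "rl":
        base = NNConfig(**{**asdict(config.rl.policy), "seed": seed})
        cfg = RLConfig(**{**asdict(config.rl), "policy": base, "seed": seed})
        return train_rl_classifier(train_rows, cfg)
    if name == "adversarial":
        base = NNConfig(**{**asdict(config.adversarial.base), "seed": seed})
        cfg = AdversarialConfig(**{**asdict(config.adversarial), "base": base, "seed": seed})
        model, _ = train_adversarial(train_rows, cfg)
        return model
    raise ValueError(f"unknown model {name!r}")


def _report_row(model: str, seed: int, rep, fairness) -> dict:
    row = {"model": model, "seed": seed}
    for m in ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv"):
        row[m] = getattr(rep, m)
        lo_hi = rep.ci.get(m)
        if lo_hi:
            row[f"{m}_lo"], row[f"{m}_hi"] = lo_hi
    row["threshold"] = rep.threshold
    if fairness is not None:
        row["sd_tp"] = fairness.sd_tp
        row["sd_fp"] = fairness.sd_fp
    return row


def run_experiment(config: ExperimentConfig = ExperimentConfig(), out_dir: str | Path | None = None) -> dict:
    """Run the full comparison; return (and optionally write) the report bundle.

    The bundle contains the performance table (one row per model x seed),
    the equalized-odds table, per-site tables, the drift report, saved
    score vectors and a provenance block. Any stage failure aborts with the
    stage name; partial outputs written so far are kept.
    """
    config.validate()
    bundle: dict = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "prepare"
    try:
        prepped, state, dropped_features = prepare_cohort(config)
        log.info("prepared cohort: %d rows, dropped features: %s", len(prepped), dropped_features)

        stage = "drift"
        train_rows = prepped[prepped["split"] == "train"]
        reference_sites = sorted(s for s in set(prepped["site"]) if s != config.target_site)
        drift_report = covariate_shift_scan(train_rows, reference_sites, config.target_site)
        drifted = select_drifted_features(drift_report)
        log.info("drifted features: %s", drifted)

        roster: list[tuple[str, tuple[str, ...]]] = [(m, ()) for m in config.roster]
        if config.include_reduced and "nn" in config.roster:
            idx = roster.index(("nn", ())) + 1
            roster[idx:idx] = reduced_feature_roster(drifted)

        val_rows = prepped[prepped["split"] == "continuous_validation"]
        test_rows = prepped[prepped["split"] == "test"]
        perf_rows, eo_rows, per_site_rows, scores_tables = [], [], [], {}

        for seed in config.seeds:
            for name, excluded in roster:
                stage = f"train:{name}:seed{seed}"
                model = _train_model(name, train_rows, config, seed, excluded)

                stage = f"calibrate:{name}:seed{seed}"
                choice = calibrate_threshold(
                    model.score(val_rows), val_rows["label"].to_numpy(),
                    config.target_sensitivity, config.sensitivity_tol,
                )

                stage = f"evaluate:{name}:seed{seed}"
                test_scores = model.score(test_rows)
                test_labels = test_rows["label"].to_numpy()
                rep = metric_report(test_scores, test_labels, choice.threshold,
                                    B=config.bootstrap_B, seed=seed)
                conf = site_confusions(test_scores, test_labels, test_rows["site"], choice.threshold)
                fair = equalized_odds_sd(conf)
                perf_rows.append(_report_row(name, seed, rep, fair))
                eo_rows.append({"model": name, "seed": seed, "eo_tp": fair.sd_tp, "eo_fp": fair.sd_fp,
                                "threshold": choice.threshold, "val_sensitivity": choice.sensitivity,
                                "feasible": choice.feasible})
                for z, site_rep in per_site_eval(test_scores, test_labels, test_rows["site"],
                                                 choice.threshold).items():
                    per_site_rows.append(_report_row(f"{name}@{z}", seed, site_rep, None) | {"site": z, "model": name})
                scores_tables[f"{name}_seed{seed}"] = pd.DataFrame(
                    {"score": test_scores, "label": test_labels, "site": test_rows["site"].to_numpy()}
                )

        bundle["performance"] = pd.DataFrame(perf_rows)
        bundle["equalized_odds"] = pd.DataFrame(eo_rows)
        bundle["per_site"] = pd.DataFrame(per_site_rows)
        bundle["drift"] = drift_report
        bundle["drifted_features"] = drifted
        bundle["dropped_features"] = dropped_features
        bundle["preprocess_state"] = state
        bundle["scores"] = scores_tables

        cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
        bundle["provenance"] = {
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seeds": list(config.seeds),
            "fairsite_version": __version__,
        }
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    if out is not None:
        bundle["performance"].to_csv(out / "table3.csv", index=False)
        bundle["equalized_odds"].to_csv(out / "table4.csv", index=False)
        for z, group in bundle["per_site"].groupby("site"):
            group.to_csv(out / f"table5_site_{z}.csv", index=False)
        drift_report.ks.to_csv(out / "drift.csv", index=False)
        (out / "drift.json").write_text(json.dumps(
            {"target_site": drift_report.target_site, "drifted_features": drifted,
             "entries": drift_report.ks.to_dict(orient="records")}, indent=2))
        for key, tab in scores_tables.items():
            tab.to_csv(out / f"scores_{key}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(bundle["provenance"], indent=2))
    return bundle
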