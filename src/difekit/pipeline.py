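"""Develop -> threshold -> validate orchestration with reproducibility metadata.

Each stage writes its artifacts plus a ``*_manifest.json`` recording the
seed, a SHA-256 hash of the effective configuration, the package version and
per-stage record counts, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, SyntheticCohortConfig, generate_cohort, good_survival_outcome, read_cohort
from .dife import DifeParameters, dife_scores
from .evaluation import (
    bootstrap_auc_ci,
    compare_auc_bootstrap,
    confusion_metrics,
    egfr_risk_scores,
    fit_logistic_comparator,
    km_estimate,
    logrank_test,
    mortality_rate_per100py,
    roc_auc,
)
from .tsfnn import DEFAULT_THRESHOLD_GRID, PsoConfig, fit_dife, remove_outliers, select_threshold
from .varselect import KlnnRbmConfig, search_subsets

__all__ = ["RunConfig", "run_develop", "run_validate"]

#: eGFR cutoffs (mL/min/1.73 m^2) swept for the conventional comparator.
EGFR_THRESHOLDS = (5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass
class RunConfig:
    """Configuration of a develop and/or validate run."""

    out_dir: str = "difekit_run"
    seed: int = 0
    development_cohort: str | None = None  # CSV path; None -> synthetic
    validation_cohort: str | None = None
    synthetic_n_development: int = 1281
    synthetic_n_validation: int = 504
    pso: PsoConfig | None = None
    klnn: KlnnRbmConfig | None = None
    run_varselect: bool = False
    varselect_strategy: str = "exhaustive_over_addons"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    threshold: float = 30.0
    n_boot: int = 2000
    outlier_rule: str = "zscore"
    outlier_cutoff: float = 4.0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        for key in ("pso", "klnn"):
            if payload[key] is not None and isinstance(payload[key].get("bounds"), np.ndarray):
                payload[key]["bounds"] = payload[key]["bounds"].tolist()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_manifest(path: Path, stage: str, config: RunConfig, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "difekit_version": __version__,
        **extra,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _load_or_generate(path: str | None, n: int, seed: int, label: str) -> Cohort:
    if path:
        return read_cohort(path, label=label)
    return generate_cohort(SyntheticCohortConfig(n=n, seed=seed, label=label))


def run_develop(config: RunConfig) -> dict[str, Path]:
    """Fit the equation on the development cohort and select the threshold.

    Artifacts: ``params.json``, ``threshold_report.csv``, optionally
    ``varselect_ranking.csv``, and ``develop_manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    cohort = _load_or_generate(
        config.development_cohort, config.synthetic_n_development, config.seed, "development"
    )
    n_raw = len(cohort)

    artifacts: dict[str, Path] = {}
    if config.run_varselect:
        klnn = config.klnn or KlnnRbmConfig(seed=config.seed)
        ranking = search_subsets(cohort, strategy=config.varselect_strategy, config=klnn)
        rank_df = pd.DataFrame(
            {
                "variables": ["+".join(r.variables) for r in ranking],
                "mean_accuracy": [r.mean_accuracy for r in ranking],
            }
        )
        artifacts["varselect_ranking"] = out / "varselect_ranking.csv"
        rank_df.to_csv(artifacts["varselect_ranking"], index=False)
        timings["varselect"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    cohort, removed = remove_outliers(cohort, config.outlier_rule, config.outlier_cutoff)
    pso = config.pso or PsoConfig(seed=config.seed)
    params, diagnostics = fit_dife(cohort, pso)
    timings["fit"] = time.perf_counter() - t1

    scores = dife_scores(cohort.df, params)
    y_poor = 1 - good_survival_outcome(cohort.df)
    report = select_threshold(
        scores,
        y_poor,
        candidates=config.thresholds,
        times=cohort.df["survival_months"],
        events=cohort.df["died_within_36m"],
    )

    artifacts["params"] = out / "params.json"
    params.to_json(artifacts["params"])
    artifacts["threshold_report"] = out / "threshold_report.csv"
    report.table.to_csv(artifacts["threshold_report"], index=False)
    artifacts["manifest"] = out / "develop_manifest.json"
    _write_manifest(
        artifacts["manifest"],
        "develop",
        config,
        {
            "n_records_raw": n_raw,
            "n_outliers_removed": len(removed),
            "n_records_fit": len(cohort),
            "chosen_threshold": report.chosen_threshold,
            "pso_iterations_used": diagnostics["n_iter"],
            "final_training_loss": float(diagnostics["loss_trace"][-1]),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        },
    )
    return artifacts


def run_validate(config: RunConfig, params_path: str | Path | None = None) -> dict[str, Path]:
    """Score the validation cohort and compute the comparison metrics.

    Artifacts: ``metrics.json`` (confusion metrics at the working threshold,
    four AUCs with bootstrap CIs, three paired-bootstrap comparison
    p-values, per-group mortality and the log-rank test),
    ``roc_comparison.csv``, ``km_groups.csv`` and ``validate_manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_path = Path(params_path or out / "params.json")
    if not params_path.exists():
        raise FileNotFoundError(f"parameter file not found: {params_path}")
    params = DifeParameters.from_json(params_path)

    cohort = _load_or_generate(
        config.validation_cohort, config.synthetic_n_validation, config.seed + 1, "validation"
    )
    df = cohort.df
    y_poor = 1 - good_survival_outcome(df)
    scores = dife_scores(df, params)
    pred_poor = (scores < config.threshold).astype(int)

    cm = confusion_metrics(pred_poor, y_poor)
    # risk orientation: higher = riskier
    risk = {
        "dife": -scores,
        "logistic": fit_logistic_comparator(df).predicted_risk,
        "egfr_cmdrd": egfr_risk_scores(df, "cmdrd"),
        "egfr_ckdepi": egfr_risk_scores(df, "ckdepi"),
    }
    aucs = {
        name: bootstrap_auc_ci(s, y_poor, n_boot=config.n_boot, seed=config.seed + 10 + i)
        for i, (name, s) in enumerate(risk.items())
    }
    comparisons = {
        f"dife_vs_{name}": compare_auc_bootstrap(
            risk["dife"], s, y_poor, n_boot=config.n_boot, seed=config.seed + 50 + i
        )
        for i, (name, s) in enumerate(risk.items())
        if name != "dife"
    }

    times = df["survival_months"].to_numpy(float)
    events = df["died_within_36m"].to_numpy(int)
    poor_mask = pred_poor == 1
    if poor_mask.any() and (~poor_mask).any():
        lr = logrank_test(
            times[poor_mask], events[poor_mask], times[~poor_mask], events[~poor_mask]
        )
        logrank_chi2, logrank_p = lr.chi2, lr.p_value
    else:
        logrank_chi2 = logrank_p = None  # degenerate split: one empty group

    # eGFR threshold sweep of the conventional assessment
    egfr = -risk["egfr_cmdrd"]
    sweep = []
    for thr in EGFR_THRESHOLDS:
        pred = (egfr < thr).astype(int)  # late start (low eGFR) predicted poor
        m = confusion_metrics(pred, y_poor)
        sweep.append(
            {"egfr_threshold": thr, "sensitivity": m.sensitivity, "specificity": m.specificity,
             "accuracy": m.accuracy}
        )

    metrics = {
        "threshold": config.threshold,
        "n": len(df),
        "n_pred_poor": int(poor_mask.sum()),
        "n_pred_good": int((~poor_mask).sum()),
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "accuracy": cm.accuracy,
        "auc": {
            name: {"auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high, "n_boot": r.n_boot}
            for name, r in aucs.items()
        },
        "auc_comparisons": {
            name: {"delta": c.delta, "p_value": c.p_value} for name, c in comparisons.items()
        },
        "mortality_per100py_pred_poor": (
            mortality_rate_per100py(times[poor_mask], events[poor_mask]) if poor_mask.any() else None
        ),
        "mortality_per100py_pred_good": (
            mortality_rate_per100py(times[~poor_mask], events[~poor_mask])
            if (~poor_mask).any()
            else None
        ),
        "logrank_chi2": logrank_chi2,
        "logrank_p": logrank_p,
        "egfr_threshold_sweep": sweep,
        "seed": config.seed,
    }

    artifacts: dict[str, Path] = {}
    artifacts["metrics"] = out / "metrics.json"
    artifacts["metrics"].write_text(json.dumps(metrics, indent=2, default=float) + "\n")

    roc_rows = [
        {"model": name, "auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for name, r in aucs.items()
    ]
    artifacts["roc_comparison"] = out / "roc_comparison.csv"
    pd.DataFrame(roc_rows).to_csv(artifacts["roc_comparison"], index=False)

    km_rows = []
    for label, mask in (("pred_poor", poor_mask), ("pred_good", ~poor_mask)):
        if not mask.any():
            continue
        curve = km_estimate(times[mask], events[mask])
        for t, s_val, n_at in zip(curve.times, curve.survival, curve.at_risk):
            km_rows.append({"group": label, "time_months": t, "survival": s_val, "at_risk": n_at})
    artifacts["km_groups"] = out / "km_groups.csv"
    pd.DataFrame(km_rows).to_csv(artifacts["km_groups"], index=False)

    artifacts["manifest"] = out / "validate_manifest.json"
    _write_manifest(
        artifacts["manifest"],
        "validate",
        config,
        {"n_records": len(df), "params_file": str(params_path)},
    )
    return artifacts
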