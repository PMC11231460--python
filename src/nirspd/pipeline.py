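"""End-to-end orchestration of the four-stage methodology.

Stages: load or synthesise a cohort → prune poor channels and correct
motion artifacts → extract the 792-column feature table → standardize →
select features under one of four settings → evaluate the final subset
with stratified k-fold logistic regression.

Settings
--------
``A_ensemble_then_wfss`` / ``A_ensemble_then_ga``
    Ensemble first stage (two-of-three filter vote swept over p=1..10 %,
    elastic-net and L1-SVM subsets, combined by union), then a wrapper
    or genetic-algorithm search restricted to the combined candidates.
``B_wfss_only`` / ``B_ga_only``
    The wrapper or genetic search alone over all extracted features.

Leakage modes
-------------
The default (full-cohort) mode standardizes and selects on the whole
cohort before cross-validation; its CV estimate is optimistically
biased because held-out subjects informed the selection.  ``leakage_mode="nested"`` additionally re-runs
standardization and selection inside each training fold and reports the
unbiased estimate alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import features as feat
from . import preprocess as pp
from . import ranking as rk
from . import subset_search as ss
from .exceptions import SpecError
from .model_eval import CVConfig, ConfusionCounts, fit_logistic, confusion_metrics, kfold_evaluate, roc_auc, Metrics
from .synthetic_data import Cohort, CohortSpec, SignalModel, generate_cohort, read_cohort

log = logging.getLogger("nirspd")

SETTINGS = ("A_ensemble_then_wfss", "A_ensemble_then_ga", "B_wfss_only", "B_ga_only")


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    spec: CohortSpec | None = None
    signal_model: SignalModel = field(default_factory=SignalModel)
    setting: str = "A_ensemble_then_ga"
    k_folds: int = 5
    ga: ss.GAConfig = field(default_factory=ss.GAConfig)
    quality_threshold: float = 0.7
    motion_correction: bool = True
    vote_percents: tuple = tuple(range(1, 11))
    leakage_mode: str = "full_cohort"  # or "nested"
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.spec is None):
            raise SpecError("exactly one of cohort_path or spec must be given")
        if self.setting not in SETTINGS:
            raise SpecError(f"unknown setting {self.setting!r}; choose from {SETTINGS}")
        if self.leakage_mode not in ("full_cohort", "nested"):
            raise SpecError(f"unknown leakage_mode {self.leakage_mode!r}")
        if self.k_folds < 2:
            raise SpecError("k_folds must be >= 2")
        self.ga.validate()


def _derive_seeds(root: int) -> dict[str, int]:
    """Every stage's randomness traces to the root seed via SeedSequence."""
    children = np.random.SeedSequence(root).spawn(5)
    names = ("cv", "ga", "ranking", "sweep", "nested")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _select(
    Xs: np.ndarray,
    y: np.ndarray,
    cfg: PipelineConfig,
    seeds: dict[str, int],
    artifacts: dict | None = None,
) -> rk.FeatureSubset:
    """Run the configured setting's selection on (already standardized) data."""
    d = Xs.shape[1]
    evaluator = ss.make_cv_evaluator(Xs, y, k=cfg.k_folds, seed=seeds["cv"])
    if cfg.setting.startswith("A_"):
        filters = [rk.mad_scores(Xs), rk.mig_scores(Xs, y), rk.fisher_scores(Xs, y)]
        vote_best, sweep_table = rk.vote_sweep(
            Xs, y, filters, evaluator, percents=cfg.vote_percents
        )
        enet = rk.elastic_net_subset(Xs, y, seed=seeds["ranking"])
        svm = rk.l1_svm_subset(Xs, y, seed=seeds["ranking"])
        combined = rk.ensemble_combine(vote_best, enet, svm)
        if artifacts is not None:
            artifacts["sweep_table"] = sweep_table
            artifacts["vote_best_size"] = vote_best.size
            artifacts["elastic_net_size"] = enet.size
            artifacts["l1_svm_size"] = svm.size
            artifacts["combined_size"] = combined.size
        universe = combined.indices
        Xu = Xs[:, universe]
    else:
        universe = np.arange(d)
        Xu = Xs
    sub_eval = ss.make_cv_evaluator(Xu, y, k=cfg.k_folds, seed=seeds["cv"])
    if cfg.setting.endswith("ga") or cfg.setting == "B_ga_only":
        ga_cfg = dataclasses.replace(cfg.ga, seed=seeds["ga"])
        sub, trace = ss.ga_select(Xu, y, sub_eval, ga_cfg, d=Xu.shape[1])
    else:
        sub, trace = ss.forward_wfss(Xu, y, sub_eval, d=Xu.shape[1])
    if artifacts is not None:
        artifacts["trace"] = trace
    mask = np.zeros(d, dtype=bool)
    mask[universe[sub.mask]] = True
    if not mask.any():
        # a degenerate search found nothing better than the empty set;
        # fall back to the single best-voted candidate so evaluation can run
        mask[universe[0] if len(universe) else 0] = True
    return rk.FeatureSubset(mask, f"{cfg.setting}")


def _nested_metrics(
    X: np.ndarray, y: np.ndarray, cfg: PipelineConfig, seeds: dict[str, int]
) -> dict:
    """Unbiased variant: standardization + selection inside each training fold."""
    from sklearn.model_selection import StratifiedKFold

    kf = StratifiedKFold(cfg.k_folds, shuffle=True, random_state=seeds["nested"])
    fold_metrics: list[Metrics] = []
    scores = np.empty(len(y))
    counts = None
    sizes = []
    for train, test in kf.split(X, y):
        Xtr, stats = pp.standardize(X[train])
        Xte = pp.apply_standardization(X[test], stats)
        subset = _select(Xtr, y[train], cfg, seeds)
        sizes.append(subset.size)
        model = fit_logistic(Xtr[:, subset.mask], y[train])
        prob = model.predict_proba(Xte[:, subset.mask])[:, 1]
        pred = (prob >= 0.5).astype(int)
        c = ConfusionCounts.from_predictions(y[test], pred)
        counts = c if counts is None else counts + c
        fold_metrics.append(confusion_metrics(c))
        scores[test] = prob
    defined = lambda vals: (
        float(np.mean([v for v in vals if v is not None]))
        if any(v is not None for v in vals) else None
    )
    return {
        "accuracy": float(np.mean([m.accuracy for m in fold_metrics])),
        "precision": defined([m.precision for m in fold_metrics]),
        "recall": defined([m.recall for m in fold_metrics]),
        "f1": defined([m.f1 for m in fold_metrics]),
        "auc": roc_auc(scores, y),
        "mean_subset_size": float(np.mean(sizes)),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline and return (and optionally write)
    the report: metrics, final subset, per-stage artifacts, seeds."""
    cfg.validate()
    seeds = _derive_seeds(cfg.seed)
    t0 = time.time()
    stage_info: dict = {}

    def stamp(stage: str, **extra):
        stage_info[stage] = {"t_elapsed_s": round(time.time() - t0, 3), **extra}
        log.info("stage %s done (%.1fs) %s", stage, time.time() - t0, extra)

    try:
        if cfg.cohort_path is not None:
            cohort = read_cohort(cfg.cohort_path)
        else:
            cohort = generate_cohort(cfg.spec, cfg.signal_model)
        stamp("load", n_subjects=len(cohort))

        pruned_records = []
        n_pruned = 0
        for rec in cohort.records:
            rec2, report = pp.prune_channels(rec, cfg.quality_threshold)
            n_pruned += int((~report.retained).sum())
            if cfg.motion_correction:
                rec2 = pp.correct_motion(rec2)
            pruned_records.append(rec2)
        cohort = Cohort(pruned_records)
        stamp("preprocess", channels_pruned_total=n_pruned,
              motion_correction=cfg.motion_correction)

        fm = feat.extract_feature_matrix(cohort)
        stamp("features", n_features=fm.n_features)

        X = fm.values
        y = fm.y
        Xs, stats = pp.standardize(X)
        stamp("standardize", zero_variance=int(stats.zero_variance.sum()))

        artifacts: dict = {}
        subset = _select(Xs, y, cfg, seeds, artifacts)
        stamp("select", subset_size=subset.size)

        cv = kfold_evaluate(Xs, y, subset.mask, CVConfig(cfg.k_folds, seed=seeds["cv"]))
        stamp("evaluate")

        report = {
            "config": {
                "setting": cfg.setting,
                "k_folds": cfg.k_folds,
                "leakage_mode": cfg.leakage_mode,
                "seed": cfg.seed,
                "ga": dataclasses.asdict(cfg.ga),
                "quality_threshold": cfg.quality_threshold,
                "motion_correction": cfg.motion_correction,
            },
            "seeds": seeds,
            "stages": stage_info,
            "n_subjects": len(y),
            "n_features": fm.n_features,
            "final_subset": {
                "size": subset.size,
                "features": [fm.feature_names[i] for i in subset.indices],
                "provenance": subset.provenance,
            },
            "metrics": cv.to_dict(),
        }
        if "sweep_table" in artifacts:
            report["ensemble"] = {
                "sweep_table": artifacts["sweep_table"],
                "vote_best_size": artifacts["vote_best_size"],
                "elastic_net_size": artifacts["elastic_net_size"],
                "l1_svm_size": artifacts["l1_svm_size"],
                "combined_size": artifacts["combined_size"],
            }
        if cfg.leakage_mode == "nested":
            report["nested_metrics"] = _nested_metrics(X, y, cfg, seeds)
        validate_report(report)
    except Exception as err:
        stage = list(stage_info)[-1] if stage_info else "load"
        err.args = (f"[after stage {stage!r}] {err.args[0] if err.args else err}",) + err.args[1:]
        raise

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        fm.to_csv(out / "features.csv")
        feat.write_feature_dictionary(out / "feature_dictionary.json")
        if "trace" in artifacts and artifacts["trace"].entries:
            artifacts["trace"].to_dataframe().to_csv(out / "search_trace.csv", index=False)
        (out / "final_subset.json").write_text(
            json.dumps(report["final_subset"], indent=2)
        )
        from .model_eval import format_results_table

        stage2 = "ga" if "ga" in cfg.setting else "wfss"
        (out / "results_table.txt").write_text(format_results_table([{
            "setting": cfg.setting.split("_")[0],
            "method": stage2,
            "k": cfg.k_folds,
            **{k: report["metrics"][k] for k in
               ("accuracy", "precision", "recall", "f1", "auc")},
            "n_features": report["final_subset"]["size"],
        }]) + "\n")
    return report


# Minimal structural schema for the report (types per key); kept as data so
# it can be published alongside serialized reports.
REPORT_SCHEMA: dict = {
    "config": dict,
    "seeds": dict,
    "stages": dict,
    "n_subjects": int,
    "n_features": int,
    "final_subset": dict,
    "metrics": dict,
}
_SUBSET_SCHEMA = {"size": int, "features": list, "provenance": str}
_METRIC_KEYS = ("k", "accuracy", "precision", "recall", "f1", "auc")


def validate_report(report: dict) -> None:
    """Check the report against the published structural schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise SpecError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise SpecError(f"report[{key!r}] must be {typ.__name__}")
    for key, typ in _SUBSET_SCHEMA.items():
        if not isinstance(report["final_subset"].get(key), typ):
            raise SpecError(f"final_subset[{key!r}] must be {typ.__name__}")
    for key in _METRIC_KEYS:
        if key not in report["metrics"]:
            raise SpecError(f"metrics missing key {key!r}")
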