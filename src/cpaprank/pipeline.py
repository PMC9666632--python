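"""End-to-end orchestration: logs -> features + outcomes -> model -> report.

``featurize_cohort`` runs the preprocessing chain (short-night filter,
weekly segmentation, adherence labeling, week-1 featurization) and drops
outcome-undefined patients (poor adherence already in week 1).
``run_experiment`` runs the full evaluation protocol on a cohort of logs:
lambda selection by five-fold cross-validated ranking accuracy, out-of-fold
PA risk scores, ROC/AUC and the Youden cutoff at the prediction horizon,
classification metrics at that cutoff, a full-data refit, and the
top-factor report — everything collected in one JSON-serializable dict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .adherence import UNDEFINED, AdherenceOutcome, compute_outcome, label_week
from .evaluation import (
    DEFAULT_LAMBDA_GRID,
    auc,
    classification_metrics,
    cross_val_ranking_accuracy,
    horizon_labels,
    make_cv_plan,
    roc_curve,
    select_lambda,
    top_factors,
    youden_cutoff,
)
from .features import FeatureSchema, Standardizer
from .model import ModelConfig, build_pairs, fit, predict_poor_within_horizon, risk_score
from .records import PatientLog, apply_short_night_filter, segment_weeks
from .synthetic import CohortSpec, GroundTruth, recovery_report, simulate_cohort

__all__ = ["CohortData", "featurize_cohort", "run_experiment"]


@dataclass(frozen=True)
class CohortData:
    """Encoded week-k features and outcomes for the modeled patients."""

    ids: tuple[str, ...]
    outcomes: tuple[AdherenceOutcome, ...]
    features: dict  # id -> raw (unstandardized) encoded vector
    schema: FeatureSchema
    n_undefined: int
    n_no_data: int


def featurize_cohort(
    logs: Sequence[PatientLog],
    schema: FeatureSchema | None = None,
    week: int = 1,
    max_weeks: int | None = None,
    min_minutes: float = 30.0,
    filter_scope: str = "physio",
    nightly_min: float = 240.0,
    nights_required: int = 5,
) -> CohortData:
    """Filter, segment, label, and featurize a cohort of patient logs.

    Patients without a complete week ``week`` are dropped (no usable data);
    patients whose first week is already poor have an undefined outcome and
    are dropped from modeling, counted in ``n_undefined``.
    """
    schema = schema or FeatureSchema()
    outcomes: list[AdherenceOutcome] = []
    features: dict = {}
    n_undefined = 0
    n_no_data = 0
    for log in logs:
        filtered = apply_short_night_filter(log, min_minutes, filter_scope)
        windows = segment_weeks(filtered, max_weeks)
        if len(windows) < week:
            n_no_data += 1
            continue
        labels = [label_week(w, nightly_min, nights_required) for w in windows]
        outcome = compute_outcome(log.patient_id, labels)
        if outcome.kind == UNDEFINED:
            n_undefined += 1
            continue
        from .features import compute_weekly_features

        wf = compute_weekly_features(
            windows[week - 1], sex=log.sex, cpap_mode=log.modal_mode
        )
        features[log.patient_id] = schema.encode(wf)
        outcomes.append(outcome)
    return CohortData(
        ids=tuple(o.patient_id for o in outcomes),
        outcomes=tuple(outcomes),
        features=features,
        schema=schema,
        n_undefined=n_undefined,
        n_no_data=n_no_data,
    )


def run_experiment(
    logs: Sequence[PatientLog],
    seed: int,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    k: int = 5,
    horizon: int = 12,
    step: float = 0.5,
    schema: FeatureSchema | None = None,
    config: ModelConfig | None = None,
    truth: GroundTruth | None = None,
    week: int = 1,
) -> dict:
    """Run the full evaluation protocol on a cohort of logs.

    ``seed`` controls the cross-validation fold assignment.  When ``truth``
    from the synthetic generator is supplied, a weight-recovery summary is
    appended.  The returned dict is deterministic given (logs, seed) and
    JSON-serializable.
    """
    cohort = featurize_cohort(logs, schema=schema, week=week)
    plan = make_cv_plan(cohort.ids, k=k, seed=seed)
    selection = select_lambda(cohort.features, cohort.outcomes, plan, lambda_grid, config)
    accs, oof_scores = cross_val_ranking_accuracy(
        cohort.features, cohort.outcomes, plan, selection.best_lam, config
    )

    labels = horizon_labels(cohort.outcomes, horizon=horizon)
    labeled_ids = [pid for pid in cohort.ids if pid in labels]
    s = [oof_scores[pid] for pid in labeled_ids]
    y = [labels[pid] for pid in labeled_ids]
    curve = roc_curve(s, y, step=step)
    cutoff = youden_cutoff(curve)
    preds = [predict_poor_within_horizon(v, cutoff) for v in s]
    metrics = classification_metrics(preds, y)

    # full-data refit for the factor report
    X = np.asarray([cohort.features[pid] for pid in cohort.ids], dtype=float)
    std = Standardizer().fit(X)
    z = {pid: std.transform(cohort.features[pid]) for pid in cohort.ids}
    base = config or ModelConfig()
    w_full = fit(
        build_pairs(cohort.outcomes, z),
        ModelConfig(lam=selection.best_lam, tol=base.tol, max_iter=base.max_iter),
    )
    factors = top_factors(w_full, cohort.schema.columns, k=10)

    lam_means = [v["mean"] for v in selection.table.values() if v.get("mean") is not None]
    valid_accs = [a for a in accs if a is not None]
    report = {
        "n_patients": len(logs),
        "n_modeled": len(cohort.ids),
        "n_undefined": cohort.n_undefined,
        "n_no_data": cohort.n_no_data,
        "cv": {
            "k": k,
            "seed": seed,
            "per_lambda": {
                str(lam): selection.table[lam] for lam in lambda_grid if lam in selection.table
            },
            "best_lambda": selection.best_lam,
            "best_lambda_accuracy_mean": float(np.mean(valid_accs)) if valid_accs else None,
            "best_lambda_accuracy_sd_over_folds": (
                float(np.std(valid_accs, ddof=1)) if len(valid_accs) > 1 else None
            ),
            "accuracy_sd_over_lambdas": (
                float(np.std(lam_means, ddof=1)) if len(lam_means) > 1 else None
            ),
        },
        "horizon_weeks": horizon,
        "roc": {
            "step": step,
            "thresholds": [float(t) for t in curve.thresholds],
            "tpr": [float(t) for t in curve.tpr],
            "fpr": [float(t) for t in curve.fpr],
        },
        "auc": auc(curve),
        "youden_cutoff": cutoff,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
        "top_factors": [
            {"name": f.name, "weight": f.weight, "implication": f.implication}
            for f in factors
        ],
        "weights": {c: float(v) for c, v in zip(cohort.schema.columns, w_full)},
    }
    if truth is not None:
        report["recovery"] = recovery_report(w_full, cohort.schema.columns, truth)
    return report
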