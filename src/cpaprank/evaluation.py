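"""Evaluation protocol: cross-validated ranking accuracy for lambda
selection, ROC/AUC with the Youden cutoff at a fixed prediction horizon,
classification metrics, and the top-factor report.

Ranking accuracy is pairwise concordance on comparable held-out pairs (same
comparability rules as training: PA < PA or PA < GA): the fraction of pairs
in which the earlier-poor patient received the strictly larger risk score,
with score ties counting one half.  The ROC is swept in fixed increments of
the risk score (0.5 by default), the AUC is the trapezoidal area, and the
operating cutoff maximizes the Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .adherence import GA, PA, AdherenceOutcome
from .features import Standardizer
from .model import ModelConfig, build_pairs, comparable, fit, risk_score

__all__ = [
    "CVPlan",
    "ROCCurve",
    "Factor",
    "Metrics",
    "LambdaSelection",
    "DEFAULT_LAMBDA_GRID",
    "make_cv_plan",
    "ranking_accuracy",
    "cross_val_ranking_accuracy",
    "select_lambda",
    "horizon_labels",
    "roc_curve",
    "auc",
    "youden_cutoff",
    "classification_metrics",
    "top_factors",
]

#: The lambda grid searched by cross-validated ranking accuracy.
DEFAULT_LAMBDA_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass(frozen=True)
class CVPlan:
    """Patient-level k-fold partition, reproducible from its seed."""

    k: int
    seed: int
    folds: tuple[tuple[str, ...], ...]


def make_cv_plan(patient_ids: Sequence[str], k: int = 5, seed: int = 0) -> CVPlan:
    """Partition patients into k folds of near-equal size (difference <= 1).

    Ids are sorted before shuffling, so the plan depends only on the set of
    patients and the seed, not on input order.
    """
    ids = sorted(set(patient_ids))
    n = len(ids)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} patients")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    base, extra = divmod(n, k)
    folds = []
    pos = 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        folds.append(tuple(perm[pos : pos + size]))
        pos += size
    return CVPlan(k=k, seed=seed, folds=tuple(folds))


def ranking_accuracy(
    scores: Mapping[str, float],
    outcomes: Sequence[AdherenceOutcome],
) -> float | None:
    """Concordance of risk scores with outcome order on comparable pairs.

    Returns ``None`` (not 0) when no comparable pair exists among the
    scored patients.
    """
    outs = [o for o in outcomes if o.patient_id in scores]
    hits = 0.0
    total = 0
    for m in outs:
        for n in outs:
            if m.patient_id == n.patient_id or not comparable(m, n):
                continue
            total += 1
            sm, sn = scores[m.patient_id], scores[n.patient_id]
            if sm > sn:
                hits += 1.0
            elif sm == sn:
                hits += 0.5
    if total == 0:
        return None
    return hits / total


def cross_val_ranking_accuracy(
    features: Mapping[str, np.ndarray],
    outcomes: Sequence[AdherenceOutcome],
    plan: CVPlan,
    lam: float,
    config: ModelConfig | None = None,
) -> tuple[list[float | None], dict[str, float]]:
    """Per-fold held-out ranking accuracy at one lambda.

    The standardizer is refitted on each training fold (no leakage into the
    held-out fold).  Returns the per-fold accuracies and the pooled
    out-of-fold risk scores keyed by patient.
    """
    base = config or ModelConfig()
    accs: list[float | None] = []
    oof_scores: dict[str, float] = {}
    for fold in plan.folds:
        test_ids = set(fold)
        train = [o for o in outcomes if o.patient_id not in test_ids]
        test = [o for o in outcomes if o.patient_id in test_ids]
        X_train = np.asarray([features[o.patient_id] for o in train], dtype=float)
        std = Standardizer().fit(X_train)
        z = {o.patient_id: std.transform(features[o.patient_id]) for o in outcomes}
        pairs = build_pairs(train, z)
        cfg = ModelConfig(lam=lam, tol=base.tol, max_iter=base.max_iter, init=base.init)
        w_hat = fit(pairs, cfg)
        fold_scores = {o.patient_id: risk_score(w_hat, z[o.patient_id]) for o in test}
        oof_scores.update(fold_scores)
        accs.append(ranking_accuracy(fold_scores, test))
    return accs, oof_scores


@dataclass(frozen=True)
class LambdaSelection:
    best_lam: float
    table: dict  # lam -> {"mean": float, "sd": float, "folds": list}


def select_lambda(
    features: Mapping[str, np.ndarray],
    outcomes: Sequence[AdherenceOutcome],
    plan: CVPlan,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    config: ModelConfig | None = None,
) -> LambdaSelection:
    """Choose lambda maximizing mean cross-validated ranking accuracy.

    A lambda whose folds all fail (no comparable pair, or no convergence)
    is marked failed and excluded from selection; ties in the mean go to
    the smaller lambda.
    """
    table: dict = {}
    best_lam = None
    best_mean = -np.inf
    for lam in grid:
        try:
            accs, _ = cross_val_ranking_accuracy(features, outcomes, plan, lam, config)
        except Exception as exc:  # fold failed to fit
            table[lam] = {"mean": None, "sd": None, "folds": None, "error": str(exc)}
            continue
        valid = [a for a in accs if a is not None]
        if not valid:
            table[lam] = {"mean": None, "sd": None, "folds": accs}
            continue
        mean = float(np.mean(valid))
        sd = float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0
        table[lam] = {"mean": mean, "sd": sd, "folds": accs}
        if mean > best_mean:
            best_mean, best_lam = mean, lam
    if best_lam is None:
        raise ValueError("every lambda in the grid failed")
    return LambdaSelection(best_lam=best_lam, table=table)


def horizon_labels(
    outcomes: Sequence[AdherenceOutcome],
    horizon: int = 12,
) -> dict[str, bool]:
    """Binary poor-within-horizon labels; censored-early patients excluded.

    PA with t <= horizon is positive; PA with t > horizon, or GA observed
    good through the horizon, is negative; GA censored before the horizon
    is omitted (true label unknown).
    """
    labels: dict[str, bool] = {}
    for o in outcomes:
        if o.kind == PA:
            labels[o.patient_id] = o.t <= horizon
        elif o.kind == GA:
            if o.t >= horizon:
                labels[o.patient_id] = False
    return labels


@dataclass(frozen=True)
class ROCCurve:
    """ROC points swept over a fixed threshold grid (descending sens order)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    step: float = 0.5,
) -> ROCCurve:
    """ROC over thresholds from min(score) - step to max(score) + step.

    A patient is predicted positive iff score >= threshold, so the extreme
    thresholds always contribute the degenerate corners (1, 1) and (0, 0).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    lo = s.min() - step
    hi = s.max() + step
    n_steps = int(math.ceil((hi - lo) / step))
    thresholds = lo + step * np.arange(n_steps + 1)
    pred = s[None, :] >= thresholds[:, None]
    tpr = (pred & y).sum(axis=1) / n_pos
    fpr = (pred & ~y).sum(axis=1) / n_neg
    return ROCCurve(thresholds=thresholds, tpr=tpr.astype(float), fpr=fpr.astype(float))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Sensitivity and FPR are both non-increasing in the threshold, so
    traversing thresholds in descending order walks the curve from (0, 0)
    to (1, 1); vertical segments (tied FPR) then contribute zero width.
    """
    order = np.argsort(-curve.thresholds, kind="stable")
    return float(np.trapezoid(curve.tpr[order], curve.fpr[order]))


def youden_cutoff(curve: ROCCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1 (ties: smaller)."""
    j = curve.tpr - curve.fpr
    best = j.max()
    candidates = curve.thresholds[j >= best - 1e-12]
    return float(candidates.min())


@dataclass(frozen=True)
class Metrics:
    precision: float | None
    recall: float | None
    f1: float | None


def classification_metrics(
    predictions: Sequence[bool],
    labels: Sequence[bool],
) -> Metrics:
    """Precision, recall, F1 = 2PR/(P+R); undefined terms reported as None."""
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must align")
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, f1=f1)


@dataclass(frozen=True)
class Factor:
    name: str
    weight: float
    implication: str


def top_factors(
    w_hat: np.ndarray,
    names: Sequence[str],
    k: int = 10,
) -> list[Factor]:
    """The k features with the largest |weight|, in descending order.

    A positive weight associates larger (standardized) feature values with
    earlier poor adherence; a negative weight with later or no poor
    adherence.  Deterministic for tied magnitudes (stable sort by input
    position).  If k exceeds the dimension the list is truncated.
    """
    w_hat = np.asarray(w_hat, dtype=float)
    if len(names) != w_hat.shape[0]:
        raise ValueError("names and weights must align")
    order = np.argsort(-np.abs(w_hat), kind="stable")[: min(k, len(names))]
    out = []
    for i in order:
        direction = "earlier poor adherence" if w_hat[i] > 0 else (
            "later/never poor adherence" if w_hat[i] < 0 else "no association"
        )
        out.append(
            Factor(
                name=names[i],
                weight=float(w_hat[i]),
                implication=f"larger value associated with {direction}",
            )
        )
    return out
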