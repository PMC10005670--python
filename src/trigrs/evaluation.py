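"""Discrimination-performance protocol for the risk scores.

Mirrors the study's evaluation design: a stratified 50/50 train/test
split of the labelled cohort, tenfold cross-validation of the logistic
response model inside the training half, a single held-out evaluation
on the test half, and the metric panel — accuracy (Clopper-Pearson CI),
AUC-ROC (DeLong CI), sensitivity/specificity on the responder class,
and McFadden's pseudo-R2.

``run_prediction_protocol`` additionally derives the per-SNP scores
from the training half only, so that the held-out metrics are free of
score-selection leakage (needed for honest null calibration; with a
genuinely separating panel the estimated signs coincide with the
full-cohort ones almost surely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, ResponseLabel
from .models import ResponseModel
from .scoring import ScoreSet, estimate_scores, grs_profiles

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "stratified_split",
    "auc_roc",
    "confusion_metrics",
    "cross_validate",
    "run_prediction_protocol",
    "ProtocolResult",
]


@dataclass
class SplitPlan:
    """A reproducible stratified split with a fold assignment in training."""

    seed: int
    train_ids: list
    test_ids: list
    fold_assignment: dict  # train id -> fold number 1..k

    @property
    def n_folds(self) -> int:
        return len(set(self.fold_assignment.values()))

    def fold_ids(self, fold: int) -> list:
        return [i for i in self.train_ids if self.fold_assignment[i] == fold]


def stratified_split(
    labels: pd.Series,
    fraction: float = 0.5,
    seed: int = 0,
    folds: int = 10,
) -> SplitPlan:
    """Deterministic stratified train/test split plus training folds.

    ``labels`` is a binary (or two-valued) Series indexed by subject id.
    The responder:nonresponder ratio of each part matches the overall
    ratio to within one subject; folds partition the training ids with
    the same stratification property.
    """
    if not 0 < fraction < 1:
        raise ValueError("train fraction must be in (0, 1)")
    labels = pd.Series(labels)
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError("stratified split requires exactly two classes")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")

    rng = np.random.default_rng(seed)
    n_train_total = int(round(len(labels) * fraction))
    # largest-remainder apportionment of training slots across classes
    quotas = {c: counts[c] * fraction for c in classes}
    base = {c: int(np.floor(quotas[c])) for c in classes}
    leftover = n_train_total - sum(base.values())
    order = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
    for c in order[:leftover]:
        base[c] += 1

    train_ids, test_ids, fold_assignment = [], [], {}
    for c in sorted(classes, key=str):
        ids = np.array(sorted(labels.index[labels == c]))
        rng.shuffle(ids)
        n_train = base[c]
        cls_train = list(ids[:n_train])
        train_ids += cls_train
        test_ids += list(ids[n_train:])
        for pos, sid in enumerate(cls_train):
            fold_assignment[sid] = pos % folds + 1
    if not test_ids:
        raise ValueError("split leaves an empty test set")
    return SplitPlan(seed, train_ids, test_ids, fold_assignment)


def _delong_ci(pos_scores, neg_scores, alpha=0.05):
    """DeLong standard error and Wald CI for the AUC."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = rankdata(combined)
    v10 = (r_all[:m] - rankdata(pos)) / n  # placements of positives
    v01 = 1.0 - (r_all[m:] - rankdata(neg)) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(1 - alpha / 2)
    return auc, max(auc - z * se, 0.0), min(auc + z * se, 1.0)


def auc_roc(scores, labels) -> tuple:
    """AUC-ROC with a 95% DeLong confidence interval.

    ``labels`` marks the positive class (responders); ``scores`` are
    predicted positive-class probabilities or any monotone score.  Ties
    count one half (Mann-Whitney convention).  Constant scores give AUC
    0.5 with a degenerate CI and a warning.

    Returns
    -------
    (auc, (ci_low, ci_high))
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("AUC requires both classes present")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC 0.5 with degenerate CI", stacklevel=2)
        return 0.5, (np.nan, np.nan)
    auc = float(roc_auc_score(y.astype(int), scores))
    _, lo, hi = _delong_ci(scores[y], scores[~y])
    return auc, (float(lo), float(hi))


def confusion_metrics(predicted, actual) -> dict:
    """Accuracy, sensitivity, specificity from binary predictions.

    Positive class = responder.  Accuracy carries an exact binomial
    (Clopper-Pearson) 95% CI; sensitivity/specificity are NaN when the
    corresponding actual class is absent.
    """
    pred = np.asarray(predicted).astype(bool)
    act = np.asarray(actual).astype(bool)
    if len(pred) != len(act):
        raise ValueError("prediction and truth lengths differ")
    n = len(act)
    correct = int((pred == act).sum())
    accuracy = correct / n
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    sensitivity = float((pred & act).sum() / act.sum()) if act.any() else np.nan
    specificity = float((~pred & ~act).sum() / (~act).sum()) if (~act).any() else np.nan
    return {
        "accuracy": accuracy,
        "accuracy_ci": (float(lo), float(hi)),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "n": n,
    }


@dataclass
class MetricsReport:
    """The metric panel on one dataset (train folds, cv mean, or test)."""

    dataset_tag: str
    n: int
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    mcfadden: float
    accuracy_ci: tuple | None = None
    auc_ci: tuple | None = None
    skipped_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "dataset": self.dataset_tag,
            "n": self.n,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcfadden": self.mcfadden,
        }
        if self.accuracy_ci is not None:
            out["accuracy_ci_low"], out["accuracy_ci_high"] = self.accuracy_ci
        if self.auc_ci is not None:
            out["auc_ci_low"], out["auc_ci_high"] = self.auc_ci
        return out


def _evaluate(results, design, y, tag, with_ci=False, skipped=None,
              threshold=0.5, mcfadden=None) -> MetricsReport:
    probs = results.predict(design)
    pred = probs >= threshold
    conf = confusion_metrics(pred, y)
    if np.ptp(probs.to_numpy()) == 0:
        auc, ci = 0.5, (np.nan, np.nan)
    else:
        auc, ci = auc_roc(probs, y)
    # pseudo-R2 is a likelihood quantity, well defined in-sample only:
    # unless supplied by the caller, refit the same specification on the
    # evaluation data (out-of-sample discrimination is carried by
    # AUC/accuracy, not by McFadden)
    if mcfadden is None:
        try:
            mcf = ResponseModel(y, design).fit().mcfadden
        except ValueError:
            mcf = np.nan
    else:
        mcf = mcfadden
    return MetricsReport(
        dataset_tag=tag,
        n=conf["n"],
        accuracy=conf["accuracy"],
        auc=auc,
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        mcfadden=mcf,
        accuracy_ci=conf["accuracy_ci"] if with_ci else None,
        auc_ci=ci if with_ci else None,
        skipped_folds=skipped or [],
    )


def cross_validate(
    cohort: Cohort,
    score_set: ScoreSet | None,
    covariates: Sequence[str],
    plan: SplitPlan,
    weighted: bool = False,
    threshold: float = 0.5,
    grs: pd.Series | None = None,
) -> tuple:
    """K-fold cross-validation in training plus one held-out test evaluation.

    Per fold, the logistic model (GRS + covariates) is fitted on the
    remaining folds and evaluated on the held-out fold; the CV report is
    the unweighted mean of fold metrics.  The final model is refitted on
    the full training set and evaluated once on the test set with
    confidence intervals.  Folds whose held-out part contains a single
    class are skipped with a warning and listed in the report.

    The per-subject GRS is computed from ``score_set`` unless a
    precomputed ``grs`` series (indexed by subject id) is supplied.
    """
    if grs is None:
        if score_set is None:
            raise ValueError("either a score set or a precomputed GRS is required")
        grs = grs_profiles(cohort, [score_set], weighted=weighted)[score_set.name]
    pheno = cohort.phenotype_frame()

    def build(ids):
        sub = pheno.loc[ids]
        y = (sub["response"] == ResponseLabel.responder.value).astype(float)
        design = pd.DataFrame(index=sub.index)
        for cov in covariates:
            if cov == "sex":
                design["sex"] = (sub["sex"] == "male").astype(float)
            else:
                design[cov] = sub[cov].astype(float)
        design["grs"] = grs.loc[ids].astype(float)
        return y, design

    fold_reports, skipped = [], []
    for fold in range(1, plan.n_folds + 1):
        held = plan.fold_ids(fold)
        rest = [i for i in plan.train_ids if plan.fold_assignment[i] != fold]
        if not held:
            continue
        y_held, X_held = build(held)
        if y_held.nunique() < 2:
            warnings.warn(f"fold {fold} has a single class; skipped", stacklevel=2)
            skipped.append(fold)
            continue
        y_rest, X_rest = build(rest)
        res = ResponseModel(y_rest, X_rest).fit()
        fold_reports.append(
            _evaluate(res, X_held, y_held, tag=f"fold{fold}", threshold=threshold,
                      mcfadden=res.mcfadden)
        )

    if not fold_reports:
        raise ValueError("no usable folds in the cross-validation plan")
    cv_report = MetricsReport(
        dataset_tag="cv_mean",
        n=sum(r.n for r in fold_reports),
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        auc=float(np.mean([r.auc for r in fold_reports])),
        sensitivity=float(np.nanmean([r.sensitivity for r in fold_reports])),
        specificity=float(np.nanmean([r.specificity for r in fold_reports])),
        mcfadden=float(np.mean([r.mcfadden for r in fold_reports])),
        skipped_folds=skipped,
    )

    y_train, X_train = build(plan.train_ids)
    final = ResponseModel(y_train, X_train).fit()
    y_test, X_test = build(plan.test_ids)
    test_report = _evaluate(final, X_test, y_test, tag="test", with_ci=True,
                            threshold=threshold)
    train_report = _evaluate(final, X_train, y_train, tag="train", with_ci=True,
                             threshold=threshold, mcfadden=final.mcfadden)
    return cv_report, test_report, train_report


@dataclass
class ProtocolResult:
    score_set: ScoreSet
    plan: SplitPlan
    cv_report: MetricsReport
    test_report: MetricsReport
    train_report: MetricsReport


def run_prediction_protocol(
    cohort: Cohort,
    variant_ids: Sequence[str] | None = None,
    covariates: Sequence[str] = (),
    fraction: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    weighted: bool = False,
    score_set: ScoreSet | None = None,
) -> ProtocolResult:
    """Full split -> score -> cross-validate -> test pipeline.

    When no pre-built ``score_set`` is given, per-SNP scores are
    estimated from the training half only (see module docstring).
    """
    labels = cohort.labels()
    labels = labels[labels != ResponseLabel.unclassified.value]
    plan = stratified_split(labels, fraction=fraction, seed=seed, folds=folds)
    if score_set is None:
        score_set = estimate_scores(cohort, variant_ids=variant_ids,
                                    subject_ids=plan.train_ids)
    cv_report, test_report, train_report = cross_validate(
        cohort, score_set, covariates, plan, weighted=weighted
    )
    return ProtocolResult(score_set, plan, cv_report, test_report, train_report)
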