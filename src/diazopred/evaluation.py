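"""Cross-validated evaluation of the nearest-neighbor classifier.

Two protocols:

* leave-one-out (LOOCV): every labeled metabolite is predicted from all the
  others; the pooled holdout predictions give a single confusion matrix and
  metric set.
* repeated stratified k-fold: per repeat, the data are split into k
  class-balanced folds, each fold held out once, the k holdout folds pooled,
  and one metric set computed.  Each repeat is the unit of observation for
  the mean, the t-based 95% confidence interval and the one-sided t-test of
  ROC-AUC against the chance value 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import Dataset, MetaboliteRecord
from .fingerprints import FingerprintConfig, fingerprint_dataset
from .scoring import PredictionResult, nearest_labeled_neighbor, predict

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at the 0.5 decision threshold; positive class = FIX 1."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def to_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVReport:
    protocol: str
    k: int
    repeats: int
    seed: Optional[int]
    per_repeat: list = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)
    auc_p_value: Optional[float] = None
    confusion: Optional[ConfusionMatrix] = None
    predictions: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "per_repeat": [m.to_dict() for m in self.per_repeat],
            "mean": self.mean,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "auc_p_value": self.auc_p_value,
            "confusion": self.confusion.to_dict() if self.confusion else None,
            "metadata": self.metadata,
        }


def compute_metrics(
    y_true: Sequence[int], probabilities: Sequence[float]
) -> tuple[MetricSet, ConfusionMatrix]:
    """Threshold metrics at 0.5 plus rank-based ROC-AUC.

    AUC is the Mann–Whitney statistic (midranks for tied probabilities), i.e.
    the probability a random positive scores above a random negative.
    Precision or recall with a zero denominator is reported as 0 and logged.
    """
    y_true = np.asarray(y_true, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    if y_true.size == 0:
        raise ValueError("no predictions to evaluate")
    y_pred = (probabilities > 0.5).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)

    accuracy = (tp + tn) / cm.n
    if tp + fp == 0:
        log.info("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        log.info("no positive truths; recall reported as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)

    if len(set(y_true.tolist())) < 2:
        raise ValueError("AUC requires both classes among the true labels")
    auc = float(roc_auc_score(y_true, probabilities))
    return MetricSet(accuracy, precision, recall, f1, auc), cm


def majority_baseline(labeled: Sequence[MetaboliteRecord]) -> float:
    """Accuracy of always predicting the majority class."""
    labels = [r.fix_label for r in labeled]
    if not labels:
        raise ValueError("empty labeled set")
    n_pos = sum(1 for v in labels if v == 1)
    return max(n_pos, len(labels) - n_pos) / len(labels)


def _holdout_predictions(
    holdout_ids: Sequence[str],
    fingerprints: dict,
    classes: dict,
) -> list[PredictionResult]:
    """Score each holdout id against all non-holdout labeled fingerprints."""
    holdout = set(holdout_ids)
    references = {
        cid: (fingerprints[cid], classes[cid])
        for cid in fingerprints
        if cid not in holdout
    }
    out = []
    for cid in holdout_ids:
        sim = nearest_labeled_neighbor(cid, fingerprints[cid], references)
        out.append(predict(sim))
    return out


def loocv(
    labeled, config: FingerprintConfig = FingerprintConfig()
) -> CVReport:
    """Leave-one-out cross-validation of the nearest-neighbor scorer.

    ``labeled`` is a Dataset or a sequence of labeled records spanning both
    classes.  Every record is held out once and predicted from the rest; the
    pooled holdout predictions yield the confusion matrix and metrics.
    """
    records = _as_labeled_records(labeled)
    classes = {r.compound_id: r.fix_label for r in records}
    if len(set(classes.values())) < 2:
        raise ValueError("LOOCV needs both classes (AUC undefined otherwise)")
    fingerprints, skipped = fingerprint_dataset(records, config)
    for cid, reason in skipped:
        log.warning("skipping %s in LOOCV: %s", cid, reason)
        del classes[cid]

    predictions = []
    for cid in fingerprints:
        sim = nearest_labeled_neighbor(
            cid,
            fingerprints[cid],
            {k: (fingerprints[k], classes[k]) for k in fingerprints},
            exclude={cid},
        )
        predictions.append(predict(sim))
    y_true = [classes[p.query_id] for p in predictions]
    probs = [p.probability for p in predictions]
    metrics, cm = compute_metrics(y_true, probs)
    return CVReport(
        protocol="loocv",
        k=len(predictions),
        repeats=1,
        seed=None,
        per_repeat=[metrics],
        mean=metrics.to_dict(),
        ci_lower={},
        ci_upper={},
        auc_p_value=None,
        confusion=cm,
        predictions=predictions,
        metadata={"n": len(predictions), "skipped": skipped,
                  "fingerprint": config.__dict__.copy()},
    )


def repeated_stratified_kfold(
    labeled,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    config: FingerprintConfig = FingerprintConfig(),
) -> CVReport:
    """Repeated stratified k-fold CV with per-repeat pooled holdout metrics.

    Fold class counts within a class differ by at most one (stratification).
    The 95% confidence interval uses Student t with repeats-1 degrees of
    freedom; the AUC-above-chance p-value is a one-sided one-sample t-test of
    the per-repeat AUCs against 0.5.  Zero variance across repeats degenerates
    to p = 0 when the mean exceeds 0.5 and p = 1 otherwise.
    """
    ids, classes, counts, fingerprints, skipped = _prepare_cv(labeled, k, config)

    per_repeat: list[MetricSet] = []
    for repeat in range(repeats):
        pooled_true, pooled_probs = _one_kfold_pass(
            ids, classes, fingerprints, k, random_state=(seed + repeat) % (2**31)
        )
        metrics, _ = compute_metrics(pooled_true, pooled_probs)
        per_repeat.append(metrics)

    mean, lower, upper = {}, {}, {}
    for name in METRIC_NAMES:
        values = np.array([getattr(m, name) for m in per_repeat])
        mean[name] = float(values.mean())
        if repeats > 1 and values.std(ddof=1) > 0:
            half = float(
                stats.t.ppf(0.975, repeats - 1)
                * values.std(ddof=1) / math.sqrt(repeats)
            )
        else:
            half = 0.0
        lower[name] = mean[name] - half
        upper[name] = mean[name] + half

    aucs = np.array([m.auc for m in per_repeat])
    if aucs.std(ddof=1) == 0:
        p_value = 0.0 if aucs.mean() > 0.5 else 1.0
    else:
        p_value = float(
            stats.ttest_1samp(aucs, 0.5, alternative="greater").pvalue
        )

    return CVReport(
        protocol="repeated_kfold",
        k=k,
        repeats=repeats,
        seed=seed,
        per_repeat=per_repeat,
        mean=mean,
        ci_lower=lower,
        ci_upper=upper,
        auc_p_value=p_value,
        confusion=None,
        metadata={
            "n": len(ids),
            "class_counts": counts,
            "skipped": skipped,
            "ci_method": "student_t_df_repeats_minus_1",
            "fingerprint": config.__dict__.copy(),
        },
    )


def _prepare_cv(labeled, k: int, config: FingerprintConfig):
    """Shared CV setup: labeled records, class map, counts, fingerprints."""
    records = _as_labeled_records(labeled)
    classes = {r.compound_id: r.fix_label for r in records}
    counts = {c: sum(1 for v in classes.values() if v == c) for c in (0, 1)}
    if min(counts.values()) < k:
        raise ValueError(f"each class needs at least k={k} members; have {counts}")
    fingerprints, skipped = fingerprint_dataset(records, config)
    for cid, reason in skipped:
        log.warning("skipping %s in CV: %s", cid, reason)
        del classes[cid]
    ids = sorted(fingerprints)
    return ids, classes, counts, fingerprints, skipped


def _one_kfold_pass(ids, classes, fingerprints, k, random_state):
    """One stratified k-fold pass; returns pooled (true labels, probabilities)."""
    y = np.array([classes[cid] for cid in ids])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    pooled_true: list[int] = []
    pooled_probs: list[float] = []
    for _, test_idx in splitter.split(np.zeros(len(ids)), y):
        holdout_ids = [ids[i] for i in test_idx]
        preds = _holdout_predictions(holdout_ids, fingerprints, classes)
        pooled_true.extend(classes[p.query_id] for p in preds)
        pooled_probs.extend(p.probability for p in preds)
    return pooled_true, pooled_probs


def permutation_null_cv(
    labeled,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    config: FingerprintConfig = FingerprintConfig(),
) -> CVReport:
    """Chance-level diagnostic: per-repeat k-fold CV under label permutation.

    Each repeat independently shuffles the labels among the records before
    its stratified k-fold pass, so the per-repeat AUCs are independent draws
    from the no-association null and their t-based 95% confidence interval
    should cover 0.5.  Structural predictions under the true labels are never
    affected; this estimates the chance baseline of the same pipeline.
    """
    ids, classes, counts, fingerprints, skipped = _prepare_cv(labeled, k, config)
    labels = [classes[cid] for cid in ids]

    per_repeat: list[MetricSet] = []
    for repeat in range(repeats):
        derived = (seed + repeat) % (2**31)
        rng = np.random.default_rng(derived)
        shuffled = dict(zip(ids, rng.permutation(labels).tolist()))
        pooled_true, pooled_probs = _one_kfold_pass(
            ids, shuffled, fingerprints, k, random_state=derived
        )
        metrics, _ = compute_metrics(pooled_true, pooled_probs)
        per_repeat.append(metrics)

    mean, lower, upper = {}, {}, {}
    for name in METRIC_NAMES:
        values = np.array([getattr(m, name) for m in per_repeat])
        mean[name] = float(values.mean())
        half = 0.0
        if repeats > 1 and values.std(ddof=1) > 0:
            half = float(
                stats.t.ppf(0.975, repeats - 1)
                * values.std(ddof=1) / math.sqrt(repeats)
            )
        lower[name] = mean[name] - half
        upper[name] = mean[name] + half

    return CVReport(
        protocol="permutation_null",
        k=k,
        repeats=repeats,
        seed=seed,
        per_repeat=per_repeat,
        mean=mean,
        ci_lower=lower,
        ci_upper=upper,
        auc_p_value=None,
        confusion=None,
        metadata={"n": len(ids), "class_counts": counts, "skipped": skipped,
                  "fingerprint": config.__dict__.copy()},
    )


def _as_labeled_records(labeled) -> list[MetaboliteRecord]:
    if isinstance(labeled, Dataset):
        records = labeled.labeled()
    else:
        records = [r for r in labeled if r.fix_label in (0, 1)]
    if len(records) < 2:
        raise ValueError("need at least two labeled records")
    return records


def dedupe_structures(records: Sequence[MetaboliteRecord]) -> list[MetaboliteRecord]:
    """Collapse records with identical canonical structures (leakage guard).

    Exact duplicates inflate cross-validation scores because a holdout copy
    finds its twin at similarity 1.  The default pipelines keep duplicates;
    this helper is the opt-in collapse, keeping the first record per
    canonical SMILES and logging the rest.
    """
    from rdkit import Chem

    seen: dict[str, str] = {}
    kept = []
    for record in records:
        mol = Chem.MolFromSmiles(record.smiles)
        key = Chem.MolToSmiles(mol) if mol is not None else record.smiles
        if key in seen:
            log.warning(
                "dropping %s: identical structure to %s (leakage risk)",
                record.compound_id, seen[key],
            )
            continue
        seen[key] = record.compound_id
        kept.append(record)
    return kept
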