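"""Classification metrics and evaluation protocols.

Confusion-matrix metrics (ACC/SEN/SPE/PRE/F1 as percentages), ROC AUC,
a stratified 90/10 holdout, stratified k-fold cross-validation, and
leave-one-site-out evaluation. MDD is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .fc_network import MDD, NC, BrainGraph


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """ACC/SEN/SPE/PRE/F1 as percentages; AUC in [0, 1]; NaN marks undefined."""

    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    auc: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "SEN": self.sen,
            "SPE": self.spe,
            "PRE": self.pre,
            "F1": self.f1,
            "AUC": self.auc,
        }


def confusion(
    predicted: Sequence[str], actual: Sequence[str], positive_class: str = MDD
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the stated positive class."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels"
        )
    tp = tn = fp = fn = 0
    for p, a in zip(predicted, actual):
        if a == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio_pct(num: int, den: int) -> float:
    return math.nan if den == 0 else 100.0 * num / den


def f1_from_precision_sensitivity(pre: float, sen: float) -> float:
    """F1 = 2*PRE*SEN/(PRE+SEN), on the percentage scale."""
    if pre + sen == 0:
        return math.nan
    return 2.0 * pre * sen / (pre + sen)


def compute_metrics(c: ConfusionCounts, auc: float = math.nan) -> MetricsReport:
    """ACC/SEN/SPE/PRE/F1 from a confusion table; zero denominators give NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    acc = _ratio_pct(c.tp + c.tn, c.total)
    sen = _ratio_pct(c.tp, c.tp + c.fn)
    spe = _ratio_pct(c.tn, c.tn + c.fp)
    pre = _ratio_pct(c.tp, c.tp + c.fp)
    if math.isnan(sen) or math.isnan(pre):
        f1 = math.nan
    else:
        f1 = f1_from_precision_sensitivity(pre, sen)
    return MetricsReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1, auc=auc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties counted 1/2)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes to be present")
    ranks = rankdata(s)  # average ranks handle ties at 1/2
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Per-fold (or per-site) metrics plus aggregate and pooled summaries."""

    fold_names: list[str]
    fold_metrics: list[MetricsReport]
    aggregate: MetricsReport
    pooled: MetricsReport
    assignments: dict[str, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"fold": name, **m.to_dict()}
            for name, m in zip(self.fold_names, self.fold_metrics)
        ]
        rows.append({"fold": "mean", **self.aggregate.to_dict()})
        rows.append({"fold": "pooled", **self.pooled.to_dict()})
        return pd.DataFrame(rows)


def _aggregate_metrics(fold_metrics: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean over folds, ignoring NaN entries per metric."""

    def mean_of(attr: str) -> float:
        vals = [getattr(m, attr) for m in fold_metrics]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return MetricsReport(
        acc=mean_of("acc"),
        sen=mean_of("sen"),
        spe=mean_of("spe"),
        pre=mean_of("pre"),
        f1=mean_of("f1"),
        auc=mean_of("auc"),
    )


def fold_report(pred_labels, true_labels, scores) -> MetricsReport:
    counts = confusion(pred_labels, true_labels)
    y = [1 if lab == MDD else 0 for lab in true_labels]
    try:
        auc = roc_auc(scores, y)
    except ValueError:
        auc = math.nan
    return compute_metrics(counts, auc=auc)


def holdout_split(
    cohort: Sequence,
    train_fraction: float = 0.9,
    seed: int = 0,
    label_fn: Callable = lambda s: s.label,
) -> tuple[list, list]:
    """Stratified random split with train size round(train_fraction * n)."""
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    labels = [label_fn(s) for s in cohort]
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 members")

    n_train = round(train_fraction * n)
    # largest-remainder allocation so per-class proportions stay within one subject
    classes = sorted(by_class)
    ideal = {lab: train_fraction * len(by_class[lab]) for lab in classes}
    counts = {lab: int(math.floor(ideal[lab])) for lab in classes}
    leftover = n_train - sum(counts.values())
    for lab in sorted(classes, key=lambda c: ideal[c] - counts[c], reverse=True):
        if leftover <= 0:
            break
        counts[lab] += 1
        leftover -= 1

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in classes:
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        train_idx.extend(idx[: counts[lab]].tolist())
        test_idx.extend(idx[counts[lab] :].tolist())
    return [cohort[i] for i in sorted(train_idx)], [cohort[i] for i in sorted(test_idx)]


def _default_factory():
    from .dgcnn import DGCNNClassifier

    return DGCNNClassifier


def kfold_cv(
    graphs: Sequence[BrainGraph],
    config,
    k: int = 10,
    seed: int = 0,
    classifier_factory: Callable | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation; each subject tested exactly once.

    ``classifier_factory(config)`` must return an object with
    ``fit(graphs)`` and ``predict_proba(graphs) -> positive-class array``;
    the default trains the bundled graph classifier per fold from scratch.
    """
    n = len(graphs)
    if n < k:
        raise ValueError(f"cannot run {k}-fold CV on {n} subjects")
    if classifier_factory is None:
        classifier_factory = _default_factory()
    y = np.array([1 if g.label == MDD else 0 for g in graphs])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_names, fold_metrics = [], []
    assignments: dict[str, str] = {}
    pooled_pred, pooled_true, pooled_scores = [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        if len(set(y[train_idx])) < 2:
            raise ValueError(f"fold {fold_i}: training split has a single class")
        train = [graphs[i] for i in train_idx]
        test = [graphs[i] for i in test_idx]
        clf = classifier_factory(config)
        clf.fit(train)
        scores = np.asarray(clf.predict_proba(test), dtype=np.float64)
        preds = [MDD if s >= 0.5 else NC for s in scores]
        true = [g.label for g in test]
        name = f"fold{fold_i}"
        fold_names.append(name)
        fold_metrics.append(fold_report(preds, true, scores))
        for g in test:
            assignments[g.subject_id] = name
        pooled_pred.extend(preds)
        pooled_true.extend(true)
        pooled_scores.extend(scores.tolist())

    return CVResult(
        fold_names=fold_names,
        fold_metrics=fold_metrics,
        aggregate=_aggregate_metrics(fold_metrics),
        pooled=fold_report(pooled_pred, pooled_true, pooled_scores),
        assignments=assignments,
    )


def leave_one_site_out(
    graphs: Sequence[BrainGraph],
    config,
    classifier_factory: Callable | None = None,
) -> CVResult:
    """Hold out each site entirely as the test set, training on the rest."""
    sites = sorted({g.site_id for g in graphs})
    if len(sites) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    if classifier_factory is None:
        classifier_factory = _default_factory()

    fold_names, fold_metrics = [], []
    assignments: dict[str, str] = {}
    pooled_pred, pooled_true, pooled_scores = [], [], []
    for site in sites:
        test = [g for g in graphs if g.site_id == site]
        train = [g for g in graphs if g.site_id != site]
        if len({g.label for g in train}) < 2:
            raise ValueError(f"training set excluding site {site!r} has a single class")
        clf = classifier_factory(config)
        clf.fit(train)
        scores = np.asarray(clf.predict_proba(test), dtype=np.float64)
        preds = [MDD if s >= 0.5 else NC for s in scores]
        true = [g.label for g in test]
        fold_names.append(site)
        fold_metrics.append(fold_report(preds, true, scores))
        for g in test:
            assignments[g.subject_id] = site
        pooled_pred.extend(preds)
        pooled_true.extend(true)
        pooled_scores.extend(scores.tolist())

    return CVResult(
        fold_names=fold_names,
        fold_metrics=fold_metrics,
        aggregate=_aggregate_metrics(fold_metrics),
        pooled=fold_report(pooled_pred, pooled_true, pooled_scores),
        assignments=assignments,
    )
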