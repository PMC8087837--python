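"""Validation metrics for filter-set classification.

Implements the full statistical validation suite: overall accuracy
(TN + TP over total), per-classifier confusion matrices with precision
and false discovery rate, balanced accuracy (mean of TPR and TNR),
Hellinger distance between binned count distributions (normalised by
1/sqrt(2) so that disjoint support scores exactly 1), per-class SMAPE,
Bray-Curtis dissimilarity and Kullback-Leibler divergence.

Counts, not frequencies, are the canonical inputs; each metric
normalises internally exactly where its definition does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateClassError
from .gates import ClassificationResult


def accuracy(tp: int, tn: int, total: int) -> float:
    """Overall accuracy (TN + TP) / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if tp + tn > total:
        raise ValueError("TP + TN exceeds total")
    return (tn + tp) / total


@dataclass
class ConfusionMatrix:
    """Counts of selections per (classifier, true class).

    ``table[c, k]`` counts particles of true class ``k`` selected by the
    class-``c`` filter (per-class filters act independently, so a
    particle can be counted by several classifiers).  Derived one-vs-rest
    quantities per classifier: TP, FP, FN, TN, precision, false discovery
    rate, TPR, TNR and balanced accuracy.
    """

    table: pd.DataFrame  # classifiers x true classes
    class_totals: pd.Series  # true-label counts in the dataset
    n_total: int

    @classmethod
    def from_result(cls, result: ClassificationResult) -> "ConfusionMatrix":
        if result.true_labels is None:
            raise ValueError("true labels are required")
        truth = pd.Series(np.asarray(result.true_labels, dtype=object))
        classes = list(result.selections.columns)
        true_classes = sorted(set(truth.unique()) | set(classes))
        table = pd.DataFrame(0, index=classes, columns=true_classes)
        for c in classes:
            sel = result.selections[c]
            counts = truth[sel.to_numpy()].value_counts()
            for k, v in counts.items():
                table.loc[c, k] = int(v)
        totals = truth.value_counts().reindex(true_classes, fill_value=0)
        return cls(table, totals, len(truth))

    def tp(self, c: str) -> int:
        return int(self.table.loc[c].get(c, 0))

    def fp(self, c: str) -> int:
        return int(self.table.loc[c].sum() - self.tp(c))

    def fn(self, c: str) -> int:
        return int(self.class_totals.get(c, 0)) - self.tp(c)

    def tn(self, c: str) -> int:
        return self.n_total - self.tp(c) - self.fp(c) - self.fn(c)

    def precision(self, c: str) -> float:
        sel = self.tp(c) + self.fp(c)
        if sel == 0:
            raise DegenerateClassError(f"{c}: no particle selected")
        return self.tp(c) / sel

    def false_discovery_rate(self, c: str) -> float:
        sel = self.tp(c) + self.fp(c)
        if sel == 0:
            raise DegenerateClassError(f"{c}: no particle selected")
        return self.fp(c) / sel

    def tpr(self, c: str) -> float:
        pos = self.tp(c) + self.fn(c)
        if pos == 0:
            raise DegenerateClassError(f"{c}: no positive particle")
        return self.tp(c) / pos

    def tnr(self, c: str) -> float:
        neg = self.tn(c) + self.fp(c)
        if neg == 0:
            raise DegenerateClassError(f"{c}: no negative particle")
        return self.tn(c) / neg

    def balanced_accuracy(self, c: str) -> float:
        return 0.5 * (self.tpr(c) + self.tnr(c))


def confusion_counts(
    selected: np.ndarray, positive: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) of one classifier's boolean selections."""
    selected = np.asarray(selected, bool)
    positive = np.asarray(positive, bool)
    tp = int(np.sum(selected & positive))
    fp = int(np.sum(selected & ~positive))
    fn = int(np.sum(~selected & positive))
    tn = int(np.sum(~selected & ~positive))
    return tp, fp, fn, tn


def balanced_accuracy(tp: int, fp: int, fn: int, tn: int) -> float:
    """Mean of the true positive rate and the true negative rate."""
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateClassError(
            "balanced accuracy needs at least one positive and one negative"
        )
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    return 0.5 * (tpr + tnr)


def hellinger_distance(
    X, T, return_per_filter: bool = False
):
    """Hellinger distance between binned count datasets X and T.

    ``X`` and ``T`` are count arrays of shape ``(s, c)`` (s filter sets,
    c bins) or ``(c,)`` (treated as s = 1).  Per filter set::

        HD_f = (1/sqrt(2)) * sqrt( sum_k ( sqrt(X_fk / X) - sqrt(T_fk / T) )**2 )

    where ``X`` and ``T`` are the grand dataset totals (summed over all
    filter sets and bins, exactly as the definition normalises), so each
    ``HD_f`` lies in [0, 1]: 0 for proportional distributions and 1 for
    disjoint support spanning the totals.  At s = 1 this is the ordinary
    normalised Hellinger distance between the two count vectors.
    Returns the mean over filter sets, or (mean, per-filter array) when
    ``return_per_filter`` is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape != T.shape:
        raise ValueError("X and T must have the same shape")
    if X.sum() <= 0 or T.sum() <= 0:
        raise ValueError("X and T must each have a positive total")
    p = X / X.sum()
    q = T / T.sum()
    per = np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2, axis=1)) / np.sqrt(2.0)
    mean = float(per.mean())
    if return_per_filter:
        return mean, per
    return mean


def smape_per_class(actual, forecast) -> float:
    """Symmetric mean absolute percentage error for one class, percent.

    ``actual`` and ``forecast`` hold the class's count under each of the
    s filter sets.  Each term is |X - X'| / (X + X'); terms with
    X = X' = 0 contribute 0.  The mean over filter sets is reported
    times 100 (a percentage in [0, 100]).
    """
    a = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel()
    if a.shape != f.shape:
        raise ValueError("actual and forecast must have the same shape")
    if np.any(a < 0) or np.any(f < 0):
        raise ValueError("counts must be non-negative")
    denom = a + f
    terms = np.zeros_like(denom)
    nz = denom > 0
    terms[nz] = np.abs(a[nz] - f[nz]) / denom[nz]
    return float(terms.mean() * 100.0)


def bray_curtis(actual, forecast) -> float:
    """Bray-Curtis dissimilarity between two count vectors, in [0, 1]."""
    a = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel()
    if a.shape != f.shape:
        raise ValueError("actual and forecast must have the same shape")
    total = float(np.sum(a + f))
    if total <= 0:
        raise ValueError("all-zero inputs")
    return float(np.sum(np.abs(a - f)) / total)


def kl_divergence(
    actual, forecast, base: float | None = None, pseudocount: float = 0.0
) -> float:
    """Kullback-Leibler divergence KL(actual || forecast) on count bins.

    Both vectors are normalised to probabilities; bins with zero actual
    count contribute 0.  A bin with positive actual but zero forecast
    count makes the divergence infinite; passing a ``pseudocount`` > 0
    adds it to every forecast bin instead.  Natural log by default;
    ``base`` switches the logarithm base.
    """
    a = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel() + pseudocount
    if a.shape != f.shape:
        raise ValueError("actual and forecast must have the same shape")
    if a.sum() <= 0 or f.sum() <= 0:
        raise ValueError("both vectors need a positive total")
    p = a / a.sum()
    q = f / f.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    kl = float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))
    if base is not None:
        kl /= float(np.log(base))
    return kl


@dataclass
class MetricReport:
    """Per-class and overall evaluation of one filter set."""

    per_class: pd.DataFrame  # rows: classes; columns: the metric list
    overall: dict

    PER_CLASS_COLUMNS = (
        "hellinger_distance",
        "balanced_accuracy_pct",
        "smape_pct",
        "precision",
        "false_discovery_rate",
    )

    def to_frame(self) -> pd.DataFrame:
        """Flat frame mirroring the summary-table layout."""
        frame = self.per_class.copy()
        for k, v in self.overall.items():
            frame[k] = v
        return frame


def evaluate_filter_set(
    result: ClassificationResult,
    truth: pd.Series | None = None,
    training_result: ClassificationResult | None = None,
) -> MetricReport:
    """Score one filter set's selections against manual labels.

    Per class: precision, false discovery rate, balanced accuracy and
    SMAPE (between the class's true and selected counts).  Overall:
    accuracy of the exclusive assignment when present, Bray-Curtis
    dissimilarity and KL divergence between the true and predicted class
    composition.  When ``training_result`` (the same filters applied to
    the training dataset, with labels) is given, the per-filter Hellinger
    distance between the training and test composition of each
    classifier's selected set is reported, with its mean in ``overall``.
    """
    if truth is None:
        truth = result.true_labels
    if truth is None:
        raise ValueError("true labels are required")
    truth = pd.Series(np.asarray(truth, dtype=object))
    if len(truth) != len(result.selections):
        raise ValueError("label/prediction length mismatch")
    classes = list(result.selections.columns)

    rows = {}
    hd_values = {}
    for c in classes:
        sel = result.selections[c].to_numpy()
        pos = (truth == c).to_numpy()
        tp, fp, fn, tn = confusion_counts(sel, pos)
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        fdr = fp / (tp + fp) if (tp + fp) else np.nan
        ba = balanced_accuracy(tp, fp, fn, tn)
        smape = smape_per_class([pos.sum()], [sel.sum()])
        hd = np.nan
        if training_result is not None and training_result.true_labels is not None:
            bins = sorted(set(truth.unique()))
            test_counts = _selected_composition(result, truth, c, bins)
            train_truth = pd.Series(
                np.asarray(training_result.true_labels, dtype=object)
            )
            train_counts = _selected_composition(
                training_result, train_truth, c, bins
            )
            if test_counts.sum() > 0 and train_counts.sum() > 0:
                hd = hellinger_distance(test_counts, train_counts)
        hd_values[c] = hd
        rows[c] = {
            "hellinger_distance": hd,
            "balanced_accuracy_pct": ba * 100.0,
            "smape_pct": smape,
            "precision": precision,
            "false_discovery_rate": fdr,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")[
        list(MetricReport.PER_CLASS_COLUMNS)
    ]

    true_counts = truth.value_counts().reindex(classes, fill_value=0).to_numpy()
    pred_counts = result.selections.sum(axis=0).to_numpy()
    overall = {
        "bray_curtis": bray_curtis(true_counts, pred_counts),
        "kl_divergence": kl_divergence(true_counts, pred_counts, pseudocount=0.5)
        if np.any(pred_counts == 0)
        else kl_divergence(true_counts, pred_counts),
    }
    hd_arr = np.array(list(hd_values.values()), dtype=float)
    if not np.all(np.isnan(hd_arr)):
        overall["hellinger_distance_mean"] = float(np.nanmean(hd_arr))
    if result.exclusive_labels is not None:
        correct = int(np.sum(result.exclusive_labels.to_numpy() == truth.to_numpy()))
        overall["exclusive_accuracy"] = correct / len(truth)
    return MetricReport(per_class, overall)


def _selected_composition(result, truth, classifier, bins):
    sel = result.selections[classifier].to_numpy()
    counts = truth[sel].value_counts()
    return np.array([int(counts.get(b, 0)) for b in bins], dtype=float)
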