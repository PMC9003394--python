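"""Performance evaluation: information transfer rate, confusion indices,
and accuracy/ITR curves over epoch windows."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .decoding import decode_trials
from .preprocessing import epoch_window

__all__ = ["ConfusionSummary", "itr", "confusion_and_indices", "evaluate_windows"]

logger = logging.getLogger(__name__)


def itr(sigma: float, k: int, t: float, rest_time: float = 0.0) -> float:
    """Information transfer rate of a K-choice selection, bits/min.

        ITR = (60/T) * [log2 K + s*log2 s + (1-s)*log2((1-s)/(K-1))]

    with the convention 0*log2(0) = 0, so sigma = 0 and sigma = 1 are well
    defined.  ``t`` is the time per selection in seconds; set ``rest_time``
    to include an inter-trial rest in T.  Chance accuracy (sigma = 1/K) is
    the global minimum of the bracket, where the rate is exactly zero;
    below chance the value rises again (systematically wrong answers still
    carry information) and is returned as computed, with a log note.
    """
    if k < 2:
        raise ValueError("need at least K = 2 stimuli")
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if t <= 0 or rest_time < 0:
        raise ValueError("selection time must be positive, rest time >= 0")
    bits = math.log2(k)
    if sigma > 0:
        bits += sigma * math.log2(sigma)
    if sigma < 1:
        bits += (1 - sigma) * math.log2((1 - sigma) / (k - 1))
    value = 60.0 / (t + rest_time) * bits
    if sigma < 1.0 / k:
        logger.warning("accuracy %.3f is below chance 1/%d", sigma, k)
    return value


@dataclass(frozen=True)
class ConfusionSummary:
    """K x K confusion counts plus per-class performance indices.

    ``per_class`` columns: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
    precision TP/(TP+FP), accuracy (TP+TN)/total.  Indices whose
    denominator is zero (e.g. sensitivity of a class with no positives) are
    NaN, not 0.  ``overall_accuracy`` is trace/total.
    """

    counts: np.ndarray = field(repr=False)
    per_class: pd.DataFrame = field(repr=False)
    overall_accuracy: float
    labels: tuple


def confusion_and_indices(true_labels, predicted_labels, k: int,
                          labels=None) -> ConfusionSummary:
    """Confusion matrix and per-class indices for a K-class prediction task.

    Labels default to 1..K when every observed label is >= 1, else 0..K-1.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label lists must have equal length")
    if labels is None:
        observed = np.concatenate([true_labels, predicted_labels])
        labels = list(range(1, k + 1)) if observed.min() >= 1 else list(range(k))
    labels = list(labels)
    if len(labels) != k:
        raise ValueError("need exactly K class labels")
    bad = set(np.unique(np.concatenate([true_labels, predicted_labels]))) - set(labels)
    if bad:
        raise ValueError(f"labels outside 1..K: {sorted(bad)}")
    counts = confusion_matrix(true_labels, predicted_labels, labels=labels)
    total = counts.sum()
    rows = {}
    for idx, lab in enumerate(labels):
        tp = counts[idx, idx]
        fn = counts[idx].sum() - tp
        fp = counts[:, idx].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den, name):
            if den == 0:
                logger.warning("class %s: %s undefined (0 denominator)", lab, name)
                return np.nan
            return num / den

        rows[lab] = {
            "sensitivity": ratio(tp, tp + fn, "sensitivity"),
            "specificity": ratio(tn, tn + fp, "specificity"),
            "precision": ratio(tp, tp + fp, "precision"),
            "accuracy": (tp + tn) / total,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class.index.name = "class"
    return ConfusionSummary(
        counts=counts,
        per_class=per_class,
        overall_accuracy=float(np.trace(counts) / total),
        labels=tuple(labels),
    )


def evaluate_windows(trials, plan, method: str, windows, nh: int = 2,
                     rest_time: float = 0.0) -> pd.DataFrame:
    """Accuracy and ITR per epoch window, mean +/- SD across subjects.

    Each trial is epoched to [0, window) s, decoded with ``method`` (cca or
    bcca), and scored against its ground-truth target; ITR uses
    T = window + rest_time.  Windows longer than the shortest trial are
    skipped with a log message.  Trials without a subject id form one
    group, so the SD columns are then 0/NaN degenerate.
    """
    trials = list(trials)
    if any(t.true_target is None for t in trials):
        raise ValueError("all trials need a ground-truth target")
    records = []
    min_duration = min(t.duration for t in trials) if trials else 0.0
    for window in windows:
        if window > min_duration + 1e-9:
            logger.warning("skipping %.2f s window: exceeds shortest trial "
                           "(%.2f s)", window, min_duration)
            continue
        epochs = [epoch_window(t, 0.0, window) for t in trials]
        results = decode_trials(epochs, plan, method=method, nh=nh)
        correct = np.array([r.predicted == t.true_target
                            for r, t in zip(results, trials)])
        subjects = np.array([t.subject if t.subject is not None else 0
                             for t in trials])
        per_subject = [correct[subjects == s].mean() for s in np.unique(subjects)]
        acc = float(correct.mean())
        per_subject_itr = [itr(a, plan.n_targets, window, rest_time)
                           for a in per_subject]
        records.append({
            "window": float(window),
            "accuracy": acc,
            "accuracy_sd": float(np.std(per_subject)),
            "itr": itr(acc, plan.n_targets, window, rest_time),
            "itr_sd": float(np.std(per_subject_itr)),
            "n_trials": int(correct.size),
        })
    return pd.DataFrame.from_records(
        records, columns=["window", "accuracy", "accuracy_sd", "itr",
                          "itr_sd", "n_trials"])
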