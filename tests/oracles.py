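"""Naive, loop-based reference implementations of every scoring metric.

These are deliberately independent of the package's vectorized code paths:
confusions are counted by iteration, AUROC by explicit positive-negative pair
comparison, AUPRC by an explicit threshold sweep. They exist solely as
oracles for equivalence tests.
"""

from __future__ import annotations

MURMUR_CLASSES = ("Present", "Unknown", "Absent")


def naive_weighted_accuracy(murmur_labels: dict, outputs) -> float:
    w = {"Present": 5.0, "Unknown": 3.0, "Absent": 1.0}
    num = 0.0
    den = 0.0
    for out in outputs:
        label = murmur_labels[out.patient_id]
        den += w[label]
        if out.murmur_class == label:
            num += w[label]
    return num / den


def naive_outcome_cost(outcome_labels: dict, outputs) -> tuple[float, float]:
    tp = fp = fn = tn = 0
    for out in outputs:
        truth = outcome_labels[out.patient_id] == "Abnormal"
        pred = out.outcome_class == "Abnormal"
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    t = tp + fp + fn + tn
    x = (tp + fp) / t
    expert = (25 + 397 * x - 1718 * x**2 + 11296 * x**4) * t
    total = 10 * t + expert + 10000 * tp + 50000 * fn
    return total, total / t


def naive_binary_auroc(y_true: list, scores: list) -> float:
    pairs = 0
    wins = 0.0
    for yt, st in zip(y_true, scores):
        if yt != 1:
            continue
        for yf, sf in zip(y_true, scores):
            if yf != 0:
                continue
            pairs += 1
            if st > sf:
                wins += 1.0
            elif st == sf:
                wins += 0.5
    return wins / pairs


def naive_binary_auprc(y_true: list, scores: list) -> float:
    pos = sum(y_true)
    thresholds = sorted(set(scores), reverse=True)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for y, s in zip(y_true, scores) if s >= t and y == 1)
        pred_pos = sum(1 for s in scores if s >= t)
        precision = tp / pred_pos
        recall = tp / pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def naive_binary_f(y_true: list, y_pred: list) -> float:
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def naive_traditional(labels: dict, outputs, task: str):
    """(auroc, auprc, f_measure, accuracy), matching the package conventions:
    murmur one-vs-rest macro over classes present in the labels, outcome on
    the Abnormal class."""
    ordered = sorted(outputs, key=lambda o: o.patient_id)
    y = [labels[o.patient_id] for o in ordered]
    if task == "outcome":
        yt = [1 if v == "Abnormal" else 0 for v in y]
        yp = [1 if o.outcome_class == "Abnormal" else 0 for o in ordered]
        s = [o.outcome_probs[0] for o in ordered]
        auroc = naive_binary_auroc(yt, s)
        auprc = naive_binary_auprc(yt, s)
        f = naive_binary_f(yt, yp)
        acc = sum(1 for o, v in zip(ordered, y) if o.outcome_class == v) / len(y)
        return auroc, auprc, f, acc
    present = [c for c in MURMUR_CLASSES if c in y]
    aurocs, auprcs, fs = [], [], []
    for i, c in enumerate(MURMUR_CLASSES):
        if c not in present:
            continue
        yt = [1 if v == c else 0 for v in y]
        yp = [1 if o.murmur_class == c else 0 for o in ordered]
        s = [o.murmur_probs[i] for o in ordered]
        aurocs.append(naive_binary_auroc(yt, s))
        auprcs.append(naive_binary_auprc(yt, s))
        fs.append(naive_binary_f(yt, yp))
    acc = sum(1 for o, v in zip(ordered, y) if o.murmur_class == v) / len(y)
    return (sum(aurocs) / len(aurocs), sum(auprcs) / len(auprcs),
            sum(fs) / len(fs), acc)
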