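"""Scoring for the two screening tasks.

Murmur detection (three classes: Present / Unknown / Absent) is scored with a
weighted accuracy that rewards correct Present classifications five times and
correct Unknown classifications three times as much as correct Absent ones:

    a = (5 m_PP + 3 m_UU + m_AA) /
        (5 (m_PP + m_UP + m_AP) + 3 (m_PU + m_UU + m_AU) + (m_PA + m_UA + m_AA))

Clinical-outcome identification (Abnormal / Normal) is scored with a
capacity-constrained screening cost. Every patient incurs a fixed algorithmic
pre-screening cost (10/patient); algorithm-positive patients are referred for
expert screening whose mean per-patient cost is the quartic

    g_expert(x) = 25 + 397 x - 1718 x^2 + 11296 x^4,   x = screenings / patients,

confirmed positives incur a treatment cost (10 000 each) and missed positives
a missed-treatment penalty (50 000 each). The quartic makes the per-screening
mean cost g(x)/x cheapest when 25% of the cohort is screened, modelling a
screening system with a finite optimal capacity.

Traditional metrics (AUROC, AUPRC, F-measure, accuracy), reconstructed
cross-task metric variants, competition ("1224") ranking and metric
concordance (Spearman rho + Huber robust line) round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .types import MURMUR_CLASSES, OUTCOME_CLASSES, ModelOutput, ValidationError

__all__ = [
    "UndefinedMetricError",
    "MurmurConfusion",
    "OutcomeConfusion",
    "CostParameters",
    "TraditionalMetrics",
    "CrossTaskMetrics",
    "OptimalScreening",
    "ScoreReport",
    "murmur_confusion",
    "outcome_confusion",
    "weighted_accuracy",
    "expert_mean_cost",
    "expert_total_cost",
    "outcome_cost",
    "optimal_screening_fraction",
    "traditional_metrics",
    "cross_task_metrics",
    "rank_entries",
    "metric_concordance",
    "score_entry",
]


class UndefinedMetricError(ValueError):
    """A metric is requested on input where it is mathematically undefined."""


@dataclass(frozen=True)
class MurmurConfusion:
    """3x3 count matrix; rows = model output, columns = expert label.

    Row/column order is (Present, Unknown, Absent).
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.m)
        if arr.shape != (3, 3):
            raise ValidationError(f"murmur confusion must be 3x3, got {arr.shape}")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)) or np.any(arr < 0):
                raise ValidationError("murmur confusion entries must be non-negative integers")
        object.__setattr__(self, "m", arr.astype(np.int64))

    @property
    def n_patients(self) -> int:
        return int(self.m.sum())


@dataclass(frozen=True)
class OutcomeConfusion:
    """2x2 screening counts: rows = model output, columns = expert label."""

    n_TP: int
    n_FP: int
    n_FN: int
    n_TN: int

    def __post_init__(self) -> None:
        for name in ("n_TP", "n_FP", "n_FN", "n_TN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_patients(self) -> int:
        return self.n_TP + self.n_FP + self.n_FN + self.n_TN


@dataclass(frozen=True)
class CostParameters:
    """Unit costs and the expert-capacity polynomial of the cost metric.

    ``expert_poly`` holds the (constant, linear, quadratic, quartic)
    coefficients of the mean expert screening cost g(x); there is no cubic
    term. Currency is abstract cost units.
    """

    prescreen_unit_cost: float = 10.0
    treatment_unit_cost: float = 10_000.0
    error_unit_cost: float = 50_000.0
    expert_poly: tuple[float, float, float, float] = (25.0, 397.0, -1718.0, 11_296.0)

    def __post_init__(self) -> None:
        for name in ("prescreen_unit_cost", "treatment_unit_cost", "error_unit_cost"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if len(self.expert_poly) != 4:
            raise ValidationError(
                "expert_poly must have exactly (constant, linear, quadratic, quartic) slots"
            )


class TraditionalMetrics(NamedTuple):
    auroc: float
    auprc: float
    f_measure: float
    accuracy: float


class CrossTaskMetrics(NamedTuple):
    """Reconstructed cross-task variants (the official supplementary
    definitions are not public; these are this package's documented
    reconstructions, not the official forms)."""

    outcome_weighted_accuracy: float
    murmur_total_cost: float
    murmur_mean_cost: float


class OptimalScreening(NamedTuple):
    fraction: float
    boundary: bool  # True when no interior minimum exists and the argmin is a boundary


def _paired_classes(
    labels: Mapping[str, str], outputs: Sequence[ModelOutput], task: str
) -> tuple[list[str], list[ModelOutput]]:
    out_ids = [o.patient_id for o in outputs]
    if len(set(out_ids)) != len(out_ids):
        dupes = sorted({i for i in out_ids if out_ids.count(i) > 1})
        raise ValidationError(f"duplicate patient ids in outputs: {dupes}")
    missing = sorted(set(labels) - set(out_ids))
    extra = sorted(set(out_ids) - set(labels))
    if missing or extra:
        raise ValidationError(
            f"patient coverage mismatch: missing outputs for {missing}, extra outputs for {extra}"
        )
    ordered = sorted(outputs, key=lambda o: o.patient_id)
    y_true = [labels[o.patient_id] for o in ordered]
    return y_true, ordered


def murmur_confusion(
    labels: Mapping[str, str], outputs: Sequence[ModelOutput]
) -> MurmurConfusion:
    """Count patients per (model output, expert label) murmur-class pair."""
    y_true, ordered = _paired_classes(labels, outputs, "murmur")
    idx = {c: i for i, c in enumerate(MURMUR_CLASSES)}
    m = np.zeros((3, 3), dtype=np.int64)
    for label, out in zip(y_true, ordered):
        if label not in idx:
            raise ValidationError(f"unknown murmur label {label!r}")
        m[idx[out.murmur_class], idx[label]] += 1
    return MurmurConfusion(m)


def outcome_confusion(
    labels: Mapping[str, str], outputs: Sequence[ModelOutput]
) -> OutcomeConfusion:
    """Count TP/FP/FN/TN with Abnormal as the positive class."""
    y_true, ordered = _paired_classes(labels, outputs, "outcome")
    tp = fp = fn = tn = 0
    for label, out in zip(y_true, ordered):
        if label not in OUTCOME_CLASSES:
            raise ValidationError(f"unknown outcome label {label!r}")
        pos_pred = out.outcome_class == "Abnormal"
        pos_true = label == "Abnormal"
        if pos_pred and pos_true:
            tp += 1
        elif pos_pred:
            fp += 1
        elif pos_true:
            fn += 1
        else:
            tn += 1
    return OutcomeConfusion(tp, fp, fn, tn)


def weighted_accuracy(
    confusion: MurmurConfusion, weights: tuple[float, float, float] = (5.0, 3.0, 1.0)
) -> float:
    """Class-weighted murmur accuracy (default weights 5 / 3 / 1).

    The denominator weights every expert-labelled patient by their class
    weight; with equal weights this reduces to plain accuracy.
    """
    m = confusion.m
    w = np.asarray(weights, dtype=float)
    denominator = float(w @ m.sum(axis=0))
    if denominator == 0:
        raise UndefinedMetricError("weighted accuracy is undefined on an empty confusion matrix")
    numerator = float(w @ np.diag(m))
    return numerator / denominator


def expert_mean_cost(x: float, params: Optional[CostParameters] = None) -> float:
    """Mean per-patient cost g(x) of expert-screening a fraction x of a cohort."""
    params = params or CostParameters()
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"screening fraction must lie in [0, 1], got {x}")
    c0, c1, c2, c4 = params.expert_poly
    return c0 + c1 * x + c2 * x**2 + c4 * x**4


def expert_total_cost(s: float, t: float, params: Optional[CostParameters] = None) -> float:
    """Total cost of s expert screenings in a cohort of t patients: g(s/t) * t."""
    if t <= 0:
        raise ValidationError("cohort size t must be positive")
    if not (0 <= s <= t):
        raise ValidationError(f"screenings s must satisfy 0 <= s <= t, got s={s}, t={t}")
    return expert_mean_cost(s / t, params) * t


def outcome_cost(
    confusion: OutcomeConfusion, params: Optional[CostParameters] = None
) -> tuple[float, float]:
    """(total, mean per-patient) screening-and-treatment cost of a classifier.

    total = prescreen * n_patients + f_expert(n_TP + n_FP, n_patients)
            + treatment * n_TP + error * n_FN
    """
    params = params or CostParameters()
    t = confusion.n_patients
    if t == 0:
        raise UndefinedMetricError("cost is undefined for an empty cohort")
    total = (
        params.prescreen_unit_cost * t
        + expert_total_cost(confusion.n_TP + confusion.n_FP, t, params)
        + params.treatment_unit_cost * confusion.n_TP
        + params.error_unit_cost * confusion.n_FN
    )
    return total, total / t


def optimal_screening_fraction(
    params: Optional[CostParameters] = None, tol: float = 1e-6
) -> OptimalScreening:
    """Argmin over x in (0, 1] of the per-screening mean cost g(x)/x.

    Solved by bracketed search refined to absolute tolerance ``tol``. When the
    objective has no interior minimum the boundary argmin is returned with
    ``boundary=True``.
    """
    params = params or CostParameters()
    c0, c1, c2, c4 = params.expert_poly

    def per_screening(x: float) -> float:
        return expert_mean_cost(x, params) / x

    grid = np.linspace(1e-6, 1.0, 4097)
    values = c0 / grid + c1 + c2 * grid + c4 * grid**3
    i = int(np.argmin(values))
    if i == 0 or i == len(grid) - 1:
        return OptimalScreening(float(grid[i]), True)
    res = optimize.minimize_scalar(
        per_screening,
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": tol / 10},
    )
    return OptimalScreening(float(res.x), False)


def _binary_auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUROC with midpoint handling of tied scores."""
    pos, neg = int(y.sum()), int((1 - y).sum())
    if pos == 0 or neg == 0:
        raise UndefinedMetricError("AUROC undefined with a single class")
    ranks = stats.rankdata(scores)  # average ranks on ties = midpoint convention
    return (float(ranks[y == 1].sum()) - pos * (pos + 1) / 2) / (pos * neg)


def _binary_auprc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUPRC as precision-weighted recall increments over score thresholds."""
    pos = int(y.sum())
    if pos == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied-score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_b = tp[block_end]
    precision = tp_b / n_pred[block_end]
    recall = tp_b / pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def _binary_f_measure(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def traditional_metrics(
    labels: Mapping[str, str], outputs: Sequence[ModelOutput], task: str
) -> TraditionalMetrics:
    """AUROC, AUPRC, F-measure and accuracy for one task.

    Murmur task: AUROC/AUPRC/F are computed one-vs-rest per class and
    macro-averaged; classes absent from the labels are excluded from the
    macro average with a warning. Outcome task: all four are computed on the
    Abnormal class. AUROC/AUPRC use the probabilities, F-measure and accuracy
    the discrete classes.
    """
    y_true, ordered = _paired_classes(labels, outputs, task)
    if not ordered:
        raise UndefinedMetricError("metrics undefined on an empty cohort")
    y_true = np.asarray(y_true)

    if task == "murmur":
        classes = MURMUR_CLASSES
        probs = np.asarray([o.murmur_probs for o in ordered], dtype=float)
        y_pred = np.asarray([o.murmur_class for o in ordered])
    elif task == "outcome":
        classes = OUTCOME_CLASSES
        probs = np.asarray([o.outcome_probs for o in ordered], dtype=float)
        y_pred = np.asarray([o.outcome_class for o in ordered])
    else:
        raise ValidationError(f"task must be 'murmur' or 'outcome', got {task!r}")

    present = [c for c in classes if np.any(y_true == c)]
    skipped = [c for c in classes if c not in present]
    if skipped:
        warnings.warn(
            f"{task} classes absent from labels excluded from macro average: {skipped}",
            stacklevel=2,
        )
    if task == "outcome":
        if len(present) < 2:
            raise UndefinedMetricError("outcome metrics require both classes in the labels")
        y = (y_true == "Abnormal").astype(int)
        yp = (y_pred == "Abnormal").astype(int)
        auroc = _binary_auroc(y, probs[:, 0])
        auprc = _binary_auprc(y, probs[:, 0])
        f_measure = _binary_f_measure(y, yp)
    else:
        if not present:
            raise UndefinedMetricError("no scoreable murmur classes in the labels")
        aurocs, auprcs, fs = [], [], []
        for c in present:
            y = (y_true == c).astype(int)
            yp = (y_pred == c).astype(int)
            s = probs[:, classes.index(c)]
            if len(present) >= 2:
                aurocs.append(_binary_auroc(y, s))
                auprcs.append(_binary_auprc(y, s))
            fs.append(_binary_f_measure(y, yp))
        if not aurocs:
            raise UndefinedMetricError("murmur ranking metrics require at least two classes")
        auroc = float(np.mean(aurocs))
        auprc = float(np.mean(auprcs))
        f_measure = float(np.mean(fs))

    accuracy = float(np.mean(y_pred == y_true))
    return TraditionalMetrics(auroc, auprc, f_measure, accuracy)


def cross_task_metrics(
    murmur_labels: Mapping[str, str],
    outcome_labels: Mapping[str, str],
    outputs: Sequence[ModelOutput],
    params: Optional[CostParameters] = None,
) -> CrossTaskMetrics:
    """Reconstructed cross-task variants of the two bespoke metrics.

    Outcome weighted accuracy: (5 n_TP + n_TN) / (5 (n_TP + n_FN) + (n_FP + n_TN)),
    i.e. the weighted-accuracy idea with Abnormal weighted 5 and Normal 1.
    Murmur cost: the outcome cost model applied to the murmur task after
    mapping Present/Unknown -> referral-positive and Absent -> negative on
    both the expert labels and the model outputs.

    These are this package's documented reconstructions; the official
    supplementary definitions were not published in the main text.
    """
    n = outcome_confusion(outcome_labels, outputs)
    denom = 5.0 * (n.n_TP + n.n_FN) + (n.n_FP + n.n_TN)
    if denom == 0:
        raise UndefinedMetricError("cross-task weighted accuracy undefined on an empty cohort")
    outcome_wa = (5.0 * n.n_TP + n.n_TN) / denom

    positive = {"Present", "Unknown"}
    mapped_labels = {
        pid: "Abnormal" if lab in positive else "Normal" for pid, lab in murmur_labels.items()
    }
    mapped_outputs = [
        ModelOutput(
            patient_id=o.patient_id,
            murmur_class=o.murmur_class,
            murmur_probs=o.murmur_probs,
            outcome_class="Abnormal" if o.murmur_class in positive else "Normal",
            outcome_probs=(0.5, 0.5),
        )
        for o in outputs
    ]
    total, mean = outcome_cost(outcome_confusion(mapped_labels, mapped_outputs), params)
    return CrossTaskMetrics(outcome_wa, total, mean)


def rank_entries(scores: Sequence[float], direction: str = "maximize") -> list[int]:
    """Competition ("1224") ranks: tied scores share the best rank, the next
    distinct score's rank equals 1 + the number of strictly better entries."""
    if direction not in ("maximize", "minimize"):
        raise ValidationError(f"direction must be 'maximize' or 'minimize', got {direction!r}")
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("rank_entries requires at least one score")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("all scores must be finite")
    better = (arr[None, :] > arr[:, None]) if direction == "maximize" else (
        arr[None, :] < arr[:, None]
    )
    return [1 + int(b.sum()) for b in better]


@dataclass(frozen=True)
class RobustLine:
    intercept: float
    slope: float


def metric_concordance(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, RobustLine]:
    """Spearman rho (average ranks on ties) and a Huber robust line b ~ a."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("scores_a and scores_b must be 1-D with equal length")
    if len(a) < 3:
        raise UndefinedMetricError("metric concordance requires at least 3 paired scores")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("scores must be finite")
    rho = float(stats.spearmanr(a, b).statistic)

    import statsmodels.api as sm

    X = sm.add_constant(a)
    fit = sm.RLM(b, X, M=sm.robust.norms.HuberT()).fit()
    return rho, RobustLine(float(fit.params[0]), float(fit.params[1]))


@dataclass(frozen=True)
class ScoreReport:
    """Every metric this toolkit computes for one entry on one cohort split."""

    n_patients: int
    murmur_confusion: MurmurConfusion
    outcome_confusion_: OutcomeConfusion
    weighted_accuracy: float
    mean_cost: float
    total_cost: float
    murmur_traditional: TraditionalMetrics
    outcome_traditional: TraditionalMetrics
    cross_task: CrossTaskMetrics

    def as_rows(self) -> list[tuple[str, str, float]]:
        """Flatten to (metric, task, value) rows for the CSV report."""
        rows: list[tuple[str, str, float]] = [
            ("weighted_accuracy", "murmur", self.weighted_accuracy),
            ("mean_cost", "outcome", self.mean_cost),
            ("total_cost", "outcome", self.total_cost),
        ]
        for task, tm in (("murmur", self.murmur_traditional),
                         ("outcome", self.outcome_traditional)):
            rows += [
                ("auroc", task, tm.auroc),
                ("auprc", task, tm.auprc),
                ("f_measure", task, tm.f_measure),
                ("accuracy", task, tm.accuracy),
            ]
        rows += [
            ("weighted_accuracy_variant", "outcome", self.cross_task.outcome_weighted_accuracy),
            ("mean_cost_variant", "murmur", self.cross_task.murmur_mean_cost),
        ]
        return rows


def score_entry(
    murmur_labels: Mapping[str, str],
    outcome_labels: Mapping[str, str],
    outputs: Sequence[ModelOutput],
    params: Optional[CostParameters] = None,
) -> ScoreReport:
    """Compute the full ScoreReport for one entry on one set of patients."""
    params = params or CostParameters()
    mc = murmur_confusion(murmur_labels, outputs)
    oc = outcome_confusion(outcome_labels, outputs)
    total, mean = outcome_cost(oc, params)
    return ScoreReport(
        n_patients=mc.n_patients,
        murmur_confusion=mc,
        outcome_confusion_=oc,
        weighted_accuracy=weighted_accuracy(mc),
        mean_cost=mean,
        total_cost=total,
        murmur_traditional=traditional_metrics(murmur_labels, outputs, "murmur"),
        outcome_traditional=traditional_metrics(outcome_labels, outputs, "outcome"),
        cross_task=cross_task_metrics(murmur_labels, outcome_labels, outputs, params),
    )
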