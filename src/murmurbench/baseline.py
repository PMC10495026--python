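"""Reference screening entry: demographic + waveform-moment features into a
random forest, one model per task.

The feature vector has 25 slots: age-group one-hot (5), female indicator (1),
height (1), weight (1), pregnancy indicator (1), then for each of the four
valve locations (AV, PV, TV, MV) a block of (recording-presence indicator,
mean, variance, skewness) of the raw amplitude samples. Multiple recordings
at one location are averaged per-statistic; a location without a recording
contributes an all-zero block; recordings at other positions are ignored.
Missing height/weight are imputed with the training-set median.

This entry is intentionally simple — it exists as a minimal working,
label-sensitive reference for the evaluation harness, the voting ensemble
and the permutation audit, not as a competitive classifier.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier

from .types import (
    AGE_GROUPS,
    MURMUR_CLASSES,
    OUTCOME_CLASSES,
    VALVE_LOCATIONS,
    ModelOutput,
    PatientRecord,
    ValidationError,
)

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "MomentFeatureExtractor",
    "BaselineScreeningClassifier",
    "train_baseline",
    "predict_baseline",
    "baseline_outputs",
]

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"age_{g}" for g in AGE_GROUPS]
    + ["sex_female", "height", "weight", "pregnant"]
    + [f"{loc}_{stat}" for loc in VALVE_LOCATIONS
       for stat in ("presence", "mean", "variance", "skewness")]
)

# severity order per task: ties in predicted probability break toward the
# more severe class
_SEVERITY = {"murmur": MURMUR_CLASSES, "outcome": OUTCOME_CLASSES}


def _moments(samples: np.ndarray) -> tuple[float, float, float]:
    x = np.asarray(samples, dtype=np.float64)
    mean = float(x.mean())
    var = float(x.var())  # population variant
    if var < 1e-12:
        return mean, var, 0.0
    skew = float(((x - mean) ** 3).mean() / var**1.5)  # Fisher g1, population
    return mean, var, skew


def extract_features(patient: PatientRecord) -> np.ndarray:
    """Deterministic 25-slot feature vector; missing height/weight are NaN
    (imputed downstream by :class:`MomentFeatureExtractor`)."""
    d = patient.demographics
    vec = [1.0 if d.age_group == g else 0.0 for g in AGE_GROUPS]
    vec.append(1.0 if d.sex == "Female" else 0.0)
    vec.append(np.nan if d.height is None else d.height)
    vec.append(np.nan if d.weight is None else d.weight)
    vec.append(1.0 if d.pregnant else 0.0)
    by_loc: dict[str, list[tuple[float, float, float]]] = {}
    for rec in patient.recordings:
        if rec.location in VALVE_LOCATIONS:
            by_loc.setdefault(rec.location, []).append(_moments(rec.samples))
    for loc in VALVE_LOCATIONS:
        stats = by_loc.get(loc)
        if not stats:
            vec += [0.0, 0.0, 0.0, 0.0]
        else:
            arr = np.asarray(stats, dtype=float)
            vec += [1.0, *arr.mean(axis=0).tolist()]
    return np.asarray(vec, dtype=float)


class MomentFeatureExtractor(TransformerMixin, BaseEstimator):
    """Patient records -> feature matrix, with median imputation of the
    anthropometric columns learned at fit time."""

    def fit(self, X: Sequence[PatientRecord], y=None) -> "MomentFeatureExtractor":
        matrix = np.asarray([extract_features(p) for p in X])
        if matrix.size == 0:
            raise ValidationError("cannot fit the feature extractor on an empty cohort")
        self.n_features_in_ = matrix.shape[1]
        medians = {}
        for name in ("height", "weight"):
            col = matrix[:, FEATURE_NAMES.index(name)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
                med = np.nanmedian(col)
            medians[name] = 0.0 if np.isnan(med) else float(med)
        self.imputation_medians_ = medians
        return self

    def transform(self, X: Sequence[PatientRecord]) -> np.ndarray:
        matrix = np.asarray([extract_features(p) for p in X])
        if matrix.size == 0:
            return matrix.reshape(0, self.n_features_in_)
        for name, med in self.imputation_medians_.items():
            col = FEATURE_NAMES.index(name)
            matrix[np.isnan(matrix[:, col]), col] = med
        return matrix


class BaselineScreeningClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over moment features for one screening task.

    Parameters
    ----------
    task : {"murmur", "outcome"}
    n_estimators : int
        Trees in the forest (probabilities are tree-vote fractions).
    random_state : int
        Fixes the forest; (seed, cohort) fully determines all outputs.
    """

    def __init__(self, task: str = "murmur", n_estimators: int = 100, random_state: int = 0):
        self.task = task
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _labels(self, X: Sequence[PatientRecord]) -> list[str]:
        if self.task == "murmur":
            return [p.murmur.label for p in X]
        if self.task == "outcome":
            return [p.outcome.label for p in X]
        raise ValidationError(f"task must be 'murmur' or 'outcome', got {self.task!r}")

    def fit(self, X: Sequence[PatientRecord], y: Optional[Sequence[str]] = None):
        y = list(y) if y is not None else self._labels(X)
        if len(y) != len(X) or not len(X):
            raise ValidationError("X and y must be non-empty and equal-length")
        self.classes_ = _SEVERITY[self.task]
        for label in y:
            if label not in self.classes_:
                raise ValidationError(f"unknown {self.task} label {label!r}")
        self.extractor_ = MomentFeatureExtractor().fit(X)
        features = self.extractor_.transform(X)
        if len(set(y)) < 2:
            warnings.warn(
                f"single-class training labels ({y[0]!r}); falling back to a constant classifier",
                stacklevel=2,
            )
            self.constant_class_ = y[0]
            self.forest_ = None
            return self
        self.constant_class_ = None
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        ).fit(features, y)
        return self

    def predict_proba(self, X: Sequence[PatientRecord]) -> np.ndarray:
        """Class probabilities in severity order (most severe first)."""
        probs = np.zeros((len(X), len(self.classes_)))
        if self.forest_ is None:
            probs[:, self.classes_.index(self.constant_class_)] = 1.0
            return probs
        raw = self.forest_.predict_proba(self.extractor_.transform(X))
        for j, cls in enumerate(self.forest_.classes_):
            probs[:, self.classes_.index(cls)] = raw[:, j]
        return probs

    def predict(self, X: Sequence[PatientRecord]) -> np.ndarray:
        """Argmax of the probabilities; ties break toward the severer class
        (classes are ordered most-severe-first, argmax takes the first)."""
        probs = self.predict_proba(X)
        return np.asarray(self.classes_)[np.argmax(probs, axis=1)]


def train_baseline(
    cohort: Sequence[PatientRecord], task: str, seed: int = 0, n_estimators: int = 100
) -> BaselineScreeningClassifier:
    """Fit the reference entry for one task on a cohort."""
    return BaselineScreeningClassifier(
        task=task, n_estimators=n_estimators, random_state=seed
    ).fit(cohort)


def predict_baseline(
    model: BaselineScreeningClassifier, patient: PatientRecord
) -> tuple[str, tuple[float, ...]]:
    """(discrete class, probability vector in severity order) for one patient."""
    probs = model.predict_proba([patient])[0]
    cls = model.predict([patient])[0]
    return str(cls), tuple(float(v) for v in probs)


def baseline_outputs(
    murmur_model: BaselineScreeningClassifier,
    outcome_model: BaselineScreeningClassifier,
    patients: Sequence[PatientRecord],
) -> list[ModelOutput]:
    """Assemble full per-patient ModelOutputs from the two task models."""
    m_probs = murmur_model.predict_proba(patients)
    m_cls = murmur_model.predict(patients)
    o_probs = outcome_model.predict_proba(patients)
    o_cls = outcome_model.predict(patients)
    return [
        ModelOutput(
            patient_id=p.patient_id,
            murmur_class=str(m_cls[i]),
            murmur_probs=tuple(float(v) for v in m_probs[i]),
            outcome_class=str(o_cls[i]),
            outcome_probs=tuple(float(v) for v in o_probs[i]),
        )
        for i, p in enumerate(patients)
    ]
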