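"""Voting meta-learners over the discrete outputs of multiple entries.

A gradient-boosted-trees or random-forest meta-model is trained on the
one-hot-encoded discrete classes of the k best entries (ranked by the
relevant task metric on the training split), k is chosen on the validation
split by the same task metric, and the fused model is then evaluated on the
untouched test split. No hyperparameters beyond k are searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .metrics import (
    CostParameters,
    murmur_confusion,
    outcome_confusion,
    outcome_cost,
    weighted_accuracy,
)
from .types import MURMUR_CLASSES, OUTCOME_CLASSES, ModelOutput, ValidationError

__all__ = [
    "EnsembleConfig",
    "vote_features",
    "VotingEnsemble",
    "order_entries",
    "fit_voting_ensemble",
    "select_k",
    "challenge_score",
    "ensemble_outputs",
    "fuse_outputs",
]

MODEL_KINDS = ("gradient_boosted_trees", "random_forest")
_CLASSES = {"murmur": MURMUR_CLASSES, "outcome": OUTCOME_CLASSES}


@dataclass
class EnsembleConfig:
    """Settings of one voting-ensemble run (one task, one meta-model kind)."""

    task: str = "murmur"
    model_kind: str = "gradient_boosted_trees"
    k: int = 1
    max_k: Optional[int] = None
    seed: int = 0

    def validate(self, n_entries: Optional[int] = None) -> "EnsembleConfig":
        if self.task not in _CLASSES:
            raise ValidationError(f"task must be 'murmur' or 'outcome', got {self.task!r}")
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"model_kind must be one of {MODEL_KINDS}")
        if self.k < 1:
            raise ValidationError("k must be a positive integer")
        if n_entries is not None and self.k > n_entries:
            raise ValidationError(f"k = {self.k} exceeds the {n_entries} available entries")
        if self.max_k is not None and self.max_k < 1:
            raise ValidationError("max_k must be a positive integer")
        return self


def _discrete(out: ModelOutput, task: str) -> str:
    return out.murmur_class if task == "murmur" else out.outcome_class


def _ordered_patients(entry_outputs: Sequence[Sequence[ModelOutput]]) -> list[str]:
    if not entry_outputs:
        raise ValidationError("at least one entry is required")
    base = sorted(o.patient_id for o in entry_outputs[0])
    for i, outputs in enumerate(entry_outputs):
        ids = sorted(o.patient_id for o in outputs)
        if ids != base:
            raise ValidationError(f"entry {i} covers a different patient set")
    return base


def vote_features(
    entry_outputs: Sequence[Sequence[ModelOutput]], task: str
) -> tuple[np.ndarray, list[str]]:
    """One-hot matrix of each entry's discrete class, plus the row patient ids.

    Columns are ordered entry-by-entry (in the given, i.e. ranked, order) and
    class-by-class within an entry, so the matrix depends only on the entry
    ranking, never on input container order. Rows are sorted by patient id.
    """
    classes = _CLASSES[task]
    patients = _ordered_patients(entry_outputs)
    row = {pid: i for i, pid in enumerate(patients)}
    matrix = np.zeros((len(patients), len(classes) * len(entry_outputs)))
    for e, outputs in enumerate(entry_outputs):
        for out in outputs:
            matrix[row[out.patient_id], e * len(classes) + classes.index(_discrete(out, task))] = 1.0
    return matrix, patients


class VotingEnsemble(ClassifierMixin, BaseEstimator):
    """Meta-classifier over one-hot entry votes for a single task.

    Defaults: 100 boosting rounds at depth 3 (GBT) or 100 trees (RF); no other
    hyperparameters are tuned. The discrete prediction is the argmax of the
    meta-model probabilities with ties broken toward the severer class.
    """

    def __init__(self, task: str = "murmur", model_kind: str = "gradient_boosted_trees",
                 n_estimators: int = 100, max_depth: int = 3, random_state: int = 0):
        self.task = task
        self.model_kind = model_kind
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "VotingEnsemble":
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"model_kind must be one of {MODEL_KINDS}")
        self.classes_ = _CLASSES[self.task]
        y = list(y)
        if len(y) != len(X):
            raise ValidationError("X and y must have equal length")
        if len(set(y)) < 2:
            self.constant_class_ = y[0]
            self.model_ = None
            return self
        self.constant_class_ = None
        if self.model_kind == "gradient_boosted_trees":
            self.model_ = GradientBoostingClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                random_state=self.random_state,
            )
        else:
            self.model_ = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.random_state
            )
        self.model_.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = np.zeros((len(X), len(self.classes_)))
        if self.model_ is None:
            probs[:, self.classes_.index(self.constant_class_)] = 1.0
            return probs
        raw = self.model_.predict_proba(X)
        for j, cls in enumerate(self.model_.classes_):
            probs[:, self.classes_.index(cls)] = raw[:, j]
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.asarray(self.classes_)[np.argmax(probs, axis=1)]


def challenge_score(
    labels: Mapping[str, str], outputs: Sequence[ModelOutput], task: str,
    params: Optional[CostParameters] = None,
) -> float:
    """The task's official metric: weighted accuracy (murmur) or mean cost
    (outcome)."""
    if task == "murmur":
        return weighted_accuracy(murmur_confusion(labels, outputs))
    return outcome_cost(outcome_confusion(labels, outputs), params)[1]


def order_entries(
    entry_outputs: Sequence[Sequence[ModelOutput]],
    labels: Mapping[str, str],
    task: str,
    params: Optional[CostParameters] = None,
) -> list[int]:
    """Entry indices sorted best-first by the task metric on these labels
    (weighted accuracy descending / mean cost ascending; ties keep input
    order)."""
    scores = [challenge_score(labels, outputs, task, params) for outputs in entry_outputs]
    sign = -1.0 if task == "murmur" else 1.0
    return sorted(range(len(scores)), key=lambda i: (sign * scores[i], i))


def fit_voting_ensemble(
    train_outputs: Sequence[Sequence[ModelOutput]],
    train_labels: Mapping[str, str],
    config: EnsembleConfig,
) -> VotingEnsemble:
    """Fit the meta-model on the top-k entries (inputs must be pre-ranked
    best-first)."""
    config.validate(n_entries=len(train_outputs))
    top_k = list(train_outputs[: config.k])
    X, patients = vote_features(top_k, config.task)
    y = [train_labels[pid] for pid in patients]
    return VotingEnsemble(
        task=config.task, model_kind=config.model_kind, random_state=config.seed
    ).fit(X, y)


def select_k(
    entry_outputs_by_split: Mapping[str, Sequence[Sequence[ModelOutput]]],
    labels_by_split: Mapping[str, Mapping[str, str]],
    config: EnsembleConfig,
    params: Optional[CostParameters] = None,
) -> tuple[int, float]:
    """Scan k = 1..max_k, refit on train each time, score on validation.

    Returns the k with the best validation score (ties -> smallest k) and
    that score. The test split is never read here.
    """
    config.validate()
    train_entries = entry_outputs_by_split["train"]
    val_entries = entry_outputs_by_split["validation"]
    if len(train_entries) != len(val_entries):
        raise ValidationError("train and validation must cover the same entries")
    if not labels_by_split.get("validation"):
        raise ValidationError("validation split must be non-empty")
    max_k = config.max_k if config.max_k is not None else len(train_entries)
    if max_k > len(train_entries):
        raise ValidationError(f"max_k = {max_k} exceeds the {len(train_entries)} entries")

    ranking = order_entries(train_entries, labels_by_split["train"], config.task, params)
    ranked_train = [train_entries[i] for i in ranking]
    ranked_val = [val_entries[i] for i in ranking]

    best_k, best_score = None, None
    maximize = config.task == "murmur"
    for k in range(1, max_k + 1):
        cfg_k = EnsembleConfig(task=config.task, model_kind=config.model_kind, k=k,
                               seed=config.seed)
        model = fit_voting_ensemble(ranked_train, labels_by_split["train"], cfg_k)
        outputs = ensemble_outputs(model, ranked_val[:k])
        score = challenge_score(labels_by_split["validation"], outputs, config.task, params)
        better = (
            best_score is None
            or (maximize and score > best_score)
            or (not maximize and score < best_score)
        )
        if better:
            best_k, best_score = k, score
    return best_k, best_score


def ensemble_outputs(
    model: VotingEnsemble, entry_outputs: Sequence[Sequence[ModelOutput]]
) -> list[ModelOutput]:
    """Fused per-patient outputs for the model's task.

    The other task's fields are filled with a neutral placeholder (least
    severe class, uniform probabilities); fuse murmur and outcome ensembles
    with :func:`fuse_outputs` to obtain a complete entry file.
    """
    X, patients = vote_features(entry_outputs, model.task)
    classes = model.predict(X)
    probs = model.predict_proba(X)
    outputs = []
    for i, pid in enumerate(patients):
        if model.task == "murmur":
            outputs.append(ModelOutput(
                patient_id=pid,
                murmur_class=str(classes[i]),
                murmur_probs=tuple(float(v) for v in probs[i]),
                outcome_class="Normal",
                outcome_probs=(0.5, 0.5),
            ))
        else:
            outputs.append(ModelOutput(
                patient_id=pid,
                murmur_class="Absent",
                murmur_probs=(1 / 3, 1 / 3, 1 / 3),
                outcome_class=str(classes[i]),
                outcome_probs=tuple(float(v) for v in probs[i]),
            ))
    return outputs


def fuse_outputs(
    murmur_outputs: Sequence[ModelOutput], outcome_outputs: Sequence[ModelOutput]
) -> list[ModelOutput]:
    """Merge the murmur fields of one output set with the outcome fields of
    another (the two independent per-task ensemble runs)."""
    by_id = {o.patient_id: o for o in outcome_outputs}
    if sorted(by_id) != sorted(o.patient_id for o in murmur_outputs):
        raise ValidationError("murmur and outcome outputs cover different patients")
    return [
        ModelOutput(
            patient_id=m.patient_id,
            murmur_class=m.murmur_class,
            murmur_probs=m.murmur_probs,
            outcome_class=by_id[m.patient_id].outcome_class,
            outcome_probs=by_id[m.patient_id].outcome_probs,
        )
        for m in murmur_outputs
    ]
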