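"""Orchestration: per-split evaluation, the label-permutation robustness
audit, and leaderboard assembly.

The audit retrains an entry on a subset of the training split whose
(murmur, outcome) label pairs have been permuted jointly across patients,
scores the retrained model on the untouched validation split with the
original labels, and compares against the same training procedure run on the
identical subset with the original labels. Entries whose validation score
degrades past a threshold are classified as "learning"; label-blind entries
degrade by exactly zero and are "insensitive"; a trainer that raises is
"crashed". Nothing about the stored cohort is ever modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import challenge_score
from .metrics import CostParameters, ScoreReport, rank_entries, score_entry
from .simulate import SPLITS, SplitAssignment
from .types import ModelOutput, PatientRecord, ValidationError

__all__ = [
    "AuditResult",
    "Leaderboard",
    "evaluate_entry",
    "permutation_audit",
    "build_leaderboard",
    "Trainer",
]

logger = logging.getLogger("murmurbench")

# A trainer maps (training cohort, seed) to a prediction function over any
# list of patients; the audit never hands it validation or test labels.
Trainer = Callable[[Sequence[PatientRecord], int], Callable[[Sequence[PatientRecord]],
                                                            Sequence[ModelOutput]]]


def _labels(patients: Sequence[PatientRecord], task: str) -> dict[str, str]:
    if task == "murmur":
        return {p.patient_id: p.murmur.label for p in patients}
    return {p.patient_id: p.outcome.label for p in patients}


def split_patients(
    cohort: Sequence[PatientRecord], assignment: SplitAssignment
) -> dict[str, list[PatientRecord]]:
    """Partition a cohort per the assignment (every patient must be mapped)."""
    missing = [p.patient_id for p in cohort if p.patient_id not in assignment.assignment]
    if missing:
        raise ValidationError(f"patients missing from split assignment: {missing}")
    out: dict[str, list[PatientRecord]] = {s: [] for s in SPLITS}
    for p in cohort:
        out[assignment[p.patient_id]].append(p)
    return out


def evaluate_entry(
    cohort: Sequence[PatientRecord],
    assignment: SplitAssignment,
    outputs_per_split: Mapping[str, Sequence[ModelOutput]],
    params: Optional[CostParameters] = None,
) -> dict[str, ScoreReport]:
    """Score one entry independently on each split it provides outputs for.

    The outputs of a split must cover exactly that split's patients.
    """
    by_split = split_patients(cohort, assignment)
    reports: dict[str, ScoreReport] = {}
    for split, outputs in outputs_per_split.items():
        if split not in SPLITS:
            raise ValidationError(f"unknown split {split!r}")
        patients = by_split[split]
        reports[split] = score_entry(
            _labels(patients, "murmur"), _labels(patients, "outcome"), outputs, params
        )
        logger.info("evaluated split=%s n=%d", split, len(patients))
    return reports


@dataclass(frozen=True)
class AuditResult:
    """Outcome of the label-permutation robustness audit for one entry."""

    entry_id: str
    score_original: Optional[float]
    score_permuted: Optional[float]
    degradation: Optional[float]  # sign-adjusted: positive = worse after permutation
    verdict: str  # learning | insensitive | crashed
    diagnostics: Optional[str] = None


def _permute_label_pairs(
    patients: Sequence[PatientRecord], rng: np.random.Generator
) -> list[PatientRecord]:
    """New records whose (murmur, outcome) pairs are permuted jointly across
    patients, preserving the labels' joint distribution."""
    order = rng.permutation(len(patients))
    return [
        replace(p, murmur=patients[j].murmur, outcome=patients[j].outcome)
        for p, j in zip(patients, order)
    ]


def permutation_audit(
    trainer: Trainer,
    cohort: Sequence[PatientRecord],
    assignment: SplitAssignment,
    subset_fraction: float = 0.5,
    seed: int = 0,
    threshold: float = 0.05,
    task: str = "murmur",
    entry_id: str = "entry",
    params: Optional[CostParameters] = None,
) -> AuditResult:
    """Classify an entry as learning / insensitive / crashed.

    Both runs train on the same random subset of the training split — one with
    the original labels, one with the (murmur, outcome) pairs permuted jointly
    across patients — and are scored on the validation split with the original
    labels. Degradation is score_original - score_permuted for the murmur task
    and the relative cost increase (permuted - original) / original for the
    outcome task, so positive always means "worse after permutation".
    """
    if not (0 < subset_fraction <= 1):
        raise ValidationError("subset_fraction must lie in (0, 1]")
    by_split = split_patients(cohort, assignment)
    train, validation = by_split["train"], by_split["validation"]
    if not train or not validation:
        raise ValidationError("audit requires non-empty train and validation splits")

    rng = np.random.default_rng(seed)
    n_subset = max(1, int(round(subset_fraction * len(train))))
    subset_idx = rng.choice(len(train), size=n_subset, replace=False)
    subset = [train[i] for i in sorted(subset_idx)]
    permuted_subset = _permute_label_pairs(subset, rng)
    val_labels = _labels(validation, task)

    try:
        predict_original = trainer(subset, seed)
        score_original = challenge_score(val_labels, predict_original(validation), task, params)
        predict_permuted = trainer(permuted_subset, seed)
        score_permuted = challenge_score(val_labels, predict_permuted(validation), task, params)
    except Exception as exc:  # noqa: BLE001 - the audit records, never propagates
        logger.warning("audit of %s crashed: %s", entry_id, exc)
        return AuditResult(entry_id, None, None, None, "crashed",
                           diagnostics=f"{type(exc).__name__}: {exc}")

    if task == "murmur":
        degradation = score_original - score_permuted
    else:
        degradation = (score_permuted - score_original) / score_original
    verdict = "learning" if degradation > threshold else "insensitive"
    logger.info(
        "audit entry=%s task=%s original=%.4f permuted=%.4f degradation=%.4f verdict=%s",
        entry_id, task, score_original, score_permuted, degradation, verdict,
    )
    return AuditResult(entry_id, score_original, score_permuted, degradation, verdict)


@dataclass(frozen=True)
class Leaderboard:
    """Competition tables for both tasks (one row per entry, official metric
    last, competition ranks with ties sharing the best rank)."""

    murmur: pd.DataFrame
    outcome: pd.DataFrame


def build_leaderboard(score_reports: Mapping[str, ScoreReport]) -> Leaderboard:
    """Rank entries: weighted accuracy descending (murmur task), mean cost
    ascending (outcome task)."""
    if not score_reports:
        raise ValidationError("at least one score report is required")
    entries = list(score_reports)
    murmur_rows, outcome_rows = [], []
    for entry in entries:
        r = score_reports[entry]
        mt, ot = r.murmur_traditional, r.outcome_traditional
        murmur_rows.append((entry, mt.auroc, mt.auprc, mt.f_measure, mt.accuracy,
                            r.weighted_accuracy))
        outcome_rows.append((entry, ot.auroc, ot.auprc, ot.f_measure, ot.accuracy, r.mean_cost))

    murmur = pd.DataFrame(murmur_rows, columns=["entry", "auroc", "auprc", "f_measure",
                                                "accuracy", "weighted_accuracy"])
    murmur.insert(0, "rank", rank_entries(murmur["weighted_accuracy"], "maximize"))
    murmur = murmur.sort_values(["rank", "entry"], kind="mergesort").reset_index(drop=True)

    outcome = pd.DataFrame(outcome_rows, columns=["entry", "auroc", "auprc", "f_measure",
                                                  "accuracy", "cost"])
    outcome.insert(0, "rank", rank_entries(outcome["cost"], "minimize"))
    outcome = outcome.sort_values(["rank", "entry"], kind="mergesort").reset_index(drop=True)
    return Leaderboard(murmur=murmur, outcome=outcome)
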