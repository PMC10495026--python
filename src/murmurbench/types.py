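"""Domain types for screened patients, annotations, recordings and model outputs.

A cohort is a list of :class:`PatientRecord`. Each patient carries demographics,
one or more located phonocardiogram (PCG) recordings, a murmur annotation
(Present / Unknown / Absent, with a structured description of the murmur when
present) and a binary clinical-outcome annotation (Abnormal / Normal).

Model outputs pair a discrete class with a probability vector for each of the
two screening tasks. The discrete class is authoritative for confusion-matrix
metrics; the probabilities are authoritative for ranking metrics (AUROC/AUPRC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "MURMUR_CLASSES",
    "OUTCOME_CLASSES",
    "LOCATIONS",
    "VALVE_LOCATIONS",
    "CAMPAIGNS",
    "SYSTOLIC_TIMINGS",
    "SYSTOLIC_SHAPES",
    "DIASTOLIC_TIMINGS",
    "DIASTOLIC_SHAPES",
    "PITCHES",
    "GRADES",
    "SYSTOLIC_QUALITIES",
    "DIASTOLIC_QUALITIES",
    "ValidationError",
    "ParseError",
    "DemographicProfile",
    "MurmurDescriptor",
    "MurmurAnnotation",
    "OutcomeAnnotation",
    "Recording",
    "PatientRecord",
    "ModelOutput",
    "validate_patient",
    "validate_cohort",
    "validate_model_output",
]

# Controlled vocabularies (annotation schema of the screening dataset).
AGE_GROUPS = ("Neonate", "Infant", "Child", "Adolescent", "Missing")
SEXES = ("Female", "Male")
MURMUR_CLASSES = ("Present", "Unknown", "Absent")
OUTCOME_CLASSES = ("Abnormal", "Normal")
LOCATIONS = ("AV", "PV", "TV", "MV", "Phc")
VALVE_LOCATIONS = ("AV", "PV", "TV", "MV")
CAMPAIGNS = ("CC2014", "CC2015")
SYSTOLIC_TIMINGS = ("Early-systolic", "Mid-systolic", "Late-systolic", "Holosystolic")
SYSTOLIC_SHAPES = ("Crescendo", "Decrescendo", "Diamond", "Plateau")
DIASTOLIC_TIMINGS = ("Early-diastolic", "Mid-diastolic", "Holodiastolic")
DIASTOLIC_SHAPES = ("Decrescendo", "Plateau")
PITCHES = ("Low", "Medium", "High")
GRADES = ("I", "II", "III")
SYSTOLIC_QUALITIES = ("Blowing", "Harsh", "Musical")
DIASTOLIC_QUALITIES = ("Blowing", "Harsh")


class ValidationError(ValueError):
    """A domain invariant is violated."""


class ParseError(ValueError):
    """A file does not conform to the documented exchange format."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


def _check_in(value, vocab, what: str) -> None:
    if value not in vocab:
        raise ValidationError(f"{what} must be one of {vocab}, got {value!r}")


@dataclass(frozen=True)
class DemographicProfile:
    """Age group, sex, anthropometrics and pregnancy status of one patient.

    ``height`` (cm) and ``weight`` (kg) are ``None`` when unknown; the text
    format writes them as the ``nan`` sentinel.
    """

    age_group: str
    sex: str
    height: Optional[float] = None
    weight: Optional[float] = None
    pregnant: bool = False

    def validate(self) -> None:
        _check_in(self.age_group, AGE_GROUPS, "age_group")
        _check_in(self.sex, SEXES, "sex")
        for name, v in (("height", self.height), ("weight", self.weight)):
            if v is not None:
                if not math.isfinite(v) or v <= 0:
                    raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.pregnant and self.age_group in ("Neonate", "Infant", "Child"):
            raise ValidationError(
                f"pregnant=True is inconsistent with age_group {self.age_group!r}"
            )


@dataclass(frozen=True)
class MurmurDescriptor:
    """Qualitative description of a murmur within one cardiac phase."""

    timing: str
    shape: str
    pitch: str
    grade: str
    quality: str

    def validate(self, phase: str) -> None:
        if phase == "systolic":
            timings, shapes, qualities = SYSTOLIC_TIMINGS, SYSTOLIC_SHAPES, SYSTOLIC_QUALITIES
        elif phase == "diastolic":
            timings, shapes, qualities = DIASTOLIC_TIMINGS, DIASTOLIC_SHAPES, DIASTOLIC_QUALITIES
        else:  # pragma: no cover - internal misuse
            raise ValueError(phase)
        _check_in(self.timing, timings, f"{phase} timing")
        _check_in(self.shape, shapes, f"{phase} shape")
        _check_in(self.pitch, PITCHES, f"{phase} pitch")
        _check_in(self.grade, GRADES, f"{phase} grade")
        _check_in(self.quality, qualities, f"{phase} quality")


@dataclass(frozen=True)
class MurmurAnnotation:
    """Expert murmur label with location and phase descriptors.

    Invariants: a non-Present label carries no locations and no descriptors;
    a Present label carries at least one location and at least one of the
    systolic/diastolic descriptors; ``most_audible`` is one of ``locations``.
    """

    label: str
    locations: frozenset[str] = frozenset()
    most_audible: Optional[str] = None
    systolic: Optional[MurmurDescriptor] = None
    diastolic: Optional[MurmurDescriptor] = None

    def validate(self) -> None:
        _check_in(self.label, MURMUR_CLASSES, "murmur label")
        for loc in self.locations:
            _check_in(loc, LOCATIONS, "murmur location")
        if self.label != "Present":
            if self.locations or self.systolic or self.diastolic or self.most_audible:
                raise ValidationError(
                    f"murmur label {self.label!r} must have no locations or descriptors"
                )
        else:
            if not self.locations:
                raise ValidationError("Present murmur requires at least one location")
            if self.systolic is None and self.diastolic is None:
                raise ValidationError(
                    "Present murmur requires a systolic and/or diastolic descriptor"
                )
            if self.most_audible is not None and self.most_audible not in self.locations:
                raise ValidationError(
                    f"most_audible {self.most_audible!r} not among locations {sorted(self.locations)}"
                )
        if self.systolic is not None:
            self.systolic.validate("systolic")
        if self.diastolic is not None:
            self.diastolic.validate("diastolic")


@dataclass(frozen=True)
class OutcomeAnnotation:
    """Binary clinical-outcome label from the full diagnostic work-up."""

    label: str

    def validate(self) -> None:
        _check_in(self.label, OUTCOME_CLASSES, "outcome label")


@dataclass
class Recording:
    """One located PCG recording: amplitudes in [-1, 1] at a fixed rate."""

    location: str
    sample_rate: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def validate(self) -> None:
        _check_in(self.location, LOCATIONS, "recording location")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValidationError(f"sample_rate must be a positive integer, got {self.sample_rate}")
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValidationError("recording must contain a non-empty 1-D sample sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("recording samples must be finite")
        amax = float(np.abs(self.samples).max())
        if amax > 1.0 + 1e-6:
            raise ValidationError(f"recording amplitudes must lie in [-1, 1], max |a| = {amax}")

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.location == other.location
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class PatientRecord:
    """One screened patient: demographics, recordings and both labels."""

    patient_id: str
    demographics: DemographicProfile
    recordings: list[Recording]
    murmur: MurmurAnnotation
    outcome: OutcomeAnnotation
    campaign: str = "CC2014"
    linked_id: Optional[str] = None

    def validate(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.linked_id is not None and self.linked_id == self.patient_id:
            raise ValidationError("linked_id must differ from patient_id")
        _check_in(self.campaign, CAMPAIGNS, "campaign")
        self.demographics.validate()
        if not self.recordings:
            raise ValidationError(f"patient {self.patient_id}: at least one recording required")
        for rec in self.recordings:
            rec.validate()
        self.murmur.validate()
        self.outcome.validate()


@dataclass(frozen=True)
class ModelOutput:
    """One entry's decisions and probabilities for a single patient.

    The discrete class need not equal the argmax of the probabilities:
    entries may threshold the two independently.
    """

    patient_id: str
    murmur_class: str
    murmur_probs: tuple[float, float, float]  # (Present, Unknown, Absent)
    outcome_class: str
    outcome_probs: tuple[float, float]  # (Abnormal, Normal)

    def validate(self) -> None:
        validate_model_output(self)


def _check_probs(probs: Sequence[float], what: str, tol: float = 1e-6) -> None:
    arr = np.asarray(probs, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} must be finite and non-negative, got {list(arr)}")
    if abs(arr.sum() - 1.0) > tol:
        raise ValidationError(f"{what} must sum to 1 (got {arr.sum():.8f})")


def validate_model_output(out: ModelOutput) -> None:
    if not out.patient_id:
        raise ValidationError("patient_id must be non-empty")
    _check_in(out.murmur_class, MURMUR_CLASSES, "murmur_class")
    _check_in(out.outcome_class, OUTCOME_CLASSES, "outcome_class")
    if len(out.murmur_probs) != 3:
        raise ValidationError("murmur_probs must have 3 entries (Present, Unknown, Absent)")
    if len(out.outcome_probs) != 2:
        raise ValidationError("outcome_probs must have 2 entries (Abnormal, Normal)")
    _check_probs(out.murmur_probs, "murmur_probs")
    _check_probs(out.outcome_probs, "outcome_probs")


def validate_patient(patient: PatientRecord) -> None:
    """Assert every invariant of a single patient record."""
    patient.validate()


def validate_cohort(cohort: Sequence[PatientRecord]) -> None:
    """Assert per-patient invariants plus cohort-level id uniqueness."""
    seen: set[str] = set()
    for p in cohort:
        validate_patient(p)
        if p.patient_id in seen:
            raise ValidationError(f"duplicate patient_id {p.patient_id!r}")
        seen.add(p.patient_id)
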