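"""Readers and writers for the cohort exchange format and entry-output files.

Cohort on disk
--------------
One UTF-8 header file ``<patient_id>.hea`` per patient with ``key: value``
lines for the annotation variables (``nan`` is the missing sentinel) followed
by one ``recording:`` line per PCG recording::

    recording: <LOCATION> <SAMPLE_RATE> <WAV_FILENAME>

Audio is stored as 16-bit PCM mono WAV; amplitudes map linearly between the
int16 range and [-1, 1]. Writing is deterministic: identical cohorts produce
byte-identical files.

Entry outputs on disk
---------------------
One CSV per split with header row
``patient_id,murmur_class,p_present,p_unknown,p_absent,outcome_class,p_abnormal,p_normal``.
Probability vectors whose sum deviates from 1 by at most 1e-3 are renormalized
on read; larger deviations are validation errors.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.io import wavfile

from .types import (
    CAMPAIGNS,
    AGE_GROUPS,
    SEXES,
    MURMUR_CLASSES,
    OUTCOME_CLASSES,
    LOCATIONS,
    DemographicProfile,
    ModelOutput,
    MurmurAnnotation,
    MurmurDescriptor,
    OutcomeAnnotation,
    ParseError,
    PatientRecord,
    Recording,
    ValidationError,
    validate_cohort,
    validate_model_output,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_model_outputs",
    "write_model_outputs",
    "read_split_manifest",
    "write_split_manifest",
    "quantize_amplitudes",
]

_PCM_FULL_SCALE = 32767.0
_MISSING = "nan"

_HEADER_KEYS = (
    "patient_id",
    "linked_id",
    "campaign",
    "age_group",
    "sex",
    "height",
    "weight",
    "pregnant",
    "murmur",
    "murmur_locations",
    "most_audible",
    "systolic_timing",
    "systolic_shape",
    "systolic_pitch",
    "systolic_grade",
    "systolic_quality",
    "diastolic_timing",
    "diastolic_shape",
    "diastolic_pitch",
    "diastolic_grade",
    "diastolic_quality",
    "outcome",
)

_OUTPUT_COLUMNS = (
    "patient_id",
    "murmur_class",
    "p_present",
    "p_unknown",
    "p_absent",
    "outcome_class",
    "p_abnormal",
    "p_normal",
)


def quantize_amplitudes(samples: np.ndarray) -> np.ndarray:
    """Snap amplitudes onto the 16-bit PCM grid (k / 32767, k in int16 range).

    Waveforms on this grid survive a WAV write/read cycle bit-exactly.
    """
    ints = np.clip(np.round(np.asarray(samples, dtype=np.float64) * _PCM_FULL_SCALE),
                   -32768, 32767)
    return (ints / _PCM_FULL_SCALE).astype(np.float32)


def _fmt(value: Optional[object]) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _patient_to_lines(patient: PatientRecord, wav_names: Sequence[str]) -> list[str]:
    m = patient.murmur
    sys_d, dia_d = m.systolic, m.diastolic
    values = {
        "patient_id": patient.patient_id,
        "linked_id": patient.linked_id,
        "campaign": patient.campaign,
        "age_group": patient.demographics.age_group,
        "sex": patient.demographics.sex,
        "height": patient.demographics.height,
        "weight": patient.demographics.weight,
        "pregnant": patient.demographics.pregnant,
        "murmur": m.label,
        "murmur_locations": "+".join(sorted(m.locations)) if m.locations else None,
        "most_audible": m.most_audible,
        "systolic_timing": sys_d.timing if sys_d else None,
        "systolic_shape": sys_d.shape if sys_d else None,
        "systolic_pitch": sys_d.pitch if sys_d else None,
        "systolic_grade": sys_d.grade if sys_d else None,
        "systolic_quality": sys_d.quality if sys_d else None,
        "diastolic_timing": dia_d.timing if dia_d else None,
        "diastolic_shape": dia_d.shape if dia_d else None,
        "diastolic_pitch": dia_d.pitch if dia_d else None,
        "diastolic_grade": dia_d.grade if dia_d else None,
        "diastolic_quality": dia_d.quality if dia_d else None,
        "outcome": patient.outcome.label,
    }
    lines = [f"{key}: {_fmt(values[key])}" for key in _HEADER_KEYS]
    for rec, name in zip(patient.recordings, wav_names):
        lines.append(f"recording: {rec.location} {rec.sample_rate} {name}")
    return lines


def write_cohort(cohort: Sequence[PatientRecord], directory: Union[str, Path]) -> list[str]:
    """Write a cohort to ``directory``; return the manifest of files written.

    Output is deterministic: the same cohort always yields byte-identical
    files. Audio is written as 16-bit PCM mono WAV.
    """
    validate_cohort(cohort)
    directory = Path(directory)
    manifest: list[str] = []
    if cohort:
        directory.mkdir(parents=True, exist_ok=True)
    for patient in cohort:
        wav_names = []
        loc_counts: dict[str, int] = {}
        for rec in patient.recordings:
            loc_counts[rec.location] = loc_counts.get(rec.location, 0) + 1
            n = loc_counts[rec.location]
            suffix = f"_{n}" if n > 1 else ""
            wav_names.append(f"{patient.patient_id}_{rec.location}{suffix}.wav")
        header_name = f"{patient.patient_id}.hea"
        text = "\n".join(_patient_to_lines(patient, wav_names)) + "\n"
        (directory / header_name).write_text(text, encoding="utf-8", newline="\n")
        manifest.append(header_name)
        for rec, name in zip(patient.recordings, wav_names):
            ints = np.clip(
                np.round(rec.samples.astype(np.float64) * _PCM_FULL_SCALE), -32768, 32767
            ).astype(np.int16)
            wavfile.write(directory / name, int(rec.sample_rate), ints)
            manifest.append(name)
    return manifest


def _parse_enum(value: str, vocab, what: str, path: str, line: int) -> str:
    if value not in vocab:
        raise ParseError(f"{what} must be one of {vocab}, got {value!r}", path, line)
    return value


def _parse_optional_float(value: str, what: str, path: str, line: int) -> Optional[float]:
    if value == _MISSING:
        return None
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{what} must be a number or 'nan', got {value!r}", path, line) from None


def _read_wav(path: Path) -> tuple[int, np.ndarray]:
    if not path.exists():
        raise IOError(f"referenced WAV file not found: {path}")
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ParseError(f"expected 16-bit PCM WAV, got dtype {data.dtype}", str(path))
    if data.ndim != 1:
        raise ParseError("expected mono WAV", str(path))
    return int(rate), (data.astype(np.float32) / _PCM_FULL_SCALE)


def _read_header(path: Path) -> PatientRecord:
    fields: dict[str, str] = {}
    field_lines: dict[str, int] = {}
    recordings: list[tuple[str, int, str, int]] = []  # location, rate, filename, line
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        if ":" not in raw:
            raise ParseError("expected 'key: value'", str(path), lineno)
        key, _, value = raw.partition(":")
        key, value = key.strip(), value.strip()
        if key == "recording":
            parts = value.split()
            if len(parts) != 3:
                raise ParseError(
                    "recording line must be '<LOC> <RATE> <FILE>'", str(path), lineno
                )
            loc = _parse_enum(parts[0], LOCATIONS, "recording location", str(path), lineno)
            try:
                rate = int(parts[1])
            except ValueError:
                raise ParseError(f"invalid sample rate {parts[1]!r}", str(path), lineno) from None
            recordings.append((loc, rate, parts[2], lineno))
        else:
            if key not in _HEADER_KEYS:
                raise ParseError(f"unknown header key {key!r}", str(path), lineno)
            fields[key] = value
            field_lines[key] = lineno

    missing = [k for k in _HEADER_KEYS if k not in fields]
    if missing:
        raise ParseError(f"missing header keys: {missing}", str(path))

    p = str(path)
    demographics = DemographicProfile(
        age_group=_parse_enum(fields["age_group"], AGE_GROUPS, "age_group", p,
                              field_lines["age_group"]),
        sex=_parse_enum(fields["sex"], SEXES, "sex", p, field_lines["sex"]),
        height=_parse_optional_float(fields["height"], "height", p, field_lines["height"]),
        weight=_parse_optional_float(fields["weight"], "weight", p, field_lines["weight"]),
        pregnant=_parse_enum(
            fields["pregnant"], ("True", "False"), "pregnant", p, field_lines["pregnant"]
        )
        == "True",
    )

    locs_raw = fields["murmur_locations"]
    locations = (
        frozenset(
            _parse_enum(tok, LOCATIONS, "murmur location", p, field_lines["murmur_locations"])
            for tok in locs_raw.split("+")
        )
        if locs_raw != _MISSING
        else frozenset()
    )

    def descriptor(phase: str) -> Optional[MurmurDescriptor]:
        keys = [f"{phase}_{part}" for part in ("timing", "shape", "pitch", "grade", "quality")]
        vals = [fields[k] for k in keys]
        if all(v == _MISSING for v in vals):
            return None
        if any(v == _MISSING for v in vals):
            raise ParseError(
                f"{phase} descriptor must be fully present or fully 'nan'", p,
                field_lines[keys[0]],
            )
        return MurmurDescriptor(*vals)

    murmur = MurmurAnnotation(
        label=_parse_enum(fields["murmur"], MURMUR_CLASSES, "murmur", p, field_lines["murmur"]),
        locations=locations,
        most_audible=None if fields["most_audible"] == _MISSING else _parse_enum(
            fields["most_audible"], LOCATIONS, "most_audible", p, field_lines["most_audible"]
        ),
        systolic=descriptor("systolic"),
        diastolic=descriptor("diastolic"),
    )
    outcome = OutcomeAnnotation(
        _parse_enum(fields["outcome"], OUTCOME_CLASSES, "outcome", p, field_lines["outcome"])
    )

    recs = []
    for loc, rate, filename, lineno in recordings:
        wav_rate, samples = _read_wav(path.parent / filename)
        if wav_rate != rate:
            raise ParseError(
                f"header sample rate {rate} != WAV sample rate {wav_rate}", p, lineno
            )
        recs.append(Recording(location=loc, sample_rate=rate, samples=samples))

    record = PatientRecord(
        patient_id=fields["patient_id"],
        linked_id=None if fields["linked_id"] == _MISSING else fields["linked_id"],
        campaign=_parse_enum(fields["campaign"], CAMPAIGNS, "campaign", p, field_lines["campaign"]),
        demographics=demographics,
        recordings=recs,
        murmur=murmur,
        outcome=outcome,
    )
    record.validate()
    return record


def read_cohort(directory: Union[str, Path]) -> list[PatientRecord]:
    """Read every patient header (and its WAV files) under ``directory``."""
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"cohort directory not found: {directory}")
    cohort = [_read_header(h) for h in sorted(directory.glob("*.hea"))]
    validate_cohort(cohort)
    return cohort


def write_model_outputs(outputs: Sequence[ModelOutput], path: Union[str, Path]) -> None:
    """Write entry outputs as the documented CSV layout (UTF-8, '.' decimal)."""
    seen: set[str] = set()
    for out in outputs:
        validate_model_output(out)
        if out.patient_id in seen:
            raise ValidationError(f"duplicate patient_id {out.patient_id!r}")
        seen.add(out.patient_id)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_OUTPUT_COLUMNS)
        for out in outputs:
            writer.writerow(
                [out.patient_id, out.murmur_class]
                + [repr(float(v)) for v in out.murmur_probs]
                + [out.outcome_class]
                + [repr(float(v)) for v in out.outcome_probs]
            )


def _normalize_probs(values: Sequence[float], what: str, path: str, line: int) -> tuple[float, ...]:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path}: line {line}: {what} must be finite and non-negative")
    total = arr.sum()
    if abs(total - 1.0) > 1e-3:
        raise ValidationError(
            f"{path}: line {line}: {what} sums to {total:.6f}, deviates from 1 by more than 1e-3"
        )
    if total > 0 and abs(total - 1.0) > 1e-12:
        arr = arr / total
    return tuple(float(v) for v in arr)


def read_model_outputs(path: Union[str, Path]) -> list[ModelOutput]:
    """Read entry outputs; renormalize probability vectors within tolerance."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"model output file not found: {path}")
    outputs: list[ModelOutput] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty model output file", str(path)) from None
        if tuple(h.strip() for h in header) != _OUTPUT_COLUMNS:
            raise ParseError(
                f"expected header {','.join(_OUTPUT_COLUMNS)}", str(path), 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_OUTPUT_COLUMNS):
                raise ParseError(f"expected {len(_OUTPUT_COLUMNS)} columns", str(path), lineno)
            pid = row[0].strip()
            if pid in seen:
                raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            murmur_class = _parse_enum(row[1].strip(), MURMUR_CLASSES, "murmur_class",
                                       str(path), lineno)
            outcome_class = _parse_enum(row[5].strip(), OUTCOME_CLASSES, "outcome_class",
                                        str(path), lineno)
            try:
                m_probs = [float(v) for v in row[2:5]]
                o_probs = [float(v) for v in row[6:8]]
            except ValueError:
                raise ParseError("invalid probability value", str(path), lineno) from None
            outputs.append(
                ModelOutput(
                    patient_id=pid,
                    murmur_class=murmur_class,
                    murmur_probs=_normalize_probs(m_probs, "murmur probabilities",
                                                  str(path), lineno),
                    outcome_class=outcome_class,
                    outcome_probs=_normalize_probs(o_probs, "outcome probabilities",
                                                   str(path), lineno),
                )
            )
    return outputs


def write_split_manifest(assignment: Mapping[str, str], path: Union[str, Path]) -> None:
    """Write a split manifest CSV (columns: patient_id, split)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "split"])
        for pid in sorted(assignment):
            writer.writerow([pid, assignment[pid]])


def read_split_manifest(path: Union[str, Path]) -> dict[str, str]:
    """Read a split manifest CSV back into a patient_id -> split mapping."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"split manifest not found: {path}")
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["patient_id", "split"]:
            raise ParseError("expected header 'patient_id,split'", str(path), 1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError("expected 2 columns", str(path), lineno)
            pid, split = row[0].strip(), row[1].strip()
            if split not in ("train", "validation", "test"):
                raise ParseError(f"unknown split {split!r}", str(path), lineno)
            if pid in mapping:
                raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
            mapping[pid] = split
    return mapping
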