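"""Synthetic phonocardiogram cohort simulator.

Generates statistically controlled cohorts — demographics, murmur taxonomy,
clinical outcomes and PCG waveforms — whose default marginal distributions
match the published screening-dataset marginals (murmur Present 0.195,
Unknown 0.076, Absent 0.730; outcome Abnormal 0.482), and splits them
60/10/30 by recording count with patient-level grouping so that linked
patients (same individual across screening campaigns) never straddle splits.

The waveform model is deliberately phenomenological: per-cycle S1/S2
transients as Gaussian-windowed tones plus, for murmur-positive patients, a
band-limited noise component gated to the annotated cardiac phase, shaped by
the annotated envelope, band-located by pitch and scaled by grade. It is a
test-signal generator, not a hemodynamic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .io import quantize_amplitudes
from .types import (
    AGE_GROUPS,
    DIASTOLIC_SHAPES,
    DIASTOLIC_TIMINGS,
    DIASTOLIC_QUALITIES,
    GRADES,
    MURMUR_CLASSES,
    PITCHES,
    SYSTOLIC_QUALITIES,
    SYSTOLIC_SHAPES,
    SYSTOLIC_TIMINGS,
    VALVE_LOCATIONS,
    DemographicProfile,
    MurmurAnnotation,
    MurmurDescriptor,
    OutcomeAnnotation,
    PatientRecord,
    Recording,
    ValidationError,
    validate_cohort,
)

__all__ = ["SimulationConfig", "SplitAssignment", "sample_cohort", "synthesize_pcg",
           "split_cohort", "SPLITS"]

SPLITS = ("train", "validation", "test")

# Anthropometrics by age group: (height mean, height sd, weight mean, weight sd).
# Chosen to bracket the published cohort medians (height ~115 cm, weight ~20 kg).
_ANTHROPOMETRY = {
    "Neonate": (50.0, 3.0, 3.4, 0.6),
    "Infant": (68.0, 6.0, 7.8, 1.6),
    "Child": (115.0, 18.0, 21.0, 7.5),
    "Adolescent": (158.0, 10.0, 50.0, 11.0),
    "Missing": (115.0, 25.0, 22.0, 10.0),
}


def _normalized(probs: Sequence[float], what: str, tol: float = 5e-3) -> tuple[float, ...]:
    arr = np.asarray(probs, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} must be finite and non-negative")
    total = arr.sum()
    if abs(total - 1.0) > tol:
        raise ValidationError(f"{what} must sum to 1 (got {total:.4f})")
    return tuple(float(v) for v in arr / total)


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator.

    Probability-vector defaults reproduce the published dataset's marginal
    distributions; printed marginals that sum to 0.999/1.001 due to rounding
    are renormalized. The outcome is sampled conditionally on the murmur
    class; the Absent-class conditional is solved at validation time so that
    the marginal abnormal rate hits ``target_abnormal_rate``.
    """

    n_patients: int = 1000
    # (Present, Unknown, Absent)
    murmur_prevalence: tuple[float, float, float] = (0.195, 0.076, 0.730)
    # P(Abnormal | murmur class); the Absent entry None means "solve from the
    # marginal target".
    outcome_abnormal_given_murmur: dict = field(
        default_factory=lambda: {"Present": 0.85, "Unknown": 0.5, "Absent": None}
    )
    target_abnormal_rate: float = 0.482
    # (Neonate, Infant, Child, Adolescent, Missing)
    age_group_probs: tuple[float, ...] = (0.006, 0.122, 0.708, 0.085, 0.078)
    female_prob: float = 0.498
    # pregnancy is only possible in the Adolescent / Missing age groups;
    # 0.43 * P(Adolescent or Missing) ~ the published 0.070 marginal
    pregnancy_prob_adolescent: float = 0.43
    missing_anthropometrics_prob: float = 0.05
    # number of distinct recorded valve locations -> probability
    recording_locations_per_patient: dict = field(
        default_factory=lambda: {1: 0.10, 2: 0.15, 3: 0.15, 4: 0.60}
    )
    linked_fraction: float = 0.06
    sample_rate: int = 4000
    recording_duration_range: tuple[float, float] = (5.0, 12.0)
    heart_rate_by_age: dict = field(
        default_factory=lambda: {
            "Neonate": (120.0, 160.0),
            "Infant": (100.0, 150.0),
            "Child": (80.0, 120.0),
            "Adolescent": (60.0, 100.0),
            "Missing": (80.0, 120.0),
        }
    )
    murmur_band_by_pitch: dict = field(
        default_factory=lambda: {"Low": (80.0, 150.0), "Medium": (150.0, 300.0),
                                 "High": (300.0, 600.0)}
    )
    grade_to_murmur_gain: dict = field(
        default_factory=lambda: {"I": 0.1, "II": 0.25, "III": 0.5}
    )
    noise_sd: float = 0.01
    # low-SNR rendering for murmur-Unknown patients ("not adequate for diagnosis")
    unknown_noise_sd: float = 0.35
    diastolic_murmur_prob: float = 0.2
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        """Check every invariant; return self for chaining."""
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            raise ValidationError("n_patients must be a positive integer")
        self.murmur_prevalence = _normalized(self.murmur_prevalence, "murmur_prevalence")
        self.age_group_probs = _normalized(self.age_group_probs, "age_group_probs")
        if len(self.age_group_probs) != len(AGE_GROUPS):
            raise ValidationError("age_group_probs must have 5 entries")
        for name, p in (
            ("female_prob", self.female_prob),
            ("pregnancy_prob_adolescent", self.pregnancy_prob_adolescent),
            ("missing_anthropometrics_prob", self.missing_anthropometrics_prob),
            ("target_abnormal_rate", self.target_abnormal_rate),
            ("linked_fraction", self.linked_fraction),
            ("diastolic_murmur_prob", self.diastolic_murmur_prob),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        counts = sorted(self.recording_locations_per_patient)
        if not counts or any(c < 1 or c > len(VALVE_LOCATIONS) for c in counts):
            raise ValidationError("recording location counts must lie in 1..4")
        probs = [self.recording_locations_per_patient[c] for c in counts]
        probs = _normalized(probs, "recording_locations_per_patient")
        self.recording_locations_per_patient = dict(zip(counts, probs))
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValidationError("sample_rate must be a positive integer")
        lo, hi = self.recording_duration_range
        if not (0 < lo < hi):
            raise ValidationError("recording_duration_range must be non-degenerate")
        for group, (a, b) in self.heart_rate_by_age.items():
            if not (0 < a < b):
                raise ValidationError(f"heart_rate_by_age[{group!r}] must be non-degenerate")
        nyquist = self.sample_rate / 2.0
        for pitch, (a, b) in self.murmur_band_by_pitch.items():
            if not (0 < a < b):
                raise ValidationError(f"murmur_band_by_pitch[{pitch!r}] must be non-degenerate")
            if b >= nyquist:
                raise ValidationError(
                    f"murmur band {pitch!r} upper edge {b} Hz exceeds Nyquist {nyquist} Hz"
                )
        for grade in GRADES:
            g = self.grade_to_murmur_gain.get(grade)
            if g is None or g <= 0:
                raise ValidationError(f"grade_to_murmur_gain[{grade!r}] must be positive")
        if self.noise_sd < 0 or self.unknown_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")
        # solve P(Abnormal | Absent) from the marginal target when unset
        cond = dict(self.outcome_abnormal_given_murmur)
        for cls in ("Present", "Unknown"):
            if not (0.0 <= cond.get(cls, -1) <= 1.0):
                raise ValidationError(f"outcome_abnormal_given_murmur[{cls!r}] must be in [0, 1]")
        pP, pU, pA = self.murmur_prevalence
        if cond.get("Absent") is None:
            if pA <= 0:
                # the Absent class is unreachable; its conditional is moot
                cond["Absent"] = 0.0
                self.outcome_abnormal_given_murmur = cond
                return self
            x = (self.target_abnormal_rate - pP * cond["Present"] - pU * cond["Unknown"]) / pA
            if not (0.0 <= x <= 1.0):
                raise ValidationError(
                    f"solved P(Abnormal|Absent) = {x:.4f} lies outside [0, 1]; "
                    "adjust target_abnormal_rate or the conditionals"
                )
            cond["Absent"] = x
        elif not (0.0 <= cond["Absent"] <= 1.0):
            raise ValidationError("outcome_abnormal_given_murmur['Absent'] must be in [0, 1]")
        self.outcome_abnormal_given_murmur = cond
        return self


@dataclass
class SplitAssignment:
    """Total mapping patient_id -> train / validation / test."""

    assignment: dict[str, str]

    def patients(self, split: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == split]

    def __getitem__(self, patient_id: str) -> str:
        return self.assignment[patient_id]


# ---------------------------------------------------------------------------
# waveform synthesis


def _envelope(shape: str, n: int) -> np.ndarray:
    ramp = np.linspace(0.0, 1.0, n)
    if shape == "Crescendo":
        return 0.1 + 0.9 * ramp
    if shape == "Decrescendo":
        return 1.0 - 0.9 * ramp
    if shape == "Diamond":
        return 0.1 + 0.9 * (1.0 - np.abs(2.0 * ramp - 1.0))
    if shape == "Plateau":
        return np.ones(n)
    raise ValidationError(f"unknown murmur shape {shape!r}")


def _phase_window(timing: str, start: float, stop: float) -> tuple[float, float]:
    """Sub-interval of a cardiac phase [start, stop] selected by `timing`."""
    length = stop - start
    key = timing.split("-")[0]
    if timing in ("Holosystolic", "Holodiastolic"):
        return start, stop
    if key == "Early":
        return start, start + 0.5 * length
    if key == "Mid":
        return start + 0.25 * length, start + 0.75 * length
    if key == "Late":
        return start + 0.5 * length, stop
    raise ValidationError(f"unknown murmur timing {timing!r}")


def _gaussian_tone(t: np.ndarray, centers: np.ndarray, freq: float, sigma: float,
                   amp: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 4 * sigma)
        hi = np.searchsorted(t, c + 4 * sigma)
        tt = t[lo:hi] - c
        out[lo:hi] += amp * np.exp(-0.5 * (tt / sigma) ** 2) * np.sin(2 * np.pi * freq * tt)
    return out


def _band_noise(rng: np.random.Generator, n: int, fs: int, band: tuple[float, float]) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.999)
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    out = sps.sosfiltfilt(sos, white)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


_S1_AMP = 1.0  # reference amplitude for grade gains
_S2_AMP = 0.8
_S1_FREQ, _S1_SIGMA = 50.0, 0.012
_S2_FREQ, _S2_SIGMA = 70.0, 0.010


def _murmur_gate(murmur: MurmurAnnotation, t: np.ndarray, period: float,
                 n_cycles: int) -> list[tuple[np.ndarray, MurmurDescriptor]]:
    """Per-descriptor multiplicative gates (envelope inside phase, 0 outside)."""
    gates = []
    for phase, desc in (("systolic", murmur.systolic), ("diastolic", murmur.diastolic)):
        if desc is None:
            continue
        gate = np.zeros_like(t)
        for k in range(n_cycles + 1):
            t0 = k * period
            if phase == "systolic":
                a, b = t0 + 0.10 * period, t0 + 0.34 * period
            else:
                a, b = t0 + 0.46 * period, t0 + 0.98 * period
            a, b = _phase_window(desc.timing, a, b)
            lo = np.searchsorted(t, a)
            hi = np.searchsorted(t, b)
            if hi > lo:
                gate[lo:hi] = _envelope(desc.shape, hi - lo)
        gates.append((gate, desc))
    return gates


def synthesize_pcg(
    murmur: MurmurAnnotation,
    heart_rate: float,
    duration: float,
    location: str,
    config: SimulationConfig,
    rng_seed,
    noise_sd: Optional[float] = None,
) -> Recording:
    """Render one located PCG recording.

    The waveform is per-cycle S1/S2 Gaussian-windowed tones plus, when the
    location is among the murmur's annotated locations, a band-limited noise
    component gated to the annotated phase and timing, enveloped by the
    annotated shape, band-located by pitch and scaled by grade relative to
    the S1 peak; white measurement noise of sd ``noise_sd`` is added and the
    result is peak-normalized to at most 0.99. The base signal (S1/S2 +
    measurement noise) is drawn from a random stream independent of the
    murmur component, so re-rendering the same seed without the murmur
    reproduces the identical base waveform.
    """
    period = 60.0 / heart_rate
    if duration < 3 * period:
        raise ValidationError(
            f"duration {duration:.2f}s is shorter than 3 cardiac cycles ({3 * period:.2f}s)"
        )
    if murmur.label == "Present" and murmur.systolic is None and murmur.diastolic is None:
        raise ValidationError("Present murmur requires a systolic and/or diastolic descriptor")

    fs = int(config.sample_rate)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    n_cycles = int(math.ceil(duration / period))

    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    base_ss, murmur_ss = ss.spawn(2)
    base_rng = np.random.default_rng(base_ss)
    murmur_rng = np.random.default_rng(murmur_ss)

    s1_centers = np.arange(n_cycles + 1) * period + 0.05 * period
    s2_centers = np.arange(n_cycles + 1) * period + 0.40 * period
    x = _gaussian_tone(t, s1_centers, _S1_FREQ, _S1_SIGMA, _S1_AMP)
    x += _gaussian_tone(t, s2_centers, _S2_FREQ, _S2_SIGMA, _S2_AMP)

    sd = config.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        x += sd * base_rng.standard_normal(n)

    if murmur.label == "Present" and location in murmur.locations:
        for gate, desc in _murmur_gate(murmur, t, period, n_cycles):
            band = config.murmur_band_by_pitch[desc.pitch]
            gain = config.grade_to_murmur_gain[desc.grade] * _S1_AMP
            x += gain * gate * _band_noise(murmur_rng, n, fs, band)

    peak = float(np.abs(x).max())
    if peak > 0.99:
        x = x * (0.99 / peak)
    return Recording(location=location, sample_rate=fs, samples=quantize_amplitudes(x))


# ---------------------------------------------------------------------------
# cohort sampling


def _sample_murmur(rng: np.random.Generator, label: str, rec_locations: Sequence[str],
                   config: SimulationConfig) -> MurmurAnnotation:
    if label != "Present":
        return MurmurAnnotation(label=label)
    locs = [loc for loc in rec_locations if rng.random() < 0.5]
    if not locs:
        locs = [rec_locations[int(rng.integers(len(rec_locations)))]]
    systolic = MurmurDescriptor(
        timing=str(rng.choice(SYSTOLIC_TIMINGS)),
        shape=str(rng.choice(SYSTOLIC_SHAPES)),
        pitch=str(rng.choice(PITCHES)),
        grade=str(rng.choice(GRADES)),
        quality=str(rng.choice(SYSTOLIC_QUALITIES)),
    )
    diastolic = None
    if rng.random() < config.diastolic_murmur_prob:
        diastolic = MurmurDescriptor(
            timing=str(rng.choice(DIASTOLIC_TIMINGS)),
            shape=str(rng.choice(DIASTOLIC_SHAPES)),
            pitch=str(rng.choice(PITCHES)),
            grade=str(rng.choice(GRADES)),
            quality=str(rng.choice(DIASTOLIC_QUALITIES)),
        )
    return MurmurAnnotation(
        label="Present",
        locations=frozenset(locs),
        most_audible=locs[int(rng.integers(len(locs)))],
        systolic=systolic,
        diastolic=diastolic,
    )


def _sample_demographics(rng: np.random.Generator, config: SimulationConfig) -> DemographicProfile:
    age_group = str(rng.choice(AGE_GROUPS, p=config.age_group_probs))
    sex = "Female" if rng.random() < config.female_prob else "Male"
    pregnant = False
    if age_group in ("Adolescent", "Missing") and sex == "Female":
        # pregnancy_prob_adolescent is the per-patient rate within the
        # eligible age groups; realizing it only in females requires dividing
        # by the female fraction so the configured marginal is preserved
        p = min(1.0, config.pregnancy_prob_adolescent / max(config.female_prob, 1e-12))
        pregnant = rng.random() < p
    hm, hs, wm, ws = _ANTHROPOMETRY[age_group]
    height = float(np.clip(rng.normal(hm, hs), 0.3 * hm, 2.0 * hm))
    weight = float(np.clip(rng.normal(wm, ws), 0.3 * wm, 2.5 * wm))
    if rng.random() < config.missing_anthropometrics_prob:
        height = None
    if rng.random() < config.missing_anthropometrics_prob:
        weight = None
    return DemographicProfile(age_group=age_group, sex=sex, height=height,
                              weight=weight, pregnant=pregnant)


def sample_cohort(config: SimulationConfig, rng_seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw a full synthetic cohort of ``config.n_patients`` patients.

    Fully reproducible: the same (config, seed) pair yields the identical
    cohort, waveforms included.
    """
    config = replace(config)  # do not mutate the caller's config during validation
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    ss = np.random.SeedSequence(seed)
    label_ss, audio_ss = ss.spawn(2)
    rng = np.random.default_rng(label_ss)
    audio_children = audio_ss.spawn(config.n_patients)

    n = config.n_patients
    width = max(4, len(str(n)))
    cond = config.outcome_abnormal_given_murmur
    counts = sorted(config.recording_locations_per_patient)
    count_probs = [config.recording_locations_per_patient[c] for c in counts]

    # designate linked pairs (same individual attending both campaigns)
    n_pairs = int(n * config.linked_fraction / 2)
    paired = rng.choice(n, size=2 * n_pairs, replace=False) if n_pairs > 0 else np.array([], int)
    partner = {}
    for i in range(n_pairs):
        a, b = int(paired[2 * i]), int(paired[2 * i + 1])
        partner[a], partner[b] = b, a

    cohort: list[PatientRecord] = []
    for i in range(n):
        pid = f"P{i:0{width}d}"
        demographics = _sample_demographics(rng, config)
        murmur_label = str(rng.choice(MURMUR_CLASSES, p=config.murmur_prevalence))
        outcome_label = "Abnormal" if rng.random() < cond[murmur_label] else "Normal"

        k = int(rng.choice(counts, p=count_probs))
        rec_locations = sorted(rng.choice(VALVE_LOCATIONS, size=k, replace=False).tolist())
        murmur = _sample_murmur(rng, murmur_label, rec_locations, config)

        hr_lo, hr_hi = config.heart_rate_by_age[demographics.age_group]
        heart_rate = float(rng.uniform(hr_lo, hr_hi))
        noise_sd = config.unknown_noise_sd if murmur_label == "Unknown" else None

        rec_seeds = audio_children[i].spawn(len(rec_locations))
        recordings = []
        dur_lo, dur_hi = config.recording_duration_range
        for loc, rseed in zip(rec_locations, rec_seeds):
            duration = float(rng.uniform(dur_lo, dur_hi))
            duration = max(duration, 3 * 60.0 / heart_rate + 1.0 / config.sample_rate)
            recordings.append(
                synthesize_pcg(murmur, heart_rate, duration, loc, config, rseed,
                               noise_sd=noise_sd)
            )

        if i in partner:
            campaign = "CC2014" if i < partner[i] else "CC2015"
            linked = f"P{partner[i]:0{width}d}"
        else:
            campaign = "CC2014" if rng.random() < 0.416 else "CC2015"
            linked = None

        cohort.append(
            PatientRecord(
                patient_id=pid,
                demographics=demographics,
                recordings=recordings,
                murmur=murmur,
                outcome=OutcomeAnnotation(outcome_label),
                campaign=campaign,
                linked_id=linked,
            )
        )
    validate_cohort(cohort)
    return cohort


# ---------------------------------------------------------------------------
# splitting


def _linked_groups(cohort: Sequence[PatientRecord]) -> list[list[int]]:
    """Connected components under the linked_id relation."""
    index = {p.patient_id: i for i, p in enumerate(cohort)}
    parent = list(range(len(cohort)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, p in enumerate(cohort):
        if p.linked_id is not None and p.linked_id in index:
            a, b = find(i), find(index[p.linked_id])
            if a != b:
                parent[a] = b
    groups: dict[int, list[int]] = {}
    for i in range(len(cohort)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def split_cohort(
    cohort: Sequence[PatientRecord],
    fractions: tuple[float, float, float] = (0.60, 0.10, 0.30),
    rng_seed: int = 0,
) -> SplitAssignment:
    """Assign patients to train/validation/test, grouped by linked identity.

    The assignment targets the requested *recording-count* fractions: linked
    groups are ordered largest-first (seeded shuffle breaks ties) and each is
    assigned greedily to the split with the largest remaining recording
    deficit, so achieved fractions are as close to the targets as the
    grouping allows. Deterministic under a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValidationError("fractions must be 3 non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {sum(fractions)!r}")
    if not cohort:
        return SplitAssignment({})

    rng = np.random.default_rng(rng_seed)
    groups = _linked_groups(cohort)
    order = rng.permutation(len(groups))
    rec_count = [sum(len(cohort[i].recordings) for i in g) for g in groups]
    ordered = sorted(order.tolist(), key=lambda gi: -rec_count[gi])

    total = sum(rec_count)
    targets = [f * total for f in fractions]
    assigned = [0.0, 0.0, 0.0]
    result: dict[str, str] = {}
    for gi in ordered:
        deficits = [targets[s] - assigned[s] for s in range(3)]
        s = int(np.argmax(deficits))
        assigned[s] += rec_count[gi]
        for i in groups[gi]:
            result[cohort[i].patient_id] = SPLITS[s]
    return SplitAssignment(result)
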