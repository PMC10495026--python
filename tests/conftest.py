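import numpy as np
import pytest

from murmurbench import (
    DemographicProfile,
    ModelOutput,
    MurmurAnnotation,
    MurmurDescriptor,
    OutcomeAnnotation,
    PatientRecord,
    Recording,
    SimulationConfig,
)

MURMUR_CLASSES = ("Present", "Unknown", "Absent")
OUTCOME_CLASSES = ("Abnormal", "Normal")


def fast_config(**overrides) -> SimulationConfig:
    """Simulator config with short, low-rate recordings for quick tests.

    Label distributions stay at the defaults unless overridden.
    """
    base = dict(
        n_patients=50,
        sample_rate=2000,
        recording_duration_range=(3.2, 4.0),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def fast_cfg():
    return fast_config()


def make_recording(location="AV", sample_rate=2000, samples=None) -> Recording:
    if samples is None:
        samples = np.linspace(-0.5, 0.5, 64)
    return Recording(location=location, sample_rate=sample_rate,
                     samples=np.asarray(samples, dtype=np.float32))


def make_patient(pid="P1", murmur_label="Absent", outcome_label="Normal",
                 locations=("AV",), height=115.0, weight=20.0, age_group="Child",
                 **kwargs) -> PatientRecord:
    if murmur_label == "Present":
        murmur = MurmurAnnotation(
            label="Present",
            locations=frozenset([locations[0]]),
            most_audible=locations[0],
            systolic=MurmurDescriptor("Holosystolic", "Plateau", "Medium", "II", "Harsh"),
        )
    else:
        murmur = MurmurAnnotation(label=murmur_label)
    return PatientRecord(
        patient_id=pid,
        demographics=DemographicProfile(age_group=age_group, sex="Female",
                                        height=height, weight=weight),
        recordings=[make_recording(loc) for loc in locations],
        murmur=murmur,
        outcome=OutcomeAnnotation(outcome_label),
        **kwargs,
    )


def make_output(pid, murmur_class="Absent", outcome_class="Normal",
                murmur_probs=None, outcome_probs=None) -> ModelOutput:
    if murmur_probs is None:
        murmur_probs = tuple(0.8 if c == murmur_class else 0.1 for c in MURMUR_CLASSES)
    if outcome_probs is None:
        outcome_probs = tuple(0.7 if c == outcome_class else 0.3 for c in OUTCOME_CLASSES)
    return ModelOutput(patient_id=pid, murmur_class=murmur_class,
                       murmur_probs=tuple(murmur_probs), outcome_class=outcome_class,
                       outcome_probs=tuple(outcome_probs))


def random_scored_cohort(rng: np.random.Generator, max_patients: int = 12):
    """Random labels + model outputs for oracle comparisons.

    Guarantees at least two murmur classes and both outcome classes so every
    metric is defined.
    """
    while True:
        n = int(rng.integers(4, max_patients + 1))
        murmur_labels = [str(rng.choice(MURMUR_CLASSES)) for _ in range(n)]
        outcome_labels = [str(rng.choice(OUTCOME_CLASSES)) for _ in range(n)]
        if len(set(murmur_labels)) >= 2 and len(set(outcome_labels)) == 2:
            break
    pids = [f"P{i}" for i in range(n)]
    outputs = []
    for pid in pids:
        mp = rng.dirichlet(np.ones(3))
        op = rng.dirichlet(np.ones(2))
        # discretize some probabilities so tied scores are exercised
        if rng.random() < 0.5:
            mp = np.round(mp, 1)
            op = np.round(op, 1)
            mp = mp / mp.sum() if mp.sum() > 0 else np.ones(3) / 3
            op = op / op.sum() if op.sum() > 0 else np.ones(2) / 2
        outputs.append(ModelOutput(
            patient_id=pid,
            murmur_class=str(rng.choice(MURMUR_CLASSES)),
            murmur_probs=tuple(float(v) for v in mp),
            outcome_class=str(rng.choice(OUTCOME_CLASSES)),
            outcome_probs=tuple(float(v) for v in op),
        ))
    return dict(zip(pids, murmur_labels)), dict(zip(pids, outcome_labels)), outputs
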