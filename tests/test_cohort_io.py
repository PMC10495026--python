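import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murmurbench import (
    DemographicProfile,
    ModelOutput,
    MurmurAnnotation,
    MurmurDescriptor,
    OutcomeAnnotation,
    ParseError,
    PatientRecord,
    Recording,
    ValidationError,
    read_cohort,
    read_model_outputs,
    read_split_manifest,
    write_cohort,
    write_model_outputs,
    write_split_manifest,
)
from murmurbench.types import validate_cohort

from conftest import make_output, make_patient, make_recording


# --- hypothesis strategies for valid domain objects -------------------------

pcm_samples = st.lists(st.integers(-32767, 32767), min_size=2, max_size=32).map(
    lambda ints: np.asarray(ints, dtype=np.float32) / 32767.0
)
locations = st.sampled_from(["AV", "PV", "TV", "MV", "Phc"])


@st.composite
def patients(draw, pid: str):
    age = draw(st.sampled_from(["Neonate", "Infant", "Child", "Adolescent", "Missing"]))
    demographics = DemographicProfile(
        age_group=age,
        sex=draw(st.sampled_from(["Female", "Male"])),
        height=draw(st.one_of(st.none(), st.floats(30, 200))),
        weight=draw(st.one_of(st.none(), st.floats(1, 120))),
        pregnant=draw(st.booleans()) if age in ("Adolescent", "Missing") else False,
    )
    label = draw(st.sampled_from(["Present", "Unknown", "Absent"]))
    if label == "Present":
        locs = draw(st.frozensets(locations, min_size=1, max_size=3))
        murmur = MurmurAnnotation(
            label="Present",
            locations=locs,
            most_audible=draw(st.sampled_from(sorted(locs))),
            systolic=MurmurDescriptor(
                draw(st.sampled_from(["Early-systolic", "Mid-systolic", "Late-systolic",
                                      "Holosystolic"])),
                draw(st.sampled_from(["Crescendo", "Decrescendo", "Diamond", "Plateau"])),
                draw(st.sampled_from(["Low", "Medium", "High"])),
                draw(st.sampled_from(["I", "II", "III"])),
                draw(st.sampled_from(["Blowing", "Harsh", "Musical"])),
            ),
            diastolic=draw(st.one_of(st.none(), st.builds(
                MurmurDescriptor,
                st.sampled_from(["Early-diastolic", "Mid-diastolic", "Holodiastolic"]),
                st.sampled_from(["Decrescendo", "Plateau"]),
                st.sampled_from(["Low", "Medium", "High"]),
                st.sampled_from(["I", "II", "III"]),
                st.sampled_from(["Blowing", "Harsh"]),
            ))),
        )
    else:
        murmur = MurmurAnnotation(label=label)
    recs = [
        Recording(location=draw(locations), sample_rate=draw(st.integers(100, 8000)),
                  samples=draw(pcm_samples))
        for _ in range(draw(st.integers(1, 3)))
    ]
    return PatientRecord(
        patient_id=pid,
        demographics=demographics,
        recordings=recs,
        murmur=murmur,
        outcome=OutcomeAnnotation(draw(st.sampled_from(["Abnormal", "Normal"]))),
        campaign=draw(st.sampled_from(["CC2014", "CC2015"])),
    )


@st.composite
def cohorts(draw):
    n = draw(st.integers(1, 4))
    return [draw(patients(f"P{i:03d}")) for i in range(n)]


class TestCohortRoundTrip:
    @given(cohort=cohorts())
    @settings(max_examples=25, deadline=None)
    def test_write_then_read_reproduces_cohort(self, cohort, tmp_path_factory):
        d = tmp_path_factory.mktemp("cohort")
        write_cohort(cohort, d)
        back = read_cohort(d)
        assert len(back) == len(cohort)
        for a, b in zip(sorted(cohort, key=lambda p: p.patient_id), back):
            assert a.patient_id == b.patient_id
            assert a.demographics == b.demographics
            assert a.murmur == b.murmur
            assert a.outcome == b.outcome
            assert a.campaign == b.campaign and a.linked_id == b.linked_id
            assert a.recordings == b.recordings

    def test_writing_twice_is_byte_identical(self, tmp_path):
        cohort = [make_patient("P1", "Present", "Abnormal", locations=("AV", "MV"))]
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = write_cohort(cohort, d1)
        m2 = write_cohort(cohort, d2)
        assert m1 == m2
        for name in m1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_empty_cohort_empty_manifest(self, tmp_path):
        assert write_cohort([], tmp_path / "empty") == []

    def test_manifest_counts_headers_and_wavs(self, tmp_path):
        cohort = [make_patient("P1", locations=("AV", "MV"))]
        manifest = write_cohort(cohort, tmp_path)
        assert len(manifest) == 3
        assert sum(n.endswith(".hea") for n in manifest) == 1
        assert sum(n.endswith(".wav") for n in manifest) == 2


class TestCohortValidation:
    def test_present_murmur_without_locations_rejected(self):
        with pytest.raises(ValidationError):
            MurmurAnnotation(
                label="Present",
                systolic=MurmurDescriptor("Holosystolic", "Plateau", "Low", "I", "Harsh"),
            ).validate()

    def test_present_murmur_without_descriptor_rejected(self):
        with pytest.raises(ValidationError):
            MurmurAnnotation(label="Present", locations=frozenset({"AV"})).validate()

    def test_absent_murmur_with_locations_rejected(self):
        with pytest.raises(ValidationError):
            MurmurAnnotation(label="Absent", locations=frozenset({"AV"})).validate()

    def test_pregnant_child_rejected(self):
        with pytest.raises(ValidationError):
            DemographicProfile(age_group="Child", sex="Female", pregnant=True).validate()

    def test_duplicate_patient_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            validate_cohort([make_patient("P1"), make_patient("P1")])

    def test_linked_id_must_differ(self):
        with pytest.raises(ValidationError):
            make_patient("P1", linked_id="P1").validate()

    def test_amplitude_bounds_enforced(self):
        with pytest.raises(ValidationError):
            Recording("AV", 1000, np.array([0.0, 1.5])).validate()


class TestHeaderParsing:
    def _write_header(self, d, pid="P001", **overrides):
        lines = {
            "patient_id": pid, "linked_id": "nan", "campaign": "CC2014",
            "age_group": "Child", "sex": "Female", "height": "115.0",
            "weight": "20.0", "pregnant": "False", "murmur": "Absent",
            "murmur_locations": "nan", "most_audible": "nan",
            "systolic_timing": "nan", "systolic_shape": "nan",
            "systolic_pitch": "nan", "systolic_grade": "nan",
            "systolic_quality": "nan", "diastolic_timing": "nan",
            "diastolic_shape": "nan", "diastolic_pitch": "nan",
            "diastolic_grade": "nan", "diastolic_quality": "nan",
            "outcome": "Normal",
        }
        lines.update(overrides)
        text = "\n".join(f"{k}: {v}" for k, v in lines.items())
        text += f"\nrecording: AV 1000 {pid}_AV.wav\n"
        (d / f"{pid}.hea").write_text(text)
        from scipy.io import wavfile
        wavfile.write(d / f"{pid}_AV.wav", 1000, np.zeros(100, dtype=np.int16) + 10)

    def test_missing_heights_parse_to_sentinel(self, tmp_path):
        """Hand-built 3-patient fixture: heights nan / 115 / 89."""
        for pid, h in (("P001", "nan"), ("P002", "115.0"), ("P003", "89.0")):
            self._write_header(tmp_path, pid=pid, height=h)
        cohort = read_cohort(tmp_path)
        heights = [p.demographics.height for p in cohort]
        assert heights == [None, 115.0, 89.0]

    def test_malformed_enum_reports_line_number(self, tmp_path):
        self._write_header(tmp_path, murmur="Maybe")
        with pytest.raises(ParseError, match="line 9"):
            read_cohort(tmp_path)

    def test_missing_wav_is_io_error_naming_file(self, tmp_path):
        self._write_header(tmp_path)
        (tmp_path / "P001_AV.wav").unlink()
        with pytest.raises(IOError, match="P001_AV.wav"):
            read_cohort(tmp_path)

    def test_present_with_empty_locations_is_validation_error(self, tmp_path):
        self._write_header(
            tmp_path, murmur="Present",
            systolic_timing="Holosystolic", systolic_shape="Plateau",
            systolic_pitch="Low", systolic_grade="I", systolic_quality="Harsh",
        )
        with pytest.raises(ValidationError):
            read_cohort(tmp_path)


class TestModelOutputs:
    def test_round_trip_identity(self, tmp_path):
        outputs = [
            make_output("P1", "Present", "Abnormal", (0.5, 0.3, 0.2), (0.9, 0.1)),
            make_output("P2", "Absent", "Normal", (0.1, 0.2, 0.7), (0.25, 0.75)),
        ]
        path = tmp_path / "out.csv"
        write_model_outputs(outputs, path)
        assert read_model_outputs(path) == outputs

    def test_normalized_probabilities_unchanged(self, tmp_path):
        path = tmp_path / "out.csv"
        write_model_outputs([make_output("P1", murmur_probs=(0.5, 0.3, 0.2))], path)
        assert read_model_outputs(path)[0].murmur_probs == (0.5, 0.3, 0.2)

    def test_small_deviation_renormalized(self, tmp_path):
        path = tmp_path / "out.csv"
        path.write_text(
            "patient_id,murmur_class,p_present,p_unknown,p_absent,"
            "outcome_class,p_abnormal,p_normal\n"
            "P1,Present,0.5,0.3,0.2005,Normal,0.5,0.5\n"
        )
        probs = read_model_outputs(path)[0].murmur_probs
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert probs[0] == pytest.approx(0.5 / 1.0005, abs=1e-12)

    def test_large_deviation_rejected(self, tmp_path):
        path = tmp_path / "out.csv"
        path.write_text(
            "patient_id,murmur_class,p_present,p_unknown,p_absent,"
            "outcome_class,p_abnormal,p_normal\n"
            "P1,Present,0.7,0.7,0.7,Normal,0.5,0.5\n"
        )
        with pytest.raises(ValidationError, match="1e-3"):
            read_model_outputs(path)

    def test_unknown_class_name_is_parse_error(self, tmp_path):
        path = tmp_path / "out.csv"
        path.write_text(
            "patient_id,murmur_class,p_present,p_unknown,p_absent,"
            "outcome_class,p_abnormal,p_normal\n"
            "P1,Loud,1.0,0.0,0.0,Normal,0.5,0.5\n"
        )
        with pytest.raises(ParseError):
            read_model_outputs(path)

    def test_duplicate_patient_rejected_on_both_paths(self, tmp_path):
        outputs = [make_output("P1"), make_output("P1")]
        with pytest.raises(ValidationError):
            write_model_outputs(outputs, tmp_path / "o.csv")
        path = tmp_path / "dup.csv"
        path.write_text(
            "patient_id,murmur_class,p_present,p_unknown,p_absent,"
            "outcome_class,p_abnormal,p_normal\n"
            "P1,Absent,0,0,1,Normal,0.5,0.5\nP1,Absent,0,0,1,Normal,0.5,0.5\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_model_outputs(path)


def test_split_manifest_round_trip(tmp_path):
    mapping = {"P1": "train", "P2": "validation", "P3": "test"}
    path = tmp_path / "splits.csv"
    write_split_manifest(mapping, path)
    assert read_split_manifest(path) == mapping
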