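"""Shared fixtures and record builders for the test suite."""

from __future__ import annotations

import datetime

import pytest

from prodrome_miner.config import AnalysisConfig
from prodrome_miner.data_model import (
    ClinicalNote,
    CohortBundle,
    DrugClass,
    Indication,
    LabResult,
    LabTest,
    MedicationOrder,
    PatientRecord,
    RadiologyReport,
)
from prodrome_miner.lexicon import default_lexicon
from prodrome_miner.synthetic import GeneratorSpec, generate_bundle
from prodrome_miner.text import LexiconTokenizer

DAY0 = datetime.date(2016, 1, 1)


def on_day(day: int) -> datetime.date:
    return DAY0 + datetime.timedelta(days=day)


def make_patient(pid: str = "P1", followup_days: int = 400,
                 code: str = "C34.1", **kw) -> PatientRecord:
    defaults = dict(patient_id=pid, first_visit_date=DAY0, diagnosis_code=code,
                    stage="IV", followup_end_date=on_day(followup_days),
                    age_years=65.0, sex="male", height_cm=165.0, weight_kg=60.0)
    defaults.update(kw)
    return PatientRecord(**defaults)


def make_lab(pid: str, day: int, test: str = "KL6", value: float = 600.0,
             units: str = "U/mL") -> LabResult:
    return LabResult(patient_id=pid, test_name=LabTest(test),
                     result_date=on_day(day), value=value, units=units)


def make_report(pid: str, day: int, finding: str = "ground-glass opacity",
                rid: str | None = None) -> RadiologyReport:
    return RadiologyReport(report_id=rid or f"{pid}-R{day}", patient_id=pid,
                           report_date=on_day(day),
                           text=f"CT: {finding}.", findings=(finding,))


def make_gc(pid: str, day: int, indication: str = "treatment",
            end_day: int | None = None) -> MedicationOrder:
    return MedicationOrder(patient_id=pid, drug_name="prednisolone",
                           start_date=on_day(day),
                           end_date=on_day(end_day) if end_day else None,
                           drug_class=DrugClass.GLUCOCORTICOID,
                           indication=Indication(indication))


def make_note(pid: str, day: int, role: str = "physician",
              sections: dict | None = None, note_id: str | None = None) -> ClinicalNote:
    return ClinicalNote(note_id=note_id or f"{pid}-N{day:04d}", patient_id=pid,
                        note_date=on_day(day), writer_role=role,
                        sections=sections if sections is not None else {"S": "疼痛あり。"})


def event_bundle(patient_events: dict[str, list[tuple[int, str]]],
                 followup_days: int = 400) -> CohortBundle:
    """Bundle with shorthand evidence per patient.

    Event kinds: lab (abnormal KL-6), lab_spd (abnormal SP-D), lab_normal,
    rad (ILD finding), rad_clear, gc (treatment steroid), gc_support.
    """
    patients, labs, reports, meds = [], [], [], []
    for pid, events in patient_events.items():
        patients.append(make_patient(pid, followup_days))
        for j, (day, kind) in enumerate(events):
            if kind == "lab":
                labs.append(make_lab(pid, day, "KL6", 600.0))
            elif kind == "lab_spd":
                labs.append(make_lab(pid, day, "SPD", 150.0, "ng/mL"))
            elif kind == "lab_normal":
                labs.append(make_lab(pid, day, "KL6", 400.0))
            elif kind == "rad":
                reports.append(make_report(pid, day, rid=f"{pid}-R{j}"))
            elif kind == "rad_clear":
                reports.append(make_report(pid, day, "pleural effusion",
                                           rid=f"{pid}-R{j}"))
            elif kind == "gc":
                meds.append(make_gc(pid, day))
            elif kind == "gc_support":
                meds.append(make_gc(pid, day, "supportive_care"))
            else:
                raise ValueError(kind)
    return CohortBundle(patients=patients, labs=labs, radiology=reports,
                        medications=meds)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tokenizer() -> LexiconTokenizer:
    return LexiconTokenizer(default_lexicon())


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort shared by read-only tests."""
    spec = GeneratorSpec(n_patients=60, seed=11)
    bundle, truth = generate_bundle(spec)
    return spec, bundle, truth
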