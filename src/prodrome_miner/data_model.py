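"""Domain records for EMR extracts and the validated cohort bundle.

Every record type is a pydantic model with strict vocabularies so that a row
either loads cleanly or raises a typed validation error; downstream stages can
then assume well-formed input. All patient-relative time arithmetic in the
pipeline uses integer day offsets with day 0 = ``first_visit_date``.
"""

from __future__ import annotations

import datetime
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class WriterRole(str, enum.Enum):
    PHYSICIAN = "physician"
    NURSE = "nurse"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


#: SOAP/POS note section labels. Plan is carried in the data model but is
#: dropped before any token ever reaches the frequency analysis.
SECTION_LABELS = ("P", "S", "O", "A", "Plan")

#: Sections whose text contributes tokens (Plan excluded).
ANALYSIS_SECTIONS = ("P", "S", "O", "A")


class LabTest(str, enum.Enum):
    KL6 = "KL6"
    SPD = "SPD"
    CRP = "CRP"
    WBC = "WBC"
    PLT = "PLT"
    NEUT = "NEUT"
    HGB = "HGB"
    ALT = "ALT"
    AST = "AST"
    TBIL = "TBIL"
    GGT = "GGT"
    CRE = "CRE"
    FT4 = "FT4"
    TSH = "TSH"


class DrugClass(str, enum.Enum):
    GLUCOCORTICOID = "glucocorticoid"
    PD1I = "PD1i"
    PDL1I = "PDL1i"
    EGFR_TKI = "EGFR_TKI"
    ALK_TKI = "ALK_TKI"
    VEGFI = "VEGFi"
    CYTOTOXIC = "cytotoxic"
    ANALGESIC = "analgesic"
    OTHER = "other"


#: Anticancer mechanism-of-action classes reported in the exposure table.
ANTICANCER_CLASSES = (
    DrugClass.PD1I,
    DrugClass.PDL1I,
    DrugClass.EGFR_TKI,
    DrugClass.ALK_TKI,
    DrugClass.VEGFI,
    DrugClass.CYTOTOXIC,
)


class Indication(str, enum.Enum):
    TREATMENT = "treatment"
    SUPPORTIVE_CARE = "supportive_care"
    OTHER = "other"


class SetLabel(str, enum.Enum):
    """Analysis-set labels produced by phenotyping.

    ILD_GC is the glucocorticoid-confirmed subset of ILD; a patient labelled
    ILD_GC also satisfies the ILD criteria (containment is asserted by tests).
    """

    ILD_GC = "ILD_GC"
    ILD = "ILD"
    NO_ILD = "NO_ILD"
    EXCLUDED_EARLY = "EXCLUDED_EARLY"
    INELIGIBLE = "INELIGIBLE"


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    first_visit_date: datetime.date
    diagnosis_code: str
    stage: str
    followup_end_date: datetime.date
    age_years: float
    sex: Sex
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None

    @field_validator("diagnosis_code")
    @classmethod
    def _code_present(cls, v: str) -> str:
        if not v:
            raise ValueError("diagnosis_code must be non-empty")
        return v

    @field_validator("age_years")
    @classmethod
    def _age_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("age_years must be >= 0")
        return v

    @field_validator("height_cm", "weight_kg")
    @classmethod
    def _positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("height/weight must be positive when present")
        return v

    @model_validator(mode="after")
    def _dates_ordered(self) -> "PatientRecord":
        if self.first_visit_date > self.followup_end_date:
            raise ValueError("first_visit_date must be <= followup_end_date")
        return self

    def day_offset(self, date: datetime.date) -> int:
        """Integer day offset of ``date`` relative to the first visit."""
        return (date - self.first_visit_date).days

    @property
    def followup_days(self) -> int:
        return self.day_offset(self.followup_end_date)


class ClinicalNote(BaseModel):
    model_config = ConfigDict(frozen=True)

    note_id: str
    patient_id: str
    note_date: datetime.date
    writer_role: WriterRole
    sections: dict[str, str]

    @field_validator("sections")
    @classmethod
    def _known_sections(cls, v: dict[str, str]) -> dict[str, str]:
        bad = set(v) - set(SECTION_LABELS)
        if bad:
            raise ValueError(f"unknown section labels: {sorted(bad)}")
        return v

    @property
    def has_analysis_section(self) -> bool:
        """True if the note carries at least one P/S/O/A section."""
        return any(s in self.sections for s in ANALYSIS_SECTIONS)


class LabResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    test_name: LabTest
    result_date: datetime.date
    value: float
    units: str = ""

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("lab value must be finite")
        return v


class RadiologyReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    report_id: str
    patient_id: str
    report_date: datetime.date
    text: str = ""
    findings: tuple[str, ...] = ()


class MedicationOrder(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    drug_name: str
    start_date: datetime.date
    end_date: Optional[datetime.date] = None
    drug_class: DrugClass
    indication: Indication

    @model_validator(mode="after")
    def _dates_ordered(self) -> "MedicationOrder":
        if self.end_date is not None and self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        return self


class CohortBundle(BaseModel):
    """All five record collections of one EMR extract, keyed by patient."""

    patients: list[PatientRecord] = []
    notes: list[ClinicalNote] = []
    labs: list[LabResult] = []
    radiology: list[RadiologyReport] = []
    medications: list[MedicationOrder] = []

    def patient_index(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def check_referential_integrity(self) -> None:
        """Raise ReferentialIntegrityError on any orphan patient_id."""
        known = {p.patient_id for p in self.patients}
        for table, records in (
            ("notes", self.notes),
            ("labs", self.labs),
            ("radiology", self.radiology),
            ("medications", self.medications),
        ):
            for rec in records:
                if rec.patient_id not in known:
                    raise ReferentialIntegrityError(
                        f"{table}: patient_id {rec.patient_id!r} not in patient table"
                    )


class ReferentialIntegrityError(ValueError):
    """A child record references a patient_id absent from the patient table."""
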