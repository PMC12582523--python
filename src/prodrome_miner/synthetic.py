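"""Seeded synthetic EMR generator with the statistical structure the
pipeline assumes.

The generator emits a cohort bundle (patients, notes, labs, radiology,
medications) plus a ground-truth table kept separate from the bundle so no
pipeline stage can see labels. Case patients are constructed to satisfy the
phenotyping rules by design: ILD-GC patients get a paired abnormal
KL-6/SP-D result and ILD-finding radiology report within the pairing window
at day >= 31, plus a treatment-indication glucocorticoid order within the
post-onset window; plain ILD patients get a single evidence type (lab or
radiology) so no qualifying pair exists; early-excluded patients get a
qualifying event at day <= 30; No-ILD patients get neither abnormal
case-defining labs nor ILD findings.

Note text is built by concatenating lexicon surfaces WITHOUT separators
(Japanese-style unsegmented text), so segmentation is nontrivial; with a
prefix-free lexicon the built-in tokenizer recovers the generating tokens
exactly. "Prodromal" tokens are planted at an elevated per-note rate inside
their target pre-onset window for case patients and at a baseline rate
everywhere else. Copy-forward repetition appends a verbatim sentence from an
earlier note of the same patient with configurable probability.
"""

from __future__ import annotations

import dataclasses
import datetime
import zlib
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from prodrome_miner.config import AnalysisConfig, DEFAULT_ILD_FINDINGS
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
    Sex,
    SetLabel,
)
from prodrome_miner.lexicon import default_lexicon

BASE_DATE = datetime.date(2015, 1, 1)

#: Radiology wording for reports without ILD findings.
NON_ILD_FINDINGS = ("pleural effusion", "no acute abnormality", "atelectasis")

_ANTICANCER_NAMES = {
    DrugClass.PD1I: ("pembrolizumab", "nivolumab"),
    DrugClass.PDL1I: ("atezolizumab",),
    DrugClass.EGFR_TKI: ("osimertinib", "gefitinib", "erlotinib", "afatinib"),
    DrugClass.ALK_TKI: ("alectinib", "crizotinib"),
    DrugClass.VEGFI: ("bevacizumab",),
    DrugClass.CYTOTOXIC: ("cisplatin", "pemetrexed", "carboplatin", "docetaxel"),
}


class GenerationError(RuntimeError):
    """The spec cannot be realized (e.g. onset window does not fit)."""


class PlantedTerm(BaseModel):
    model_config = ConfigDict(frozen=True)

    token: str
    baseline_rate_per_note: float = Field(ge=0.0, le=1.0)
    pre_onset_rate_per_note: float = Field(ge=0.0, le=1.0)
    window_label: str = "W1"
    writer_role: str = "physician"

    @model_validator(mode="after")
    def _elevated(self) -> "PlantedTerm":
        if self.pre_onset_rate_per_note < self.baseline_rate_per_note:
            raise ValueError("pre_onset rate must be >= baseline rate")
        return self


class LabTrajectory(BaseModel):
    model_config = ConfigDict(frozen=True)

    baseline_mean: float
    baseline_sd: float = Field(ge=0.0)
    preonset_shift: float = 0.0  # added linearly over the last 30 pre-onset days
    cadence_days: int = Field(default=14, ge=1)


def _default_planted() -> list[PlantedTerm]:
    return [
        PlantedTerm(token="息切れ", baseline_rate_per_note=0.05,
                    pre_onset_rate_per_note=0.30, window_label="W1",
                    writer_role="physician"),
        PlantedTerm(token="疼痛", baseline_rate_per_note=0.05,
                    pre_onset_rate_per_note=0.30, window_label="W1",
                    writer_role="nurse"),
    ]


def _default_lab_model() -> dict[str, LabTrajectory]:
    return {
        "CRP": LabTrajectory(baseline_mean=0.8, baseline_sd=0.6,
                             preonset_shift=6.0, cadence_days=14),
    }


def _default_med_model() -> dict[str, float]:
    return {"cytotoxic": 0.30, "EGFR_TKI": 0.20, "PD1i": 0.08,
            "ALK_TKI": 0.07, "VEGFi": 0.03, "PDL1i": 0.01}


class GeneratorSpec(BaseModel):
    n_patients: int = Field(default=300, ge=0)
    frac_ild: float = Field(default=0.2, ge=0.0, le=1.0)
    frac_ild_gc_given_ild: float = Field(default=0.15, ge=0.0, le=1.0)
    frac_early_excluded: float = Field(default=0.1, ge=0.0, le=1.0)
    followup_days_range: tuple[int, int] = (180, 420)
    notes_per_week_by_role: dict[str, float] = {"physician": 1.5, "nurse": 2.0}
    copy_forward_prob: float = Field(default=0.25, ge=0.0, le=1.0)
    lexicon: Optional[dict[str, str]] = None  # None -> packaged default
    planted_terms: list[PlantedTerm] = Field(default_factory=_default_planted)
    lab_model: dict[str, LabTrajectory] = Field(default_factory=_default_lab_model)
    med_model: dict[str, float] = Field(default_factory=_default_med_model)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorSpec":
        lo, hi = self.followup_days_range
        if lo > hi or lo < 0:
            raise ValueError("invalid followup_days_range")
        if self.lexicon is not None:
            if not self.lexicon or any(not s for s in self.lexicon):
                raise ValueError("lexicon surfaces must be non-empty")
        return self


@dataclasses.dataclass
class GroundTruth:
    """True labels and onsets (never part of the bundle)."""

    labels: pd.DataFrame  # patient_id, true_label, true_onset_day
    planted_terms: list[PlantedTerm]


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(patient_id.encode())])


def _truth_label(rng: np.random.Generator, spec: GeneratorSpec) -> SetLabel:
    if rng.random() < spec.frac_early_excluded:
        return SetLabel.EXCLUDED_EARLY
    if rng.random() < spec.frac_ild:
        if rng.random() < spec.frac_ild_gc_given_ild:
            return SetLabel.ILD_GC
        return SetLabel.ILD
    return SetLabel.NO_ILD


def _abnormal_lab(rng, pid: str, day: int, first_visit: datetime.date,
                  config: AnalysisConfig) -> LabResult:
    if rng.random() < 0.5:
        value = config.kl6_threshold * (1.2 + rng.random() * 1.5)
        test, units = LabTest.KL6, "U/mL"
    else:
        value = config.spd_threshold * (1.2 + rng.random() * 1.5)
        test, units = LabTest.SPD, "ng/mL"
    return LabResult(patient_id=pid, test_name=test,
                     result_date=first_visit + datetime.timedelta(days=day),
                     value=round(float(value), 1), units=units)


def _ild_report(rng, pid: str, rid: str, day: int,
                first_visit: datetime.date) -> RadiologyReport:
    finding = DEFAULT_ILD_FINDINGS[int(rng.integers(len(DEFAULT_ILD_FINDINGS)))]
    return RadiologyReport(
        report_id=rid, patient_id=pid,
        report_date=first_visit + datetime.timedelta(days=day),
        text=f"CT chest: new {finding} noted bilaterally.",
        findings=(finding,))


def generate_bundle(
    spec: GeneratorSpec,
    config: Optional[AnalysisConfig] = None,
) -> tuple[CohortBundle, GroundTruth]:
    """Generate a cohort bundle and its ground truth from a seeded spec.

    Deterministic: identical specs produce identical bundles; per-patient
    randomness comes from sub-streams keyed by a stable hash of the patient
    id, so output does not depend on iteration order.
    """
    config = config or AnalysisConfig()
    lexicon = spec.lexicon if spec.lexicon is not None else default_lexicon()
    planted_tokens = {t.token for t in spec.planted_terms}
    filler = sorted(s for s in lexicon if s not in planted_tokens)
    if not filler:
        raise GenerationError("lexicon has no non-planted surfaces to sample")

    onset_min = config.early_exclusion_days + 91
    onset_margin = 14  # leave room for post-onset confirmation and treatment
    if spec.n_patients and spec.followup_days_range[0] < onset_min + onset_margin:
        raise GenerationError(
            f"follow-up must be >= {onset_min + onset_margin} days so the "
            "baseline and all pre-onset windows fit before follow-up end")

    patients, notes, labs, radiology, medications = [], [], [], [], []
    truth_rows = []

    for idx in range(spec.n_patients):
        pid = f"P{idx:04d}"
        rng = _patient_rng(spec.seed, pid)

        label = _truth_label(rng, spec)
        followup_days = int(rng.integers(spec.followup_days_range[0],
                                         spec.followup_days_range[1] + 1))
        first_visit = BASE_DATE + datetime.timedelta(days=int(rng.integers(0, 365)))

        onset: Optional[int] = None
        if label in (SetLabel.ILD, SetLabel.ILD_GC):
            onset = int(rng.integers(onset_min, followup_days - onset_margin + 1))

        height = round(float(rng.normal(162, 9)), 1) if rng.random() > 0.05 else None
        weight = round(float(rng.normal(56, 12)), 1) if rng.random() > 0.05 else None
        patients.append(PatientRecord(
            patient_id=pid, first_visit_date=first_visit,
            diagnosis_code="C34.9", stage="IV",
            followup_end_date=first_visit + datetime.timedelta(days=followup_days),
            age_years=float(np.clip(round(rng.normal(65, 11)), 30, 92)),
            sex=Sex.MALE if rng.random() < 0.6 else Sex.FEMALE,
            height_cm=height if height is None or height > 0 else 162.0,
            weight_kg=weight if weight is None or weight > 0 else 56.0,
        ))

        # --- case-defining evidence -------------------------------------
        def add_day(d: int) -> datetime.date:
            return first_visit + datetime.timedelta(days=d)

        if label == SetLabel.ILD_GC:
            gap = int(rng.integers(0, config.pair_window_days + 1))
            labs.append(_abnormal_lab(rng, pid, onset, first_visit, config))
            radiology.append(_ild_report(rng, pid, f"{pid}-R0", onset + gap,
                                         first_visit))
            gc_day = onset + int(rng.integers(0, config.gc_window_days + 1))
            medications.append(MedicationOrder(
                patient_id=pid, drug_name="prednisolone",
                start_date=add_day(gc_day),
                end_date=add_day(min(gc_day + 21, followup_days)),
                drug_class=DrugClass.GLUCOCORTICOID,
                indication=Indication.TREATMENT))
        elif label == SetLabel.ILD:
            if rng.random() < 0.5:
                labs.append(_abnormal_lab(rng, pid, onset, first_visit, config))
                if rng.random() < 0.4:  # repeat documentation later
                    labs.append(_abnormal_lab(rng, pid,
                                              min(onset + 20, followup_days),
                                              first_visit, config))
            else:
                radiology.append(_ild_report(rng, pid, f"{pid}-R0", onset,
                                             first_visit))
        elif label == SetLabel.EXCLUDED_EARLY:
            early_day = int(rng.integers(0, config.early_exclusion_days + 1))
            if rng.random() < 0.5:
                labs.append(_abnormal_lab(rng, pid, early_day, first_visit, config))
            else:
                radiology.append(_ild_report(rng, pid, f"{pid}-R0", early_day,
                                             first_visit))
            if rng.random() < 0.3:  # later documentation does not rescue them
                labs.append(_abnormal_lab(
                    rng, pid,
                    int(rng.integers(config.early_exclusion_days + 1,
                                     followup_days + 1)),
                    first_visit, config))

        if label == SetLabel.NO_ILD:
            if rng.random() < 0.2:  # occasional normal biomarker measurement
                labs.append(LabResult(
                    patient_id=pid, test_name=LabTest.KL6,
                    result_date=add_day(int(rng.integers(0, followup_days + 1))),
                    value=round(float(np.clip(rng.normal(250, 80), 50,
                                              config.kl6_threshold * 0.9)), 1),
                    units="U/mL"))
            if rng.random() < 0.5:
                d = int(rng.integers(0, followup_days + 1))
                finding = NON_ILD_FINDINGS[int(rng.integers(len(NON_ILD_FINDINGS)))]
                radiology.append(RadiologyReport(
                    report_id=f"{pid}-R0", patient_id=pid, report_date=add_day(d),
                    text=f"CT chest: {finding}.", findings=(finding,)))

        # --- descriptive laboratory trajectories ------------------------
        for test_name, model in spec.lab_model.items():
            day = int(rng.integers(0, model.cadence_days + 1))
            while day <= followup_days:
                value = rng.normal(model.baseline_mean, model.baseline_sd)
                if onset is not None and 0 < onset - day <= 30:
                    value += model.preonset_shift * (1 - (onset - day) / 30.0)
                labs.append(LabResult(
                    patient_id=pid, test_name=LabTest(test_name),
                    result_date=add_day(day),
                    value=round(float(max(value, 0.0)), 2), units="mg/dL"))
                day += model.cadence_days

        # --- medication orders -------------------------------------------
        for class_name, prob in spec.med_model.items():
            if rng.random() >= prob:
                continue
            cls = DrugClass(class_name)
            names = _ANTICANCER_NAMES[cls]
            name = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, max(followup_days - 30, 1)))
            duration = int(rng.integers(30, 121))
            medications.append(MedicationOrder(
                patient_id=pid, drug_name=name, start_date=add_day(start),
                end_date=add_day(min(start + duration, followup_days)),
                drug_class=cls, indication=Indication.TREATMENT))
        if rng.random() < 0.15:  # supportive-care steroids never define cases
            start = int(rng.integers(0, followup_days + 1))
            medications.append(MedicationOrder(
                patient_id=pid, drug_name="dexamethasone", start_date=add_day(start),
                end_date=add_day(min(start + 3, followup_days)),
                drug_class=DrugClass.GLUCOCORTICOID,
                indication=Indication.SUPPORTIVE_CARE))

        # --- clinical notes ----------------------------------------------
        is_case = label in (SetLabel.ILD, SetLabel.ILD_GC)
        past_sentences: list[str] = []
        note_seq = 0
        role_days = []
        for role, rate in sorted(spec.notes_per_week_by_role.items()):
            n_notes = int(rng.poisson(rate / 7.0 * followup_days))
            days = np.sort(rng.integers(0, followup_days + 1, size=n_notes))
            role_days.extend((int(d), role) for d in days)
        role_days.sort()

        for day, role in role_days:
            sentences = []
            n_sent = int(rng.integers(2, 5))
            for _ in range(n_sent):
                k = int(rng.integers(3, 9))
                toks = [filler[int(j)] for j in rng.integers(0, len(filler), size=k)]
                sentences.append("".join(toks))

            for term in spec.planted_terms:
                if term.writer_role != role:
                    continue
                rate = term.baseline_rate_per_note
                if is_case and onset is not None:
                    w = config.window(term.window_label)
                    if w.contains(day, onset if w.anchor == "onset" else 0):
                        rate = term.pre_onset_rate_per_note
                if rng.random() < rate:
                    si = int(rng.integers(len(sentences)))
                    s = sentences[si]
                    cut_tokens = int(rng.integers(0, 2))
                    sentences[si] = (s + term.token if cut_tokens == 0
                                     else term.token + s)

            sections: dict[str, str] = {"P": "肺癌"}
            assign = rng.integers(0, 3, size=len(sentences))
            for sec_idx, sec in enumerate(("S", "O", "A")):
                texts = [s for s, a in zip(sentences, assign) if a == sec_idx]
                if texts:
                    sections[sec] = "。".join(texts) + "。"
            if rng.random() < 0.3:
                k = int(rng.integers(3, 7))
                plan = "".join(filler[int(j)]
                               for j in rng.integers(0, len(filler), size=k))
                sections["Plan"] = plan + "。"

            if past_sentences and rng.random() < spec.copy_forward_prob:
                copied = past_sentences[int(rng.integers(len(past_sentences)))]
                sec = ("S", "O", "A")[int(rng.integers(3))]
                sections[sec] = sections.get(sec, "") + copied + "。"

            past_sentences.extend(sentences)
            notes.append(ClinicalNote(
                note_id=f"{pid}-N{note_seq:04d}", patient_id=pid,
                note_date=add_day(day),
                writer_role=role, sections=sections))
            note_seq += 1

        truth_rows.append({"patient_id": pid, "true_label": label.value,
                           "true_onset_day": onset})

    bundle = CohortBundle(patients=patients, notes=notes, labs=labs,
                          radiology=radiology, medications=medications)
    truth = GroundTruth(
        labels=pd.DataFrame(truth_rows,
                            columns=["patient_id", "true_label", "true_onset_day"]),
        planted_terms=list(spec.planted_terms))
    return bundle, truth
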