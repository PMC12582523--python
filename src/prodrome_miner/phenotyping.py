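"""Rule-based cohort phenotyping: eligibility, exclusion, and set assignment.

The algorithm converts raw EMR evidence into one of five labels per patient:

* ``INELIGIBLE`` — diagnosis code is not C34 (lung cancer);
* ``EXCLUDED_EARLY`` — case-defining documentation within the first
  ``early_exclusion_days`` (default 30) of the first visit, too early to
  observe prodromal symptoms;
* ``ILD`` — an abnormal KL-6 (> 500 U/mL) or SP-D (> 110 ng/mL) result, or
  ILD-related radiology documentation, at day >= 31;
* ``ILD_GC`` — within ILD, a lab/radiology pair no more than
  ``pair_window_days`` apart plus glucocorticoid treatment started within
  ``gc_window_days`` after onset (supportive-care steroids do not count);
* ``NO_ILD`` — none of the above documentation (the control set).

Onset is the earliest qualifying event day for ILD, and the earlier member of
the earliest fully qualifying lab/radiology pair for ILD_GC.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

from prodrome_miner.config import AnalysisConfig
from prodrome_miner.data_model import (
    CohortBundle,
    DrugClass,
    Indication,
    LabTest,
    ReferentialIntegrityError,
    SetLabel,
)


class EventType(str, enum.Enum):
    ABNORMAL_LAB = "abnormal_lab"
    ILD_RADIOLOGY = "ild_radiology"
    GLUCOCORTICOID_TREATMENT = "glucocorticoid_treatment"


@dataclasses.dataclass(frozen=True, order=True)
class ClinicalEvent:
    """One dated piece of phenotyping evidence, in patient-relative days."""

    patient_id: str
    event_day: int
    event_type: EventType
    source_id: str


@dataclasses.dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    set_label: SetLabel
    onset_day: Optional[int]
    qualifying_events: tuple[ClinicalEvent, ...] = ()

    @property
    def is_case(self) -> bool:
        return self.set_label in (SetLabel.ILD, SetLabel.ILD_GC)


def _report_findings(report, vocabulary: tuple[str, ...]) -> tuple[str, ...]:
    """Explicit findings win; otherwise match the vocabulary against text."""
    if report.findings:
        return report.findings
    low = report.text.lower()
    return tuple(t for t in vocabulary if t.lower() in low)


def derive_events(bundle: CohortBundle, config: AnalysisConfig) -> list[ClinicalEvent]:
    """Extract abnormal-lab, ILD-radiology and glucocorticoid-treatment events.

    Abnormality is strict: KL-6 must exceed 500 U/mL and SP-D must exceed
    110 ng/mL; values exactly at threshold are normal. Only KL-6/SP-D are
    case-defining — the other laboratory tests are descriptive. Glucocorticoid
    orders given as supportive care for anticancer therapy are skipped.
    """
    patients = bundle.patient_index()
    events: list[ClinicalEvent] = []

    for i, lab in enumerate(bundle.labs):
        abnormal = (
            (lab.test_name == LabTest.KL6 and lab.value > config.kl6_threshold)
            or (lab.test_name == LabTest.SPD and lab.value > config.spd_threshold)
        )
        if abnormal:
            day = patients[lab.patient_id].day_offset(lab.result_date)
            events.append(ClinicalEvent(lab.patient_id, day,
                                        EventType.ABNORMAL_LAB, f"lab-{i}"))

    vocab = config.ild_finding_vocabulary
    vocab_low = {t.lower() for t in vocab}
    for report in bundle.radiology:
        found = _report_findings(report, vocab)
        if any(f.lower() in vocab_low for f in found):
            day = patients[report.patient_id].day_offset(report.report_date)
            events.append(ClinicalEvent(report.patient_id, day,
                                        EventType.ILD_RADIOLOGY, report.report_id))

    for i, order in enumerate(bundle.medications):
        if (order.drug_class == DrugClass.GLUCOCORTICOID
                and order.indication != Indication.SUPPORTIVE_CARE):
            day = patients[order.patient_id].day_offset(order.start_date)
            events.append(ClinicalEvent(order.patient_id, day,
                                        EventType.GLUCOCORTICOID_TREATMENT,
                                        f"med-{i}"))
    return events


def _assign_patient(
    events: list[ClinicalEvent], config: AnalysisConfig
) -> tuple[SetLabel, Optional[int], tuple[ClinicalEvent, ...]]:
    cutoff = config.early_exclusion_days
    defining = [e for e in events
                if e.event_type in (EventType.ABNORMAL_LAB, EventType.ILD_RADIOLOGY)]

    if any(e.event_day <= cutoff for e in defining):
        early = tuple(sorted(e for e in defining if e.event_day <= cutoff))
        return SetLabel.EXCLUDED_EARLY, None, early

    qualifying = sorted(e for e in defining if e.event_day >= cutoff + 1)
    if not qualifying:
        return SetLabel.NO_ILD, None, ()

    # ILD-GC: a lab/radiology pair at most pair_window_days apart (either
    # order) whose earlier member, taken as candidate onset, is followed by
    # glucocorticoid treatment within gc_window_days (inclusive both ends).
    labs = [e for e in qualifying if e.event_type == EventType.ABNORMAL_LAB]
    rads = [e for e in qualifying if e.event_type == EventType.ILD_RADIOLOGY]
    gcs = [e for e in events
           if e.event_type == EventType.GLUCOCORTICOID_TREATMENT]

    best_pair: Optional[tuple[ClinicalEvent, ClinicalEvent]] = None
    for a in labs:
        for r in rads:
            if abs(a.event_day - r.event_day) > config.pair_window_days:
                continue
            pair_onset = min(a.event_day, r.event_day)
            if not any(pair_onset <= g.event_day <= pair_onset + config.gc_window_days
                       for g in gcs):
                continue
            if best_pair is None or pair_onset < min(best_pair[0].event_day,
                                                     best_pair[1].event_day):
                best_pair = (a, r)

    if best_pair is not None:
        onset = min(best_pair[0].event_day, best_pair[1].event_day)
        gc = min(g for g in gcs
                 if onset <= g.event_day <= onset + config.gc_window_days)
        return SetLabel.ILD_GC, onset, (best_pair[0], best_pair[1], gc)

    onset = qualifying[0].event_day
    firsts = tuple(e for e in qualifying if e.event_day == onset)
    return SetLabel.ILD, onset, firsts


def assign_sets(
    events: list[ClinicalEvent],
    bundle: CohortBundle,
    config: AnalysisConfig,
) -> list[CohortAssignment]:
    """Assign every patient in the bundle to exactly one analysis set.

    Returns assignments in patient-table order. Patients whose diagnosis code
    does not start with C34 are INELIGIBLE regardless of evidence.
    """
    known = {p.patient_id for p in bundle.patients}
    by_patient: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        if e.patient_id not in known:
            raise ReferentialIntegrityError(
                f"event for unknown patient_id {e.patient_id!r}")
        by_patient.setdefault(e.patient_id, []).append(e)

    assignments = []
    for patient in bundle.patients:
        if not patient.diagnosis_code.upper().startswith("C34"):
            assignments.append(CohortAssignment(patient.patient_id,
                                                SetLabel.INELIGIBLE, None))
            continue
        label, onset, quals = _assign_patient(
            by_patient.get(patient.patient_id, []), config)
        assignments.append(CohortAssignment(patient.patient_id, label, onset, quals))
    return assignments


def set_members(assignments: list[CohortAssignment], set_label: SetLabel) -> set[str]:
    """Patient ids belonging to an analysis set.

    The ILD set contains its glucocorticoid-confirmed subset: membership in
    ILD includes patients labelled ILD_GC.
    """
    if set_label == SetLabel.ILD:
        wanted = {SetLabel.ILD, SetLabel.ILD_GC}
    else:
        wanted = {set_label}
    return {a.patient_id for a in assignments if a.set_label in wanted}


def set_counts(assignments: list[CohortAssignment]) -> dict[str, int]:
    """Flow-diagram counts: per-label sizes plus the inclusive ILD set."""
    counts = {label.value: 0 for label in SetLabel}
    for a in assignments:
        counts[a.set_label.value] += 1
    counts["ILD_total"] = counts["ILD"] + counts["ILD_GC"]
    return counts
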