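"""The per-1000-notes word-frequency endpoint.

For each stratum (writer role x analysis set x time window) the frequency of
a word is ``1000 * c / n_notes`` where ``n_notes`` is the number of notes by
that role, from that set's patients, dated inside the window and carrying at
least one P/S/O/A section, and ``c`` counts either the notes containing the
word (``note_presence``, default) or its token occurrences
(``token_occurrence``). Case strata (ILD or ILD-GC, pre-onset windows) are
compared to the control stratum — the No-ILD set over its entire follow-up —
by simple subtraction; ranked reports keep case-present words documented for
at least ``min_patient_count`` patients, ordered by the difference in the
window of interest.
"""

from __future__ import annotations

import re
from typing import Optional

import numpy as np
import pandas as pd

from prodrome_miner.config import (
    CONTROL_WINDOW,
    PRE_ONSET_WINDOWS,
    AnalysisConfig,
    WindowSpec,
)
from prodrome_miner.data_model import (
    ClinicalNote,
    CohortBundle,
    PatientRecord,
    SetLabel,
    WriterRole,
)
from prodrome_miner.phenotyping import CohortAssignment
from prodrome_miner.text import TokenEvent

FREQUENCY_COLUMNS = [
    "word", "writer_role", "set_label", "window", "n_notes",
    "n_notes_with_word", "n_occurrences", "n_patients", "freq_per_1000",
    "diff_vs_control",
]


class WindowContractError(ValueError):
    """An onset-anchored window was requested for a patient without onset."""


class ControlContractError(ValueError):
    """The control stratum has no notes, so differences are undefined."""


def assign_window(
    note_date,
    assignment: CohortAssignment,
    patient: PatientRecord,
    windows: list[WindowSpec],
) -> Optional[str]:
    """Map a note date to its unique window label for this patient, or None.

    Control (No-ILD) patients map every in-follow-up note to the full
    follow-up window. Case patients are checked against onset-anchored
    windows first, then first-visit-anchored ones, so a pre-onset window
    wins over baseline in the (unusual) case of an onset before day 61.
    """
    offset = patient.day_offset(note_date)

    if assignment.set_label == SetLabel.NO_ILD:
        for w in windows:
            if w.label == CONTROL_WINDOW:
                end = w.end_offset if w.end_offset is not None else patient.followup_days
                if w.start_offset <= offset <= end:
                    return w.label
        return None

    for anchor in ("onset", "first_visit"):
        for w in windows:
            if w.anchor != anchor or w.label == CONTROL_WINDOW:
                continue
            if anchor == "onset":
                if assignment.onset_day is None:
                    raise WindowContractError(
                        f"onset-anchored window {w.label!r} requested for "
                        f"patient {assignment.patient_id!r} without onset")
                anchor_day = assignment.onset_day
            else:
                anchor_day = 0
            if w.contains(offset, anchor_day):
                return w.label
    return None


def _strata(note: ClinicalNote, assignment: CohortAssignment,
            patient: PatientRecord, windows: list[WindowSpec]) -> list[tuple]:
    """(writer_role, set_label, window) strata this note belongs to.

    A note from an ILD_GC patient contributes both to the ILD_GC strata and
    to the inclusive ILD strata.
    """
    sets = {SetLabel.ILD_GC: [SetLabel.ILD_GC, SetLabel.ILD],
            SetLabel.ILD: [SetLabel.ILD],
            SetLabel.NO_ILD: [SetLabel.NO_ILD]}.get(assignment.set_label, [])
    if not sets:  # excluded / ineligible patients contribute to no stratum
        return []
    window = assign_window(note.note_date, assignment, patient, windows)
    if window is None:
        return []
    return [(note.writer_role.value, s.value, window) for s in sets]


def count_frequencies(
    tokens: list[TokenEvent],
    bundle: CohortBundle,
    assignments: list[CohortAssignment],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Compute all frequency rows over (writer x set x window) strata.

    ``tokens`` must be the kept noun tokens from non-duplicate sentences.
    The note denominator is independent of the tokens: every in-window note
    with at least one P/S/O/A section counts, even if all of its sentences
    were deduplicated away. Strata with zero notes emit no rows; words absent
    from a stratum emit no rows (implicit frequency 0).
    """
    patients = bundle.patient_index()
    by_patient = {a.patient_id: a for a in assignments}
    windows = config.window_spec

    note_strata: dict[str, list[tuple]] = {}
    n_notes: dict[tuple, int] = {}
    for note in bundle.notes:
        if not note.has_analysis_section:
            continue
        assignment = by_patient.get(note.patient_id)
        if assignment is None:
            continue
        strata = _strata(note, assignment, patients[note.patient_id], windows)
        note_strata[note.note_id] = strata
        for st in strata:
            n_notes[st] = n_notes.get(st, 0) + 1

    # word-level tallies per stratum
    occurrences: dict[tuple, int] = {}
    note_sets: dict[tuple, set[str]] = {}
    patient_sets: dict[tuple, set[str]] = {}
    for t in tokens:
        for st in note_strata.get(t.note_id, ()):
            key = st + (t.surface,)
            occurrences[key] = occurrences.get(key, 0) + 1
            note_sets.setdefault(key, set()).add(t.note_id)
            patient_sets.setdefault(key, set()).add(t.patient_id)

    rows = []
    for key, occ in occurrences.items():
        role, set_label, window, word = key
        st = (role, set_label, window)
        nw = len(note_sets[key])
        c = nw if config.counting_mode == "note_presence" else occ
        rows.append({
            "word": word, "writer_role": role, "set_label": set_label,
            "window": window, "n_notes": n_notes[st],
            "n_notes_with_word": nw, "n_occurrences": occ,
            "n_patients": len(patient_sets[key]),
            "freq_per_1000": 1000.0 * c / n_notes[st],
            "diff_vs_control": float("nan"),
        })
    df = pd.DataFrame(rows, columns=FREQUENCY_COLUMNS)
    return df.sort_values(["set_label", "writer_role", "window", "word"],
                          kind="mergesort").reset_index(drop=True)


def diff_vs_control(
    case_rows: pd.DataFrame,
    control_rows: pd.DataFrame,
    include_control_only: bool = False,
) -> pd.DataFrame:
    """Fill ``diff_vs_control`` = case frequency - control frequency.

    ``control_rows`` must hold the No-ILD full-follow-up strata (one per
    writer role). Words absent from control contribute a control frequency
    of 0. With ``include_control_only`` the result also carries rows for
    control-only words (case frequency 0, negative difference).
    """
    ctrl = control_rows[
        (control_rows["set_label"] == SetLabel.NO_ILD.value)
        & (control_rows["window"] == CONTROL_WINDOW)
    ]
    case = case_rows.copy()
    if case.empty and not include_control_only:
        return case

    roles = set(case["writer_role"]) if not case.empty else set(ctrl["writer_role"])
    for role in roles:
        if ctrl[ctrl["writer_role"] == role].empty:
            raise ControlContractError(
                f"control stratum for writer_role {role!r} has no notes")

    ctrl_freq = ctrl.set_index(["writer_role", "word"])["freq_per_1000"]
    key = pd.MultiIndex.from_frame(case[["writer_role", "word"]])
    case["diff_vs_control"] = (
        case["freq_per_1000"].to_numpy()
        - ctrl_freq.reindex(key, fill_value=0.0).to_numpy()
    )

    if include_control_only and not case.empty:
        present = set(zip(case["writer_role"], case["word"],
                          case["set_label"], case["window"]))
        extra = []
        for (set_label, window), grp in case.groupby(["set_label", "window"]):
            n_by_role = grp.set_index("writer_role")["n_notes"].to_dict()
            for (role, word), freq in ctrl_freq.items():
                if role in n_by_role and (role, word, set_label, window) not in present:
                    extra.append({
                        "word": word, "writer_role": role, "set_label": set_label,
                        "window": window, "n_notes": n_by_role[role],
                        "n_notes_with_word": 0, "n_occurrences": 0,
                        "n_patients": 0, "freq_per_1000": 0.0,
                        "diff_vs_control": -float(freq),
                    })
        if extra:
            case = pd.concat([case, pd.DataFrame(extra, columns=FREQUENCY_COLUMNS)],
                             ignore_index=True)
    return case.reset_index(drop=True)


def rank_words(
    rows: pd.DataFrame,
    writer_role: WriterRole | str,
    set_label: SetLabel | str,
    config: AnalysisConfig,
    window_of_interest: str = "W1",
    control_rows: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Build the ranked report for one writer role and case set.

    Keeps case-present words with at least ``min_patient_count`` patients in
    the window of interest whose surface does not match the report-level
    exclusion regex (bare alphanumerics/units); orders by the difference in
    that window, descending, ties broken by (n_patients desc, word asc);
    returns the top ``top_k`` rows carrying the differences in all three
    pre-onset windows and the patient count. When ``control_rows`` is given,
    a word absent from the case stratum in a carried window contributes a
    case frequency of 0, i.e. a difference of minus the control frequency.
    """
    role = writer_role.value if isinstance(writer_role, WriterRole) else writer_role
    label = set_label.value if isinstance(set_label, SetLabel) else set_label
    excl = re.compile(config.report_exclusion_pattern)

    sub = rows[(rows["writer_role"] == role) & (rows["set_label"] == label)]
    base = sub[(sub["window"] == window_of_interest)
               & (sub["n_patients"] >= config.min_patient_count)
               & (sub["n_notes_with_word"] > 0)]
    keep = np.array([excl.fullmatch(w) is None for w in base["word"]], dtype=bool)
    base = base[keep]

    if control_rows is not None:
        ctrl = control_rows[
            (control_rows["set_label"] == SetLabel.NO_ILD.value)
            & (control_rows["window"] == CONTROL_WINDOW)
            & (control_rows["writer_role"] == role)
        ].set_index("word")["freq_per_1000"]
    else:
        ctrl = pd.Series(dtype=float)

    report = base[["word", "diff_vs_control", "n_patients"]].rename(
        columns={"diff_vs_control": f"diff_{window_of_interest}",
                 "n_patients": f"n_patients_{window_of_interest}"})
    for w in PRE_ONSET_WINDOWS:
        if w == window_of_interest:
            continue
        other = sub[sub["window"] == w].set_index("word")["diff_vs_control"]
        fallback = -ctrl.reindex(report["word"]).fillna(0.0).to_numpy()
        vals = other.reindex(report["word"]).to_numpy()
        missing = pd.isna(vals)
        vals[missing] = fallback[missing]
        report[f"diff_{w}"] = vals

    report = report.sort_values(
        [f"diff_{window_of_interest}", f"n_patients_{window_of_interest}", "word"],
        ascending=[False, False, True], kind="mergesort")
    cols = ["word", f"diff_{window_of_interest}",
            f"n_patients_{window_of_interest}"] + [
        f"diff_{w}" for w in PRE_ONSET_WINDOWS if w != window_of_interest]
    return report.head(config.top_k)[cols].reset_index(drop=True)
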