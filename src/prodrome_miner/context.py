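"""Descriptive companion tables: lab trends, drug exposure, baseline traits.

These tables accompany the word-frequency endpoint with clinical context:

* per-window laboratory summaries using, per patient, the in-window result
  closest to the window's anchor (onset for pre-onset windows, first visit
  for baseline) as the representative value;
* per-window anticancer-medication exposure by mechanism-of-action class,
  counting a patient once per class whose order interval overlaps the
  window, with a "None" row for patients on no anticancer class;
* baseline characteristics (age, sex, height, weight) per analysis set.

All tables are purely descriptive; no between-set inference is performed.
"""

from __future__ import annotations

import csv
import importlib.resources
from typing import Optional, Sequence

import pandas as pd

from prodrome_miner.config import AnalysisConfig
from prodrome_miner.data_model import (
    ANTICANCER_CLASSES,
    CohortBundle,
    DrugClass,
    LabTest,
    Sex,
    SetLabel,
)
from prodrome_miner.phenotyping import CohortAssignment, set_members

DEFAULT_TREND_TESTS = (LabTest.CRP, LabTest.KL6, LabTest.SPD)
DEFAULT_TREND_WINDOWS = ("baseline", "W3", "W2", "W1")
DEFAULT_EXPOSURE_WINDOWS = ("W3", "W2", "W1")
DEFAULT_TABLE_SETS = (SetLabel.ILD, SetLabel.ILD_GC)


def _window_anchor_day(window_label: str, config: AnalysisConfig,
                       assignment: CohortAssignment) -> Optional[int]:
    w = config.window(window_label)
    if w.anchor == "onset":
        return assignment.onset_day
    return 0


def _representative_day_value(days_values: list[tuple[int, float]],
                              anchor_day: int) -> Optional[float]:
    """Value closest to the anchor; ties resolved toward the later date."""
    if not days_values:
        return None
    best = max(days_values, key=lambda dv: (-abs(dv[0] - anchor_day), dv[0]))
    return best[1]


def lab_trend_table(
    bundle: CohortBundle,
    assignments: list[CohortAssignment],
    config: AnalysisConfig,
    tests: Sequence[LabTest] = DEFAULT_TREND_TESTS,
    windows: Sequence[str] = DEFAULT_TREND_WINDOWS,
    sets: Sequence[SetLabel] = DEFAULT_TABLE_SETS,
) -> pd.DataFrame:
    """Per (set, window, test): n, pct of set, mean, SD, median.

    Only results dated inside the window are eligible; the representative
    value per patient is the one closest to the window anchor. SD is missing
    when n = 1 and all summary cells are missing when n = 0.
    """
    patients = bundle.patient_index()
    by_patient = {a.patient_id: a for a in assignments}
    rows = []
    for set_label in sets:
        members = sorted(set_members(assignments, set_label))
        for window in windows:
            w = config.window(window)
            for test in tests:
                reps = []
                for pid in members:
                    a = by_patient[pid]
                    anchor = _window_anchor_day(window, config, a)
                    if anchor is None:
                        continue
                    dv = [
                        (patients[pid].day_offset(lab.result_date), lab.value)
                        for lab in bundle.labs
                        if lab.patient_id == pid and lab.test_name == test
                        and w.contains(patients[pid].day_offset(lab.result_date), anchor)
                    ]
                    rep = _representative_day_value(dv, anchor)
                    if rep is not None:
                        reps.append(rep)
                n = len(reps)
                s = pd.Series(reps, dtype=float)
                rows.append({
                    "set_label": set_label.value, "window": window,
                    "test": test.value, "n": n,
                    "pct": 100.0 * n / len(members) if members else float("nan"),
                    "mean": s.mean() if n else float("nan"),
                    "sd": s.std(ddof=1) if n > 1 else float("nan"),
                    "median": s.median() if n else float("nan"),
                })
    return pd.DataFrame(rows)


def load_drug_class_map() -> dict[str, DrugClass]:
    """Packaged anticancer drug-name -> class map (editable via TSV)."""
    ref = importlib.resources.files("prodrome_miner") / "data" / "drug_classes.tsv"
    out: dict[str, DrugClass] = {}
    with ref.open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0].strip().lower()] = DrugClass(row[1].strip())
    return out


def medication_exposure_table(
    bundle: CohortBundle,
    assignments: list[CohortAssignment],
    config: AnalysisConfig,
    windows: Sequence[str] = DEFAULT_EXPOSURE_WINDOWS,
    sets: Sequence[SetLabel] = DEFAULT_TABLE_SETS,
    class_map: Optional[dict[str, DrugClass]] = None,
) -> pd.DataFrame:
    """Per (set, window, anticancer class): n patients and % of set size.

    A patient counts once per class if any order of that class overlaps the
    window (order interval = [start, end], missing end treated as start);
    concurrent drugs of the same class therefore count as one case, and
    concurrent drugs of different classes count once in each class. The
    "None" row counts patients with no anticancer-class overlap.
    """
    if class_map is None:
        class_map = load_drug_class_map()
    patients = bundle.patient_index()
    by_patient = {a.patient_id: a for a in assignments}

    orders = []
    for order in bundle.medications:
        cls = order.drug_class
        if cls in (DrugClass.OTHER,) and order.drug_name.lower() in class_map:
            cls = class_map[order.drug_name.lower()]
        if cls not in ANTICANCER_CLASSES:
            continue
        p = patients[order.patient_id]
        start = p.day_offset(order.start_date)
        end = p.day_offset(order.end_date) if order.end_date else start
        orders.append((order.patient_id, cls, start, end))

    rows = []
    for set_label in sets:
        members = sorted(set_members(assignments, set_label))
        denom = len(members)
        for window in windows:
            w = config.window(window)
            exposed: dict[DrugClass, set[str]] = {c: set() for c in ANTICANCER_CLASSES}
            any_exposed: set[str] = set()
            for pid in members:
                a = by_patient[pid]
                anchor = _window_anchor_day(window, config, a)
                if anchor is None:
                    continue
                lo, hi = anchor + w.start_offset, anchor + w.end_offset
                for opid, cls, start, end in orders:
                    if opid == pid and start <= hi and end >= lo:
                        exposed[cls].add(pid)
                        any_exposed.add(pid)
            for cls in ANTICANCER_CLASSES:
                n = len(exposed[cls])
                rows.append({"set_label": set_label.value, "window": window,
                             "drug_class": cls.value, "n": n,
                             "pct": 100.0 * n / denom if denom else float("nan")})
            n_none = denom - len(any_exposed)
            rows.append({"set_label": set_label.value, "window": window,
                         "drug_class": "None", "n": n_none,
                         "pct": 100.0 * n_none / denom if denom else float("nan")})
    return pd.DataFrame(rows)


def baseline_table(
    bundle: CohortBundle,
    assignments: list[CohortAssignment],
    sets: Sequence[SetLabel] = (SetLabel.ILD, SetLabel.ILD_GC, SetLabel.NO_ILD),
) -> pd.DataFrame:
    """Baseline characteristics per analysis set.

    Age/height/weight as mean (SD) with missing values excluded pairwise;
    sex as n (%). SD is missing for single-patient sets.
    """
    patient_map = bundle.patient_index()

    def summarize(values: list[float]) -> tuple[float, float]:
        s = pd.Series(values, dtype=float)
        mean = s.mean() if len(s) else float("nan")
        sd = s.std(ddof=1) if len(s) > 1 else float("nan")
        return mean, sd

    rows = []
    for set_label in sets:
        members = [patient_map[pid] for pid in sorted(set_members(assignments, set_label))]
        n = len(members)
        age_mean, age_sd = summarize([p.age_years for p in members])
        h_mean, h_sd = summarize([p.height_cm for p in members if p.height_cm is not None])
        w_mean, w_sd = summarize([p.weight_kg for p in members if p.weight_kg is not None])
        n_male = sum(1 for p in members if p.sex == Sex.MALE)
        n_female = n - n_male
        rows.append({
            "set_label": set_label.value, "n": n,
            "age_mean": age_mean, "age_sd": age_sd,
            "male_n": n_male, "male_pct": 100.0 * n_male / n if n else float("nan"),
            "female_n": n_female,
            "female_pct": 100.0 * n_female / n if n else float("nan"),
            "height_mean": h_mean, "height_sd": h_sd,
            "weight_mean": w_mean, "weight_sd": w_sd,
        })
    return pd.DataFrame(rows)
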