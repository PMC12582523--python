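"""Window assignment, per-1000-notes counting, differencing and ranking."""

from __future__ import annotations

import math

import pandas as pd
import pytest

from conftest import event_bundle, make_note, make_patient, on_day
from prodrome_miner.config import AnalysisConfig
from prodrome_miner.data_model import CohortBundle, SetLabel
from prodrome_miner.frequency import (
    ControlContractError,
    WindowContractError,
    assign_window,
    count_frequencies,
    diff_vs_control,
    rank_words,
)
from prodrome_miner.phenotyping import CohortAssignment, assign_sets, derive_events
from prodrome_miner.text import compile_exclusion_patterns, notes_to_kept_tokens


def _case(pid="P1", onset=100):
    return CohortAssignment(pid, SetLabel.ILD, onset)


def _control(pid="P2"):
    return CohortAssignment(pid, SetLabel.NO_ILD, None)


class TestAssignWindow:
    @pytest.mark.parametrize("note_day,expected", [
        (70, "W1"),    # onset-30
        (99, "W1"),    # onset-1
        (100, None),   # onset day itself precedes no window
        (69, "W2"),    # onset-31
        (40, "W2"),    # onset-60
        (39, "W3"),    # onset-61
        (10, "W3"),    # onset-90; takes precedence over baseline overlap
        (9, "baseline"),
        (31, "W3"),
    ])
    def test_case_patient_windows(self, config, note_day, expected):
        patient = make_patient("P1")
        got = assign_window(on_day(note_day), _case(), patient, config.window_spec)
        assert got == expected

    def test_every_preonset_offset_agrees_with_interval_oracle(self, config):
        patient = make_patient("P1", followup_days=400)
        onset = 200
        for rel in range(-95, 1):
            got = assign_window(on_day(onset + rel), _case(onset=onset), patient,
                                config.window_spec)
            if -30 <= rel <= -1:
                assert got == "W1"
            elif -60 <= rel <= -31:
                assert got == "W2"
            elif -90 <= rel <= -61:
                assert got == "W3"
            else:
                assert got is None  # onset 200: baseline does not overlap

    def test_control_notes_map_to_full_followup(self, config):
        patient = make_patient("P2", followup_days=300)
        assert assign_window(on_day(250), _control(), patient,
                             config.window_spec) == "full_followup"
        assert assign_window(on_day(301), _control(), patient,
                             config.window_spec) is None

    def test_onset_window_without_onset_is_contract_error(self, config):
        broken = CohortAssignment("P1", SetLabel.ILD, None)
        with pytest.raises(WindowContractError):
            assign_window(on_day(50), broken, make_patient("P1"),
                          config.window_spec)


def _counting_fixture(config):
    """One ILD patient (onset 100) with 4 physician W1 notes, 疼痛 in 2;
    one control patient with 2 notes, 疼痛 in 1."""
    p1, p2 = make_patient("P1"), make_patient("P2")
    notes = [
        make_note("P1", 70, sections={"S": "疼痛発熱。"}, note_id="P1-a"),
        make_note("P1", 80, sections={"S": "疼痛嘔気。"}, note_id="P1-b"),
        make_note("P1", 90, sections={"S": "発熱あり。"}, note_id="P1-c"),
        make_note("P1", 95, sections={"S": "嘔気あり。"}, note_id="P1-d"),
        make_note("P2", 50, sections={"S": "疼痛頭痛。"}, note_id="P2-a"),
        make_note("P2", 60, sections={"S": "下痢あり。"}, note_id="P2-b"),
    ]
    bundle = CohortBundle(patients=[p1, p2], notes=notes,
                          labs=[], radiology=[], medications=[])
    assignments = [_case("P1", 100), _control("P2")]
    return bundle, assignments


def test_note_presence_frequency_worked_example(config, tokenizer):
    bundle, assignments = _counting_fixture(config)
    tokens = notes_to_kept_tokens(bundle.notes, tokenizer,
                                  compile_exclusion_patterns())
    rows = count_frequencies(tokens, bundle, assignments, config)
    r = rows[(rows.word == "疼痛") & (rows.set_label == "ILD")
             & (rows.window == "W1")].iloc[0]
    assert r.n_notes == 4 and r.n_notes_with_word == 2
    assert r.freq_per_1000 == pytest.approx(500.0)
    assert r.n_patients == 1
    # absent words emit no rows
    assert "せん妄" not in set(rows.word)


def test_token_occurrence_mode_counts_repeats(config, tokenizer):
    cfg = config.model_copy(update={"counting_mode": "token_occurrence"})
    p = make_patient("P1")
    notes = [make_note("P1", 70, sections={"S": "疼痛疼痛。"}, note_id="a"),
             make_note("P1", 80, sections={"S": "発熱あり。"}, note_id="b")]
    bundle = CohortBundle(patients=[p], notes=notes)
    tokens = notes_to_kept_tokens(notes, tokenizer, compile_exclusion_patterns())
    rows = count_frequencies(tokens, bundle, [_case("P1", 100)], cfg)
    r = rows[rows.word == "疼痛"].iloc[0]
    assert r.n_occurrences == 2 and r.freq_per_1000 == pytest.approx(1000.0)


def test_denominator_counts_notes_emptied_by_dedup(config, tokenizer):
    # second note is a verbatim copy: its tokens vanish, the note still counts
    p = make_patient("P1")
    notes = [make_note("P1", 70, sections={"S": "疼痛あり。"}, note_id="a"),
             make_note("P1", 80, sections={"S": "疼痛あり。"}, note_id="b")]
    bundle = CohortBundle(patients=[p], notes=notes)
    tokens = notes_to_kept_tokens(notes, tokenizer, compile_exclusion_patterns())
    rows = count_frequencies(tokens, bundle, [_case("P1", 100)], config)
    r = rows[rows.word == "疼痛"].iloc[0]
    assert r.n_notes == 2 and r.n_notes_with_word == 1
    assert r.freq_per_1000 == pytest.approx(500.0)


def test_scale_equivariance_under_note_doubling(config, tokenizer):
    bundle, assignments = _counting_fixture(config)
    doubled = list(bundle.notes) + [
        make_note(n.patient_id, (n.note_date - on_day(0)).days,
                  sections=dict(n.sections), note_id=n.note_id + "-copy")
        for n in bundle.notes
    ]
    big = CohortBundle(patients=bundle.patients, notes=doubled)
    patterns = compile_exclusion_patterns()
    rows1 = count_frequencies(
        notes_to_kept_tokens(bundle.notes, tokenizer, patterns, deduplicate=False),
        bundle, assignments, config)
    rows2 = count_frequencies(
        notes_to_kept_tokens(doubled, tokenizer, patterns, deduplicate=False),
        big, assignments, config)
    merged = rows1.merge(rows2, on=["word", "writer_role", "set_label", "window"],
                         suffixes=("_1", "_2"))
    assert len(merged) == len(rows1)
    assert merged["freq_per_1000_1"].to_numpy() == pytest.approx(
        merged["freq_per_1000_2"].to_numpy())


class TestDiffVsControl:
    def _rows(self, **over):
        base = {"word": "w", "writer_role": "physician", "set_label": "ILD",
                "window": "W1", "n_notes": 10, "n_notes_with_word": 2,
                "n_occurrences": 2, "n_patients": 2, "freq_per_1000": 170.0,
                "diff_vs_control": float("nan")}
        base.update(over)
        return pd.DataFrame([base])

    def test_simple_subtraction(self):
        case = self._rows(freq_per_1000=170.0)
        ctrl = self._rows(set_label="NO_ILD", window="full_followup",
                          freq_per_1000=39.41)
        out = diff_vs_control(case, ctrl)
        assert out["diff_vs_control"].iloc[0] == pytest.approx(130.59)

    def test_word_absent_from_control(self):
        case = self._rows(word="only-case", freq_per_1000=88.0)
        ctrl = self._rows(set_label="NO_ILD", window="full_followup",
                          word="other")
        out = diff_vs_control(case, ctrl)
        assert out["diff_vs_control"].iloc[0] == pytest.approx(88.0)

    def test_control_only_words_included_on_request(self):
        case = self._rows(word="shared", freq_per_1000=10.0)
        ctrl = pd.concat([
            self._rows(set_label="NO_ILD", window="full_followup",
                       word="shared", freq_per_1000=4.0),
            self._rows(set_label="NO_ILD", window="full_followup",
                       word="ctrl-only", freq_per_1000=25.0),
        ], ignore_index=True)
        out = diff_vs_control(case, ctrl, include_control_only=True)
        extra = out[out.word == "ctrl-only"].iloc[0]
        assert extra.freq_per_1000 == 0.0
        assert extra.diff_vs_control == pytest.approx(-25.0)

    def test_empty_control_stratum_is_contract_error(self):
        case = self._rows()
        ctrl = self._rows(set_label="NO_ILD", window="full_followup",
                          writer_role="nurse")
        with pytest.raises(ControlContractError):
            diff_vs_control(case, ctrl)


class TestRankWords:
    def _rows(self, entries):
        rows = []
        for word, window, diff, n_pat in entries:
            rows.append({"word": word, "writer_role": "physician",
                         "set_label": "ILD_GC", "window": window, "n_notes": 50,
                         "n_notes_with_word": 5, "n_occurrences": 5,
                         "n_patients": n_pat, "freq_per_1000": 100.0,
                         "diff_vs_control": diff})
        return pd.DataFrame(rows)

    def test_single_patient_words_excluded(self, config):
        rows = self._rows([("疼痛", "W1", 200.0, 3), ("出血", "W1", 300.0, 1)])
        report = rank_words(rows, "physician", "ILD_GC", config)
        assert list(report["word"]) == ["疼痛"]

    def test_alphanumeric_surfaces_excluded_from_report(self, config):
        rows = self._rows([("SpO2", "W1", 500.0, 5), ("疼痛", "W1", 100.0, 3)])
        report = rank_words(rows, "physician", "ILD_GC", config)
        assert list(report["word"]) == ["疼痛"]

    def test_deterministic_tie_break(self, config):
        rows = self._rows([("い", "W1", 100.0, 2), ("あ", "W1", 100.0, 2),
                           ("う", "W1", 100.0, 4)])
        report = rank_words(rows, "physician", "ILD_GC", config)
        assert list(report["word"]) == ["う", "あ", "い"]

    def test_carries_other_window_diffs(self, config):
        rows = self._rows([("疼痛", "W1", 200.0, 3), ("疼痛", "W2", 50.0, 3)])
        ctrl = pd.DataFrame([{
            "word": "疼痛", "writer_role": "physician", "set_label": "NO_ILD",
            "window": "full_followup", "n_notes": 100, "n_notes_with_word": 3,
            "n_occurrences": 3, "n_patients": 3, "freq_per_1000": 30.0,
            "diff_vs_control": float("nan")}])
        report = rank_words(rows, "physician", "ILD_GC", config,
                            control_rows=ctrl)
        row = report.iloc[0]
        assert row["diff_W2"] == pytest.approx(50.0)
        # absent from W3 entirely -> case freq 0 -> minus the control rate
        assert row["diff_W3"] == pytest.approx(-30.0)

    def test_top_k_limit(self, config):
        cfg = config.model_copy(update={"top_k": 2})
        rows = self._rows([(f"語{i}", "W1", float(i), 3) for i in range(5)])
        report = rank_words(rows, "physician", "ILD_GC", cfg)
        assert list(report["word"]) == ["語4", "語3"]


def test_control_rows_invariant_to_case_composition(config, tokenizer):
    """No-ILD frequencies do not depend on which case patients exist."""
    bundle = event_bundle({
        "A": [(100, "lab"), (101, "rad"), (105, "gc")],
        "B": [(120, "lab")],
        "C": [], "D": [],
    })
    notes = []
    for pid in ("A", "B", "C", "D"):
        for d in (40, 80, 90):
            notes.append(make_note(pid, d, sections={"S": f"疼痛発熱。"},
                                   note_id=f"{pid}-{d}"))
    bundle = CohortBundle(patients=bundle.patients, notes=notes,
                          labs=bundle.labs, radiology=bundle.radiology,
                          medications=bundle.medications)
    assignments = assign_sets(derive_events(bundle, config), bundle, config)
    patterns = compile_exclusion_patterns()
    tokens = notes_to_kept_tokens(notes, tokenizer, patterns)
    full = count_frequencies(tokens, bundle, assignments, config)

    reduced_assignments = [a for a in assignments if a.patient_id != "A"]
    reduced_notes = [n for n in notes if n.patient_id != "A"]
    reduced = CohortBundle(
        patients=[p for p in bundle.patients if p.patient_id != "A"],
        notes=reduced_notes)
    tokens_r = notes_to_kept_tokens(reduced_notes, tokenizer, patterns)
    partial = count_frequencies(tokens_r, reduced, reduced_assignments, config)

    ctrl_full = full[full.set_label == "NO_ILD"].reset_index(drop=True)
    ctrl_partial = partial[partial.set_label == "NO_ILD"].reset_index(drop=True)
    pd.testing.assert_frame_equal(ctrl_full, ctrl_partial)
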