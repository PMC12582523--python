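"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration (nested loops,
set membership) rather than calling the package's own implementations, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

from prodrome_miner.config import AnalysisConfig


def oracle_assign_patient(
    events: list[tuple[int, str]], config: AnalysisConfig
) -> tuple[str, int | None]:
    """Label and onset for one patient's (day, event_type) evidence list,
    by exhaustive enumeration of all lab/radiology pairs and steroid events."""
    cutoff = config.early_exclusion_days
    defining = [(d, t) for d, t in events
                if t in ("abnormal_lab", "ild_radiology")]
    if any(d <= cutoff for d, _ in defining):
        return "EXCLUDED_EARLY", None
    qualifying = [(d, t) for d, t in defining if d >= cutoff + 1]
    if not qualifying:
        return "NO_ILD", None

    lab_days = [d for d, t in qualifying if t == "abnormal_lab"]
    rad_days = [d for d, t in qualifying if t == "ild_radiology"]
    gc_days = [d for d, t in events if t == "glucocorticoid_treatment"]

    best: int | None = None
    for a in lab_days:
        for r in rad_days:
            if abs(a - r) <= config.pair_window_days:
                onset = min(a, r)
                for g in gc_days:
                    if onset <= g <= onset + config.gc_window_days:
                        if best is None or onset < best:
                            best = onset
    if best is not None:
        return "ILD_GC", best
    return "ILD", min(d for d, _ in qualifying)


def oracle_dedup_flags(
    sentences: list[tuple[str, str, object, str]]
) -> list[bool]:
    """Duplicate flags for (patient_id, note_id, note_date, text) tuples in
    per-patient chronological order: duplicate iff the text appeared in a
    prior note of the same patient."""
    prior: dict[str, set[str]] = {}
    per_note: dict[tuple[str, str], set[str]] = {}
    note_order: dict[str, list[tuple]] = {}
    flags = []
    for pid, note_id, note_date, text in sentences:
        key = (note_date, note_id)
        seen = set()
        for other_key, texts in note_order.get(pid, []):
            if other_key < key:
                seen |= texts
        flags.append(text in seen)
        # register this sentence under its note
        for i, (other_key, texts) in enumerate(note_order.setdefault(pid, [])):
            if other_key == key:
                texts.add(text)
                break
        else:
            note_order[pid].append((key, {text}))
    return flags


def oracle_window(day: int, set_label: str, onset: int | None,
                  followup_days: int) -> str | None:
    """Independent interval-membership check over the default window layout."""
    if set_label == "NO_ILD":
        return "full_followup" if 0 <= day <= followup_days else None
    if set_label in ("ILD", "ILD_GC"):
        rel = day - onset
        if -30 <= rel <= -1:
            return "W1"
        if -60 <= rel <= -31:
            return "W2"
        if -90 <= rel <= -61:
            return "W3"
        if 0 <= day <= 30:
            return "baseline"
    return None


def oracle_frequencies(
    notes: list[dict],
    note_words: dict[str, list[str]],
    labels: dict[str, tuple[str, int | None]],
    followups: dict[str, int],
    counting_mode: str,
) -> dict[tuple, dict]:
    """Direct nested-loop recount of every stratum.

    ``notes``: dicts with note_id, patient_id, day, role, has_section.
    ``note_words``: kept token surfaces per note (occurrence list).
    ``labels``: patient -> (set_label, onset). Returns per
    (role, set, window, word): the counts and per-1000-notes frequency.
    """
    set_membership = {
        "ILD": ("ILD", "ILD_GC"),
        "ILD_GC": ("ILD_GC",),
        "NO_ILD": ("NO_ILD",),
    }
    out: dict[tuple, dict] = {}
    for set_name, member_labels in set_membership.items():
        for role in ("physician", "nurse"):
            for window in ("baseline", "W1", "W2", "W3", "full_followup"):
                n_notes = 0
                per_word: dict[str, dict] = {}
                for note in notes:
                    pid = note["patient_id"]
                    label, onset = labels[pid]
                    if label not in member_labels:
                        continue
                    if note["role"] != role or not note["has_section"]:
                        continue
                    w = oracle_window(note["day"], label, onset, followups[pid])
                    if w != window:
                        continue
                    n_notes += 1
                    words = note_words.get(note["note_id"], [])
                    for word in set(words):
                        rec = per_word.setdefault(
                            word, {"n_notes_with_word": 0, "n_occurrences": 0,
                                   "patients": set()})
                        rec["n_notes_with_word"] += 1
                        rec["n_occurrences"] += sum(1 for x in words if x == word)
                        rec["patients"].add(pid)
                if n_notes == 0:
                    continue
                for word, rec in per_word.items():
                    c = (rec["n_notes_with_word"] if counting_mode == "note_presence"
                         else rec["n_occurrences"])
                    out[(role, set_name, window, word)] = {
                        "n_notes": n_notes,
                        "n_notes_with_word": rec["n_notes_with_word"],
                        "n_occurrences": rec["n_occurrences"],
                        "n_patients": len(rec["patients"]),
                        "freq_per_1000": 1000.0 * c / n_notes,
                    }
    return out
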