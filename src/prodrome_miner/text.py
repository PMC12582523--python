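"""Clinical-note text processing: sentences, dedup, tokenization, filtering.

Notes are reduced to noun token streams in four steps:

1. ``split_sentences`` — drop the Plan section, split P/S/O/A text into
   normalized sentences (Unicode NFKC + whitespace collapse);
2. ``dedup_sentences`` — flag any sentence whose normalized text already
   appeared in a strictly earlier note of the same patient (copy-forward
   suppression; within-note repeats are kept);
3. ``tokenize`` — segment each sentence into part-of-speech-tagged surfaces.
   The built-in tokenizer performs greedy longest-match against a lexicon,
   which is the behaviour the pipeline needs from a morphological analyzer;
   a real engine (e.g. MeCab with a medical dictionary) can be plugged in via
   the external-adapter contract ``text -> [(surface, pos)]``;
4. ``filter_tokens`` — keep nouns whose surface is not a bare number, symbol
   run, or measurement unit.
"""

from __future__ import annotations

import dataclasses
import datetime
import re
import unicodedata
from typing import Callable, Iterable, Optional

from prodrome_miner.data_model import ANALYSIS_SECTIONS, ClinicalNote, WriterRole

_SENTENCE_DELIMS = re.compile(r"[。．.!?！？\n]+")
_WS = re.compile(r"\s+")


@dataclasses.dataclass(frozen=True)
class Sentence:
    patient_id: str
    note_id: str
    note_date: datetime.date
    writer_role: WriterRole
    section: str
    text: str
    is_duplicate: bool = False


@dataclasses.dataclass(frozen=True)
class TokenEvent:
    patient_id: str
    note_id: str
    note_date: datetime.date
    writer_role: WriterRole
    section: str
    surface: str
    pos: str  # "noun" | "other"
    kept: bool = False


def normalize_text(text: str) -> str:
    """NFKC-normalize and collapse runs of whitespace to single spaces."""
    return _WS.sub(" ", unicodedata.normalize("NFKC", text)).strip()


def split_sentences(note: ClinicalNote) -> list[Sentence]:
    """Split a note's P/S/O/A sections into normalized, non-empty sentences.

    The Plan section is dropped entirely. Sentence terminators are the
    Japanese and Western full stops plus !, ? and newline.
    """
    sentences = []
    for section in ANALYSIS_SECTIONS:
        raw = note.sections.get(section)
        if raw is None:
            continue
        for fragment in _SENTENCE_DELIMS.split(unicodedata.normalize("NFKC", raw)):
            text = _WS.sub(" ", fragment).strip()
            if text:
                sentences.append(Sentence(note.patient_id, note.note_id,
                                          note.note_date, note.writer_role,
                                          section, text))
    return sentences


class UnsortedSentencesError(ValueError):
    """dedup_sentences requires per-patient (note_date, note_id) order."""


def dedup_sentences(sentences: list[Sentence]) -> list[Sentence]:
    """Flag copy-forward duplicates within each patient's note stream.

    A sentence is a duplicate iff its normalized text occurred in ANY strictly
    earlier note (by ``(note_date, note_id)``) of the same patient, whatever
    the writer or section. The first occurrence is kept, and repeats inside a
    single note are kept — only text resurfacing from past notes is flagged.
    Idempotent; input must be sorted by (note_date, note_id) within patient.
    """
    last_key: dict[str, tuple] = {}
    seen_prior: dict[str, set[str]] = {}
    current_note: dict[str, tuple] = {}
    current_texts: dict[str, set[str]] = {}

    out = []
    for s in sentences:
        key = (s.note_date, s.note_id)
        prev = last_key.get(s.patient_id)
        if prev is not None and key < prev:
            raise UnsortedSentencesError(
                f"sentences for patient {s.patient_id!r} not sorted by "
                f"(note_date, note_id): {key} after {prev}")
        last_key[s.patient_id] = key

        if current_note.get(s.patient_id) != key:
            # moving to a new note: bank the previous note's sentences
            seen_prior.setdefault(s.patient_id, set()).update(
                current_texts.get(s.patient_id, ()))
            current_note[s.patient_id] = key
            current_texts[s.patient_id] = set()

        dup = s.text in seen_prior.get(s.patient_id, ())
        current_texts[s.patient_id].add(s.text)
        out.append(dataclasses.replace(s, is_duplicate=dup))
    return out


class TokenizerConfigError(ValueError):
    pass


class LexiconTokenizer:
    """Greedy longest-match segmenter over a surface -> pos lexicon.

    At each position the longest lexicon surface matching the remaining text
    is emitted; characters matching no entry become single-character tokens
    with pos ``other``. Surfaces always concatenate back to the input, so
    segmentation never loses text. With a prefix-free lexicon the greedy
    segmentation of any concatenation of lexicon surfaces recovers the exact
    generating token sequence.
    """

    def __init__(self, lexicon: dict[str, str]):
        if not lexicon:
            raise TokenizerConfigError("builtin tokenizer requires a non-empty lexicon")
        bad = [s for s, p in lexicon.items() if not s or p not in ("noun", "other")]
        if bad:
            raise TokenizerConfigError(f"bad lexicon entries: {bad[:5]}")
        self.lexicon = dict(lexicon)
        # candidate surface lengths per leading character, longest first
        lengths: dict[str, set[int]] = {}
        for s in lexicon:
            lengths.setdefault(s[0], set()).add(len(s))
        self._lengths = {c: sorted(ls, reverse=True) for c, ls in lengths.items()}

    def __call__(self, text: str) -> list[tuple[str, str]]:
        out = []
        lexicon = self.lexicon
        i, n = 0, len(text)
        while i < n:
            for length in self._lengths.get(text[i], ()):
                if i + length > n:
                    continue
                surface = text[i:i + length]
                pos = lexicon.get(surface)
                if pos is not None:
                    out.append((surface, pos))
                    i += length
                    break
            else:
                out.append((text[i], "other"))
                i += 1
        return out


Adapter = Callable[[str], list[tuple[str, str]]]


def tokenize(sentence: Sentence, tokenizer: Adapter) -> list[TokenEvent]:
    """Segment one sentence; ``tokenizer`` is any text -> [(surface, pos)]."""
    return [
        TokenEvent(sentence.patient_id, sentence.note_id, sentence.note_date,
                   sentence.writer_role, sentence.section, surface, pos)
        for surface, pos in tokenizer(sentence.text)
    ]


def compile_exclusion_patterns(unit_terms: Iterable[str] = ()) -> list[re.Pattern]:
    """Default surface exclusions: pure digits, pure symbols/punctuation,
    and configured measurement-unit strings (full-surface matches only)."""
    patterns = [
        re.compile(r"^\d+([.,]\d+)*$"),
        re.compile(r"^[\W_]+$"),
    ]
    units = sorted({u for u in unit_terms if u}, key=len, reverse=True)
    if units:
        patterns.append(re.compile("^(" + "|".join(re.escape(u) for u in units) + ")$"))
    return patterns


def filter_tokens(tokens: list[TokenEvent],
                  exclusion_patterns: list[re.Pattern]) -> list[TokenEvent]:
    """Set ``kept`` = (pos is noun) and no exclusion pattern matches the
    whole surface. Tokens from duplicate sentences must not reach this stage."""
    out = []
    for t in tokens:
        kept = t.pos == "noun" and not any(p.fullmatch(t.surface)
                                           for p in exclusion_patterns)
        out.append(dataclasses.replace(t, kept=kept))
    return out


def note_sort_key(note: ClinicalNote) -> tuple:
    return (note.patient_id, note.note_date, note.note_id)


def notes_to_kept_tokens(
    notes: list[ClinicalNote],
    tokenizer: Adapter,
    exclusion_patterns: list[re.Pattern],
    deduplicate: bool = True,
) -> list[TokenEvent]:
    """Full text stage: notes -> kept noun tokens from non-duplicate sentences.

    Notes are processed per patient in (note_date, note_id) order so dedup
    semantics do not depend on input order.
    """
    sentences: list[Sentence] = []
    for note in sorted(notes, key=note_sort_key):
        sentences.extend(split_sentences(note))
    if deduplicate:
        sentences = dedup_sentences(sentences)
    tokens: list[TokenEvent] = []
    for s in sentences:
        if s.is_duplicate:
            continue
        tokens.extend(tokenize(s, tokenizer))
    return [t for t in filter_tokens(tokens, exclusion_patterns) if t.kept]
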