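"""Post hoc term categorization of reported words.

Words surfacing in the ranked reports are mapped to clinical term categories
(respiratory, pain/analgesic, appetite, delirium, anemia, bleeding,
sleepiness, skin eruption, other) by exact-surface lookup in a user-editable
TSV mapping. The packaged default transcribes the category membership used
for the published report tables; proprietary drug/expression dictionaries are
replaced by this file. Unmapped words are ``uncategorized``.
"""

from __future__ import annotations

import csv
import importlib.resources
import pathlib
from typing import Iterable, Union

import pandas as pd

KNOWN_CATEGORIES = (
    "respiratory", "pain_analgesic", "appetite", "delirium", "anemia",
    "bleeding", "sleepiness", "skin_eruption", "other", "uncategorized",
)

UNCATEGORIZED = "uncategorized"


class CategoryMapError(ValueError):
    """Malformed category mapping (duplicate surface, missing column)."""


class TermCategoryMap:
    """Immutable surface -> (category, english_gloss) lookup."""

    def __init__(self, entries: dict[str, str],
                 glosses: Union[dict[str, str], None] = None):
        self.entries = dict(entries)
        self.glosses = dict(glosses or {})

    @classmethod
    def from_rows(cls, rows) -> "TermCategoryMap":
        entries: dict[str, str] = {}
        glosses: dict[str, str] = {}
        for i, row in enumerate(rows, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise CategoryMapError(f"row {i}: need surface and category")
            surface, category = row[0], row[1]
            if surface in entries:
                raise CategoryMapError(f"row {i}: duplicate surface {surface!r}")
            entries[surface] = category
            if len(row) > 2 and row[2]:
                glosses[surface] = row[2]
        return cls(entries, glosses)

    @classmethod
    def from_tsv(cls, path: Union[str, pathlib.Path]) -> "TermCategoryMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_rows(csv.reader(fh, delimiter="\t"))

    @classmethod
    def default(cls) -> "TermCategoryMap":
        ref = importlib.resources.files("prodrome_miner") / "data" / "term_categories.tsv"
        with ref.open(encoding="utf-8") as fh:
            return cls.from_rows(csv.reader(fh, delimiter="\t"))

    def category(self, word: str) -> str:
        return self.entries.get(word, UNCATEGORIZED)

    def gloss(self, word: str) -> str:
        return self.glosses.get(word, "")


def categorize(words: Iterable[str], cmap: TermCategoryMap) -> dict[str, str]:
    """Exact-surface category per word; unmapped -> uncategorized."""
    return {w: cmap.category(w) for w in words}


def annotate_report(report: pd.DataFrame, cmap: TermCategoryMap) -> pd.DataFrame:
    """Append ``term_category`` and ``english_gloss`` columns to a ranked report."""
    out = report.copy()
    out["term_category"] = [cmap.category(w) for w in out["word"]]
    out["english_gloss"] = [cmap.gloss(w) for w in out["word"]]
    return out
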