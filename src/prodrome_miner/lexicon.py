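"""Lexicon loading for the built-in tokenizer and the synthetic generator.

A lexicon row is ``surface <TAB> pos [<TAB> category]`` with pos in
{noun, other}. The packaged default is a small Japanese clinical vocabulary
(symptom and drug nouns, function words, a few unit/number surfaces that
exercise the token filters). It is prefix-free — no surface is a prefix of
another — which makes greedy longest-match segmentation of any concatenation
of surfaces exact.
"""

from __future__ import annotations

import csv
import importlib.resources
import pathlib
from typing import Union


class LexiconError(ValueError):
    pass


def parse_lexicon_rows(rows) -> dict[str, str]:
    lexicon: dict[str, str] = {}
    for i, row in enumerate(rows, start=1):
        if not row or row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise LexiconError(f"lexicon row {i}: need surface and pos")
        surface, pos = row[0], row[1]
        if not surface:
            raise LexiconError(f"lexicon row {i}: empty surface")
        if pos not in ("noun", "other"):
            raise LexiconError(f"lexicon row {i}: pos must be noun|other, got {pos!r}")
        if surface in lexicon:
            raise LexiconError(f"lexicon row {i}: duplicate surface {surface!r}")
        lexicon[surface] = pos
    return lexicon


def load_lexicon(path: Union[str, pathlib.Path]) -> dict[str, str]:
    with open(path, encoding="utf-8") as fh:
        return parse_lexicon_rows(csv.reader(fh, delimiter="\t"))


def default_lexicon() -> dict[str, str]:
    ref = importlib.resources.files("prodrome_miner") / "data" / "lexicon.tsv"
    with ref.open(encoding="utf-8") as fh:
        return parse_lexicon_rows(csv.reader(fh, delimiter="\t"))


def is_prefix_free(surfaces) -> bool:
    """True if no surface is a proper prefix of another."""
    ordered = sorted(surfaces)
    return not any(b.startswith(a) for a, b in zip(ordered, ordered[1:]))
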