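"""Analysis configuration: thresholds, windows, counting and tokenizer modes.

Houses every numeric constant of the phenotyping algorithm and the frequency
endpoint: the KL-6 / SP-D abnormality cut-offs (> 500 U/mL, > 110 ng/mL), the
30-day early-documentation exclusion, the 7-day lab/radiology pairing window,
the 7-day post-onset glucocorticoid window, and the risk-window layout
(baseline = first visit +0..+30; pre-onset months -1..-30, -31..-60, -61..-90;
control follow-up = entire period after first visit).
"""

from __future__ import annotations

import pathlib
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

#: Radiology finding terms that define ILD-related documentation.
DEFAULT_ILD_FINDINGS = (
    "interstitial pneumonia",
    "traction bronchiectasis",
    "reticular abnormalities",
    "diffuse involvement",
    "ground-glass opacity",
)

#: Unit strings with no standalone medical meaning, excluded at token filtering.
DEFAULT_UNIT_TERMS = (
    "mg", "g", "kg", "ml", "mL", "dL", "L", "cm", "mm", "mmHg",
    "U/mL", "ng/mL", "mg/dL", "IU", "mEq", "μg", "ug", "μL", "%",
)

#: Report-level exclusion: bare alphanumeric strings without clear medical
#: significance are dropped from ranked reports (not from the full tables).
DEFAULT_REPORT_EXCLUSION = r"^[A-Za-z0-9]+$"


class WindowSpec(BaseModel):
    """One inclusive day-offset interval anchored to first visit or onset."""

    model_config = ConfigDict(frozen=True)

    label: str
    anchor: Literal["first_visit", "onset"]
    start_offset: Optional[int]
    end_offset: Optional[int]  # None = open end (runs to follow-up end)

    def contains(self, offset: int, anchor_day: int) -> bool:
        rel = offset - anchor_day
        if self.start_offset is not None and rel < self.start_offset:
            return False
        if self.end_offset is not None and rel > self.end_offset:
            return False
        return True


def default_windows() -> list[WindowSpec]:
    return [
        WindowSpec(label="baseline", anchor="first_visit", start_offset=0, end_offset=30),
        WindowSpec(label="W1", anchor="onset", start_offset=-30, end_offset=-1),
        WindowSpec(label="W2", anchor="onset", start_offset=-60, end_offset=-31),
        WindowSpec(label="W3", anchor="onset", start_offset=-90, end_offset=-61),
        WindowSpec(label="full_followup", anchor="first_visit", start_offset=0, end_offset=None),
    ]


#: Labels of the three monthly pre-onset windows, nearest-first.
PRE_ONSET_WINDOWS = ("W1", "W2", "W3")
CONTROL_WINDOW = "full_followup"


class AnalysisConfig(BaseModel):
    kl6_threshold: float = 500.0
    spd_threshold: float = 110.0
    early_exclusion_days: int = 30
    pair_window_days: int = 7
    gc_window_days: int = 7
    window_spec: list[WindowSpec] = Field(default_factory=default_windows)
    min_patient_count: int = 2
    top_k: int = 50
    counting_mode: Literal["note_presence", "token_occurrence"] = "note_presence"
    tokenizer: Literal["builtin_lexicon", "external_adapter"] = "builtin_lexicon"
    random_seed: int = 0
    ild_finding_vocabulary: tuple[str, ...] = DEFAULT_ILD_FINDINGS
    unit_terms: tuple[str, ...] = DEFAULT_UNIT_TERMS
    report_exclusion_pattern: str = DEFAULT_REPORT_EXCLUSION

    @field_validator("kl6_threshold", "spd_threshold")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be > 0")
        return v

    @field_validator("top_k")
    @classmethod
    def _topk(cls, v: int) -> int:
        if v < 1:
            raise ValueError("top_k must be >= 1")
        return v

    @field_validator("window_spec")
    @classmethod
    def _windows_wellformed(cls, v: list[WindowSpec]) -> list[WindowSpec]:
        labels = [w.label for w in v]
        if len(labels) != len(set(labels)):
            raise ValueError("window labels must be unique")
        for w in v:
            if w.start_offset is not None and w.end_offset is not None:
                if w.start_offset > w.end_offset:
                    raise ValueError(f"window {w.label}: start > end")
        # Same-anchor windows must not overlap (cross-anchor overlap depends
        # on the patient's onset day and is resolved at assignment time).
        for anchor in ("first_visit", "onset"):
            spans = sorted(
                (w.start_offset, w.end_offset)
                for w in v
                if w.anchor == anchor and w.label != CONTROL_WINDOW
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if e1 is None or s2 is None or s2 <= e1:
                    raise ValueError(f"{anchor}-anchored windows overlap")
        return v

    def window(self, label: str) -> WindowSpec:
        for w in self.window_spec:
            if w.label == label:
                return w
        raise KeyError(label)

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | pathlib.Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True,
                           allow_unicode=True)
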