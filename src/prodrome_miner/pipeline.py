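"""End-to-end orchestration: bundle -> phenotype -> text -> frequencies ->
categories -> context tables -> run manifest.

Every artifact is written deterministically (sorted rows, fixed column
order, no timestamps), so two runs with identical inputs, configuration and
seed produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from typing import Optional

import pandas as pd

from prodrome_miner import io as bundle_io
from prodrome_miner.categories import TermCategoryMap, annotate_report
from prodrome_miner.config import AnalysisConfig, PRE_ONSET_WINDOWS
from prodrome_miner.context import (
    baseline_table,
    lab_trend_table,
    medication_exposure_table,
)
from prodrome_miner.data_model import CohortBundle, SetLabel, WriterRole
from prodrome_miner.frequency import count_frequencies, diff_vs_control, rank_words
from prodrome_miner.lexicon import default_lexicon
from prodrome_miner.phenotyping import (
    CohortAssignment,
    assign_sets,
    derive_events,
    set_counts,
)
from prodrome_miner.synthetic import GeneratorSpec, generate_bundle
from prodrome_miner.text import (
    LexiconTokenizer,
    compile_exclusion_patterns,
    notes_to_kept_tokens,
)

log = logging.getLogger("prodrome_miner")

REPORT_SETS = (SetLabel.ILD, SetLabel.ILD_GC)
REPORT_ROLES = (WriterRole.PHYSICIAN, WriterRole.NURSE)


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def assignments_frame(assignments: list[CohortAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": a.patient_id, "set_label": a.set_label.value,
          "onset_day": a.onset_day, "n_qualifying_events": len(a.qualifying_events)}
         for a in assignments],
        columns=["patient_id", "set_label", "onset_day", "n_qualifying_events"],
    )


def compute_frequency_tables(
    bundle: CohortBundle,
    assignments: list[CohortAssignment],
    config: AnalysisConfig,
    tokenizer=None,
) -> pd.DataFrame:
    """Token stream -> all frequency rows with case-control differences.

    Case strata (ILD / ILD-GC in the pre-onset windows) get their difference
    against the No-ILD full-follow-up control; control and baseline rows
    keep a missing difference.
    """
    if tokenizer is None:
        tokenizer = LexiconTokenizer(default_lexicon())
    patterns = compile_exclusion_patterns(config.unit_terms)
    tokens = notes_to_kept_tokens(bundle.notes, tokenizer, patterns)
    log.info("text stage: %d kept noun tokens", len(tokens))

    rows = count_frequencies(tokens, bundle, assignments, config)
    control = rows[(rows["set_label"] == SetLabel.NO_ILD.value)]
    case_mask = (rows["set_label"].isin([s.value for s in REPORT_SETS])
                 & rows["window"].isin(PRE_ONSET_WINDOWS))
    if case_mask.any() and not control.empty:
        with_diff = diff_vs_control(rows[case_mask], control)
        rows = pd.concat([rows[~case_mask], with_diff], ignore_index=True)
        rows = rows.sort_values(["set_label", "writer_role", "window", "word"],
                                kind="mergesort").reset_index(drop=True)
    return rows


def run_pipeline(
    output_dir: str | pathlib.Path,
    config: Optional[AnalysisConfig] = None,
    input_dir: Optional[str | pathlib.Path] = None,
    synthetic_spec: Optional[GeneratorSpec] = None,
    category_map: Optional[TermCategoryMap] = None,
) -> dict:
    """Run every stage and write the artifact set; returns the manifest.

    Exactly one of ``input_dir`` (an on-disk bundle) or ``synthetic_spec``
    must be given. With a synthetic spec the generated bundle and its ground
    truth are also written (truth.csv is reference output only; no stage
    reads it).
    """
    if (input_dir is None) == (synthetic_spec is None):
        raise ValueError("provide exactly one of input_dir or synthetic_spec")
    config = config or AnalysisConfig()
    out = pathlib.Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if synthetic_spec is not None:
        bundle, truth = generate_bundle(synthetic_spec, config)
        bundle_io.write_cohort_bundle(bundle, out / "bundle")
        _write_csv(truth.labels, out / "truth.csv")
        log.info("generated synthetic bundle: %d patients, %d notes",
                 len(bundle.patients), len(bundle.notes))
    else:
        bundle = bundle_io.read_cohort_bundle(input_dir)
        log.info("loaded bundle from %s: %d patients, %d notes",
                 input_dir, len(bundle.patients), len(bundle.notes))

    events = derive_events(bundle, config)
    assignments = assign_sets(events, bundle, config)
    counts = set_counts(assignments)
    log.info("phenotyping: %s", counts)
    _write_csv(assignments_frame(assignments), out / "assignments.csv")

    rows = compute_frequency_tables(bundle, assignments, config)
    _write_csv(rows, out / "frequencies.csv")

    token_summary = (
        rows.groupby(["set_label", "writer_role", "window"], as_index=False)
        .agg(n_words=("word", "nunique"), n_notes=("n_notes", "max"))
        .sort_values(["set_label", "writer_role", "window"], kind="mergesort")
    )
    _write_csv(token_summary, out / "tokens_summary.csv")

    cmap = category_map or TermCategoryMap.default()
    control = rows[rows["set_label"] == SetLabel.NO_ILD.value]
    for set_label in REPORT_SETS:
        members = counts["ILD_total"] if set_label == SetLabel.ILD else counts["ILD_GC"]
        if members == 0:
            log.info("set %s empty; ranked reports skipped", set_label.value)
            continue
        for role in REPORT_ROLES:
            report = rank_words(rows, role, set_label, config,
                                window_of_interest="W1", control_rows=control)
            report = annotate_report(report, cmap)
            _write_csv(report,
                       out / f"report_{set_label.value}_{role.value}_W1.csv")

    _write_csv(lab_trend_table(bundle, assignments, config), out / "lab_trends.csv")
    _write_csv(medication_exposure_table(bundle, assignments, config),
               out / "med_exposure.csv")
    _write_csv(baseline_table(bundle, assignments), out / "baseline.csv")

    manifest = {
        "config_hash": config_hash(config),
        "seed": synthetic_spec.seed if synthetic_spec is not None else config.random_seed,
        "set_counts": counts,
        "n_patients": len(bundle.patients),
        "n_notes": len(bundle.notes),
        "n_labs": len(bundle.labs),
        "n_radiology": len(bundle.radiology),
        "n_medications": len(bundle.medications),
        "thresholds": {
            "kl6_threshold": config.kl6_threshold,
            "spd_threshold": config.spd_threshold,
            "early_exclusion_days": config.early_exclusion_days,
            "pair_window_days": config.pair_window_days,
            "gc_window_days": config.gc_window_days,
        },
        "counting_mode": config.counting_mode,
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
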