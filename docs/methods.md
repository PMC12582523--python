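# Methods

This note documents the procedures implemented in `prodrome_miner`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Phenotyping model

Patients enter the analysis with an ICD-10 C34 (lung cancer) diagnosis; all
patient time is measured in integer day offsets with day 0 = the first
visit. Three kinds of evidence are derived from the record streams:

* **abnormal_lab** — a KL-6 result strictly greater than 500 U/mL or an
  SP-D result strictly greater than 110 ng/mL. The comparisons are strict:
  a value exactly at the threshold is normal. Only these two biomarkers are
  case-defining; every other laboratory test (CRP included) is descriptive.
* **ild_radiology** — a radiology report whose findings intersect the
  configured ILD vocabulary (interstitial pneumonia, traction
  bronchiectasis, reticular abnormalities, diffuse involvement,
  ground-glass opacity). When a report carries no explicit findings list,
  findings are derived by case-insensitive substring match of the
  vocabulary against the report text; an explicit list always wins. A coded
  ILD diagnosis, where available, is supplied as an explicit finding in the
  report stream rather than trusted as a separate source, since coded
  diagnoses misdate or misstate onset.
* **glucocorticoid_treatment** — a steroid order whose indication is not
  supportive care; the order's start date is the event day.

Assignment per patient:

* any abnormal_lab or ild_radiology event at day ≤ 30 → **EXCLUDED_EARLY**
  (the pre-onset observation period would be empty). "Within 30 days" is
  inclusive of day 30 and "after 30 days" means day ≥ 31, so the two rules
  partition the timeline with no gap.
* otherwise any such event at day ≥ 31 → **ILD**, with onset = the earliest
  qualifying event day.
* within ILD, **ILD_GC** requires a lab event *a* and radiology event *r*
  with |a − r| ≤ 7 (either order — the pairing is symmetric because no
  ordering is clinically implied) and a treatment steroid started within
  [onset, onset + 7]. The ILD-GC onset is the earlier member of the
  earliest fully qualifying pair.
* no qualifying evidence → **NO_ILD** (control).

A same-day lab + radiology pair straddling day 30 cannot arise: early
exclusion pre-empts set assignment, so both members of any qualifying pair
necessarily lie after day 30.

## Risk windows

Onset-anchored windows W1 = −30..−1, W2 = −60..−31, W3 = −90..−61 (both
ends inclusive) reflect the 3–4-week cycles of lung-cancer regimens;
baseline = first visit +0..+30; the control window is the entire follow-up
of No-ILD patients, giving a period-free reference rate. The onset day
itself belongs to no pre-onset window. If a patient's onset falls before
day 61 the baseline window can overlap W2/W3; onset-anchored windows take
precedence in that case, on the reasoning that the pre-onset signal is the
quantity of interest and baseline is merely background. The synthetic
generator draws onsets late enough (≥ day 121) that the overlap never
occurs in generated data.

## Text processing

Only P/S/O/A sections contribute text; the Plan section records intentions,
not observations, and is dropped. Sentences are split on 。 ． . ! ? and
newlines, NFKC-normalized, and whitespace-collapsed. Deduplication flags a
sentence when its normalized text appeared in any strictly earlier note
(ordered by note date, then note id) of the same patient, across writers
and sections — copy-forward pasting does not respect role boundaries.
Repeats inside a single note are kept: only text resurfacing from past
notes is copy-forward. Dedup removes token sources but never notes: a note
whose every sentence is a duplicate still counts in the frequency
denominator, because the denominator measures documentation opportunities.

The built-in tokenizer segments by greedy longest match against a
surface → part-of-speech lexicon; unmatched characters become single
`other` tokens, so surfaces always concatenate back to the input. This is
deliberately the minimal behaviour the pipeline needs from morphological
analysis; production Japanese processing should be supplied through the
adapter contract (`text -> [(surface, pos)]`), e.g. MeCab with a medical
dictionary. The packaged lexicon is prefix-free (no surface is a prefix of
another), which makes the greedy segmentation of any concatenation of
lexicon surfaces provably exact — the property the generator round-trip
tests rely on.

Token filtering keeps nouns whose whole surface is not a number, a
symbol/punctuation run, or a configured unit string. A second, report-level
exclusion (default `^[A-Za-z0-9]+$`) removes bare alphanumerics from ranked
reports only; the full frequency tables keep them, since the exclusion is a
presentation rule, not a counting rule.

## Frequency endpoint

For stratum (writer role, set, window): `n_notes` = notes by that role from
that set's patients dated in the window with at least one P/S/O/A section.
Per word, `freq_per_1000 = 1000 · c / n_notes` with `c` = notes containing
the word (`note_presence`, default — a word repeated in one note counts
once) or token occurrences (`token_occurrence`, retained as a switch since
"total appearance" is also a defensible reading). The difference statistic
is `freq_case − freq_control` with the No-ILD full-follow-up stratum as
control; a word absent from control contributes control frequency 0.
Ranked reports restrict to case-present words with ≥ `min_patient_count`
(default 2) patients in the window of interest — single-patient words are
idiosyncratic, not population signal — order by the difference descending
with ties broken by (patient count desc, word lexicographic), and keep the
top `top_k` (default 50) rows carrying all three pre-onset differences.
No confidence intervals or p-values are attached: the statistic is an
exploratory screen, and multiplicity-adjusted inference on thousands of
words would require a different design.

The ILD set is inclusive: notes of ILD-GC patients contribute to both the
ILD-GC and ILD strata, so the two reports are nested the way the cohort is.

## Term categories

Reported words are mapped to clinical categories (respiratory,
pain/analgesic, appetite, delirium, anemia, bleeding, sleepiness, skin
eruption, other) by exact-surface lookup in a TSV file shipped with the
package and meant to be edited; unmapped words are `uncategorized`. The
default file carries both the Japanese surfaces the built-in lexicon emits
and English glosses. Category membership is an editorial act — licensed
drug/expression dictionaries are deliberately replaced by this flat,
reviewable file.

## Companion tables

* **Lab trends** — per (set, window, test), each patient's representative
  value is the in-window result closest to the window anchor (onset for
  W1–W3, first visit for baseline); equidistant ties resolve to the later
  result, the one written with more knowledge of the patient's state.
  Results outside the window are never borrowed, so the per-window n is an
  honest measurement count. SD is omitted at n = 1, all cells at n = 0.
* **Medication exposure** — a patient counts once per anticancer class when
  any order's [start, end] interval (missing end = start) intersects the
  window: exposure means being on drug, not initiating it. Concurrent
  same-class drugs count once; different classes count once each; a "None"
  row counts patients with no anticancer overlap. Percentages are over the
  set size.
* **Baseline** — age/height/weight as mean (SD) with pairwise exclusion of
  missing values; sex as n (%).

## Synthetic cohort generator

The generator is the package's test bed, not a patient simulator. Its
defaults define the study conditions used throughout the tests and the
acceptance script:

| Parameter | Default | Rationale |
| --- | --- | --- |
| n_patients | 300 | large enough for stable W1 strata, small enough for fast runs |
| frac_ild | 0.20 | case fraction giving ~60 cases |
| frac_ild_gc_given_ild | 0.15 | steroid-confirmed subset, ~1/7 of cases |
| frac_early_excluded | 0.10 | early-documentation fraction |
| follow-up | uniform 180–420 d | stage-IV oncology follow-up on the order of 6–14 months |
| notes/week | physician 1.5, nurse 2.0 | outpatient oncology documentation cadence |
| copy_forward_prob | 0.25 | a quarter of notes paste one earlier sentence |
| planted terms | 息切れ (physician), 疼痛 (nurse) | one prodromal token per writer role |
| planted rates | 0.05 baseline / 0.30 in W1 of cases | strong, unambiguous signal for recovery tests |
| onset | uniform [121, follow-up − 14] | baseline and all three pre-onset windows fit inside follow-up |
| CRP model | N(0.8, 0.6) + linear shift to +6 mg/dL at onset | mimics the inflammatory rise toward onset |

Case evidence is generated noise-free so that phenotyping recovers the
truth labels exactly: ILD-GC patients get the paired lab/radiology evidence
and a timely treatment steroid; plain ILD patients get a single evidence
type so no qualifying pair can exist; No-ILD patients never receive an
abnormal KL-6/SP-D or an ILD finding. Randomness is drawn from per-patient
substreams keyed by (seed, CRC-32 of patient id), so output is independent
of iteration order and byte-identical across runs.

What the generator does **not** emulate: real Japanese grammar (sentences
are bags of lexicon surfaces), negation ("息切れなし" would count toward
breathlessness — a limitation the word-counting method itself shares),
inter-note clinical narrative coherence, realistic ICD coding beyond C34,
measurement error in phenotyping evidence, and informative missingness of
biomarker tests. Passing tests therefore demonstrate that the pipeline's
rules and arithmetic are correct and that a strong planted signal is
recovered under copy-forward noise — not that the method has any particular
sensitivity on real clinical text.

## Numerical and degenerate-input choices

* All thresholds are strict inequalities; all window bounds are inclusive.
* Strata with zero notes emit no frequency rows; differencing against an
  empty control stratum is a contract error rather than a silent 0.
* Ties in ranking are totally ordered (difference desc, patient count desc,
  word lexicographic) so reports are reproducible.
* Zero-patient bundles, empty sets (e.g. no ILD-GC patients) and
  all-duplicate notes are handled without error; ranked reports for empty
  sets are skipped with a log notice.
* Outputs are written with fixed column order, sorted rows, `%.6g` floats
  and no timestamps, making whole output trees byte-comparable.
* The acceptance script scales its replications (5 seeds for recovery, 3
  for null calibration, n = 150 for the null cohorts) to keep a full run
  near one minute; the test suite uses 20 seeds for the same checks.

## Known limitations

* The frequency difference has no attached inferential error control; it
  ranks, it does not test.
* Sentence-level dedup can discard a genuinely re-observed symptom written
  in identical words; conversely trivial template sentences differing by
  one character are kept.
* The built-in tokenizer is not a morphological analyzer; its output on
  free text outside the lexicon degrades to character tokens (which the
  noun filter then drops).
* Exact-surface category lookup does not fold inflections or synonyms;
  the mapping file must enumerate every surface of interest.
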