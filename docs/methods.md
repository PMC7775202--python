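# Methods

## The extraction model

A past-medical-history field is modelled as a sequence of three kinds of
token: disease mentions, negation markers, and duration expressions.
Extraction is a two-stage pipeline: *tag identification* reduces the raw
string to that token tape, and *clustering* — a three-state deterministic
finite-state machine — decides which duration belongs to which disease and
which mentions are negated.

The machine rests on three structural assumptions about the input:

1. disease names are spelled exactly as some lexicon keyword (there is no
   fuzzy matching or spelling correction);
2. a duration, when present, *follows* its disease, never precedes it;
3. when disease D1 is followed by disease D2 with no duration in between,
   D1 simply has no duration and the next duration belongs to D2.

States: **0** start (nothing pending), **1** a disease is pending its
duration (`prev_disease` set), **2** a negation is pending its disease.
On a DISEASE in state 1 the pending record is closed *without* a duration
(warning) — this is assumption 3; on a TIME in state 1 the pending record
is closed with that duration; on a DISEASE in state 2 the mention is
recorded as absent and suppressed from output. One negation marker scopes
over exactly one following disease mention: "no DM or HTN" negates only
the diabetes mention. The machine therefore attaches a duration to a
disease exactly when the duration tag is the *immediately next* tag after
that disease on the tape — a property exploited by the brute-force oracle
used in the tests.

### Error recovery

Four transition cells are errors (duration before any disease, negation
after a pending disease, two consecutive negations, duration after a
negation). A batch extractor must not abort on one malformed note, and the
transition table names no successor state for these cells, so the engine
adopts a fixed recovery policy: the error is appended to the result as a
structured event and processing continues — a stray TIME is dropped in
place (state unchanged); a NO arriving while a disease is pending closes
that record without a duration and then honours the negation (state 2);
repeated NOs and a TIME after a NO leave the machine in state 2, so the
negation still applies to the next disease mention. At the end of the tape
a disease still pending in state 1 is flushed as a record with no duration
plus a warning (configurable off), mirroring how a missing duration is
handled mid-tape.

The "duration before any disease" cell is labelled an error by the
transition table but its action message is phrased as a warning; the event
carries the verbatim message with severity `error`, which is the stricter
reading.

All per-cell action messages are emitted verbatim as structured events
(severity info/warning/error) rather than printed, so they are testable
and routable through standard logging.

## Tagging choices

- **Word boundaries.** A keyword matches only when flanked by
  non-alphanumeric characters or string edges; plain substring matching
  would fire "RA" inside "random". Multi-word keywords ("Joint pain")
  match as contiguous word sequences with flexible whitespace.
- **Case.** Matching is case-insensitive, *except* all-uppercase
  abbreviations of ≤ 4 letters (`DM`, `HTN`, `CAD`, `RA`, `FBS`, `PPBS`,
  `IDDM`), which match only in uppercase: "ra" or "dm" in lowercase prose
  is almost never a disease mention. Both rules are configurable
  (`case_sensitive`, `strict_abbreviations`).
- **Durations.** A non-negative integer or one-dot decimal immediately
  followed (modulo whitespace) by a unit word; units are the closed set
  day/week/month/year with plural forms and `yr`/`yrs`/`y` accepted and
  normalised. Number words ("five") and calendar dates ("since 2014") are
  out of scope. A number without a unit is not a duration. Filler words
  ("since", "for") sit outside the tag. Zero-valued matches are skipped.
- **Negation.** The default marker set is minimal — `no`, `no h/o`,
  `not a`, `denies` — and deliberately configurable: real notes vary
  widely and the right set is a site-specific decision.
- **Overlaps.** Candidate tags are resolved left to right, preferring on
  equal starts DISEASE > TIME > NO, then the longer match; the result is a
  strictly ordered, non-overlapping tape ("no h/o" beats its embedded
  "no"; "diabetes mellitus" yields one tag).
- **Spans** are 0-based half-open character offsets; `surface` always
  equals the input slice.

The bundled lexicon groups each associated keyword under one canonical
disease (e.g. `Cholesterol` under *Coronary artery disease*, `Gastric` and
`Ulcer` under *Acid peptic disease*). Grouping of an associated keyword
with its disease follows clinical usage where a published flat keyword
list is ambiguous, and the file format exists precisely so users can
regroup: one canonical name per key, a list of extra keywords as the
value. Duration normalisation to days (day=1, week=7, month=30, year=365)
is provided as `Duration.to_days()` but never applied implicitly — records
store the unit as written.

## Evaluation protocol

Scoring is record-level and all-or-nothing: in *diagnosis* mode the
predicted disease-name set must equal the gold set exactly; in *duration*
mode the full (disease, duration) pair sets must match, durations compared
after unit normalisation so `2 yrs` equals 2 years. A record with gold
diseases is TP on exact match and FN otherwise; a record with none is TN
when the prediction is empty and FP otherwise — "Actual No" is read as "a
record with no true (affirmed) diseases". Gold diseases absent from the
lexicon are scored as-is and become FNs: the evaluation deliberately
measures lexicon coverage too. Metrics with a zero denominator are
reported as undefined, never as a division failure; display rounding is
one decimal place (94/99 → 94.9%).

## What the synthetic corpus does and does not emulate

The generator fabricates short semi-structured notes from a small template
bank — `"known case of {D} since {N} {U}"`, `"{D}, {D2} for {N} {U}"`,
`"no {D}"`, `"{D} on treatment"` — because no raw patient text can be
shipped; the templates encode only the structures the model's assumptions
imply. Defaults (chosen once, documented as arbitrary where no external
anchor exists): 0–4 distinct diseases per record with probabilities
(.05, .40, .30, .15, .10) skewed toward 1–2 mentions and few empty
records; a 0.7 chance an affirmed mention carries a duration; a 0.1
negation rate; a 0.5 chance of an abbreviation/keyword surface instead of
the canonical name; duration values 1–20 with units weighted heavily
toward years. All randomness flows from a single integer seed and the same
seed reproduces the corpus byte for byte.

Noise modes recreate the extractor's two documented failure modes while
the gold annotation keeps describing the *intended* truth, so the damage
is measurable: `duration_before_disease` moves one duration phrase in
front of its disease (the duration becomes unattachable — the affected
record's duration-mode score drops to FN while diagnosis mode is
untouched); `misspelling` applies one character edit inside a keyword (the
mention becomes invisible, degrading both modes). Noise decisions are
drawn from a stream independent of corpus generation, so a noisy run
differs from its clean counterpart only in the corrupted records.

A noise-free corpus is recoverable by construction, and the pipeline
scores 100% in both modes on it. That round trip validates the machinery
— tagging, clustering, negation, scoring — under the model's assumptions;
it says nothing about performance on real clinical text, whose
misspellings, ad-hoc abbreviations, free word order and richer negation
vocabulary violate those assumptions in ways the two noise modes only
sketch. Published figures on real EMR data of this kind (95% / 93%
accuracy in diagnosis / duration mode) come from a confidential dataset
and cannot be reproduced here; the evaluation module's worked-example
tests pin the metric arithmetic on those confusion matrices instead.

## Numerical and test-size choices

Problem sizes used by the test suite and the acceptance script — 500
round-trip records, 10,000 random tapes of length ≤ 12 for the
machine-vs-oracle comparison, 200 records at a 0.2 corruption rate for the
noise runs — are large enough that every structural path (all nine
transition cells, error recovery, flush) is exercised many times while the
whole suite stays fast. Metric comparisons are exact where the quantity is
a ratio of small integers; no tolerances are involved anywhere in the
pipeline itself. Duration equality uses numeric value equality, so `2.0`
parsed from text equals the generator's integer `2`.

## Known limitations

- A duration preceding its disease is not attachable (by design —
  assumption 2); it surfaces as an error event and the disease is recorded
  without a duration.
- Misspelled disease names are invisible to exact keyword matching.
- Negation scope is exactly one following mention; coordinated negation
  ("no DM or HTN") under-negates.
- Only `<number> <unit>` durations are parsed — no dates, no number words.
- The default negation marker set is a minimal guess; extend it per site.
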