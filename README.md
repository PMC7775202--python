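# medhx

Structure free-text **past-medical-history** notes into `(disease, duration)`
records.

Electronic medical records store a patient's systemic-disease history as a
short free-text string typed by clinic staff — `"no h/o DM, HTN since 5
yrs"` — which is unusable for analytics until it is structured. `medhx`
is a rule-based extractor for exactly that kind of field, built for
medical-informatics teams who need a transparent, auditable alternative to
black-box NLP:

1. **Lexicon** — a many-to-one map from surface keywords (`DM`, `Insulin`,
   `HTN`, `Joint pain`, …) to canonical disease names (*Diabetes mellitus*,
   *Hypertension*, *Arthritis*, …). The built-in lexicon covers 19 systemic
   diseases commonly documented in ophthalmic EMRs and is fully editable.
2. **Tagging** — the note is reduced to an ordered tape of typed tokens:
   `DISEASE` (word-boundary lexicon matches), `TIME` (`<number> <unit>`
   durations in days/weeks/months/years), and `NO` (negation markers).
3. **Finite-state machine** — a 3-state deterministic automaton walks the
   tape and clusters each duration with its disease:

   | state | meaning | NO | DISEASE | TIME |
   |---|---|---|---|---|
   | 0 | start, nothing pending | → 2 | → 1 (store disease) | error |
   | 1 | disease awaiting duration | error | → 1 (emit `⟨prev, no time⟩`) | → 0 (emit `⟨prev, time⟩`) |
   | 2 | negation pending disease | error | → 0 (suppress mention) | error |

   Error cells never abort a batch run: each logs a structured event and
   applies a documented recovery. A disease still pending at the end of the
   tape is emitted without a duration, with a warning.
4. **Evaluation** — strict record-level scoring against gold annotations:
   a record is a true positive only when the *entire* extracted set matches
   the gold set exactly (disease names in *diagnosis* mode; full
   (disease, duration) pairs in *duration* mode), yielding a 2×2 confusion
   matrix and accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN),
   PPV = TP/(TP+FP).
5. **Synthetic corpus** — a seeded generator of gold-annotated history
   strings, so the whole pipeline can be tested and benchmarked without
   access to patient data.

## Worked example

```python
>>> import medhx
>>> result = medhx.extract("no h/o DM, HTN since 5 yrs, joint pain")
>>> for r in result.records:
...     print(r.disease, "|", r.duration)
Hypertension | 5 years
Arthritis | None
>>> [w.message for w in result.warnings]
['Warning: prev_disease was not followed by a time.']
```

The negation marker `no h/o` suppresses the diabetes mention; `HTN` is
canonicalised to *Hypertension* and clustered with the `5 yrs` duration
that follows it; `joint pain` maps to *Arthritis* and, having no duration
before the tape ends, is emitted without one — the warning records that.

The same pipeline from the shell:

```bash
medhx simulate --out sim/ --n 100 --seed 7        # synthetic corpus + gold
medhx extract  --input sim/corpus.csv --out pred.jsonl
medhx evaluate --pred pred.jsonl --gold sim/gold.csv --mode all
```

The `evaluate` command prints both confusion matrices and their metrics;
on a noise-free synthetic corpus every metric is 100%:

```
[diagnosis] n=100
  predicted yes / no   gold yes:    91     0
                       gold no :     0     9
  accuracy 100.0%  sensitivity 100.0%  PPV 100.0%
```

## Layout

| module | contents |
|---|---|
| `medhx.lexicon` | `Lexicon`, `load_lexicon`, `canonicalize` |
| `medhx.tagging` | `Tag`, `Duration`, `tag_text` and the per-kind scanners |
| `medhx.fsm` | `transition`, `run_fsm`, `extract`, `EngineConfig` |
| `medhx.evaluation` | `score_record`, `build_confusion`, `compute_metrics`, gold I/O |
| `medhx.synthetic` | `GeneratorParams`, `generate_corpus`, `inject_noise` |
| `medhx.cli` | the `medhx` command (`extract` / `evaluate` / `simulate`) |

See `docs/methods.md` for the model, its assumptions, and the design
choices behind the defaults.
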