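"""Seeded generator of gold-annotated synthetic past-medical-history notes.

Real past-medical-history fields are short, semi-structured strings typed by
clinic staff: zero to a few disease mentions (often as abbreviations),
optionally trailed by a ``<number> <unit>`` duration, occasionally negated
("no DM"). This module fabricates such strings *together with* their gold
annotation, so the tagging + state-machine pipeline can be exercised and
scored end to end without access to any patient data.

By construction, a noise-free corpus obeys the three structural baselines
the extractor assumes: disease names are spelled exactly as in the lexicon,
a duration always follows its disease, and a disease followed by another
disease without an intervening duration simply has no duration. Under those
conditions every gold pair is recoverable and the pipeline scores 100%
record-level accuracy — the generator's job is to make that round-trip a
testable property.

Two noise modes re-create the extractor's documented failure modes so the
resulting degradation is measurable (the gold keeps describing the
*intended* truth, not the corrupted surface):

* ``duration_before_disease`` — moves a duration phrase in front of its
  disease mention; the duration becomes unattachable.
* ``misspelling`` — one character edit inside a disease keyword; the
  mention becomes invisible to exact string matching.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .evaluation import GoldAnnotation
from .lexicon import Lexicon, default_lexicon
from .tagging import Duration, tag_text

__all__ = ["NOISE_KINDS", "GeneratorParams", "generate_corpus", "inject_noise"]

NOISE_KINDS = ("none", "duration_before_disease", "misspelling")

# Unit mix for generated durations: histories overwhelmingly report years.
_UNIT_CHOICES = ("year", "year", "year", "year", "year", "year", "year",
                 "month", "month", "week", "day")

_UNIT_SURFACES = {
    "day": ("day", "days"),
    "week": ("week", "weeks"),
    "month": ("month", "months"),
    "year": ("year", "years", "yrs"),
}

# Mention templates; {d} = disease surface, {v}/{u} = duration value/unit.
_TIMED_TEMPLATES = ("{d} since {v} {u}", "{d} for {v} {u}", "{d} - {v} {u}")
_UNTIMED_TEMPLATES = ("{d}", "{d}", "{d} on treatment")
_NEGATED_TEMPLATES = ("no {d}", "no h/o {d}")
_LEAD_INS = ("", "", "known case of ")
_EMPTY_TEXTS = ("nil", "nothing significant", "")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the corpus generator; all randomness flows from ``seed``.

    disease_count_dist
        Probabilities of a record mentioning 0..4 distinct diseases. The
        default is skewed towards 1–2 mentions with few empty records.
    p_duration
        Probability an affirmed mention carries a duration.
    p_negation
        Probability a mention is negated ("no <disease>").
    p_abbreviation
        Probability the surface form is an associated keyword (e.g. "DM")
        rather than the canonical name, when the entry has one.
    noise_kind / noise_rate
        Corruption mode and the fraction of eligible records corrupted
        (one corruption per affected record).
    """

    n_records: int = 100
    disease_count_dist: tuple[float, ...] = (0.05, 0.40, 0.30, 0.15, 0.10)
    p_duration: float = 0.7
    p_negation: float = 0.1
    p_abbreviation: float = 0.5
    noise_kind: str = "none"
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        probs = (self.p_duration, self.p_negation, self.p_abbreviation,
                 self.noise_rate, *self.disease_count_dist)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.disease_count_dist) - 1.0) > 1e-9:
            raise ValueError("disease_count_dist must sum to 1")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")


@dataclass
class _Mention:
    surface: str
    canonical: str
    negated: bool
    duration: Duration | None


def _sample_mention(
    rng: random.Random, canonical: str, lex: Lexicon, params: GeneratorParams
) -> _Mention:
    extras = sorted(lex.entries[canonical] - {canonical})
    surface = canonical
    if extras and rng.random() < params.p_abbreviation:
        surface = rng.choice(extras)
    negated = rng.random() < params.p_negation
    duration = None
    if not negated and rng.random() < params.p_duration:
        duration = Duration(value=rng.randint(1, 20), unit=rng.choice(_UNIT_CHOICES))
    return _Mention(surface, canonical, negated, duration)


def _render_duration(rng: random.Random, d: Duration) -> tuple[str, str]:
    value = int(d.value)
    surfaces = _UNIT_SURFACES[d.unit]
    unit = surfaces[0] if value == 1 else rng.choice(surfaces[1:])
    return str(value), unit


def _render_record(rng: random.Random, mentions: list[_Mention]) -> str:
    if not mentions:
        return rng.choice(_EMPTY_TEXTS)
    # negated mentions first: "no DM, HTN since 5 years" reads like a note
    ordered = [m for m in mentions if m.negated] + [m for m in mentions if not m.negated]
    phrases = []
    for m in ordered:
        if m.negated:
            phrases.append(rng.choice(_NEGATED_TEMPLATES).format(d=m.surface))
        elif m.duration is not None:
            v, u = _render_duration(rng, m.duration)
            phrases.append(rng.choice(_TIMED_TEMPLATES).format(d=m.surface, v=v, u=u))
        else:
            phrases.append(rng.choice(_UNTIMED_TEMPLATES).format(d=m.surface))
    lead = rng.choice(_LEAD_INS) if not ordered[0].negated else ""
    return lead + ", ".join(phrases)


def generate_corpus(
    params: GeneratorParams, lex: Lexicon | None = None
) -> tuple[list[tuple[str, str]], list[GoldAnnotation]]:
    """Generate ``(records, gold)``: texts plus their annotated truth.

    Deterministic given ``params.seed``. With ``noise_kind="none"`` every
    gold pair is recoverable by the extraction pipeline.
    """
    if lex is None:
        lex = default_lexicon()
    rng = random.Random(params.seed)
    diseases = sorted(lex.entries)
    counts = list(range(len(params.disease_count_dist)))
    records: list[tuple[str, str]] = []
    golds: list[GoldAnnotation] = []
    width = max(4, len(str(max(params.n_records, 1))))
    for i in range(params.n_records):
        rid = f"R{i + 1:0{width}d}"
        k = rng.choices(counts, weights=params.disease_count_dist)[0]
        mentions = [
            _sample_mention(rng, canonical, lex, params)
            for canonical in rng.sample(diseases, k)
        ]
        text = _render_record(rng, mentions)
        gold = GoldAnnotation(
            record_id=rid,
            diseases=frozenset(
                (m.canonical, m.duration) for m in mentions if not m.negated
            ),
        )
        records.append((rid, text))
        golds.append(gold)
    if params.noise_kind != "none":
        # independent stream: the clean corpus is byte-identical to a
        # noise_kind="none" run with the same seed, so the effect of noise
        # is attributable record by record
        nrng = random.Random(params.seed + 1_000_003)
        for i, ((rid, text), gold) in enumerate(zip(records, golds)):
            if nrng.random() < params.noise_rate:
                text, gold = inject_noise(text, gold, params.noise_kind, nrng, lex)
                records[i] = (rid, text)
                golds[i] = gold
    return records, golds


def inject_noise(
    text: str,
    gold: GoldAnnotation,
    kind: str,
    rng: random.Random,
    lex: Lexicon | None = None,
) -> tuple[str, GoldAnnotation]:
    """Apply one corruption of ``kind`` to ``text``; the gold is unchanged.

    The gold annotation keeps describing the intended truth so that the
    extractor's failure on the corrupted surface shows up as a scoring
    miss. If the text offers no eligible site (e.g. no timed mention for
    ``duration_before_disease``), the input is returned unchanged.
    """
    if kind == "none":
        return text, gold
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}")
    if lex is None:
        lex = default_lexicon()
    if kind == "duration_before_disease":
        return _move_duration_before(text, rng, lex), gold
    return _misspell_keyword(text, rng, lex), gold


def _move_duration_before(text: str, rng: random.Random, lex: Lexicon) -> str:
    tape = tag_text(text, lex)
    sites = [
        (tape[i], tape[i + 1])
        for i in range(len(tape) - 1)
        if tape[i].kind == "DISEASE" and tape[i + 1].kind == "TIME"
    ]
    if not sites:
        return text
    disease, time = rng.choice(sites)
    # "DM since 2 years" -> "since 2 years DM": the filler between the
    # disease and the duration moves along with the duration phrase
    moved = text[disease.end : time.end].strip()
    return text[: disease.start] + moved + " " + disease.surface + text[time.end :]


def _misspell_keyword(text: str, rng: random.Random, lex: Lexicon) -> str:
    tape = [t for t in tag_text(text, lex) if t.kind == "DISEASE"]
    if not tape:
        return text
    target = rng.choice(tape)
    for _ in range(25):
        corrupted = _one_char_edit(rng, target.surface)
        candidate = text[: target.start] + corrupted + text[target.end :]
        found = {t.disease for t in tag_text(candidate, lex) if t.kind == "DISEASE"}
        intended = {t.disease for t in tag_text(text, lex) if t.kind == "DISEASE"}
        if target.disease in intended - found:
            return candidate
    return text  # pragma: no cover - a 25-attempt miss is astronomically unlikely


def _one_char_edit(rng: random.Random, word: str) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    op = rng.choice(["substitute", "insert", "delete"] if len(word) > 1 else ["substitute", "insert"])
    i = rng.randrange(len(word))
    if op == "substitute":
        repl = rng.choice([c for c in letters if c != word[i].lower()])
        return word[:i] + repl + word[i + 1 :]
    if op == "insert":
        return word[:i] + rng.choice(letters) + word[i:]
    return word[:i] + word[i + 1 :]
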