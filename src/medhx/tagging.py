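"""Tokenise a medical-history string into DISEASE / NO / TIME tags.

The downstream state machine never sees raw text; its input tape is the
ordered, non-overlapping tag sequence produced here:

* ``DISEASE`` — a lexicon keyword found at word boundaries, carrying the
  canonical disease name.
* ``TIME`` — a duration expression, a number immediately followed by a unit
  word (day/week/month/year, plural and ``yr``/``yrs``/``y`` forms
  accepted), parsed into a :class:`Duration`.
* ``NO`` — a negation marker (``no``, ``no h/o``, ``not a``, ``denies`` by
  default; configurable).

A keyword matches only when flanked by non-alphanumeric characters or the
string edges, so "RA" never fires inside "random". Overlapping candidates
are resolved left to right, preferring on equal starts DISEASE over TIME
over NO and longer matches over shorter ones, so "diabetes mellitus"
produces one tag and "no h/o" beats its embedded "no".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon import Lexicon, _is_strict_abbreviation, default_lexicon

__all__ = [
    "Duration",
    "Tag",
    "DEFAULT_NEGATION_FORMS",
    "UNIT_SYNONYMS",
    "DAYS_PER_UNIT",
    "find_disease_tags",
    "find_time_tags",
    "find_no_tags",
    "tag_text",
]

log = logging.getLogger(__name__)

#: Canonical duration units, in increasing size.
UNITS = ("day", "week", "month", "year")

#: Surface unit word (lowercase) -> canonical unit.
UNIT_SYNONYMS: dict[str, str] = {
    "day": "day", "days": "day",
    "week": "week", "weeks": "week",
    "month": "month", "months": "month",
    "year": "year", "years": "year",
    "yr": "year", "yrs": "year", "y": "year",
}

#: Nominal length of each unit in days, for the optional normalisation helper.
DAYS_PER_UNIT = {"day": 1, "week": 7, "month": 30, "year": 365}

DEFAULT_NEGATION_FORMS: tuple[str, ...] = ("no h/o", "not a", "denies", "no")


@dataclass(frozen=True, order=True)
class Duration:
    """A disease duration: a positive count of days, weeks, months or years."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if not self.value > 0:
            raise ValueError(f"duration value must be positive, got {self.value!r}")

    def to_days(self) -> float:
        """Nominal length in days (day=1, week=7, month=30, year=365)."""
        return self.value * DAYS_PER_UNIT[self.unit]

    def __str__(self) -> str:
        v = int(self.value) if float(self.value).is_integer() else self.value
        return f"{v} {self.unit}" + ("s" if v != 1 else "")


@dataclass(frozen=True)
class Tag:
    """A typed token located in the input text.

    ``span`` is a 0-based half-open character range; ``surface`` always
    equals the input slice at that range. ``disease`` is set iff
    ``kind == "DISEASE"``; ``duration`` is set iff ``kind == "TIME"``.
    """

    kind: str
    surface: str
    span: tuple[int, int]
    disease: str | None = None
    duration: Duration | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("DISEASE", "NO", "TIME"):
            raise ValueError(f"unknown tag kind {self.kind!r}")
        if not self.span[0] < self.span[1]:
            raise ValueError(f"span must be non-empty, got {self.span}")
        if (self.kind == "DISEASE") != (self.disease is not None):
            raise ValueError("disease must be set exactly for DISEASE tags")
        if (self.kind == "TIME") != (self.duration is not None):
            raise ValueError("duration must be set exactly for TIME tags")

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _keyword_pattern(keyword: str) -> str:
    """Regex for one keyword: words joined by whitespace, boundary-guarded."""
    words = [re.escape(w) for w in keyword.split()]
    body = r"\s+".join(words)
    return rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])"


def find_disease_tags(text: str, lex: Lexicon | None = None) -> list[Tag]:
    """All word-boundary lexicon matches, longest-match-first, as DISEASE tags."""
    if lex is None:
        lex = default_lexicon()
    candidates: list[Tag] = []
    for canonical, keywords in lex.entries.items():
        for kw in keywords:
            strict = not lex.case_sensitive and (
                lex.strict_abbreviations and _is_strict_abbreviation(kw)
            )
            flags = 0 if (lex.case_sensitive or strict) else re.IGNORECASE
            for m in re.finditer(_keyword_pattern(kw), text, flags):
                candidates.append(
                    Tag(
                        kind="DISEASE",
                        surface=m.group(0),
                        span=(m.start(), m.end()),
                        disease=canonical,
                    )
                )
    return _resolve_overlaps(candidates)


_TIME_RE = re.compile(
    r"(?<![A-Za-z0-9.])"
    r"(?P<value>\d+(?:\.\d+)?)"
    r"\s*"
    r"(?P<unit>days?|weeks?|months?|years?|yrs?|y)"
    r"(?![A-Za-z0-9])",
    re.IGNORECASE,
)


def find_time_tags(text: str) -> list[Tag]:
    """All ``<number> <unit>`` duration expressions as TIME tags.

    A number without a recognised unit word directly after it yields no tag;
    zero-valued durations are skipped (logged at debug level).
    """
    tags: list[Tag] = []
    for m in _TIME_RE.finditer(text):
        value = float(m.group("value"))
        if value <= 0:
            log.debug("skipping zero duration %r at %d", m.group(0), m.start())
            continue
        unit = UNIT_SYNONYMS[m.group("unit").lower()]
        tags.append(
            Tag(
                kind="TIME",
                surface=m.group(0),
                span=(m.start(), m.end()),
                duration=Duration(value=value, unit=unit),
            )
        )
    return tags


def find_no_tags(
    text: str, negation_forms: Sequence[str] = DEFAULT_NEGATION_FORMS
) -> list[Tag]:
    """All word-boundary negation-marker occurrences as NO tags."""
    candidates: list[Tag] = []
    for form in negation_forms:
        # treat any whitespace run in the form as flexible whitespace
        body = r"\s+".join(re.escape(w) for w in form.split())
        pattern = rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])"
        for m in re.finditer(pattern, text, re.IGNORECASE):
            candidates.append(
                Tag(kind="NO", surface=m.group(0), span=(m.start(), m.end()))
            )
    return _resolve_overlaps(candidates)


_KIND_PRIORITY = {"DISEASE": 0, "TIME": 1, "NO": 2}


def _resolve_overlaps(candidates: Iterable[Tag]) -> list[Tag]:
    """Left-to-right sweep keeping non-overlapping tags.

    Sort key prefers earlier start, then DISEASE > TIME > NO, then the
    longer match; a candidate overlapping an already-kept tag is dropped.
    """
    kept: list[Tag] = []
    last_end = -1
    for tag in sorted(
        candidates,
        key=lambda t: (t.start, _KIND_PRIORITY[t.kind], -(t.end - t.start)),
    ):
        if tag.start >= last_end:
            kept.append(tag)
            last_end = tag.end
    return kept


def tag_text(
    text: str,
    lex: Lexicon | None = None,
    negation_forms: Sequence[str] = DEFAULT_NEGATION_FORMS,
) -> list[Tag]:
    """Merge disease, duration and negation tags into one ordered tape."""
    if lex is None:
        lex = default_lexicon()
    candidates = (
        find_disease_tags(text, lex)
        + find_time_tags(text)
        + find_no_tags(text, negation_forms)
    )
    return _resolve_overlaps(candidates)
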