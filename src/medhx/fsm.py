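"""Three-state machine clustering disease tags with their duration tags.

A past-medical-history note is reduced by :mod:`medhx.tagging` to a tape of
DISEASE / NO / TIME tags. This module runs a deterministic finite-state
machine over that tape to decide which duration belongs to which disease
and which mentions are negated:

* **State 0** — start state, nothing pending (``prev_disease = NULL``).
* **State 1** — a disease has been seen and is waiting for its duration.
* **State 2** — a negation marker has been seen; the next disease mention
  is absent and must not be recorded.

The transition table (state x tag kind -> next state) and the per-cell
actions are fixed lookups, exposed through :func:`transition` so they can be
enumerated exhaustively. The interesting cells: in state 1 a TIME tag
closes the pending record with its duration; a second DISEASE closes the
pending record *without* a duration (warning) and makes the new disease
pending; in state 2 a DISEASE is swallowed by the negation.

Four cells of the table are errors (e.g. a duration with no disease before
it, two consecutive negations). Errors never abort a run: each appends an
error event to the result and applies a documented recovery so that batch
extraction always completes. At the end of the tape a still-pending disease
is flushed as a record with no duration, with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .lexicon import Lexicon
from .tagging import DEFAULT_NEGATION_FORMS, Duration, Tag, tag_text

__all__ = [
    "ERROR",
    "START",
    "AWAIT_TIME",
    "NEGATION",
    "STATES",
    "EngineConfig",
    "Event",
    "DiseaseRecord",
    "ExtractionResult",
    "transition",
    "run_fsm",
    "extract",
    "ACTION_MESSAGES",
]

START, AWAIT_TIME, NEGATION = 0, 1, 2
STATES = (START, AWAIT_TIME, NEGATION)

#: Sentinel returned by :func:`transition` for error cells of the table.
ERROR = "ERROR"

TAG_KINDS = ("NO", "DISEASE", "TIME")

# state -> tag kind -> (next state | ERROR, action code)
_TRANSITIONS: dict[int, dict[str, tuple[int | str, str]]] = {
    START: {
        "NO": (NEGATION, "enter-negation"),
        "DISEASE": (AWAIT_TIME, "store-disease"),
        "TIME": (ERROR, "time-before-disease"),
    },
    AWAIT_TIME: {
        "NO": (ERROR, "no-after-disease"),
        "DISEASE": (AWAIT_TIME, "record-no-time"),
        "TIME": (START, "record-with-time"),
    },
    NEGATION: {
        "NO": (ERROR, "two-consecutive-nos"),
        "DISEASE": (START, "ignore-negated"),
        "TIME": (ERROR, "time-after-no"),
    },
}

#: Verbatim action message and its severity for every cell that prints one.
ACTION_MESSAGES: dict[str, tuple[str, str]] = {
    "store-disease": (
        "Found a disease. Hoping for it to be followed by a time since when "
        "disease existed.",
        "info",
    ),
    "time-before-disease": (
        "Warning: Found a time unit before finding a disease",
        "error",
    ),
    "no-after-disease": (
        "Disease Name followed by NO. Not according to how it should be",
        "error",
    ),
    "record-no-time": (
        "Warning: prev_disease was not followed by a time.",
        "warning",
    ),
    "record-with-time": (
        "Successfully detected disease and time since when",
        "info",
    ),
    "two-consecutive-nos": (
        "Error: Found two consecutive NOs",
        "error",
    ),
    "ignore-negated": (
        "Detected a “NO Disease statement. Ignoring and not recording.",
        "info",
    ),
    "time-after-no": (
        "Found a time unit after NO. Something wrong",
        "error",
    ),
}

# Recovery successor for each error cell: extraction must not abort on one
# malformed note. A stray TIME is dropped in place; a NO after a pending
# disease closes that record without a duration and honours the negation.
_ERROR_RECOVERY_STATE: dict[str, int] = {
    "time-before-disease": START,
    "no-after-disease": NEGATION,
    "two-consecutive-nos": NEGATION,
    "time-after-no": NEGATION,
}


def transition(state: int, tag_kind: str) -> tuple[int | str, str]:
    """Pure transition-table lookup.

    Returns ``(next_state, action_code)`` where ``next_state`` is one of the
    three states or the :data:`ERROR` sentinel. Never raises for in-alphabet
    input; the error cells are legal return values.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if tag_kind not in TAG_KINDS:
        raise ValueError(f"unknown tag kind {tag_kind!r}")
    return _TRANSITIONS[state][tag_kind]


@dataclass(frozen=True)
class EngineConfig:
    """Engine knobs.

    negation_surface_forms
        Markers recognised as NO tags when tagging text via :func:`extract`.
    emit_negated
        If True, negated diseases appear in the output with
        ``negated=True`` instead of being suppressed (the default mirrors
        the "ignore and do not record" behaviour).
    flush_pending_at_end
        Emit a pending disease left in state 1 at end of tape as a record
        with no duration (with a warning). Disable to drop it silently.
    error_policy
        Only ``"recover"`` is implemented: log the error event and continue
        at the documented recovery state.
    """

    negation_surface_forms: tuple[str, ...] = DEFAULT_NEGATION_FORMS
    emit_negated: bool = False
    flush_pending_at_end: bool = True
    error_policy: str = "recover"

    def __post_init__(self) -> None:
        if self.error_policy != "recover":
            raise ValueError(f"unsupported error_policy {self.error_policy!r}")


@dataclass(frozen=True)
class Event:
    """One action/anomaly raised while running the machine."""

    code: str
    severity: str  # info | warning | error
    message: str
    span: tuple[int, int] | None = None


@dataclass(frozen=True)
class DiseaseRecord:
    """One structured (disease, duration) output pair.

    ``duration`` is None when the mention carried no duration expression.
    ``negated`` records only appear when the engine is configured with
    ``emit_negated=True``; by default negated mentions are suppressed.
    """

    disease: str
    duration: Duration | None = None
    negated: bool = False
    source_span: tuple[int, int] | None = None


@dataclass
class ExtractionResult:
    """All records and events produced for one input string."""

    records: list[DiseaseRecord] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    final_state: int = START

    @property
    def warnings(self) -> list[Event]:
        return [e for e in self.events if e.severity == "warning"]

    @property
    def errors(self) -> list[Event]:
        return [e for e in self.events if e.severity == "error"]

    def pairs(self, include_negated: bool = False) -> set[tuple[str, Duration | None]]:
        """The (disease, duration) set, for evaluation against a gold record."""
        return {
            (r.disease, r.duration)
            for r in self.records
            if include_negated or not r.negated
        }


def run_fsm(tags: Sequence[Tag], config: EngineConfig | None = None) -> ExtractionResult:
    """Run the machine over an ordered, non-overlapping tag tape.

    Starts in state 0 with no pending disease; processes tags left to
    right; returns every emitted record plus all action events. Anomalies
    are events in the result, never exceptions.
    """
    cfg = config or EngineConfig()
    result = ExtractionResult()
    state = START
    pending: Tag | None = None  # the prev_disease memory cell

    def emit_event(code: str, span: tuple[int, int] | None) -> None:
        message, severity = ACTION_MESSAGES[code]
        result.events.append(Event(code=code, severity=severity, message=message, span=span))

    def emit_record(disease_tag: Tag, duration: Duration | None, negated: bool = False) -> None:
        result.records.append(
            DiseaseRecord(
                disease=disease_tag.disease,  # type: ignore[arg-type]
                duration=duration,
                negated=negated,
                source_span=disease_tag.span,
            )
        )

    for tag in tags:
        next_state, action = transition(state, tag.kind)
        if action in ACTION_MESSAGES:
            emit_event(action, tag.span)

        if action == "store-disease":
            pending = tag
        elif action == "record-no-time":
            assert pending is not None
            emit_record(pending, None)
            pending = tag
        elif action == "record-with-time":
            assert pending is not None
            emit_record(pending, tag.duration)
            pending = None
        elif action == "ignore-negated":
            if cfg.emit_negated:
                emit_record(tag, None, negated=True)
        elif action == "no-after-disease":
            # recovery: close the pending record without a duration, then
            # honour the negation that follows
            assert pending is not None
            emit_record(pending, None)
            pending = None

        state = _ERROR_RECOVERY_STATE[action] if next_state == ERROR else next_state

    if state == AWAIT_TIME and pending is not None and cfg.flush_pending_at_end:
        emit_record(pending, None)
        emit_event("record-no-time", pending.span)

    result.final_state = state
    return result


def extract(
    text: str,
    lex: Lexicon | None = None,
    config: EngineConfig | None = None,
) -> ExtractionResult:
    """Tag ``text`` and run the machine: the whole pipeline for one note."""
    cfg = config or EngineConfig()
    tape = tag_text(text, lex, negation_forms=cfg.negation_surface_forms)
    return run_fsm(tape, cfg)
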