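"""Shared fixtures: a session lexicon, tape builders, and an independent
brute-force clustering oracle used to cross-check the state machine."""

from __future__ import annotations

import random

import pytest

from medhx import default_lexicon
from medhx.tagging import Duration, Tag


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


# --- tape builders -----------------------------------------------------------
# Unit tests drive run_fsm with hand-built tapes; spans are synthetic but
# ordered and non-overlapping, surfaces are placeholders.

def D(disease: str, pos: int = 0) -> Tag:
    return Tag(kind="DISEASE", surface=disease, span=(pos * 10, pos * 10 + 5),
               disease=disease)


def T(value: float, unit: str = "year", pos: int = 0) -> Tag:
    return Tag(kind="TIME", surface=f"{value} {unit}", span=(pos * 10, pos * 10 + 5),
               duration=Duration(value=value, unit=unit))


def N(pos: int = 0) -> Tag:
    return Tag(kind="NO", surface="no", span=(pos * 10, pos * 10 + 2))


def random_tape(rng: random.Random, max_len: int = 12) -> list[Tag]:
    """A random ordered tape over a small disease/duration alphabet."""
    diseases = ["Hypertension", "Diabetes mellitus", "Asthma", "Epilepsy"]
    tape = []
    for pos in range(rng.randint(0, max_len)):
        kind = rng.choice(["DISEASE", "NO", "TIME"])
        if kind == "DISEASE":
            tape.append(D(rng.choice(diseases), pos))
        elif kind == "TIME":
            tape.append(T(rng.randint(1, 30), rng.choice(["day", "week", "month", "year"]), pos))
        else:
            tape.append(N(pos))
    return tape


# --- independent oracle ------------------------------------------------------

def oracle_records(tape: list[Tag], emit_negated: bool = False):
    """Brute-force re-statement of the clustering semantics, coded without a
    state machine: a NO negates exactly the next disease mention; an
    un-negated disease takes the duration of the tag immediately after it,
    if that tag is a TIME; everything else gets no duration.
    Returns (disease, duration, negated) triples in mention order.
    """
    out = []
    prev_disease_idx = -1
    for i, tag in enumerate(tape):
        if tag.kind != "DISEASE":
            continue
        negated = any(
            t.kind == "NO" for t in tape[prev_disease_idx + 1 : i]
        )
        if negated:
            if emit_negated:
                out.append((tag.disease, None, True))
        else:
            nxt = tape[i + 1] if i + 1 < len(tape) else None
            duration = nxt.duration if nxt is not None and nxt.kind == "TIME" else None
            out.append((tag.disease, duration, False))
        prev_disease_idx = i
    return out
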