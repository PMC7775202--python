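"""Record-level scoring of extractions against a manually annotated gold standard.

Scoring is deliberately strict, all-or-nothing at the record level: a
prediction counts as a true positive only when the *entire* set of diseases
(and, in duration mode, every (disease, duration) pair) matches the gold
annotation exactly. Partial credit is excluded on purpose — a structured
history with one missing comorbidity is a wrong history.

Two modes:

* ``diagnosis`` — compare the disease-name sets only.
* ``duration`` — compare the full (disease, duration) pair sets, with
  durations equal after unit normalisation (``2 yrs`` == 2 years).

A record with at least one gold disease is Actual-Yes: scored TP on exact
match, FN otherwise. A record with no gold disease is Actual-No: TN when
the prediction is empty, FP otherwise. Tallying over a corpus gives a 2x2
confusion matrix from which accuracy, sensitivity and positive predictive
value (PPV) are computed; any metric with a zero denominator is undefined
(None), never a division failure.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .fsm import ExtractionResult
from .tagging import Duration

__all__ = [
    "MODES",
    "GoldAnnotation",
    "ConfusionMatrix",
    "Metrics",
    "score_record",
    "build_confusion",
    "compute_metrics",
    "load_gold",
    "evaluate_corpus",
    "format_report",
]

MODES = ("diagnosis", "duration")

Pair = tuple[str, Duration | None]


@dataclass(frozen=True)
class GoldAnnotation:
    """The annotated truth for one record: a set of (disease, duration) pairs.

    Disease names are unique within a record; ``duration`` is None for a
    disease documented without one. An empty set means the record mentions
    no (affirmed) disease at all.
    """

    record_id: str
    diseases: frozenset[Pair]

    def __post_init__(self) -> None:
        names = [d for d, _ in self.diseases]
        if len(names) != len(set(names)):
            raise ValueError(
                f"record {self.record_id!r}: disease names must be unique"
            )

    @property
    def disease_names(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.diseases)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Record-level 2x2 counts (rows: gold yes/no, columns: predicted)."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity and PPV as proportions in [0, 1] (None if undefined)."""

    accuracy: float | None
    sensitivity: float | None
    ppv: float | None

    def as_percent(self, digits: int = 1) -> dict[str, float | None]:
        """The three metrics on the 0–100 scale, rounded for display."""
        return {
            k: (None if v is None else round(100.0 * v, digits))
            for k, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("ppv", self.ppv),
            )
        }


def _pred_pairs(pred: ExtractionResult | Iterable[Pair]) -> set[Pair]:
    if isinstance(pred, ExtractionResult):
        return pred.pairs()
    return set(pred)


def score_record(
    pred: ExtractionResult | Iterable[Pair],
    gold: GoldAnnotation,
    mode: str = "duration",
) -> str:
    """Label one record TP / FN / FP / TN under exact-set matching."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    pairs = _pred_pairs(pred)
    if mode == "diagnosis":
        predicted: set = {d for d, _ in pairs}
        actual: set = set(gold.disease_names)
    else:
        predicted = pairs
        actual = set(gold.diseases)
    if actual:
        return "TP" if predicted == actual else "FN"
    return "TN" if not predicted else "FP"


def build_confusion(
    preds: Sequence[ExtractionResult | Iterable[Pair]] | Mapping[str, Iterable[Pair]],
    golds: Sequence[GoldAnnotation],
    mode: str = "duration",
) -> ConfusionMatrix:
    """Tally :func:`score_record` over a corpus.

    ``preds`` is either a sequence aligned with ``golds`` or a mapping from
    record id; a missing or extra id is an error.
    """
    if isinstance(preds, Mapping):
        gold_ids = {g.record_id for g in golds}
        if set(preds) != gold_ids:
            missing = sorted(gold_ids - set(preds))[:5]
            extra = sorted(set(preds) - gold_ids)[:5]
            raise ValueError(
                f"prediction/gold id mismatch (missing={missing}, extra={extra})"
            )
        aligned: list = [preds[g.record_id] for g in golds]
    else:
        if len(preds) != len(golds):
            raise ValueError(
                f"got {len(preds)} predictions for {len(golds)} gold records"
            )
        aligned = list(preds)
    counts = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for pred, gold in zip(aligned, golds):
        counts[score_record(pred, gold, mode)] += 1
    return ConfusionMatrix(**{k.lower(): v for k, v in counts.items()})


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """accuracy=(TP+TN)/n, sensitivity=TP/(TP+FN), PPV=TP/(TP+FP)."""
    return Metrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
    )


# ---------------------------------------------------------------------------
# gold-standard file I/O
#
# One row per gold (disease, duration) pair: record_id, disease,
# duration_value, duration_unit. A record with no diseases appears as a
# single row with an empty disease. CSV or JSONL, chosen by extension.

def _rows_to_gold(rows: Iterable[Mapping[str, object]]) -> list[GoldAnnotation]:
    by_id: dict[str, set[Pair]] = {}
    for row in rows:
        rid = str(row["record_id"])
        pairs = by_id.setdefault(rid, set())
        disease = str(row.get("disease") or "").strip()
        if not disease:
            continue
        value = row.get("duration_value")
        unit = row.get("duration_unit")
        has_value = value not in (None, "") and value == value  # NaN-safe
        duration = (
            Duration(value=float(value), unit=str(unit)) if has_value else None  # type: ignore[arg-type]
        )
        pairs.add((disease, duration))
    return [
        GoldAnnotation(record_id=rid, diseases=frozenset(pairs))
        for rid, pairs in by_id.items()
    ]


def load_gold(path: str | PathLike) -> list[GoldAnnotation]:
    """Read gold annotations from a CSV or JSONL file (see module docstring)."""
    path = Path(path)
    if path.suffix.lower() in (".jsonl", ".json"):
        with path.open(encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    return _rows_to_gold(rows)


def evaluate_corpus(
    preds: Mapping[str, Iterable[Pair]] | Sequence[ExtractionResult | Iterable[Pair]],
    golds: Sequence[GoldAnnotation],
    modes: Sequence[str] = MODES,
) -> dict[str, dict[str, object]]:
    """Confusion matrix + metrics per mode, as a JSON-ready dict."""
    report: dict[str, dict[str, object]] = {}
    for mode in modes:
        cm = build_confusion(preds, golds, mode)
        metrics = compute_metrics(cm)
        report[mode] = {
            "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn, "n": cm.n},
            "metrics_percent": metrics.as_percent(),
        }
    return report


def format_report(report: Mapping[str, Mapping[str, object]]) -> str:
    """Plain-text table for a dict produced by :func:`evaluate_corpus`."""
    lines = []
    for mode, block in report.items():
        cm = block["confusion"]
        m = block["metrics_percent"]
        fmt = lambda v: "undefined" if v is None else f"{v:.1f}%"  # noqa: E731
        lines += [
            f"[{mode}] n={cm['n']}",
            f"  predicted yes / no   gold yes: {cm['tp']:>5} {cm['fn']:>5}",
            f"                       gold no : {cm['fp']:>5} {cm['tn']:>5}",
            f"  accuracy {fmt(m['accuracy'])}  sensitivity {fmt(m['sensitivity'])}  "
            f"PPV {fmt(m['ppv'])}",
        ]
    return "\n".join(lines)
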