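"""Record-level scoring protocol and the accuracy / sensitivity / PPV formulas."""

import random

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, precision_score, recall_score

from medhx import (
    ConfusionMatrix,
    GoldAnnotation,
    build_confusion,
    compute_metrics,
    load_gold,
    score_record,
)
from medhx.evaluation import evaluate_corpus, format_report
from medhx.tagging import Duration

Y2 = Duration(2, "year")
Y3 = Duration(3, "year")


def gold(*pairs, record_id="r1"):
    return GoldAnnotation(record_id=record_id, diseases=frozenset(pairs))


class TestScoreRecord:
    @pytest.mark.parametrize(
        "pred,gold_pairs,mode,expected",
        [
            # exact pair match
            ([("Diabetes mellitus", Y2)], [("Diabetes mellitus", Y2)], "duration", "TP"),
            # empty-vs-empty
            ([], [], "duration", "TN"),
            ([], [], "diagnosis", "TN"),
            # wrong duration: diagnosis TP, duration FN
            ([("Diabetes mellitus", Y2)], [("Diabetes mellitus", Y3)], "diagnosis", "TP"),
            ([("Diabetes mellitus", Y2)], [("Diabetes mellitus", Y3)], "duration", "FN"),
            # missing or extra disease is an outright miss (no partial credit)
            ([("Asthma", None)], [("Asthma", None), ("Epilepsy", None)], "diagnosis", "FN"),
            ([("Asthma", None), ("Epilepsy", None)], [("Asthma", None)], "diagnosis", "FN"),
            # spurious prediction on an empty record
            ([("Asthma", None)], [], "diagnosis", "FP"),
            # unit-normalised equality: 2 years parsed from "2 yrs"
            ([("Asthma", Duration(2.0, "year"))], [("Asthma", Duration(2, "year"))],
             "duration", "TP"),
        ],
    )
    def test_protocol(self, pred, gold_pairs, mode, expected):
        assert score_record(pred, gold(*gold_pairs), mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            score_record([], gold(), "mention")

    def test_gold_rejects_duplicate_disease_names(self):
        with pytest.raises(ValueError):
            gold(("Asthma", None), ("Asthma", Y2))


class TestConfusion:
    def test_tally_and_partition(self):
        golds = [gold(("Asthma", None), record_id=f"g{i}") for i in range(3)]
        golds.append(gold(record_id="g3"))
        preds = [
            [("Asthma", None)],   # TP
            [("Epilepsy", None)], # FN
            [],                   # FN
            [],                   # TN
        ]
        cm = build_confusion(preds, golds, "diagnosis")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 2, 0, 1)
        assert cm.n == len(golds)

    def test_empty(self):
        assert build_confusion([], [], "diagnosis") == ConfusionMatrix(0, 0, 0, 0)

    def test_id_mismatch_rejected(self):
        golds = [gold(record_id="a")]
        with pytest.raises(ValueError, match="mismatch"):
            build_confusion({"b": []}, golds)
        with pytest.raises(ValueError):
            build_confusion([[], []], golds)

    def test_mapping_predictions_align_by_id(self):
        golds = [gold(("Asthma", None), record_id="x"), gold(record_id="y")]
        cm = build_confusion({"y": [], "x": [("Asthma", None)]}, golds, "diagnosis")
        assert (cm.tp, cm.tn) == (1, 1)


class TestMetrics:
    def test_zero_denominators_are_undefined(self):
        m = compute_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert m.accuracy == 1.0
        assert m.sensitivity is None and m.ppv is None
        assert m.as_percent() == {"accuracy": 100.0, "sensitivity": None, "ppv": None}

    def test_display_rounding_one_decimal(self):
        m = compute_metrics(ConfusionMatrix(94, 5, 0, 1))
        assert m.as_percent()["sensitivity"] == 94.9  # 94/99

    def test_crosscheck_against_sklearn(self):
        # expand each matrix into label vectors and compare formulas
        rng = random.Random(123)
        for _ in range(1000):
            tp, fn, fp, tn = (rng.randint(0, 20) for _ in range(4))
            if tp + fn + fp + tn == 0:
                continue
            cm = ConfusionMatrix(tp, fn, fp, tn)
            y_true = np.array([1] * (tp + fn) + [0] * (fp + tn))
            y_pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
            m = compute_metrics(cm)
            assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
            if tp + fn:
                assert m.sensitivity == pytest.approx(recall_score(y_true, y_pred, zero_division=0))
            if tp + fp:
                assert m.ppv == pytest.approx(precision_score(y_true, y_pred, zero_division=0))

    def test_fn_to_tp_never_decreases_defined_metrics(self):
        rng = random.Random(9)
        for _ in range(500):
            tp, fn, fp, tn = (rng.randint(0, 15) for _ in range(4))
            if fn == 0:
                fn = 1
            before = compute_metrics(ConfusionMatrix(tp, fn, fp, tn))
            after = compute_metrics(ConfusionMatrix(tp + 1, fn - 1, fp, tn))
            for name in ("accuracy", "sensitivity", "ppv"):
                b, a = getattr(before, name), getattr(after, name)
                if b is not None and a is not None:
                    assert a >= b

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestGoldIO:
    def test_csv_and_jsonl_roundtrip(self, tmp_path):
        csv_path = tmp_path / "gold.csv"
        csv_path.write_text(
            "record_id,disease,duration_value,duration_unit\n"
            "r1,Diabetes mellitus,2,year\n"
            "r1,Asthma,,\n"
            "r2,,,\n"
        )
        golds = {g.record_id: g for g in load_gold(csv_path)}
        assert golds["r1"].diseases == frozenset(
            {("Diabetes mellitus", Y2), ("Asthma", None)}
        )
        assert golds["r2"].diseases == frozenset()

        jsonl_path = tmp_path / "gold.jsonl"
        jsonl_path.write_text(
            '{"record_id": "r1", "disease": "Diabetes mellitus", '
            '"duration_value": 2, "duration_unit": "year"}\n'
            '{"record_id": "r1", "disease": "Asthma"}\n'
            '{"record_id": "r2", "disease": ""}\n'
        )
        assert {g.record_id: g.diseases for g in load_gold(jsonl_path)} == {
            g.record_id: g.diseases for g in load_gold(csv_path)
        }

    def test_report_rendering(self):
        golds = [gold(("Asthma", None), record_id="a"), gold(record_id="b")]
        report = evaluate_corpus({"a": [("Asthma", None)], "b": []}, golds)
        assert report["diagnosis"]["metrics_percent"]["accuracy"] == 100.0
        text = format_report(report)
        assert "diagnosis" in text and "duration" in text and "100.0%" in text
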