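"""Confusion-count scoring, precision/recall/F arithmetic, prediction merge."""

import random

import pytest

from pgdbcompare import (
    ConfusionCounts,
    ConservationError,
    GoldStandard,
    PredictionSet,
    check_conservation,
    classify,
    merge_predictions,
    metrics,
)
from pgdbcompare.evaluation import read_prediction_set, write_prediction_set


def make_gold(annotations):
    return GoldStandard(annotations={g: set(v) for g, v in annotations.items()})


def make_pred(predictions, universe=None, name="x"):
    preds = {g: set(v) for g, v in predictions.items()}
    if universe is None:
        universe = set(preds)
    return PredictionSet(name=name, predictions=preds, gene_universe=set(universe))


class TestClassify:
    def test_exact_match(self):
        c = classify(make_pred({"g1": {"1.1.1.1"}}), make_gold({"g1": {"1.1.1.1"}}))
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_mismatch_is_both_fp_and_fn(self):
        c = classify(make_pred({"g1": {"2.2.2.2"}}), make_gold({"g1": {"1.1.1.1"}}))
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_missing_gene_rule_turns_all_gold_labels_into_fn(self):
        gold = make_gold({"g1": {"1.1.1.1", "2.2.2.2"}})
        c = classify(make_pred({}, universe={"g9"}), gold)
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)

    def test_predictions_outside_gold_are_unscored(self):
        gold = make_gold({"g1": {"1.1.1.1"}})
        pred = make_pred({"g1": {"1.1.1.1"}, "g2": {"3.3.3.3"}})
        c = classify(pred, gold)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_partial_label_matches_only_identical_partial(self):
        gold = make_gold({"g1": {"2.7.7.-"}})
        assert classify(make_pred({"g1": {"2.7.7.-"}}), gold).tp == 1
        c = classify(make_pred({"g1": {"2.7.7.7"}}), gold)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_agrees_with_brute_force_per_gene_set_differences(self):
        rng = random.Random(99)
        labels = [f"{c}.{x}.1.1" for c in range(1, 7) for x in range(1, 9)]
        gold = make_gold(
            {f"g{i}": rng.sample(labels, rng.randrange(1, 4)) for i in range(200)}
        )
        universe = {f"g{i}" for i in range(150)}  # 50 gold genes missing
        pred = make_pred(
            {f"g{i}": rng.sample(labels, rng.randrange(0, 4)) for i in range(150)},
            universe=universe,
        )
        tp = fp = fn = 0
        for g, gl in gold.annotations.items():
            pl = pred.predictions.get(g, set()) if g in universe else set()
            tp += len(pl & gl)
            fp += len(pl - gl)
            fn += len(gl - pl)
        c = classify(pred, gold)
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        c.check_internal_sums()

    def test_conservation_holds_for_any_prediction_set(self):
        gold = make_gold({"g1": {"1.1.1.1"}, "g2": {"2.2.2.2", "3.3.3.3"}})
        for pred in (
            make_pred({}),
            make_pred({"g1": {"1.1.1.1"}}),
            make_pred({"g2": {"9.9.9.9"}}, universe={"g1", "g2"}),
        ):
            check_conservation(classify(pred, gold), gold)

    def test_conservation_error_message_carries_counts(self):
        gold = make_gold({"g1": {"1.1.1.1"}})
        broken = ConfusionCounts(tp=5, fp=0, fn=0)
        with pytest.raises(ConservationError, match="5"):
            check_conservation(broken, gold)


class TestMetrics:
    @pytest.mark.parametrize(
        "tp, fp, fn, precision, recall, f",
        [
            (1326, 213, 149, 0.86, 0.90, 0.88),
            (1235, 436, 240, 0.74, 0.84, 0.79),
        ],
    )
    def test_two_resource_benchmark_rows(self, tp, fp, fn, precision, recall, f):
        m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        assert round(m.precision, 2) == precision
        assert round(m.recall, 2) == recall
        assert round(m.f_measure, 2) == f

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, fn=0))
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    def test_empty_denominators_score_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0))
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    def test_f_between_precision_and_recall(self):
        rng = random.Random(3)
        for _ in range(100):
            c = ConfusionCounts(
                tp=rng.randrange(1, 50), fp=rng.randrange(0, 50), fn=rng.randrange(0, 50)
            )
            m = metrics(c)
            assert min(m.precision, m.recall) <= m.f_measure <= max(m.precision, m.recall)

    def test_agrees_with_per_gene_detail_sums(self):
        gold = make_gold({f"g{i}": {f"1.1.1.{i + 1}"} for i in range(20)})
        pred = make_pred({f"g{i}": {f"1.1.1.{i + 1}"} for i in range(10)},
                         universe={f"g{i}" for i in range(20)})
        c = classify(pred, gold)
        tp = sum(t for t, _, _ in c.per_gene_detail.values())
        fp = sum(f for _, f, _ in c.per_gene_detail.values())
        fn = sum(n for _, _, n in c.per_gene_detail.values())
        assert metrics(c) == metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))


class TestMergePredictions:
    def test_per_gene_label_union(self):
        merged = merge_predictions(
            make_pred({"g1": {"1.1.1.1"}}), make_pred({"g1": {"2.2.2.2"}})
        )
        assert merged.predictions == {"g1": {"1.1.1.1", "2.2.2.2"}}

    def test_idempotent(self):
        a = make_pred({"g1": {"1.1.1.1"}}, universe={"g1", "g2"})
        merged = merge_predictions(a, a)
        assert merged.predictions == a.predictions
        assert merged.gene_universe == a.gene_universe

    def test_merge_monotonicity_against_brute_force(self):
        # 50 genes with random label sets: merged TP can only gain, FN only
        # shrink, FP at most add up — verified against direct enumeration
        rng = random.Random(17)
        labels = [f"{c}.1.1.{x}" for c in range(1, 7) for x in range(1, 6)]
        gold = make_gold({f"g{i}": rng.sample(labels, 2) for i in range(50)})
        universe = {f"g{i}" for i in range(50)}
        a = make_pred({f"g{i}": rng.sample(labels, rng.randrange(0, 3))
                       for i in range(50)}, universe=universe)
        b = make_pred({f"g{i}": rng.sample(labels, rng.randrange(0, 3))
                       for i in range(50)}, universe=universe)
        ca, cb = classify(a, gold), classify(b, gold)
        cm = classify(merge_predictions(a, b), gold)
        assert cm.tp >= max(ca.tp, cb.tp)
        assert cm.fn <= min(ca.fn, cb.fn)
        assert cm.fp <= ca.fp + cb.fp
        # brute-force TP of the merged set
        tp = sum(
            len((a.predictions.get(g, set()) | b.predictions.get(g, set())) & gl)
            for g, gl in gold.annotations.items()
        )
        assert cm.tp == tp


def test_prediction_set_rejects_genes_outside_universe():
    with pytest.raises(ValueError, match="outside"):
        PredictionSet("x", {"g1": {"1.1.1.1"}}, gene_universe=set())


def test_prediction_set_tsv_round_trip(tmp_path):
    pred = make_pred({"g1": {"1.1.1.1", "2.2.2.2"}}, universe={"g1", "g2"})
    write_prediction_set(pred, tmp_path / "p.tsv", tmp_path / "u.txt")
    back = read_prediction_set(tmp_path / "p.tsv", tmp_path / "u.txt", "x")
    assert back.predictions == pred.predictions
    assert back.gene_universe == pred.gene_universe
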