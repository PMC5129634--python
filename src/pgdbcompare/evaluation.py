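"""Score predicted enzyme annotations against a gene-level gold standard.

Scoring is restricted to gold-standard genes, since true negatives cannot be
counted for open-ended enzyme function prediction.  For each gold gene ``g``
with label set ``gold(g)`` and predictions ``pred(g)``:

* TP = |pred(g) ∩ gold(g)|
* FP = |pred(g) \\ gold(g)|
* FN = |gold(g) \\ pred(g)|

A gold gene absent from a resource's gene universe has an empty ``pred(g)``,
so all of its labels count as false negatives (the missing-gene rule).
Predictions on genes without gold labels are unscorable and contribute
nothing.  This bookkeeping conserves TP + FN = total gold annotation count
for every prediction set.

precision = TP/(TP+FP); recall = TP/(TP+FN); F = 2·P·R/(P+R).

EC labels are compared by exact four-field string equality after
normalization; a partial label like ``2.7.7.-`` matches only an identical
partial label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path


class ConservationError(AssertionError):
    """TP + FN failed to equal the gold-standard annotation count."""


@dataclass
class PredictionSet:
    """One resource's predicted gene → EC-label map plus its gene universe.

    The universe is the full set of genes the resource contains; it decides
    whether an unpredicted gold label is an ordinary miss or a missing-gene
    false negative.
    """

    name: str
    predictions: dict[str, set[str]] = field(default_factory=dict)
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        stray = set(self.predictions) - self.gene_universe
        if stray:
            raise ValueError(
                f"prediction set {self.name!r}: {len(stray)} predicted genes outside "
                f"the gene universe (e.g. {sorted(stray)[:3]})"
            )


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_gene_detail: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def check_internal_sums(self) -> None:
        sums = tuple(
            sum(t[i] for t in self.per_gene_detail.values()) for i in range(3)
        )
        if sums != (self.tp, self.fp, self.fn):
            raise AssertionError(
                f"per-gene detail sums {sums} disagree with totals "
                f"({self.tp}, {self.fp}, {self.fn})"
            )


@dataclass
class Metrics:
    precision: float
    recall: float
    f_measure: float


def classify(pred: PredictionSet, gold) -> ConfusionCounts:
    """Confusion counts of a prediction set against the gold standard.

    ``gold`` is a :class:`~pgdbcompare.gold_standard.GoldStandard` or anything
    with an ``annotations`` gene→labels mapping.
    """
    counts = ConfusionCounts()
    for gene_id, gold_labels in gold.annotations.items():
        if gene_id in pred.gene_universe:
            predicted = pred.predictions.get(gene_id, set())
        else:
            predicted = set()  # missing-gene rule: every gold label is a FN
        tp = len(predicted & gold_labels)
        fp = len(predicted - gold_labels)
        fn = len(gold_labels - predicted)
        counts.per_gene_detail[gene_id] = (tp, fp, fn)
        counts.tp += tp
        counts.fp += fp
        counts.fn += fn
    return counts


def check_conservation(counts: ConfusionCounts, gold) -> None:
    """Assert TP + FN equals the gold annotation count; raise otherwise."""
    total = sum(len(v) for v in gold.annotations.values())
    if counts.tp + counts.fn != total:
        raise ConservationError(
            f"TP + FN = {counts.tp + counts.fn} but the gold standard holds "
            f"{total} annotations"
        )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision, recall and F-measure, with empty denominators scored as 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0.0:
        f_measure = 0.0
    else:
        f_measure = 2.0 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, f_measure=f_measure)


def merge_predictions(a: PredictionSet, b: PredictionSet) -> PredictionSet:
    """Per-gene label union over the union of the two gene universes."""
    merged: dict[str, set[str]] = {}
    for src in (a, b):
        for gene_id, labels in src.predictions.items():
            merged.setdefault(gene_id, set()).update(labels)
    name = a.name if a.name == b.name else f"{a.name}+{b.name}"
    return PredictionSet(
        name=name,
        predictions=merged,
        gene_universe=a.gene_universe | b.gene_universe,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_prediction_set(
    predictions_path: str | Path, universe_path: str | Path, name: str
) -> PredictionSet:
    """Predictions TSV (gene_id, ec_label; header) + universe file (one gene
    id per line)."""
    import pandas as pd

    df = pd.read_csv(predictions_path, sep="\t", dtype=str)
    if not {"gene_id", "ec_label"}.issubset(df.columns):
        raise ValueError(f"{predictions_path}: needs columns gene_id, ec_label")
    predictions: dict[str, set[str]] = {}
    for row in df.itertuples():
        predictions.setdefault(row.gene_id, set()).add(row.ec_label)
    universe = {
        line.strip()
        for line in Path(universe_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    return PredictionSet(name=name, predictions=predictions, gene_universe=universe)


def write_prediction_set(
    pred: PredictionSet, predictions_path: str | Path, universe_path: str | Path
) -> None:
    with open(predictions_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "ec_label"])
        for gene_id in sorted(pred.predictions):
            for ec in sorted(pred.predictions[gene_id]):
                writer.writerow([gene_id, ec])
    Path(universe_path).write_text(
        "".join(f"{g}\n" for g in sorted(pred.gene_universe)), encoding="utf-8"
    )


def write_confusion_table(
    rows: list[tuple[str, ConfusionCounts, Metrics]], path: str | Path
) -> None:
    """TSV: resource, tp, fp, fn, precision, recall, f_measure (full precision)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["resource", "tp", "fp", "fn", "precision", "recall", "f_measure"]
        )
        for name, counts, m in rows:
            writer.writerow(
                [
                    name, counts.tp, counts.fp, counts.fn,
                    repr(m.precision), repr(m.recall), repr(m.f_measure),
                ]
            )
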