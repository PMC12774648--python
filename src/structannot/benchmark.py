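"""Evaluation machinery: the binary annotation task, multiclass micro
metrics at group/product/category level, per-category breakdowns and
annotation-rate summaries.

The binary task asks whether a method assigns *any* non-hypothetical
function to a protein whose reference annotation is non-hypothetical;
multiclass metrics ask whether the assigned label is the *correct* one
at a chosen level of the label hierarchy. Reference annotations come
from a pseudo ground truth (typically the same pipeline run in
structures mode at a permissive E-value threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotate import CdsAnnotation
from .model import AnnotationLabel, StructannotError

__all__ = [
    "BenchmarkReport",
    "binary_metrics",
    "multiclass_micro_f1",
    "per_category_f1",
    "annotation_rates",
    "evaluate",
]

LEVELS = ("group", "product", "category")

LabelMap = Mapping[str, Optional[AnnotationLabel]]


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _check_ids(pred: LabelMap, truth: LabelMap) -> None:
    if set(pred) != set(truth):
        diff = sorted(set(pred) ^ set(truth))[:5]
        raise StructannotError(f"CDS id sets differ, e.g. {diff}")


def _known(label: Optional[AnnotationLabel]) -> bool:
    return label is not None and label.is_known()


def binary_metrics(pred: LabelMap, truth: LabelMap) -> tuple[float, float, float]:
    """Precision/recall/F1 of assigning *any* known function.

    Positives are the truth-known CDS; a predicted-known CDS counts as a
    true positive when its truth is known and a false positive when its
    truth is unknown.
    """
    _check_ids(pred, truth)
    tp = sum(1 for c in truth if _known(truth[c]) and _known(pred[c]))
    fp = sum(1 for c in truth if not _known(truth[c]) and _known(pred[c]))
    fn = sum(1 for c in truth if _known(truth[c]) and not _known(pred[c]))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, _f1(precision, recall)


def _at_level(label: AnnotationLabel, level: str) -> str:
    if level == "group":
        return label.group_id
    if level == "product":
        return label.product.strip().lower()
    if level == "category":
        return label.category
    raise StructannotError(f"unknown level {level!r}")


def multiclass_micro_f1(pred: LabelMap, truth: LabelMap, level: str) -> float:
    """Micro-averaged F1 over the truth-known CDS.

    A prediction is correct iff its label equals the reference label at
    the requested level; positives without a known prediction count as
    false negatives, wrong known predictions as both FP and FN.
    """
    _check_ids(pred, truth)
    if level not in LEVELS:
        raise StructannotError(f"unknown level {level!r}")
    positives = [c for c in truth if _known(truth[c])]
    tp = fp = 0
    for c in positives:
        if not _known(pred[c]):
            continue
        if _at_level(pred[c], level) == _at_level(truth[c], level):
            tp += 1
        else:
            fp += 1
    n_pos = len(positives)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_pos if n_pos else 0.0
    return _f1(precision, recall)


def per_category_f1(pred: LabelMap, truth: LabelMap) -> dict[str, Optional[float]]:
    """One-vs-rest F1 per functional category.

    Categories absent from the truth are reported as ``None`` (undefined)
    unless the method predicted them anyway, in which case F1 is 0 —
    sparse categories with spurious predictions score zero rather than
    vanishing from the report.
    """
    _check_ids(pred, truth)
    cats = {truth[c].category for c in truth if _known(truth[c])}
    cats |= {pred[c].category for c in pred if _known(pred[c])}
    out: dict[str, Optional[float]] = {}
    for cat in sorted(cats):
        tp = sum(
            1
            for c in truth
            if _known(truth[c])
            and truth[c].category == cat
            and _known(pred[c])
            and pred[c].category == cat
        )
        n_truth = sum(1 for c in truth if _known(truth[c]) and truth[c].category == cat)
        n_pred = sum(1 for c in pred if _known(pred[c]) and pred[c].category == cat)
        if n_truth == 0:
            out[cat] = 0.0 if n_pred > 0 else None
            continue
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_truth
        out[cat] = _f1(precision, recall)
    return out


DEFAULT_LENGTH_BINS = (100, 250)


def annotation_rates(
    annotations: Sequence[CdsAnnotation],
    length_bins: tuple[int, int] = DEFAULT_LENGTH_BINS,
) -> tuple[float, float, dict[str, dict[str, float]]]:
    """Functional and any-hit annotation rates, plus the same rates within
    protein-length bins (default <100, 100-250, >250 residues)."""
    if not annotations:
        raise StructannotError("no annotations supplied")
    lo, hi = length_bins

    def rates(subset: Sequence[CdsAnnotation]) -> dict[str, float]:
        n = len(subset)
        return {
            "n": n,
            "functional_rate": sum(a.functional_hit for a in subset) / n if n else 0.0,
            "any_hit_rate": sum(a.any_hit_count > 0 for a in subset) / n if n else 0.0,
        }

    overall = rates(annotations)
    with_len = [a for a in annotations if a.protein_length is not None]
    by_bin = {
        f"<{lo}": rates([a for a in with_len if a.protein_length < lo]),
        f"{lo}-{hi}": rates([a for a in with_len if lo <= a.protein_length <= hi]),
        f">{hi}": rates([a for a in with_len if a.protein_length > hi]),
    }
    return overall["functional_rate"], overall["any_hit_rate"], by_bin


@dataclass
class BenchmarkReport:
    """Bundled evaluation result."""

    binary_precision: float
    binary_recall: float
    binary_f1: float
    micro_f1: dict[str, float]
    per_category_f1: dict[str, Optional[float]]
    annotation_rate: float
    any_hit_rate: float
    n_cds: int
    by_length: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "binary_precision": self.binary_precision,
            "binary_recall": self.binary_recall,
            "binary_f1": self.binary_f1,
            "micro_f1": self.micro_f1,
            "per_category_f1": self.per_category_f1,
            "annotation_rate": self.annotation_rate,
            "any_hit_rate": self.any_hit_rate,
            "n_cds": self.n_cds,
            "by_length": self.by_length,
        }


def evaluate(
    annotations: Sequence[CdsAnnotation],
    truth: LabelMap,
) -> BenchmarkReport:
    """Full evaluation of a set of CDS annotations against a reference."""
    pred = {a.cds_id: a.label for a in annotations}
    p, r, f1 = binary_metrics(pred, truth)
    micro = {lvl: multiclass_micro_f1(pred, truth, lvl) for lvl in LEVELS}
    cats = per_category_f1(pred, truth)
    func_rate, any_rate, by_len = annotation_rates(annotations)
    return BenchmarkReport(
        binary_precision=p,
        binary_recall=r,
        binary_f1=f1,
        micro_f1=micro,
        per_category_f1=cats,
        annotation_rate=func_rate,
        any_hit_rate=any_rate,
        n_cds=len(annotations),
        by_length=by_len,
    )
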