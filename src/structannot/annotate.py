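"""Annotation transfer from ranked hits and confidence-tier classification.

The top-ranking hit (by E-value) whose database target carries a known
function supplies the transferred label. Each functional annotation is
then graded high/medium/low:

* **high** — reciprocal (query and target) alignment coverage >= 80%, and
  either >30% AA identity, or query mean 3Di-prediction confidence >= 60,
  or E-value < 1e-10;
* **medium** — one-sided coverage >= 80%, (>30% identity or confidence in
  [45, 60)), and E-value < 1e-5;
* **low** — every other hit below the search E-value threshold.

In structures mode (3Di read from experimental/predicted structures) the
confidence clauses are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import AnnotationLabel, DualSequence, StructannotError
from .search import Alignment, Calibration, SearchParams, search
from .threedi import protein_confidence

__all__ = ["CdsAnnotation", "transfer_annotation", "classify_tier", "annotate_genome"]

TIERS = ("high", "medium", "low", "none")


@dataclass
class CdsAnnotation:
    """Transferred label, confidence tier and provenance for one CDS."""

    cds_id: str
    label: Optional[AnnotationLabel] = None
    tier: str = "none"
    best_hit: Optional[Alignment] = None
    any_hit_count: int = 0
    functional_hit: bool = False
    protein_length: Optional[int] = None
    query_conf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise StructannotError(f"invalid tier {self.tier!r}")
        if self.functional_hit and (self.label is None or not self.label.is_known()):
            raise StructannotError(
                f"functional_hit set for {self.cds_id} without a known-function label"
            )


def transfer_annotation(
    hits: Sequence[Alignment],
    labels: Mapping[str, AnnotationLabel],
    evalue_max: float,
) -> CdsAnnotation:
    """Scan ranked hits; the first whose target is known-function supplies
    the annotation. When only unknown-function hits exist, the top hit's
    group is kept with product "hypothetical protein" so PHROG-membership
    statistics remain computable. ``any_hit_count`` counts every hit at or
    below ``evalue_max``, functional or not."""
    considered = [h for h in hits if h.evalue <= evalue_max]
    cds_id = hits[0].query_id if hits else ""
    for h in considered:
        if h.target_id not in labels:
            raise StructannotError(f"hit target {h.target_id} absent from label table")
    ann = CdsAnnotation(cds_id=cds_id, any_hit_count=len(considered))
    for h in considered:
        if labels[h.target_id].is_known():
            ann.label = labels[h.target_id]
            ann.best_hit = h
            ann.functional_hit = True
            return ann
    if considered:
        top = considered[0]
        src = labels[top.target_id]
        ann.label = AnnotationLabel(
            group_id=src.group_id,
            product="hypothetical protein",
            category="unknown function",
        )
        ann.best_hit = top
    return ann


def classify_tier(
    hit: Alignment,
    query_conf: Optional[float],
    mode: str = "prostt5",
    evalue_max: float = 1e-3,
) -> str:
    """Grade one functional hit as ``high``/``medium``/``low``."""
    if mode not in ("prostt5", "structures"):
        raise StructannotError(f"unknown mode {mode!r}")
    if hit.evalue > evalue_max:
        raise StructannotError(
            f"hit E-value {hit.evalue} exceeds threshold {evalue_max}"
        )
    if mode == "prostt5" and query_conf is None:
        raise StructannotError("prostt5 mode requires the query mean confidence")
    use_conf = mode == "prostt5"
    high_alt = hit.fident > 0.30 or hit.evalue < 1e-10
    if use_conf and query_conf >= 60.0:
        high_alt = True
    if hit.qcov >= 0.8 and hit.tcov >= 0.8 and high_alt:
        return "high"
    med_alt = hit.fident > 0.30
    if use_conf and 45.0 <= query_conf < 60.0:
        med_alt = True
    if (hit.qcov >= 0.8 or hit.tcov >= 0.8) and med_alt and hit.evalue < 1e-5:
        return "medium"
    return "low"


def annotate_genome(
    cds_list: Sequence[DualSequence],
    db: Sequence[DualSequence],
    labels: Mapping[str, AnnotationLabel],
    params: Optional[SearchParams] = None,
    mode: str = "prostt5",
    calib: Optional[Calibration] = None,
    exhaustive: bool = False,
    seed: int = 0,
) -> tuple[list[CdsAnnotation], dict]:
    """Annotate every CDS of a genome and summarize the result.

    Returns per-CDS annotations (sorted by CDS id, so the output is
    independent of input order) and a summary with per-category counts,
    the functional annotation rate (known-function labels / total CDS)
    and the any-PHROG hit rate.
    """
    params = params or SearchParams()
    hits_by_query = search(
        cds_list, db, params, calib=calib, exhaustive=exhaustive, seed=seed
    )
    annotations: list[CdsAnnotation] = []
    for cds in sorted(cds_list, key=lambda c: c.id):
        hits = hits_by_query.get(cds.id, [])
        ann = transfer_annotation(hits, labels, params.evalue_max)
        ann.cds_id = cds.id
        ann.protein_length = len(cds)
        if cds.conf is not None:
            ann.query_conf = protein_confidence(cds.conf)
        if ann.functional_hit:
            conf = ann.query_conf if mode == "prostt5" else None
            if mode == "prostt5" and conf is None:
                # queries without a confidence track are graded on the
                # structure-independent clauses only
                ann.tier = classify_tier(ann.best_hit, None, "structures", params.evalue_max)
            else:
                ann.tier = classify_tier(ann.best_hit, conf, mode, params.evalue_max)
        annotations.append(ann)
    n = len(annotations)
    cat_counts = Counter(
        a.label.category for a in annotations if a.label is not None
    )
    summary = {
        "n_cds": n,
        "category_counts": dict(sorted(cat_counts.items())),
        "functional_rate": sum(a.functional_hit for a in annotations) / n if n else 0.0,
        "any_hit_rate": sum(a.any_hit_count > 0 for a in annotations) / n if n else 0.0,
    }
    return annotations, summary
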