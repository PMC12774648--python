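"""Database-construction rule engine.

Codifies the reproducible core of how the annotation database is built
and curated: fragmentation of over-long proteins ahead of structure
prediction, best-structure selection by pLDDT, acceptance of structural
hits on coverage/TM-score/E-value thresholds, reconciliation of
structural and HMM evidence, and the conservative heuristics that
propagate annotations into unknown-function protein families.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import AnnotationLabel, StructannotError, StructureModel

__all__ = [
    "CurationHit",
    "PropagationVerdict",
    "fragment_protein",
    "select_best_model",
    "accept_structural_hit",
    "hmm_hit_passes",
    "resolve_dual_evidence",
    "propagate_unknown_phrog",
    "AGREEMENT_CLASSES",
]

#: Taxonomy of dual-evidence outcomes when a protein family has both a
#: structural (foldseek) and an HMM hit.
AGREEMENT_CLASSES = (
    "identical_phrog",
    "same_annotation",
    "same_category",
    "one_unknown",
    "conflicting_categories",
)

#: Predictor priority for pLDDT ties (the first listed wins).
PREDICTOR_PRIORITY = ("colabfold", "colabfold_enriched", "esmfold")

#: Tokens marking an annotation as too vague to propagate.
VAGUE_TOKENS = ("duf", "uncharacterized", "hypothetical", "putative")


@dataclass
class CurationHit:
    """One hit used during database curation (structural or HMM)."""

    query_id: str
    target_id: str
    evalue: float
    qcov: float
    tcov: float
    alnlen: int
    source: str  # "foldseek" | "hmm"
    target_label: AnnotationLabel
    tmscore: Optional[float] = None
    lddt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in ("foldseek", "hmm"):
            raise StructannotError(f"unknown hit source {self.source!r}")
        if self.source == "hmm" and self.tmscore is not None:
            raise StructannotError("HMM hits carry no TM-score")
        for name in ("tmscore", "lddt"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise StructannotError(f"{name} {v} outside [0,1]")


@dataclass
class PropagationVerdict:
    """Outcome of the annotation-propagation heuristics for one family."""

    phrog_id: str
    decision: str  # "propagate" | "reject"
    proposed_label: Optional[str] = None
    support_fraction: float = 0.0
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.decision == "propagate" and self.proposed_label is None:
            raise StructannotError("propagate verdict requires a proposed label")


def fragment_protein(seq: str, limit: int = 3000) -> list[str]:
    """Split a protein longer than ``limit`` residues into the minimal
    number of equal-size contiguous parts, each below ``limit``.

    A 5000-residue protein yields two 2500-residue parts; an 8100-residue
    protein yields three 2700-residue parts. When the length is not
    divisible, part sizes differ by at most one residue. Proteins at or
    under the limit are returned unsplit.
    """
    if limit < 1:
        raise StructannotError("fragmentation limit must be >= 1")
    if not seq:
        raise StructannotError("cannot fragment an empty sequence")
    n_res = len(seq)
    if n_res <= limit:
        return [seq]
    n_parts = -(-n_res // limit)  # ceil
    base, rem = divmod(n_res, n_parts)
    parts = []
    pos = 0
    for i in range(n_parts):
        size = base + (1 if i < rem else 0)
        parts.append(seq[pos : pos + size])
        pos += size
    return parts


def select_best_model(models: Sequence[StructureModel]) -> StructureModel:
    """Pick the structure prediction with the highest mean pLDDT; exact
    ties break by predictor priority (colabfold first)."""
    if not models:
        raise StructannotError("no structure models supplied")
    ids = {m.protein_id for m in models}
    if len(ids) > 1:
        raise StructannotError(f"mixed protein ids in model selection: {sorted(ids)}")

    def rank(m: StructureModel) -> tuple:
        try:
            prio = PREDICTOR_PRIORITY.index(m.predictor)
        except ValueError:
            prio = len(PREDICTOR_PRIORITY)
        return (-m.plddt_mean, prio)

    return min(models, key=rank)


def accept_structural_hit(hit: CurationHit) -> bool:
    """Acceptance rule for a structural hit during database assignment:
    bidirectional coverage >= 0.7, TM-score >= 0.6, and for alignments
    under 75 residues additionally E-value <= 0.01."""
    if hit.source != "foldseek":
        raise StructannotError("acceptance rule applies to structural hits only")
    if hit.tmscore is None:
        raise StructannotError(f"hit {hit.query_id}->{hit.target_id} lacks a TM-score")
    return (
        hit.qcov >= 0.7
        and hit.tcov >= 0.7
        and hit.tmscore >= 0.6
        and (hit.alnlen >= 75 or hit.evalue <= 0.01)
    )


def hmm_hit_passes(hit: CurationHit) -> bool:
    """Pre-filter for HMM evidence: E <= 0.001 and >= 70% coverage of both
    the query and target consensus sequences."""
    if hit.source != "hmm":
        raise StructannotError("hmm filter applies to HMM hits only")
    return hit.evalue <= 1e-3 and hit.qcov >= 0.7 and hit.tcov >= 0.7


def _agreement_class(fs: CurationHit, hmm: CurationHit) -> str:
    a, b = fs.target_label, hmm.target_label
    if a.group_id == b.group_id:
        return "identical_phrog"
    if _normalize_annotation(a.product) == _normalize_annotation(b.product):
        return "same_annotation"
    a_known = a.category != "unknown function"
    b_known = b.category != "unknown function"
    if a_known and b_known:
        return "same_category" if a.category == b.category else "conflicting_categories"
    if a_known != b_known:
        return "one_unknown"
    # both unknown-function families with different products
    return "same_category"


def resolve_dual_evidence(
    fs: Optional[CurationHit], hmm: Optional[CurationHit]
) -> tuple[CurationHit, str]:
    """Reconcile structural and HMM evidence for one protein family.

    A single source wins outright (class ``foldseek_only``/``hmm_only``).
    With both present the lower-E-value hit is assigned, except when one
    hit points at an unknown-function family — then the known-function
    hit is taken regardless of E-value.
    """
    if fs is None and hmm is None:
        raise StructannotError("no evidence supplied")
    if hmm is None:
        return fs, "foldseek_only"
    if fs is None:
        return hmm, "hmm_only"
    cls = _agreement_class(fs, hmm)
    if cls == "one_unknown":
        winner = fs if fs.target_label.category != "unknown function" else hmm
    else:
        winner = fs if fs.evalue <= hmm.evalue else hmm
    return winner, cls


_PUNCT_RE = re.compile(r"[^\w\s]")


def _normalize_annotation(text: str) -> str:
    return " ".join(_PUNCT_RE.sub(" ", text.lower()).split())


def is_vague_annotation(text: str) -> bool:
    low = text.lower()
    return any(tok in low for tok in VAGUE_TOKENS)


def required_support(member_count: int) -> float:
    """Minimal supporter fraction: 100% for 1-2 members, 2/3 for exactly
    three, 10% for four or more."""
    if member_count <= 2:
        return 1.0
    if member_count == 3:
        return 2.0 / 3.0
    return 0.10


def propagate_unknown_phrog(
    phrog_id: str,
    member_hits: Sequence[Optional[str]],
    member_count: Optional[int] = None,
    synonyms: Optional[dict[str, str]] = None,
    divergence_margin: float = 0.5,
) -> PropagationVerdict:
    """Decide whether an unknown-function family inherits an annotation.

    ``member_hits`` holds the best external annotation string per member
    (``None`` for members without hits). The modal non-vague annotation
    (after lowercasing, punctuation stripping and optional synonym
    mapping) is proposed; it propagates iff its supporter fraction meets
    :func:`required_support` and no second non-vague annotation reaches
    ``divergence_margin`` times the leader's support.
    """
    if member_count is None:
        member_count = len(member_hits)
    if member_count < 1:
        raise StructannotError("member_count must be >= 1")
    synonyms = synonyms or {}
    counts: Counter[str] = Counter()
    canonical: dict[str, str] = {}
    n_vague = 0
    for ann in member_hits:
        if ann is None:
            continue
        if is_vague_annotation(ann):
            n_vague += 1
            continue
        norm = _normalize_annotation(ann)
        norm = synonyms.get(norm, norm)
        counts[norm] += 1
        # deterministic representative independent of input order
        if norm not in canonical or ann < canonical[norm]:
            canonical[norm] = ann
    if not counts:
        reason = "only_vague_annotations" if n_vague else "no_informative_hits"
        return PropagationVerdict(phrog_id, "reject", None, 0.0, [reason])
    # sort by count then name so verdicts ignore input order
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    leader, lead_n = ranked[0]
    support = lead_n / member_count
    reasons = []
    if len(ranked) > 1 and ranked[1][1] >= divergence_margin * lead_n:
        return PropagationVerdict(
            phrog_id, "reject", None, support, ["divergent_annotations"]
        )
    need = required_support(member_count)
    if support < need:
        return PropagationVerdict(
            phrog_id,
            "reject",
            None,
            support,
            [f"support_below_threshold({support:.2f}<{need:.2f})"],
        )
    reasons.append(f"support_ok({support:.2f}>={need:.2f})")
    return PropagationVerdict(phrog_id, "propagate", canonical[leader], support, reasons)
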