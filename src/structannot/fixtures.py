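"""Seeded synthetic-data generation.

Everything downstream is testable without network downloads: labelled
dual-sequence databases across the ten PHROG categories, queries derived
from database members at controlled AA/3Di divergence with indels,
per-residue confidence tracks correlated with 3Di corruption, decoy
queries with no true homolog, toy genomes, and curation-stage hit
scenarios. Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .curate import CurationHit
from .io import LabelTable
from .model import (
    PHROG_CATEGORIES,
    AnnotationLabel,
    Cds,
    DualSequence,
    StructannotError,
)

__all__ = [
    "FixtureSpec",
    "GenomeFixture",
    "generate_database",
    "mutate_homolog",
    "generate_decoy",
    "generate_genome",
    "generate_curation_hits",
]

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
TDI20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Default category mix, loosely shaped like a curated phage database:
#: structural categories and nucleotide metabolism dominate the known
#: classes, with a substantial unknown-function fraction.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "head and packaging": 0.12,
    "connector": 0.04,
    "tail": 0.14,
    "lysis": 0.07,
    "integration and excision": 0.06,
    "DNA, RNA and nucleotide metabolism": 0.14,
    "transcription regulation": 0.05,
    "moron, auxiliary metabolic gene and host takeover": 0.06,
    "other": 0.07,
    "unknown function": 0.25,
}

#: Small product vocabularies per category; products are unique to their
#: category so the label hierarchy is functional (product -> category).
PRODUCT_POOLS: dict[str, list[str]] = {
    "head and packaging": ["terminase large subunit", "major capsid protein", "portal protein"],
    "connector": ["head-tail adaptor", "head closure protein"],
    "tail": ["tail fiber protein", "major tail protein", "baseplate wedge"],
    "lysis": ["endolysin", "holin"],
    "integration and excision": ["integrase", "excisionase"],
    "DNA, RNA and nucleotide metabolism": ["DNA polymerase", "ribonucleotide reductase", "DNA helicase"],
    "transcription regulation": ["transcriptional repressor", "anti-sigma factor"],
    "moron, auxiliary metabolic gene and host takeover": ["anti-CRISPR protein", "superinfection exclusion protein"],
    "other": ["membrane protein", "chaperone"],
    "unknown function": ["hypothetical protein"],
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    db_size: int = 500
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    aa_divergence: float = 0.2
    tdi_divergence: float = 0.2
    indel_rate: float = 0.01
    conf_base: float = 0.85
    conf_noise_sd: float = 8.0
    decoy_fraction: float = 0.2
    length_mean: float = 220.0
    length_min: int = 60

    def __post_init__(self) -> None:
        probs = np.array([self.category_mix.get(c, 0.0) for c in PHROG_CATEGORIES])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise StructannotError("category_mix probabilities must sum to 1")
        for name in ("aa_divergence", "tdi_divergence", "indel_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise StructannotError(f"{name} {v} outside [0,1]")

    @classmethod
    def remote_homology(cls, seed: int = 0, **kw) -> "FixtureSpec":
        """3Di-conserved / AA-diverged regime emulating remote homologs:
        structural tokens drift far slower than the sequence."""
        kw.setdefault("aa_divergence", 0.2)
        kw.setdefault("tdi_divergence", 0.05)
        return cls(seed=seed, **kw)


def _draw_length(rng: np.random.Generator, spec: FixtureSpec) -> int:
    length = int(rng.gamma(shape=4.0, scale=spec.length_mean / 4.0))
    return max(spec.length_min, length)


def _random_seq(rng: np.random.Generator, length: int) -> tuple[str, str]:
    aa = "".join(rng.choice(AA20, size=length))
    tdi = "".join(rng.choice(TDI20, size=length))
    return aa, tdi


def generate_database(spec: FixtureSpec) -> tuple[list[DualSequence], LabelTable]:
    """Generate ``db_size`` labelled records with i.i.d. composition.

    Each record belongs to its own group; the group's product is drawn
    from its category's pool, so group determines product determines
    category. Deterministic per seed.
    """
    if spec.db_size < 1:
        raise StructannotError("db_size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.category_mix.get(c, 0.0) for c in PHROG_CATEGORIES])
    by_record: dict[str, AnnotationLabel] = {}
    by_group: dict[str, AnnotationLabel] = {}
    records = []
    for i in range(spec.db_size):
        length = _draw_length(rng, spec)
        aa, tdi = _random_seq(rng, length)
        rid = f"db_{i:05d}"
        cat = PHROG_CATEGORIES[rng.choice(len(PHROG_CATEGORIES), p=probs)]
        pool = PRODUCT_POOLS[cat]
        product = pool[int(rng.integers(len(pool)))]
        label = AnnotationLabel(group_id=f"phrog_{i + 1}", product=product, category=cat)
        records.append(DualSequence(id=rid, aa=aa, tdi=tdi))
        by_record[rid] = label
        by_group[label.group_id] = label
    return records, LabelTable(by_record=by_record, by_group=by_group)


def _confidence_track(
    rng: np.random.Generator, corrupted: np.ndarray, spec: FixtureSpec
) -> np.ndarray:
    """conf = clamp(100 * base * (1 - u) + noise, 0, 100) where u marks
    residues whose 3Di token was corrupted."""
    base = 100.0 * spec.conf_base * (1.0 - corrupted.astype(float))
    noise = rng.normal(0.0, spec.conf_noise_sd, size=len(corrupted))
    return np.clip(base + np.abs(noise) * (base == 0) + noise * (base > 0), 0.0, 100.0)


def mutate_homolog(
    parent: DualSequence,
    spec: FixtureSpec,
    seed: int,
    child_id: Optional[str] = None,
) -> DualSequence:
    """Derive a homolog: AA and 3Di tokens substituted independently at
    the spec's rates, geometric-length indels at ``indel_rate``, and a
    confidence track that is systematically lower at corrupted 3Di
    positions."""
    rng = np.random.default_rng(seed)
    aa = list(parent.aa)
    tdi = list(parent.tdi_unmasked())
    n = len(aa)
    aa_sub = rng.random(n) < spec.aa_divergence
    td_sub = rng.random(n) < spec.tdi_divergence
    for i in np.flatnonzero(aa_sub):
        choices = AA20[AA20 != aa[i]]
        aa[i] = str(rng.choice(choices))
    for i in np.flatnonzero(td_sub):
        choices = TDI20[TDI20 != tdi[i]]
        tdi[i] = str(rng.choice(choices))
    corrupted = td_sub.astype(bool).tolist()

    out_aa: list[str] = []
    out_tdi: list[str] = []
    out_u: list[bool] = []
    i = 0
    while i < n:
        r = rng.random()
        if r < spec.indel_rate / 2:  # deletion run
            i += int(rng.geometric(0.5))
            continue
        if r < spec.indel_rate:  # insertion run
            run = int(rng.geometric(0.5))
            ins_aa, ins_td = _random_seq(rng, run)
            out_aa.extend(ins_aa)
            out_tdi.extend(ins_td)
            out_u.extend([True] * run)
        out_aa.append(aa[i])
        out_tdi.append(tdi[i])
        out_u.append(corrupted[i])
        i += 1
    if not out_aa:  # pathological all-deleted case
        out_aa, out_tdi, out_u = [aa[0]], [tdi[0]], [corrupted[0]]
    conf = _confidence_track(rng, np.array(out_u), spec)
    return DualSequence(
        id=child_id or f"{parent.id}_homolog",
        aa="".join(out_aa),
        tdi="".join(out_tdi),
        conf=conf,
    )


def generate_decoy(spec: FixtureSpec, seed: int, decoy_id: str) -> DualSequence:
    """A random query with no true homolog in the database; full-looking
    confidence track (no corruption signal)."""
    rng = np.random.default_rng(seed)
    length = _draw_length(rng, spec)
    aa, tdi = _random_seq(rng, length)
    conf = _confidence_track(rng, np.zeros(length, dtype=bool), spec)
    return DualSequence(id=decoy_id, aa=aa, tdi=tdi, conf=conf)


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for codon, aa_ in sorted(_STANDARD.forward_table.items()):
    _CODONS.setdefault(aa_, []).append(codon)


def _back_translate(rng: np.random.Generator, aa: str) -> str:
    codons = [
        _CODONS[a][int(rng.integers(len(_CODONS[a])))] if a in _CODONS else "NNN"
        for a in aa
    ]
    return "".join(codons) + "TAA"


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


@dataclass
class GenomeFixture:
    """A toy genome with per-CDS ground truth."""

    genome_id: str
    sequence: str
    cds: list[Cds]
    truth: dict[str, AnnotationLabel]
    parents: dict[str, Optional[str]]

    @property
    def queries(self) -> list[DualSequence]:
        return [c.sequence for c in self.cds]

    def truth_rows(self) -> list[dict]:
        rows = []
        for c in self.cds:
            lab = self.truth[c.cds_id]
            rows.append(
                {
                    "cds_id": c.cds_id,
                    "parent": self.parents[c.cds_id] or "",
                    "group_id": lab.group_id,
                    "product": lab.product,
                    "category": lab.category,
                }
            )
        return rows


UNKNOWN_LABEL = AnnotationLabel(
    group_id="", product="hypothetical protein", category="unknown function"
)


def generate_genome(
    spec: FixtureSpec,
    db: Sequence[DualSequence],
    labels: LabelTable,
    n_cds: int,
    planted_fraction: float,
    genome_id: str = "toy_phage",
) -> GenomeFixture:
    """A toy genome whose CDS mix mutated database homologs (with truth
    labels) and decoys (truth unknown). Deterministic per spec seed."""
    if n_cds < 1:
        raise StructannotError("n_cds must be >= 1")
    if not (0.0 <= planted_fraction <= 1.0):
        raise StructannotError("planted_fraction outside [0,1]")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n_planted = round(planted_fraction * n_cds)
    parent_idx = rng.integers(0, len(db), size=n_planted)
    seqs: list[DualSequence] = []
    truth: dict[str, AnnotationLabel] = {}
    parents: dict[str, Optional[str]] = {}
    for k in range(n_cds):
        cid = f"{genome_id}_CDS_{k:04d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if k < n_planted:
            parent = db[int(parent_idx[k])]
            seq = mutate_homolog(parent, spec, seed=sub_seed, child_id=cid)
            truth[cid] = labels[parent.id]
            parents[cid] = parent.id
        else:
            seq = generate_decoy(spec, seed=sub_seed, decoy_id=cid)
            truth[cid] = UNKNOWN_LABEL
            parents[cid] = None
        seqs.append(seq)

    # lay the CDS on a nucleotide molecule with short intergenic gaps
    parts: list[str] = []
    cds_list: list[Cds] = []
    pos = 0
    for seq in seqs:
        gap = "".join(rng.choice(np.array(list("ACGT")), size=20))
        parts.append(gap)
        pos += 20
        nt = _back_translate(rng, seq.aa)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(nt if strand == "+" else _revcomp(nt))
        cds_list.append(
            Cds(
                genome_id=genome_id,
                cds_id=seq.id,
                start=pos,
                end=pos + len(nt),
                strand=strand,
                sequence=seq,
            )
        )
        pos += len(nt)
    return GenomeFixture(
        genome_id=genome_id,
        sequence="".join(parts),
        cds=cds_list,
        truth=truth,
        parents=parents,
    )


# ---------------------------------------------------------------------------
# curation-stage hit scenarios
# ---------------------------------------------------------------------------

DUAL_CLASSES = (
    "foldseek_only",
    "hmm_only",
    "identical_phrog",
    "same_annotation",
    "same_category",
    "one_unknown",
    "conflicting_categories",
)

KNOWN_CATEGORIES = tuple(c for c in PHROG_CATEGORIES if c != "unknown function")


def _make_label(rng: np.random.Generator, category: str, group: str) -> AnnotationLabel:
    pool = PRODUCT_POOLS[category]
    return AnnotationLabel(
        group_id=group,
        product=pool[int(rng.integers(len(pool)))],
        category=category,
    )


def _make_hit(
    rng: np.random.Generator,
    query_id: str,
    label: AnnotationLabel,
    source: str,
) -> CurationHit:
    return CurationHit(
        query_id=query_id,
        target_id=label.group_id,
        evalue=float(10 ** rng.uniform(-20, -2)),
        qcov=float(rng.uniform(0.7, 1.0)),
        tcov=float(rng.uniform(0.7, 1.0)),
        alnlen=int(rng.integers(75, 400)),
        source=source,
        target_label=label,
        tmscore=float(rng.uniform(0.6, 0.95)) if source == "foldseek" else None,
        lddt=float(rng.uniform(0.4, 0.9)) if source == "foldseek" else None,
    )


def generate_curation_hits(
    spec: FixtureSpec,
    n: int,
    class_probs: Optional[dict[str, float]] = None,
) -> list[dict]:
    """Dual-evidence scenarios spanning single-source cases and all five
    agreement classes; each item holds the class name and the structural
    and/or HMM hit. Class frequencies are configurable."""
    if n < 1:
        raise StructannotError("n must be >= 1")
    if class_probs is None:
        class_probs = {c: 1.0 / len(DUAL_CLASSES) for c in DUAL_CLASSES}
    names = list(class_probs)
    probs = np.array([class_probs[c] for c in names], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed + 7_000_009)
    out = []
    for k in range(n):
        cls = names[int(rng.choice(len(names), p=probs))]
        qid = f"envhog_{k:05d}"
        cat_a = KNOWN_CATEGORIES[int(rng.integers(len(KNOWN_CATEGORIES)))]
        fs = hmm = None
        if cls == "foldseek_only":
            fs = _make_hit(rng, qid, _make_label(rng, cat_a, f"phrog_f{k}"), "foldseek")
        elif cls == "hmm_only":
            hmm = _make_hit(rng, qid, _make_label(rng, cat_a, f"phrog_h{k}"), "hmm")
        elif cls == "identical_phrog":
            lab = _make_label(rng, cat_a, f"phrog_s{k}")
            fs = _make_hit(rng, qid, lab, "foldseek")
            hmm = _make_hit(rng, qid, lab, "hmm")
        elif cls == "same_annotation":
            lab_a = _make_label(rng, cat_a, f"phrog_a{k}")
            lab_b = AnnotationLabel(f"phrog_b{k}", lab_a.product, lab_a.category)
            fs = _make_hit(rng, qid, lab_a, "foldseek")
            hmm = _make_hit(rng, qid, lab_b, "hmm")
        elif cls == "same_category":
            pool = PRODUCT_POOLS[cat_a]
            while len(pool) < 2:  # need two distinct products
                cat_a = KNOWN_CATEGORIES[int(rng.integers(len(KNOWN_CATEGORIES)))]
                pool = PRODUCT_POOLS[cat_a]
            fs = _make_hit(
                rng, qid, AnnotationLabel(f"phrog_a{k}", pool[0], cat_a), "foldseek"
            )
            hmm = _make_hit(
                rng, qid, AnnotationLabel(f"phrog_b{k}", pool[1], cat_a), "hmm"
            )
        elif cls == "one_unknown":
            unk = AnnotationLabel(f"phrog_u{k}", "hypothetical protein", "unknown function")
            known = _make_label(rng, cat_a, f"phrog_k{k}")
            if rng.random() < 0.5:
                fs = _make_hit(rng, qid, unk, "foldseek")
                hmm = _make_hit(rng, qid, known, "hmm")
            else:
                fs = _make_hit(rng, qid, known, "foldseek")
                hmm = _make_hit(rng, qid, unk, "hmm")
        else:  # conflicting_categories
            cat_b = cat_a
            while cat_b == cat_a:
                cat_b = KNOWN_CATEGORIES[int(rng.integers(len(KNOWN_CATEGORIES)))]
            fs = _make_hit(rng, qid, _make_label(rng, cat_a, f"phrog_a{k}"), "foldseek")
            hmm = _make_hit(rng, qid, _make_label(rng, cat_b, f"phrog_b{k}"), "hmm")
        out.append({"case": cls, "fs": fs, "hmm": hmm})
    return out
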