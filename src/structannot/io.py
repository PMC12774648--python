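"""Readers and writers for every format the tool touches.

FASTA (AA, 3Di, and per-residue confidence as comma-separated values under
matching headers), GenBank, GFF3, NCBI-format substitution matrices, TSV
label tables and TSV hit tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import (
    PHROG_CATEGORIES,
    AnnotationLabel,
    Cds,
    DualSequence,
    StructannotError,
    SubstitutionMatrix,
)

PathLike = Union[str, Path]

HIT_TABLE_COLUMNS = [
    "query",
    "target",
    "evalue",
    "bits",
    "fident",
    "qcov",
    "tcov",
    "alnlen",
    "tmscore",
    "lddt",
]


# ---------------------------------------------------------------------------
# dual FASTA
# ---------------------------------------------------------------------------

def _read_fasta(path: PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_conf_fasta(path: PathLike) -> dict[str, np.ndarray]:
    """Read a confidence track file: FASTA-style headers, comma-separated
    per-residue values in [0, 100] on the body lines."""
    tracks: dict[str, np.ndarray] = {}
    header: Optional[str] = None
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    tracks[header] = _parse_conf_body(header, body)
                header = line[1:].split()[0]
                body = []
            else:
                body.append(line)
    if header is not None:
        tracks[header] = _parse_conf_body(header, body)
    return tracks


def _parse_conf_body(header: str, body: list[str]) -> np.ndarray:
    values = ",".join(body)
    try:
        arr = np.array([float(v) for v in values.split(",") if v != ""])
    except ValueError as exc:
        raise StructannotError(f"bad confidence value for {header}: {exc}")
    return arr


def write_conf_fasta(tracks: Mapping[str, np.ndarray], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rid, arr in tracks.items():
            fh.write(f">{rid}\n")
            fh.write(",".join(f"{v:g}" for v in np.asarray(arr)) + "\n")


def read_dual_fasta(
    aa_path: PathLike,
    tdi_path: PathLike,
    conf_path: Optional[PathLike] = None,
) -> list[DualSequence]:
    """Read paired AA and 3Di FASTA files (plus an optional confidence file)
    into :class:`DualSequence` records.

    Headers of the two (three) files must agree as ordered sets; AA
    sequences are uppercased on read.
    """
    aa_recs = _read_fasta(aa_path)
    tdi_recs = _read_fasta(tdi_path)
    aa_ids = [r[0] for r in aa_recs]
    tdi_ids = [r[0] for r in tdi_recs]
    if aa_ids != tdi_ids:
        offender = next(
            (a for a, t in zip(aa_ids, tdi_ids) if a != t),
            aa_ids[len(tdi_ids):][0] if len(aa_ids) > len(tdi_ids) else
            tdi_ids[len(aa_ids):][0] if len(tdi_ids) > len(aa_ids) else None,
        )
        raise StructannotError(f"header mismatch between AA and 3Di FASTA: {offender}")
    conf = read_conf_fasta(conf_path) if conf_path is not None else {}
    if conf and set(conf) != set(aa_ids):
        offender = next(iter(set(conf) ^ set(aa_ids)))
        raise StructannotError(f"header mismatch in confidence file: {offender}")
    out = []
    for (rid, aa), (_, tdi) in zip(aa_recs, tdi_recs):
        out.append(DualSequence(id=rid, aa=aa, tdi=tdi, conf=conf.get(rid)))
    return out


def write_dual_fasta(
    records: Sequence[DualSequence],
    aa_path: PathLike,
    tdi_path: PathLike,
    conf_path: Optional[PathLike] = None,
) -> None:
    with open(aa_path, "w") as fa, open(tdi_path, "w") as ft:
        for rec in records:
            fa.write(f">{rec.id}\n{rec.aa}\n")
            ft.write(f">{rec.id}\n{rec.tdi}\n")
    if conf_path is not None:
        tracks = {r.id: r.conf for r in records if r.conf is not None}
        write_conf_fasta(tracks, conf_path)


# ---------------------------------------------------------------------------
# label table
# ---------------------------------------------------------------------------

@dataclass
class LabelTable:
    """Maps record ids and group ids to :class:`AnnotationLabel`.

    Within one table every group id carries exactly one (product,
    category) pair; record ids point at their group's label.
    """

    by_record: dict[str, AnnotationLabel]
    by_group: dict[str, AnnotationLabel]

    def __getitem__(self, record_id: str) -> AnnotationLabel:
        return self.by_record[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.by_record

    def __len__(self) -> int:
        return len(self.by_record)


def _normalize_category(cat: str) -> str:
    cat = " ".join(str(cat).split())
    if cat not in PHROG_CATEGORIES:
        raise StructannotError(f"unknown PHROG category {cat!r}")
    return cat


def read_label_table(path: PathLike) -> LabelTable:
    """Read a TSV with columns ``id, group_id, product, category``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "group_id", "product", "category"}
    if not required.issubset(df.columns):
        raise StructannotError(
            f"label table missing columns: {sorted(required - set(df.columns))}"
        )
    by_group: dict[str, AnnotationLabel] = {}
    by_record: dict[str, AnnotationLabel] = {}
    for row in df.itertuples(index=False):
        label = AnnotationLabel(
            group_id=row.group_id.strip(),
            product=" ".join(row.product.split()),
            category=_normalize_category(row.category),
        )
        prev = by_group.get(label.group_id)
        if prev is not None and prev != label:
            raise StructannotError(
                f"conflicting labels for group {label.group_id}: "
                f"({prev.product!r}, {prev.category!r}) vs "
                f"({label.product!r}, {label.category!r})"
            )
        by_group[label.group_id] = label
        by_record[row.id.strip()] = label
    return LabelTable(by_record=by_record, by_group=by_group)


def write_label_table(table: LabelTable, path: PathLike) -> None:
    rows = [
        {"id": rid, "group_id": lab.group_id, "product": lab.product,
         "category": lab.category}
        for rid, lab in table.by_record.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09"}


def _gff3_escape(value: str) -> str:
    value = value.replace("%", "%25")
    for ch, rep in _GFF3_ESCAPE.items():
        value = value.replace(ch, rep)
    return value


def write_gff3(annotations: Sequence, path: Optional[PathLike] = None) -> str:
    """Emit GFF3 for a list of (:class:`Cds`, ``CdsAnnotation``) pairs or
    bare :class:`Cds` records. Internal 0-based half-open coordinates are
    converted to GFF3's 1-based inclusive convention."""
    lines = ["##gff-version 3"]
    for item in annotations:
        if isinstance(item, tuple):
            cds, ann = item
        else:
            cds, ann = item, None
        attrs = [f"ID={_gff3_escape(cds.cds_id)}"]
        if ann is not None and ann.label is not None:
            attrs.append(f"product={_gff3_escape(ann.label.product)}")
            attrs.append(f"phrog={_gff3_escape(ann.label.group_id)}")
            attrs.append(f"category={_gff3_escape(ann.label.category)}")
            attrs.append(f"confidence={ann.tier}")
            if ann.best_hit is not None:
                attrs.append(f"evalue={ann.best_hit.evalue:.3g}")
        lines.append(
            "\t".join(
                [
                    cds.genome_id,
                    "structannot",
                    "CDS",
                    str(cds.start + 1),
                    str(cds.end),
                    ".",
                    cds.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# NCBI matrix format
# ---------------------------------------------------------------------------

def read_matrix(path: PathLike) -> SubstitutionMatrix:
    """Read a whitespace-separated NCBI-format substitution matrix.

    Comment lines (``#``) are ignored; the first non-comment row is the
    header symbol row. Asymmetric entries are an error.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise StructannotError(f"empty matrix file: {path}")
    alphabet = rows[0]
    scores: dict[tuple[str, str], int] = {}
    for row in rows[1:]:
        sym, entries = row[0], row[1:]
        if len(entries) != len(alphabet):
            raise StructannotError(
                f"matrix row {sym} has {len(entries)} entries, expected {len(alphabet)}"
            )
        for other, val in zip(alphabet, entries):
            scores[(sym, other)] = int(val)
    for a in alphabet:
        for b in alphabet:
            if scores.get((a, b)) != scores.get((b, a)):
                raise StructannotError(
                    f"asymmetric matrix entry ({a},{b}): "
                    f"{scores.get((a, b))} vs {scores.get((b, a))}"
                )
    return SubstitutionMatrix(alphabet, scores)


def write_matrix(matrix: SubstitutionMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(" " + "  ".join(matrix.alphabet) + "\n")
        for a in matrix.alphabet:
            fh.write(a + "".join(f"{matrix.score(a, b):3d}" for b in matrix.alphabet) + "\n")


def load_bundled_matrix(name: str) -> SubstitutionMatrix:
    """Load a matrix bundled with the package: ``"blosum62"`` (the published
    BLOSUM62) or ``"threedi"`` (a synthetic 3Di matrix stand-in)."""
    fname = {"blosum62": "blosum62.txt", "threedi": "threedi_synthetic.mat"}[name]
    ref = importlib.resources.files("structannot.data").joinpath(fname)
    with importlib.resources.as_file(ref) as p:
        return read_matrix(p)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: PathLike) -> list[Cds]:
    """Extract CDS features (with translations) from a GenBank file."""
    out: list[Cds] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        idx = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            idx += 1
            qualifiers = feat.qualifiers
            cds_id = qualifiers.get("locus_tag", qualifiers.get("protein_id", [f"{rec.id}_CDS_{idx:04d}"]))[0]
            translation = qualifiers.get("translation", [None])[0]
            if translation is None:
                nt = feat.extract(rec.seq)
                translation = str(nt.translate(to_stop=True))
            strand = "-" if feat.location.strand == -1 else "+"
            # GenBank carries no 3Di track; placeholder tokens are replaced
            # by the caller when a 3Di source is supplied.
            seq = DualSequence(id=cds_id, aa=translation, tdi="D" * len(translation))
            out.append(
                Cds(
                    genome_id=rec.id,
                    cds_id=cds_id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=strand,
                    sequence=seq,
                )
            )
    return out


def write_genbank(
    genome_id: str,
    genome_seq: str,
    cds_list: Sequence[Cds],
    path: PathLike,
    annotations: Optional[Mapping[str, "object"]] = None,
) -> None:
    """Write a genome and its CDS features (optionally with transferred
    products) as a GenBank flat file."""
    rec = SeqRecord(Seq(genome_seq), id=genome_id, name=genome_id[:16],
                    description="", annotations={"molecule_type": "DNA"})
    for cds in cds_list:
        strand = -1 if cds.strand == "-" else 1
        quals = {
            "locus_tag": [cds.cds_id],
            "translation": [cds.sequence.aa],
            "transl_table": ["11"],
        }
        if annotations is not None and cds.cds_id in annotations:
            ann = annotations[cds.cds_id]
            if getattr(ann, "label", None) is not None:
                quals["product"] = [ann.label.product]
                quals["note"] = [
                    f"phrog={ann.label.group_id};category={ann.label.category};"
                    f"confidence={ann.tier}"
                ]
        feat = SeqFeature(
            FeatureLocation(cds.start, cds.end, strand=strand),
            type="CDS",
            qualifiers=quals,
        )
        rec.features.append(feat)
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_TABLE_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise StructannotError(f"hit table missing columns: {sorted(missing)}")
    return df


def write_hit_table(df: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in HIT_TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)
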