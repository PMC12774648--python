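"""Core domain types for structure-informed phage annotation.

The unit of work is a protein carried in two parallel alphabets: the
20-letter amino-acid alphabet and the 20-letter 3Di structural alphabet
(each 3Di token encodes the local tertiary geometry around a residue).
A per-residue confidence track in [0, 100] records how reliable each 3Di
token is; low-confidence tokens can be masked out of structural scoring.

Functional labels follow the PHROG hierarchy: a group id (the homologous
cluster), a free-text product, and one of ten broad categories (nine
functional plus ``unknown function``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PHROG_CATEGORIES",
    "HYPOTHETICAL_SYNONYMS",
    "AA_ALPHABET",
    "TDI_ALPHABET",
    "AnnotationLabel",
    "DualSequence",
    "Cds",
    "StructureModel",
    "SubstitutionMatrix",
    "StructannotError",
]

#: The ten PHROG functional categories (closed vocabulary).
PHROG_CATEGORIES: tuple[str, ...] = (
    "head and packaging",
    "connector",
    "tail",
    "lysis",
    "integration and excision",
    "DNA, RNA and nucleotide metabolism",
    "transcription regulation",
    "moron, auxiliary metabolic gene and host takeover",
    "other",
    "unknown function",
)

#: Product strings treated as carrying no functional information
#: (case-insensitive exact match).
HYPOTHETICAL_SYNONYMS: frozenset[str] = frozenset(
    {"hypothetical protein", "unknown function", ""}
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
#: 3Di structural states reuse the same 20 letters as the AA alphabet.
TDI_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class StructannotError(ValueError):
    """Structured error raised for invalid inputs across the package."""


@dataclass(frozen=True)
class AnnotationLabel:
    """Three-level PHROG-style functional label.

    Parameters
    ----------
    group_id : str
        Homologous-group identifier, e.g. ``"phrog_295"``.
    product : str
        Free-text product annotation, e.g. ``"tail fiber protein"``.
    category : str
        One of the ten :data:`PHROG_CATEGORIES`.
    """

    group_id: str
    product: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in PHROG_CATEGORIES:
            raise StructannotError(
                f"unknown PHROG category {self.category!r} for {self.group_id}"
            )

    def is_known(self) -> bool:
        """True iff the label carries real functional information."""
        return (
            self.category != "unknown function"
            and self.product.strip().lower() not in HYPOTHETICAL_SYNONYMS
        )


def _is_masked(token: str) -> bool:
    return token.islower()


@dataclass
class DualSequence:
    """A protein as parallel AA and 3Di strings plus optional confidence.

    Masked 3Di tokens are carried as lowercase letters; the AA track is
    always uppercase. ``conf`` values live in [0, 100].
    """

    id: str
    aa: str
    tdi: str
    conf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.aa = self.aa.upper()
        if len(self.aa) != len(self.tdi):
            raise StructannotError(
                f"length mismatch {self.id} {len(self.aa)}≠{len(self.tdi)}"
            )
        if self.conf is not None:
            self.conf = np.asarray(self.conf, dtype=float)
            if len(self.conf) != len(self.aa):
                raise StructannotError(
                    f"confidence track length mismatch {self.id} "
                    f"{len(self.aa)}≠{len(self.conf)}"
                )
            if np.any(self.conf < 0) or np.any(self.conf > 100):
                raise StructannotError(
                    f"confidence values outside [0,100] for {self.id}"
                )

    def __len__(self) -> int:
        return len(self.aa)

    @property
    def masked(self) -> np.ndarray:
        """Boolean array: True where the 3Di token is masked."""
        return np.fromiter(
            (_is_masked(t) for t in self.tdi), dtype=bool, count=len(self.tdi)
        )

    def tdi_unmasked(self) -> str:
        """3Di track with masking undone (all tokens uppercased)."""
        return self.tdi.upper()


@dataclass
class Cds:
    """A coding sequence on a genome. Internal coordinates are 0-based
    half-open; GenBank/GFF3 emission converts to 1-based inclusive."""

    genome_id: str
    cds_id: str
    start: int
    end: int
    strand: str
    sequence: DualSequence

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StructannotError(
                f"invalid CDS interval [{self.start},{self.end}) for {self.cds_id}"
            )
        if self.strand not in ("+", "-"):
            raise StructannotError(f"invalid strand {self.strand!r} for {self.cds_id}")


@dataclass(frozen=True)
class StructureModel:
    """One predicted structure for a protein, summarized by mean pLDDT."""

    protein_id: str
    predictor: str
    plddt_mean: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.plddt_mean <= 100.0):
            raise StructannotError(
                f"pLDDT {self.plddt_mean} outside [0,100] for {self.protein_id}"
            )


class SubstitutionMatrix:
    """Symmetric integer substitution matrix over an ordered alphabet."""

    def __init__(self, alphabet: Sequence[str], scores: Mapping[tuple[str, str], int]):
        self.alphabet = list(alphabet)
        self.index = {a: i for i, a in enumerate(self.alphabet)}
        n = len(self.alphabet)
        self._arr = np.zeros((n, n), dtype=np.int32)
        for (a, b), s in scores.items():
            self._arr[self.index[a], self.index[b]] = s
        for a in self.alphabet:
            for b in self.alphabet:
                ia, ib = self.index[a], self.index[b]
                if self._arr[ia, ib] != self._arr[ib, ia]:
                    raise StructannotError(
                        f"asymmetric matrix entry ({a},{b}): "
                        f"{self._arr[ia, ib]} vs {self._arr[ib, ia]}"
                    )

    @property
    def array(self) -> np.ndarray:
        return self._arr

    def score(self, a: str, b: str) -> int:
        try:
            return int(self._arr[self.index[a], self.index[b]])
        except KeyError as exc:
            sym = a if a not in self.index else b
            raise StructannotError(f"symbol {sym!r} not in matrix alphabet") from exc

    def encode(self, seq: Iterable[str]) -> np.ndarray:
        """Map symbols to matrix row indices (raises on unknown symbols)."""
        try:
            return np.fromiter((self.index[s] for s in seq), dtype=np.int64)
        except KeyError as exc:
            raise StructannotError(f"symbol {exc.args[0]!r} not in matrix alphabet")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SubstitutionMatrix)
            and self.alphabet == other.alphabet
            and np.array_equal(self._arr, other._arr)
        )
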