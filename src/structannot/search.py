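"""Dual-alphabet local alignment search with k-mer prefiltering and
Karlin–Altschul-style E-value calibration.

Each query/target pair is aligned with an affine-gap Smith–Waterman
(Gotoh) maximizing a column score that sums a weighted amino-acid
substitution term and a weighted 3Di structural term; masked 3Di tokens
contribute nothing to the structural term. Statistical significance is
obtained by fitting a Gumbel (extreme-value) distribution to optimal
local-alignment scores of random decoy pairs drawn from database residue
frequencies, giving (lambda, K) for BLAST-like E-values
``E = K * m * N * exp(-lambda * S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

from .io import load_bundled_matrix
from .model import DualSequence, StructannotError, SubstitutionMatrix
from .threedi import DEFAULT_MASK_THRESHOLD, mask_3di

__all__ = [
    "SearchParams",
    "Alignment",
    "Calibration",
    "combined_score",
    "align_pair",
    "calibrate",
    "evalue",
    "bit_score",
    "prefilter",
    "search",
]


@dataclass
class SearchParams:
    """Tunable parameters of the dual-alphabet search."""

    evalue_max: float = 1e-3
    max_seqs: int = 1000
    mask_threshold: float = DEFAULT_MASK_THRESHOLD
    weight_aa: float = 1.0
    weight_3di: float = 1.0
    gap_open: int = 10
    gap_extend: int = 1
    aa_matrix: SubstitutionMatrix = field(default=None)  # type: ignore[assignment]
    tdi_matrix: SubstitutionMatrix = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise StructannotError("evalue_max must be positive")
        if self.max_seqs < 1:
            raise StructannotError("max_seqs must be >= 1")
        if self.weight_aa < 0 or self.weight_3di < 0:
            raise StructannotError("score weights must be non-negative")
        if self.weight_aa == 0 and self.weight_3di == 0:
            raise StructannotError("at least one score weight must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise StructannotError("gap penalties must be positive integers")
        if self.aa_matrix is None:
            self.aa_matrix = load_bundled_matrix("blosum62")
        if self.tdi_matrix is None:
            self.tdi_matrix = load_bundled_matrix("threedi")


@dataclass
class Alignment:
    """One query–target local alignment."""

    query_id: str
    target_id: str
    score: float
    bits: float
    evalue: float
    fident: float
    qcov: float
    tcov: float
    alnlen: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    tmscore: Optional[float] = None
    lddt: Optional[float] = None

    def sort_key(self) -> tuple:
        """Deterministic ranking key: ascending E-value, then higher bits,
        then higher coverage product, then target id."""
        return (self.evalue, -self.bits, -(self.qcov * self.tcov), self.target_id)


@dataclass
class Calibration:
    """Fitted Gumbel parameters for E-value computation."""

    lam: float
    K: float
    db_residues: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise StructannotError("calibration requires positive lambda and K")
        if self.db_residues < 1:
            raise StructannotError("db_residues must be >= 1")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def combined_score(qa: str, qt: str, ta: str, tt: str, params: SearchParams) -> float:
    """Score of a single aligned column: ``w_aa*S_aa + w_3di*S_3di``, with
    the 3Di term zero when either 3Di token is masked (lowercase)."""
    s = params.weight_aa * params.aa_matrix.score(qa.upper(), ta.upper())
    if not (qt.islower() or tt.islower()):
        s += params.weight_3di * params.tdi_matrix.score(qt, tt)
    else:
        # still validate masked symbols against the alphabet
        params.tdi_matrix.score(qt.upper(), tt.upper())
    return s


def _score_grid(query: DualSequence, target: DualSequence, params: SearchParams) -> np.ndarray:
    """Dense per-column combined-score matrix (len(query) x len(target))."""
    aa = params.aa_matrix
    td = params.tdi_matrix
    qa = aa.encode(query.aa)
    ta = aa.encode(target.aa)
    qt = td.encode(query.tdi_unmasked())
    tt = td.encode(target.tdi_unmasked())
    grid = params.weight_aa * aa.array[np.ix_(qa, ta)].astype(np.float64)
    if params.weight_3di > 0:
        tdi_part = td.array[np.ix_(qt, tt)].astype(np.float64)
        unmasked = np.outer(~query.masked, ~target.masked)
        grid += params.weight_3di * tdi_part * unmasked
    return grid


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    NEG = -1e30
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            v = prev + S[i - 1, j - 1]
            if v < 0.0:
                v = 0.0
            M[i, j] = v
            a = M[i - 1, j] - go
            b = Ix[i - 1, j] - gap_extend
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] - go
            b = Iy[i, j - 1] - gap_extend
            Iy[i, j] = a if a > b else b
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return M, Ix, Iy, best, bi, bj


_EPS = 1e-6


def _traceback(S, M, Ix, Iy, gap_open, gap_extend, bi, bj):
    """Recover aligned columns ending at M[bi, bj]. Returns a list of
    (qpos, tpos) with None marking a gap, oldest column first."""
    cols: list[tuple[Optional[int], Optional[int]]] = []
    go = gap_open + gap_extend
    state = "M"
    i, j = bi, bj
    while True:
        if state == "M":
            cols.append((i - 1, j - 1))
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if prev <= _EPS:
                break
            if abs(M[i - 1, j - 1] - prev) < _EPS:
                state = "M"
            elif abs(Ix[i - 1, j - 1] - prev) < _EPS:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            cols.append((i - 1, None))
            if abs(Ix[i, j] - (M[i - 1, j] - go)) < _EPS:
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy
            cols.append((None, j - 1))
            if abs(Iy[i, j] - (M[i, j - 1] - go)) < _EPS:
                state = "M"
            else:
                state = "Iy"
            j -= 1
    cols.reverse()
    return cols


def align_pair(
    query: DualSequence,
    target: DualSequence,
    params: SearchParams,
    calib: Optional[Calibration] = None,
) -> Optional[Alignment]:
    """Optimal local alignment of a query/target pair under affine gaps
    (a gap of length L costs ``gap_open + L*gap_extend``).

    Returns ``None`` when no positive-scoring local alignment exists.
    E-value and bit score are filled from ``calib`` when provided
    (otherwise ``evalue`` is NaN and ``bits`` 0).
    """
    if len(query) == 0 or len(target) == 0:
        raise StructannotError("cannot align empty sequences")
    S = _score_grid(query, target, params)
    M, Ix, Iy, best, bi, bj = _gotoh_fill(S, float(params.gap_open), float(params.gap_extend))
    if best <= 0.0:
        return None
    cols = _traceback(S, M, Ix, Iy, params.gap_open, params.gap_extend, bi, bj)
    qpos = [c[0] for c in cols if c[0] is not None]
    tpos = [c[1] for c in cols if c[1] is not None]
    match_cols = [(q, t) for q, t in cols if q is not None and t is not None]
    ident = sum(1 for q, t in match_cols if query.aa[q] == target.aa[t])
    fident = ident / len(match_cols) if match_cols else 0.0
    qstart, qend = qpos[0], qpos[-1] + 1
    tstart, tend = tpos[0], tpos[-1] + 1
    if calib is not None:
        e = evalue(best, len(query), calib)
        b = bit_score(best, calib)
    else:
        e, b = float("nan"), 0.0
    return Alignment(
        query_id=query.id,
        target_id=target.id,
        score=float(best),
        bits=b,
        evalue=e,
        fident=fident,
        qcov=(qend - qstart) / len(query),
        tcov=(tend - tstart) / len(target),
        alnlen=len(cols),
        qstart=qstart,
        qend=qend,
        tstart=tstart,
        tend=tend,
    )


# ---------------------------------------------------------------------------
# calibration and E-values
# ---------------------------------------------------------------------------

def _random_dual(rng, length, aa_alphabet, tdi_alphabet, aa_freqs, tdi_freqs, rid):
    aa = "".join(rng.choice(aa_alphabet, size=length, p=aa_freqs))
    td = "".join(rng.choice(tdi_alphabet, size=length, p=tdi_freqs))
    return DualSequence(id=rid, aa=aa, tdi=td)


def residue_frequencies(db: Sequence[DualSequence], matrix: SubstitutionMatrix, track: str) -> np.ndarray:
    """Empirical symbol frequencies of a database over a matrix alphabet."""
    counts = np.zeros(len(matrix.alphabet))
    for rec in db:
        seq = rec.aa if track == "aa" else rec.tdi_unmasked()
        for idx in matrix.encode(seq):
            counts[idx] += 1
    if counts.sum() == 0:
        raise StructannotError("empty database")
    return counts / counts.sum()


def calibrate(
    params: SearchParams,
    decoy_count: int = 500,
    decoy_len: int = 150,
    seed: int = 0,
    db: Optional[Sequence[DualSequence]] = None,
) -> Calibration:
    """Fit (lambda, K) by maximum-likelihood Gumbel fit to optimal
    local-alignment scores of seeded random query/target pairs.

    Decoy residues are drawn from the database composition when ``db`` is
    given, otherwise from uniform composition over the 20 standard symbols
    of each alphabet. ``db_residues`` (the E-value search space) is the
    total AA residue count of ``db`` when given, else
    ``decoy_count * decoy_len``.
    """
    if decoy_count < 100:
        raise StructannotError("calibration needs at least 100 decoy pairs")
    rng = np.random.default_rng(seed)
    aa_sym = [a for a in params.aa_matrix.alphabet if a.isalpha() and a not in "XBZJUO"]
    td_sym = [a for a in params.tdi_matrix.alphabet if a.isalpha()]
    if db is not None:
        aa_f = residue_frequencies(db, params.aa_matrix, "aa")
        td_f = residue_frequencies(db, params.tdi_matrix, "tdi")
        aa_freqs = np.array([aa_f[params.aa_matrix.index[a]] for a in aa_sym])
        td_freqs = np.array([td_f[params.tdi_matrix.index[a]] for a in td_sym])
        aa_freqs = aa_freqs / aa_freqs.sum()
        td_freqs = td_freqs / td_freqs.sum()
        db_residues = sum(len(r) for r in db)
    else:
        aa_freqs = np.full(len(aa_sym), 1.0 / len(aa_sym))
        td_freqs = np.full(len(td_sym), 1.0 / len(td_sym))
        db_residues = decoy_count * decoy_len
    aa_sym = np.array(aa_sym)
    td_sym = np.array(td_sym)
    scores = np.empty(decoy_count)
    for k in range(decoy_count):
        q = _random_dual(rng, decoy_len, aa_sym, td_sym, aa_freqs, td_freqs, f"dq{k}")
        t = _random_dual(rng, decoy_len, aa_sym, td_sym, aa_freqs, td_freqs, f"dt{k}")
        aln = align_pair(q, t, params)
        scores[k] = 0.0 if aln is None else aln.score
    if np.ptp(scores) == 0:
        raise StructannotError("degenerate decoy score distribution (all equal)")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (decoy_len * decoy_len)
    return Calibration(lam=lam, K=K, db_residues=db_residues)


def evalue(score: float, query_len: int, calib: Calibration) -> float:
    """Expected chance hits at or above ``score``:
    ``K * query_len * db_residues * exp(-lambda*score)``."""
    return calib.K * query_len * calib.db_residues * math.exp(-calib.lam * score)


def bit_score(score: float, calib: Calibration) -> float:
    """Normalized score ``(lambda*S - ln K) / ln 2``."""
    return (calib.lam * score - math.log(calib.K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# prefilter and search
# ---------------------------------------------------------------------------

AA_KMER = 5
TDI_KMER = 6


def _kmers(seq: str, k: int, skip_masked: bool = False) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if skip_masked and not kmer.isupper():
            continue
        out.add(kmer)
    return out


def prefilter(
    query: DualSequence, db: Sequence[DualSequence], max_seqs: int
) -> list[DualSequence]:
    """Retain up to ``max_seqs`` candidates by shared k-mer count (k=5 over
    AA plus k=6 over 3Di, union of both alphabets). Candidates sharing no
    k-mer with the query are dropped; ties break by target id."""
    q_aa = _kmers(query.aa, AA_KMER)
    q_td = _kmers(query.tdi, TDI_KMER, skip_masked=True)
    scored = []
    for rec in db:
        count = len(q_aa & _kmers(rec.aa, AA_KMER)) + len(
            q_td & _kmers(rec.tdi, TDI_KMER, skip_masked=True)
        )
        if count > 0:
            scored.append((-count, rec.id, rec))
    scored.sort(key=lambda x: (x[0], x[1]))
    return [rec for _, _, rec in scored[:max_seqs]]


def search(
    queries: Sequence[DualSequence],
    db: Sequence[DualSequence],
    params: SearchParams,
    calib: Optional[Calibration] = None,
    exhaustive: bool = False,
    seed: int = 0,
) -> dict[str, list[Alignment]]:
    """Search queries against the database.

    Per query: the k-mer prefilter retains up to ``params.max_seqs``
    candidates (all targets when ``exhaustive``), survivors are fully
    aligned, and hits with ``evalue <= params.evalue_max`` are returned
    sorted ascending by E-value with deterministic tie-breaks.
    """
    if not db:
        raise StructannotError("empty database")
    if calib is None:
        calib = calibrate(params, seed=seed, db=db)
    results: dict[str, list[Alignment]] = {}
    for query in queries:
        if query.conf is not None and params.mask_threshold > 0:
            query = mask_3di(query, params.mask_threshold)
        candidates = list(db) if exhaustive else prefilter(query, db, params.max_seqs)
        hits = []
        for target in candidates:
            aln = align_pair(query, target, params, calib=calib)
            if aln is not None and aln.evalue <= params.evalue_max:
                hits.append(aln)
        hits.sort(key=Alignment.sort_key)
        results[query.id] = hits
    return results
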