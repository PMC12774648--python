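"""Per-residue 3Di confidence, confidence-threshold masking, and empirical
3Di similarity.

The per-residue confidence of a predicted 3Di token is 100 times the
maximum softmax probability over the 3Di alphabet; the per-protein value
is the arithmetic mean across residues. Masking replaces 3Di tokens whose
confidence falls strictly below a threshold with their lowercase form, so
structural scoring can ignore them while the AA track is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .model import DualSequence, StructannotError

DEFAULT_MASK_THRESHOLD = 25.0


@dataclass
class TokenDistribution:
    """Per-residue probability vectors over the 3Di alphabet (rows sum to 1)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if np.any(self.probs < 0):
            raise StructannotError("token distribution has negative entries")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise StructannotError(
                f"token distribution row {bad} sums to {sums[bad]!r}, not 1"
            )


def residue_confidence(dist: TokenDistribution | np.ndarray) -> np.ndarray:
    """Confidence of the argmax token per residue: ``100 * max(probs)``.

    Accepts a single probability vector or a stack of them; returns one
    float per residue, each in [100/|alphabet|, 100].
    """
    if not isinstance(dist, TokenDistribution):
        dist = TokenDistribution(dist)
    return 100.0 * dist.probs.max(axis=1)


def protein_confidence(conf: np.ndarray) -> float:
    """Mean of the per-residue confidence scores across the protein."""
    conf = np.asarray(conf, dtype=float)
    if conf.size == 0:
        raise StructannotError("empty confidence track")
    return float(conf.mean())


def mask_3di(seq: DualSequence, threshold: float = DEFAULT_MASK_THRESHOLD) -> DualSequence:
    """Mask 3Di tokens at residues whose confidence is strictly below
    ``threshold``; the AA track and the confidence track are unchanged.

    Masked tokens are carried as lowercase. Idempotent: already-masked
    tokens stay masked (raising the threshold never unmasks).
    """
    if not (0.0 <= threshold <= 100.0):
        raise StructannotError(f"mask threshold {threshold} outside [0,100]")
    if seq.conf is None:
        if threshold == 0.0:
            return seq
        raise StructannotError(
            f"cannot mask {seq.id}: no confidence track with threshold {threshold}"
        )
    tokens = [
        t.lower() if c < threshold else t
        for t, c in zip(seq.tdi, seq.conf)
    ]
    return DualSequence(id=seq.id, aa=seq.aa, tdi="".join(tokens), conf=seq.conf)


def empirical_3di_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity between two 3Di strings:
    ``1 - levenshtein(a, b) / max(len(a), len(b))``, in [0, 1]."""
    if not a or not b:
        raise StructannotError("empty 3Di string in similarity computation")
    dist = edlib.align(a.upper(), b.upper(), task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))
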