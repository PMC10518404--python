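"""Candidate-pool expansion by rank-filter label voting, and Dice agreement.

An ensemble of N segmentation networks yields N single candidate
segmentations (SCS).  Pixel-wise statistical rank filters over the SCS stack
produce N combined candidate segmentations (CCS): for rank k, a pixel is
foreground iff at least k of the N masks vote for it, so rank 1 is the union
and rank N the intersection, with the outputs nested monotonically in k.
The full pool of 2N candidates is summarised by the symmetric matrix of
pairwise Dice similarity coefficients, which is the only input the
ground-truth-free quality predictor sees.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "dice", "rank_filter", "build_candidate_set", "agreement_matrix",
    "CandidateSet", "AgreementMatrix",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) between binary masks.

    Two empty masks agree perfectly (returns 1.0); one empty mask against a
    non-empty one returns 0.0.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def rank_filter(scs: Sequence[np.ndarray], rank: int) -> np.ndarray:
    """Pixel-wise vote-threshold fusion of a mask stack.

    A pixel is foreground iff at least ``rank`` of the N masks mark it
    foreground: rank 1 = union, rank N = intersection.
    """
    n = len(scs)
    if n < 1:
        raise ValueError("need at least one mask")
    if not 1 <= rank <= n:
        raise ValueError(f"rank must be in 1..{n}, got {rank}")
    stack = np.asarray([np.asarray(m, dtype=bool) for m in scs])
    if stack.ndim != 3:
        raise ValueError("masks must share a single 2-D shape")
    votes = stack.sum(axis=0)
    return (votes >= rank).astype(np.uint8)


@dataclass(frozen=True)
class CandidateSet:
    """Ordered candidate pool for one image: N SCS then N CCS (rank 1..N).

    The order is part of the contract — the quality regressors' features are
    position-bound — and is fingerprinted by ``ordering_hash``.
    """

    masks: tuple[np.ndarray, ...]
    provenance: tuple[str, ...]
    image_ref: str = ""

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.provenance):
            raise ValueError("masks and provenance length mismatch")
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError(f"candidate masks have mixed shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def ordering_hash(self) -> str:
        return hashlib.sha1("|".join(self.provenance).encode()).hexdigest()[:16]


def build_candidate_set(scs: Sequence[np.ndarray],
                        image_ref: str = "") -> CandidateSet:
    """Expand N SCS into the 2N-candidate pool (SCS in model order, then CCS
    for every rank 1..N ascending)."""
    n = len(scs)
    if n < 2:
        raise ValueError(f"need >= 2 single candidates, got {n}")
    masks = [np.asarray(m, dtype=np.uint8) for m in scs]
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"single candidates have mixed shapes: {shapes}")
    ccs = [rank_filter(masks, k) for k in range(1, n + 1)]
    prov = tuple(f"SCS:{i}" for i in range(n)) + tuple(
        f"CCS:rank{k}" for k in range(1, n + 1))
    return CandidateSet(masks=tuple(masks + ccs), provenance=prov,
                        image_ref=image_ref)


@dataclass(frozen=True)
class AgreementMatrix:
    """Symmetric pairwise-Dice matrix over a candidate pool."""

    values: np.ndarray
    ordering_hash: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"agreement matrix must be square, got {v.shape}")

    def row_features(self, i: int) -> np.ndarray:
        """Row i with its diagonal entry removed (the regressor features)."""
        return np.delete(self.values[i], i)


def agreement_matrix(cs: CandidateSet) -> AgreementMatrix:
    """Pairwise Dice over all candidates; symmetric with unit diagonal."""
    n = len(cs)
    if n < 2:
        raise ValueError("need >= 2 candidates")
    # Vectorised pairwise Dice over the flattened boolean stack.
    stack = np.asarray([m.ravel().astype(bool) for m in cs.masks])
    sizes = stack.sum(axis=1).astype(np.float64)
    inter = (stack.astype(np.float64) @ stack.T.astype(np.float64))
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, 2.0 * inter / denom, 1.0)
    np.fill_diagonal(values, 1.0)
    return AgreementMatrix(values=values, ordering_hash=cs.ordering_hash)
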