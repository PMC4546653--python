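"""Confusion-matrix-derived representational dissimilarity.

A multi-class confusion matrix has a well-defined, nonzero diagonal, unlike
pairwise-classifier or correlation RDMs.  The conversion chain is:

1. self-normalization: divide every row by its diagonal, CM'_ij = CM_ij/CM_ii,
   so each class has unit self-similarity;
2. symmetrization by the elementwise geometric mean of the matrix and its
   transpose, S_ij = sqrt(CM'_ij * CM'_ji);
3. distance: D = L(1 - S), the lower-triangle vectorization of 1 - S.

When an off-diagonal confusion exceeds its row diagonal, S_ij can exceed 1
and the raw distance goes negative; such entries are clipped to 0 and the
clip is flagged, since MDS and UPGMA downstream need nonnegative distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilaritySpace",
    "self_normalize",
    "symmetrize",
    "to_distance",
    "confusion_to_distance",
    "condensed_index",
]


@dataclass
class SimilaritySpace:
    """Symmetric unit-diagonal similarity matrix with its condensed distances.

    ``D`` is ordered over the lower triangle row-major (pairs (i, j) with
    i > j: (1,0), (2,0), (2,1), (3,0), ...).  ``clipped`` records whether any
    negative raw distance was clipped to 0.
    """

    S: np.ndarray
    D: np.ndarray
    clipped: bool

    @property
    def n_classes(self) -> int:
        return self.S.shape[0]


def condensed_index(i: int, j: int) -> int:
    """Position of pair (i, j), i > j, in the lower-triangle row-major order."""
    if i == j:
        raise ValueError("diagonal pairs have no condensed index")
    i, j = max(i, j), min(i, j)
    return i * (i - 1) // 2 + j


def self_normalize(CM: np.ndarray) -> np.ndarray:
    """Divide each row of a row-stochastic confusion matrix by its diagonal."""
    CM = np.asarray(CM, dtype=np.float64)
    diag = np.diag(CM)
    if np.any(diag <= 0):
        bad = np.flatnonzero(diag <= 0).tolist()
        raise ValueError(
            f"confusion diagonal is zero for classes {bad}; self-normalization "
            "is undefined (merge or drop these classes)"
        )
    return CM / diag[:, None]


def symmetrize(CMp: np.ndarray) -> np.ndarray:
    """Elementwise geometric mean of the normalized matrix and its transpose."""
    CMp = np.asarray(CMp, dtype=np.float64)
    if np.any(CMp < 0):
        raise ValueError("normalized confusion matrix has negative entries")
    return np.sqrt(CMp * CMp.T)


def to_distance(S: np.ndarray) -> tuple[np.ndarray, bool]:
    """Lower-triangle distance vector D = L(1 - S), clipped at 0 if needed."""
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    il, jl = np.tril_indices(n, k=-1)
    D = 1.0 - S[il, jl]
    clipped = bool(np.any(D < 0))
    if clipped:
        D = np.clip(D, 0.0, None)
    return D, clipped


def confusion_to_distance(CM: np.ndarray) -> SimilaritySpace:
    """Full chain: row-stochastic CM -> self-normalize -> symmetrize -> D."""
    S = symmetrize(self_normalize(CM))
    D, clipped = to_distance(S)
    return SimilaritySpace(S=S, D=D, clipped=clipped)
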