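"""Classical (Torgerson) MDS and UPGMA clustering of condensed distances.

Both operate on the lower-triangle condensed distance vector produced by the
similarity chain.  Classical MDS double-centers the squared distances,
B = -1/2 J D^2 J, keeps the eigenpairs with positive eigenvalue (relative
tolerance 1e-10; negative eigenvalues from non-Euclidean distances are
dropped and logged), and returns coordinates sorted by descending eigenvalue
with a deterministic sign convention.  UPGMA iteratively merges the closest
pair of clusters under size-weighted average linkage, with lexicographic
tie-breaking; merge heights are the inter-cluster distance at merge, giving
an ultrametric cophenetic matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rdm import condensed_index

__all__ = [
    "Embedding",
    "Dendrogram",
    "condensed_to_square",
    "classical_mds",
    "upgma",
    "reorder_confusion",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10  # relative eigenvalue cutoff for kept MDS dimensions


def condensed_to_square(D: np.ndarray) -> np.ndarray:
    """Expand a lower-triangle condensed vector to a symmetric square matrix."""
    D = np.asarray(D, dtype=np.float64)
    m = D.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"condensed vector of length {m} is not triangular")
    sq = np.zeros((n, n))
    il, jl = np.tril_indices(n, k=-1)
    sq[il, jl] = D
    sq[jl, il] = D
    return sq


@dataclass
class Embedding:
    """Classical-MDS coordinates, one column per kept dimension.

    Dimensions are sorted by descending eigenvalue (variance explained);
    ``eigenvalues`` holds only the kept, strictly positive values.
    """

    coordinates: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,)

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(D: np.ndarray) -> Embedding:
    """Torgerson MDS of a condensed distance vector.

    An all-zero D yields a degenerate 0-dimensional embedding rather than an
    error.  Negative eigenvalues (non-Euclidean input) are dropped with a log
    message.  Coordinate signs follow the convention that the
    largest-magnitude coordinate of each dimension is positive.
    """
    sq = condensed_to_square(np.asarray(D, dtype=np.float64))
    if np.any(sq < 0):
        raise ValueError("distances must be nonnegative")
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (sq ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.size == 0 or vals[0] <= 0:
        return Embedding(coordinates=np.zeros((n, 0)), eigenvalues=np.zeros(0))
    keep = vals > _EIG_TOL * vals[0]
    n_dropped_neg = int(np.sum(vals < 0))
    if n_dropped_neg:
        logger.info(
            "dropping %d negative eigenvalue(s): distances are non-Euclidean",
            n_dropped_neg,
        )
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(vals)
    signs = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return Embedding(coordinates=coords * signs, eigenvalues=vals)


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges`` rows are (cluster_a, cluster_b, height, new_size) in merge
    order; leaves are clusters 0..n-1 and merge i creates cluster n+i
    (the scipy linkage convention).  ``leaf_order`` is the left-to-right
    display order of the leaves.
    """

    merges: np.ndarray  # (n-1, 4)
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                row = self.merges[node - self.n_leaves]
                walk(int(row[0]))
                walk(int(row[1]))

        walk(self.n_leaves + self.merges.shape[0] - 1)
        return order

    def top_cut(self) -> tuple[frozenset[int], frozenset[int]]:
        """Leaf sets of the two subtrees below the final (highest) merge."""

        def leaves(node: int) -> frozenset[int]:
            if node < self.n_leaves:
                return frozenset([node])
            row = self.merges[node - self.n_leaves]
            return leaves(int(row[0])) | leaves(int(row[1]))

        last = self.merges[-1]
        return leaves(int(last[0])), leaves(int(last[1]))

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances (height of the lowest common merge)."""
        members: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(self.n_leaves)
        }
        coph = np.zeros(self.n_leaves * (self.n_leaves - 1) // 2)
        for m, row in enumerate(self.merges):
            a, b, h = int(row[0]), int(row[1]), row[2]
            for i in members[a]:
                for j in members[b]:
                    coph[condensed_index(i, j)] = h
            members[self.n_leaves + m] = members[a] | members[b]
        return coph

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick string; branch length = parent height - child height."""
        if labels is None:
            labels = [str(i) for i in range(self.n_leaves)]

        def height(node: int) -> float:
            if node < self.n_leaves:
                return 0.0
            return float(self.merges[node - self.n_leaves][2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < self.n_leaves:
                return f"{labels[node]}:{bl:.6g}"
            row = self.merges[node - self.n_leaves]
            left = render(int(row[0]), height(node))
            right = render(int(row[1]), height(node))
            return f"({left},{right}):{bl:.6g}"

        root = self.n_leaves + self.merges.shape[0] - 1
        row = self.merges[-1]
        h = height(root)
        left = render(int(row[0]), h)
        right = render(int(row[1]), h)
        return f"({left},{right});"


def upgma(D: np.ndarray) -> Dendrogram:
    """Size-weighted average-linkage (UPGMA) clustering of condensed distances.

    At each step the pair of clusters with the smallest average inter-member
    distance is merged; exact ties break toward the lexicographically
    smallest (cluster_a, cluster_b) id pair.  Heights are nondecreasing.
    """
    sq = condensed_to_square(np.asarray(D, dtype=np.float64))
    n = sq.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    # active clusters: id -> (size, row of current inter-cluster distances)
    dist = {i: {j: sq[i, j] for j in range(n) if j != i} for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for m in range(n - 1):
        best = None
        for a in sorted(dist):
            for b in sorted(dist[a]):
                if b <= a:
                    continue
                d = dist[a][b]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        merges[m] = (a, b, d, sizes[a] + sizes[b])
        # size-weighted average linkage update
        new_row = {}
        for c in dist:
            if c in (a, b):
                continue
            new_row[c] = (sizes[a] * dist[a][c] + sizes[b] * dist[b][c]) / (
                sizes[a] + sizes[b]
            )
        del dist[a], dist[b]
        for c in dist:
            dist[c].pop(a, None)
            dist[c].pop(b, None)
            dist[c][next_id] = new_row[c]
        dist[next_id] = new_row
        sizes[next_id] = int(merges[m, 3])
        next_id += 1
    return Dendrogram(merges=merges, n_leaves=n)


def reorder_confusion(CM: np.ndarray, dend: Dendrogram) -> np.ndarray:
    """Permute confusion rows and columns into the dendrogram's leaf order."""
    CM = np.asarray(CM)
    if CM.shape[0] != dend.n_leaves or CM.shape[1] != dend.n_leaves:
        raise ValueError(
            f"confusion is {CM.shape} but dendrogram has {dend.n_leaves} leaves"
        )
    order = dend.leaf_order
    return CM[np.ix_(order, order)]
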