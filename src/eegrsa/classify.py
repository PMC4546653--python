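"""PCA-rotated one-vs-rest LDA with nested cross-validated component selection.

The decoding recipe: the trial-space matrix is rotated into component space
by a thin SVD (X1 = U S V^T, components = U S), computed once on the full
matrix before partitioning (the reference shortcut; a fold-safe per-training
SVD is available via ``CVConfig.fold_safe_svd``).  Ten outer cross-validation
folds each run a nested ten-fold inner cross-validation on the training
partitions only, selecting the number of leading principal components k in
[k_min, min(200, K)] that maximizes mean inner accuracy (ties break toward
the smallest k).  Classification is one-against-all linear discriminant
analysis: one binary discriminant per class against the pooled remainder,
predictions by argmax of the discriminant scores.  The outputs are count and
row-stochastic confusion matrices (rows = actual, columns = predicted) whose
diagonal mean is the accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import TrialSpaceDataset

__all__ = [
    "CVConfig",
    "ComponentSpace",
    "LDAModel",
    "ConfusionMatrix",
    "CVResult",
    "SVDError",
    "svd_rotate",
    "lda_fit",
    "lda_predict",
    "select_components_nested",
    "crossvalidate",
]

logger = logging.getLogger(__name__)

# (rank, requested k_max) pairs already warned about, to avoid log spam when
# the same truncation recurs across folds and searchlight cells
_truncation_warned: set[tuple[int, int]] = set()


class SVDError(np.linalg.LinAlgError):
    """SVD failed to converge while computing principal components."""


@dataclass
class CVConfig:
    """Cross-validation and classifier settings.

    ``k_grid`` defaults to every integer in [k_min, min(200, K)] when K <= 32
    and to a 24-point log-spaced grid otherwise; pass an explicit grid for
    exhaustive or custom searches.  ``shrinkage`` adds a ridge to the pooled
    within-class covariance diagonal (0 = none; rank-deficient data raise an
    error pointing here).  ``fold_safe_svd`` recomputes the SVD on each outer
    training partition instead of once on the full matrix.
    """

    n_folds_outer: int = 10
    n_folds_inner: int = 10
    k_min: int = 3
    k_max: int | None = None  # None -> min(200, K)
    k_grid: tuple[int, ...] | None = None
    seed: int = 0
    stratified: bool = False
    shrinkage: float = 0.0
    fold_safe_svd: bool = False
    allow_unbalanced: bool = False

    def __post_init__(self) -> None:
        if self.n_folds_outer < 2 or self.n_folds_inner < 2:
            raise ValueError("fold counts must be >= 2")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be nonnegative")
        if self.k_grid is not None:
            grid = tuple(int(k) for k in self.k_grid)
            if len(grid) == 0 or list(grid) != sorted(set(grid)):
                raise ValueError("k_grid must be non-empty, sorted and duplicate-free")
            self.k_grid = grid

    def resolve_grid(self, n_features: int, rank: int | None = None) -> list[int]:
        """Candidate component counts for a K-dimensional feature vector."""
        k_max = self.k_max if self.k_max is not None else min(200, n_features)
        k_max = min(k_max, n_features)
        if rank is not None and k_max > rank:
            if (rank, k_max) not in _truncation_warned:
                _truncation_warned.add((rank, k_max))
                logger.warning("component grid truncated to rank %d (was %d)", rank, k_max)
            k_max = rank
        k_min = min(self.k_min, k_max)
        if self.k_grid is not None:
            grid = [k for k in self.k_grid if k <= k_max]
            if not grid:
                grid = [k_max]
            return grid
        if k_max - k_min + 1 <= 30 or n_features <= 32:
            return list(range(k_min, k_max + 1))
        pts = np.unique(
            np.round(np.geomspace(k_min, k_max, num=24)).astype(int)
        )
        return [int(k) for k in pts]


@dataclass
class ComponentSpace:
    """Thin-SVD rotation of a trial-space matrix.

    ``rotated`` is U S (trials x rank), ``basis`` is V (features x rank) with
    the sign convention that each basis column's largest-magnitude entry is
    positive, ``singular_values`` is the diagonal of S in descending order.
    """

    rotated: np.ndarray
    basis: np.ndarray
    singular_values: np.ndarray

    @property
    def rank(self) -> int:
        s = self.singular_values
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > 1e-12 * s[0]))


def svd_rotate(ds: TrialSpaceDataset | np.ndarray) -> ComponentSpace:
    """Rotate X1 into component space via thin SVD (PCA without centering).

    Raises a data error for non-finite entries and :class:`SVDError` if the
    underlying factorization does not converge (this is known to happen on
    real recordings).
    """
    X1 = ds.X1 if isinstance(ds, TrialSpaceDataset) else np.asarray(ds, dtype=np.float64)
    if X1.shape[0] < 2:
        raise ValueError("need at least 2 trials for component rotation")
    if not np.all(np.isfinite(X1)):
        raise ValueError("X1 contains non-finite entries")
    try:
        U, s, Vt = np.linalg.svd(X1, full_matrices=False)
    except np.linalg.LinAlgError as err:  # pragma: no cover - data dependent
        raise SVDError(f"SVD did not converge: {err}") from err
    V = Vt.T
    # sign convention: largest-magnitude entry of each basis column positive
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    U = U * signs
    return ComponentSpace(rotated=U * s, basis=V, singular_values=s)


@dataclass
class LDAModel:
    """One-vs-rest LDA: per-class linear score w_c . z + b_c over k components."""

    weights: np.ndarray  # (n_classes, k)
    biases: np.ndarray  # (n_classes,)
    class_list: np.ndarray
    k: int


def _class_stats(Z: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Per-class counts, sums and grams, plus totals, for pooled scatters."""
    n, k = Z.shape
    counts = np.array([np.sum(y == c) for c in classes])
    sums = np.stack([Z[y == c].sum(axis=0) for c in classes])
    grams = np.stack([Z[y == c].T @ Z[y == c] for c in classes])
    return counts, sums, grams


def lda_fit(
    Z: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig | None = None,
    k: int | None = None,
) -> LDAModel:
    """Fit one two-class LDA per class (class vs. pooled rest).

    Each discriminant uses the pooled within-group covariance of the two
    groups (plus ``cfg.shrinkage`` on the diagonal), normal along
    ``Sigma^-1 (mu_c - mu_rest)`` with the boundary through the midpoint of
    the group means.  Only the first ``k`` columns of ``Z`` are used.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y).ravel()
    if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
        raise ValueError("Z must be (n, k) with one label per row")
    shrinkage = cfg.shrinkage if cfg is not None else 0.0
    if k is None:
        k = Z.shape[1]
    if k > Z.shape[1]:
        raise ValueError(f"k={k} exceeds available columns {Z.shape[1]}")
    Z = Z[:, :k]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit LDA")
    counts, sums, grams = _class_stats(Z, y, classes)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes {bad.tolist()} have fewer than 2 training rows")
    n = Z.shape[0]
    tot_sum = sums.sum(axis=0)
    tot_gram = grams.sum(axis=0)
    weights = np.empty((classes.size, k))
    biases = np.empty(classes.size)
    for i, c in enumerate(classes):
        n_c = counts[i]
        n_r = n - n_c
        mu_c = sums[i] / n_c
        mu_r = (tot_sum - sums[i]) / n_r
        scatter_c = grams[i] - n_c * np.outer(mu_c, mu_c)
        gram_r = tot_gram - grams[i]
        scatter_r = gram_r - n_r * np.outer(mu_r, mu_r)
        cov = (scatter_c + scatter_r) / (n - 2)
        if shrinkage > 0:
            cov = cov + shrinkage * np.eye(k)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular; set CVConfig.shrinkage > 0 "
                "or reduce the number of components"
            ) from err
        diff = mu_c - mu_r
        w = np.linalg.solve(L.T, np.linalg.solve(L, diff))
        weights[i] = w
        biases[i] = -0.5 * w @ (mu_c + mu_r)
    return LDAModel(weights=weights, biases=biases, class_list=classes, k=k)


def lda_predict(model: LDAModel, Z: np.ndarray) -> np.ndarray:
    """Argmax of the one-vs-rest discriminant scores; ties -> lowest class index."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] < model.k:
        raise ValueError(f"Z has {Z.shape[1]} columns; model needs {model.k}")
    scores = Z[:, : model.k] @ model.weights.T + model.biases
    # np.argmax returns the first maximum; class_list ascending => lowest index
    return model.class_list[np.argmax(scores, axis=1)]


def _partition(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into roughly equal folds; remainders go to early folds."""
    perm = rng.permutation(n)
    base = n // n_folds
    rem = n % n_folds
    folds = []
    start = 0
    for f in range(n_folds):
        size = base + (1 if f < rem else 0)
        folds.append(perm[start : start + size])
        start += size
    return folds


def _stratified_partition(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    # rotate the starting fold per class so small classes still cover all folds
    for ci, c in enumerate(np.unique(y)):
        idx = rng.permutation(np.flatnonzero(y == c))
        for j, t in enumerate(idx):
            folds[(j + ci) % n_folds].append(int(t))
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def select_components_nested(
    Z_train: np.ndarray,
    y_train: np.ndarray,
    cfg: CVConfig,
    rng: np.random.Generator | None = None,
) -> int:
    """Nested inner CV over the component grid; return the best (smallest-tied) k.

    For each candidate k the first k component columns are classified under
    ``cfg.n_folds_inner``-fold CV on the training rows only; k* maximizes the
    mean inner accuracy, with exact ties resolved toward the smallest k.
    """
    Z_train = np.asarray(Z_train, dtype=np.float64)
    y_train = np.asarray(y_train).ravel()
    n = Z_train.shape[0]
    if n < cfg.n_folds_inner:
        raise ValueError(
            f"{n} training rows are too few for {cfg.n_folds_inner} inner folds"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.stratified:
        folds = _stratified_partition(y_train, cfg.n_folds_inner, rng)
    else:
        folds = _partition(n, cfg.n_folds_inner, rng)
    # pooled covariance needs k <= (inner training rows) - 2 to be invertible
    min_inner_train = n - max(len(f) for f in folds)
    rank = min(n, Z_train.shape[1], max(min_inner_train - 2, 1))
    grid = cfg.resolve_grid(Z_train.shape[1], rank=rank)
    acc = np.zeros(len(grid))
    attempts = np.zeros(len(grid))
    for f, test_idx in enumerate(folds):
        if test_idx.size == 0:
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_in = y_train[train_mask]
        counts = np.bincount(y_in.astype(int), minlength=int(y_train.max()) + 1)
        present = np.unique(y_train)
        if np.any(counts[present] < 2):
            continue  # degenerate inner split: a class lost its training rows
        Z_in, Z_out = Z_train[train_mask], Z_train[test_idx]
        y_out = y_train[test_idx]
        for gi, k in enumerate(grid):
            model = lda_fit(Z_in, y_in, cfg, k=k)
            pred = lda_predict(model, Z_out)
            acc[gi] += np.sum(pred == y_out)
            attempts[gi] += y_out.size
    if np.all(attempts == 0):
        raise ValueError("no usable inner fold: too few rows per class")
    mean_acc = acc / attempts
    return int(grid[int(np.argmax(mean_acc))])  # first max = smallest tied k


@dataclass
class ConfusionMatrix:
    """Count and row-normalized confusion matrices (rows actual, cols predicted)."""

    counts: np.ndarray
    class_list: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.class_list = np.asarray(self.class_list)
        if self.counts.shape != (self.class_list.size, self.class_list.size):
            raise ValueError("counts must be square over class_list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def normalized(self) -> np.ndarray:
        """Row-stochastic confusion matrix CM (each row sums to 1)."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise ValueError("a class has no test trials; cannot normalize")
        return self.counts / row_sums

    @property
    def accuracy(self) -> float:
        """Mean of the diagonal of the normalized confusion matrix."""
        return float(np.mean(np.diag(self.normalized)))

    @property
    def total_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())


@dataclass
class CVResult:
    """Outcome of a cross-validated classification."""

    confusion: ConfusionMatrix
    fold_k: list[int]
    fold_correct: list[int]
    fold_sizes: list[int]

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


def crossvalidate(
    ds: TrialSpaceDataset,
    level: str,
    cfg: CVConfig | None = None,
) -> CVResult:
    """Ten-fold cross-validated one-vs-rest LDA decoding of ``level`` labels.

    The SVD is computed once on the full matrix before partitioning (set
    ``cfg.fold_safe_svd`` to recompute it per training partition).  Trials are
    randomly partitioned into ``n_folds_outer`` roughly equal folds (remainder
    trials in the earliest folds); each fold is tested exactly once, with the
    component count chosen by nested inner CV on the training partitions.
    Requires balanced class counts unless ``cfg.allow_unbalanced`` is set.
    """
    if cfg is None:
        cfg = CVConfig()
    y = ds.labels(level)
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if not cfg.allow_unbalanced and np.unique(class_counts).size > 1:
        raise ValueError(
            "class counts are unbalanced; set CVConfig.allow_unbalanced to proceed"
        )
    n = ds.n_trials
    rng = np.random.default_rng(cfg.seed)
    if cfg.stratified:
        folds = _stratified_partition(y, cfg.n_folds_outer, rng)
    else:
        folds = _partition(n, cfg.n_folds_outer, rng)
    inner_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_folds_outer)

    if not cfg.fold_safe_svd:
        comp = svd_rotate(ds)
        Z_full = comp.rotated

    counts = np.zeros((classes.size, classes.size), dtype=np.int64)
    class_index = {int(c): i for i, c in enumerate(classes)}
    fold_k: list[int] = []
    fold_correct: list[int] = []
    fold_sizes: list[int] = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if cfg.fold_safe_svd:
            comp = svd_rotate(ds.X1[train_mask])
            Z_train = comp.rotated
            Z_test = ds.X1[test_idx] @ comp.basis
        else:
            Z_train = Z_full[train_mask]
            Z_test = Z_full[test_idx]
        inner_rng = np.random.default_rng(inner_seeds[f])
        k_star = select_components_nested(Z_train, y[train_mask], cfg, rng=inner_rng)
        model = lda_fit(Z_train, y[train_mask], cfg, k=k_star)
        pred = lda_predict(model, Z_test)
        actual = y[test_idx]
        for a, p in zip(actual, pred):
            counts[class_index[int(a)], class_index[int(p)]] += 1
        fold_k.append(k_star)
        fold_correct.append(int(np.sum(pred == actual)))
        fold_sizes.append(int(test_idx.size))
    return CVResult(
        confusion=ConfusionMatrix(counts=counts, class_list=classes),
        fold_k=fold_k,
        fold_correct=fold_correct,
        fold_sizes=fold_sizes,
    )
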