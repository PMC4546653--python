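"""SVD rotation, one-vs-rest LDA, nested component selection, cross-validation."""

import numpy as np
import pytest
from scipy.stats import binom

from eegrsa import (
    CVConfig,
    GeneratorConfig,
    crossvalidate,
    lda_fit,
    lda_predict,
    select_components_nested,
    simulate_dataset,
    svd_rotate,
)
from eegrsa.classify import ConfusionMatrix, _partition


def closed_form_two_class(Z, y, Ztest):
    """Independent two-class LDA oracle: w = Sigma^-1 (mu1 - mu0), midpoint bias."""
    c0, c1 = np.unique(y)
    A, B = Z[y == c0], Z[y == c1]
    mu0, mu1 = A.mean(axis=0), B.mean(axis=0)
    S = ((A - mu0).T @ (A - mu0) + (B - mu1).T @ (B - mu1)) / (len(y) - 2)
    w = np.linalg.solve(S, mu1 - mu0)
    score = Ztest @ w - w @ (mu0 + mu1) / 2
    return np.where(score > 0, c1, c0)


class TestSVDRotate:
    def test_reconstruction_identity(self, small_ds):
        comp = svd_rotate(small_ds)
        recon = comp.rotated @ comp.basis.T
        err = np.linalg.norm(recon - small_ds.X1) / np.linalg.norm(small_ds.X1)
        assert err < 1e-10

    def test_singular_values_sorted_nonnegative(self, small_ds):
        s = svd_rotate(small_ds).singular_values
        assert np.all(s >= 0) and np.all(np.diff(s) <= 0)

    def test_orthogonal_rows_rotate_to_themselves(self):
        """Orthogonal input rows come back as the rotated matrix up to order/sign."""
        X = np.diag([3.0, 2.0, 1.0])
        comp = svd_rotate(X)
        np.testing.assert_allclose(np.abs(comp.rotated), np.diag([3.0, 2.0, 1.0]), atol=1e-12)

    def test_rank_one_matrix(self):
        X = np.outer(np.arange(1, 5, dtype=float), np.ones(6))
        s = svd_rotate(X).singular_values
        assert np.sum(s > 1e-10 * s[0]) == 1

    def test_sign_convention_deterministic(self, small_ds):
        a, b = svd_rotate(small_ds), svd_rotate(small_ds)
        np.testing.assert_array_equal(a.basis, b.basis)
        assert np.all(
            a.basis[np.argmax(np.abs(a.basis), axis=0), np.arange(a.basis.shape[1])] > 0
        )

    def test_non_finite_rejected(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            svd_rotate(X)


class TestLDA:
    def test_matches_closed_form_two_class_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n, k = rng.integers(10, 41), rng.integers(2, 6)
            Z = rng.standard_normal((int(n), int(k)))
            y = np.array([0] * (n // 2) + [1] * (n - n // 2))
            Ztest = rng.standard_normal((15, int(k)))
            model = lda_fit(Z, y)
            np.testing.assert_array_equal(
                lda_predict(model, Ztest), closed_form_two_class(Z, y, Ztest)
            )

    def test_multiclass_matches_independent_per_class_oracle(self):
        """One-vs-rest scores agree with independently fit binary discriminants."""
        rng = np.random.default_rng(1)
        for trial in range(10):
            n_classes = int(rng.integers(3, 9))
            n_per = int(rng.integers(4, 6))
            k = 3
            y = np.repeat(np.arange(n_classes), n_per)
            Z = rng.standard_normal((y.size, k)) + 2.0 * rng.standard_normal((n_classes, k))[y]
            Ztest = rng.standard_normal((20, k))
            model = lda_fit(Z, y)
            # oracle: binary LDA per class against the pooled remainder
            scores = np.empty((20, n_classes))
            for c in range(n_classes):
                yc = (y == c).astype(int)
                A, B = Z[yc == 0], Z[yc == 1]
                mu0, mu1 = A.mean(axis=0), B.mean(axis=0)
                S = ((A - mu0).T @ (A - mu0) + (B - mu1).T @ (B - mu1)) / (y.size - 2)
                w = np.linalg.solve(S, mu1 - mu0)
                scores[:, c] = Ztest @ w - w @ (mu0 + mu1) / 2
            np.testing.assert_array_equal(
                lda_predict(model, Ztest), np.argmax(scores, axis=1)
            )

    def test_symmetric_means_boundary_through_origin(self):
        rng = np.random.default_rng(2)
        mu = np.array([2.0, -1.0])
        Z = np.vstack([mu + 0.1 * rng.standard_normal((30, 2)),
                       -mu + 0.1 * rng.standard_normal((30, 2))])
        # enforce exact symmetry so the pooled mean is exactly zero
        Z[30:] = -Z[:30]
        y = np.array([0] * 30 + [1] * 30)
        model = lda_fit(Z, y)
        scores = np.zeros((1, 2)) @ model.weights.T + model.biases
        assert abs(scores[0, 0] - scores[0, 1]) < 1e-10

    def test_point_at_class_mean_predicted_as_that_class(self):
        rng = np.random.default_rng(3)
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        y = np.repeat([0, 1, 2], 20)
        Z = means[y] + 0.1 * rng.standard_normal((60, 2))
        model = lda_fit(Z, y)
        np.testing.assert_array_equal(lda_predict(model, means), [0, 1, 2])

    def test_exact_tie_breaks_to_lowest_class(self):
        from eegrsa.classify import LDAModel

        model = LDAModel(
            weights=np.array([[1.0, 0.0], [1.0, 0.0]]),
            biases=np.array([0.0, 0.0]),
            class_list=np.array([4, 9]),
            k=2,
        )
        pred = lda_predict(model, np.array([[2.0, 3.0]]))
        assert pred[0] == 4

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            lda_fit(np.ones((6, 2)), np.zeros(6))

    def test_singular_covariance_advises_shrinkage(self):
        Z = np.zeros((8, 3))
        Z[:, 0] = [0, 0, 0, 0, 1, 1, 1, 1]
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            lda_fit(Z, y)
        # with shrinkage the same data fit fine
        lda_fit(Z, y, CVConfig(shrinkage=1e-3))

    def test_two_class_multiclass_equals_binary(self):
        """For 2 classes, argmax over one-vs-rest equals the binary decision."""
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((24, 4))
        y = np.array([0] * 12 + [1] * 12)
        Ztest = rng.standard_normal((30, 4))
        np.testing.assert_array_equal(
            lda_predict(lda_fit(Z, y), Ztest), closed_form_two_class(Z, y, Ztest)
        )


class TestComponentSelection:
    def test_low_rank_signal_selects_small_k(self):
        """Signal confined to the first 3 components -> k* = 3 wins the grid vote."""
        votes = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 120
            y = np.repeat(np.arange(3), 40)
            Z = 0.05 * rng.standard_normal((n, 50))
            means = 3.0 * rng.standard_normal((3, 3))
            Z[:, :3] += means[y]
            cfg = CVConfig(k_grid=(3, 50), seed=seed)
            votes.append(select_components_nested(Z, y, cfg))
        assert sum(v == 3 for v in votes) >= 3

    def test_kmax_rule_min_200_K(self):
        assert CVConfig().resolve_grid(6) == [3, 4, 5, 6]
        grid = CVConfig().resolve_grid(3968)
        assert grid[0] == 3 and grid[-1] == 200 and len(grid) <= 24

    def test_exact_tie_returns_smallest_k(self):
        """A negligible 4th component leaves k=3 and k=4 tied -> returns 3."""
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 20)
        Z = np.hstack(
            [
                rng.standard_normal((40, 3)) + 2.0 * y[:, None],
                1e-8 * rng.standard_normal((40, 1)),
            ]
        )
        cfg = CVConfig(k_grid=(3, 4), n_folds_inner=5, seed=0)
        assert select_components_nested(Z, y, cfg) == 3

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((60, 10))
        y = np.repeat(np.arange(3), 20)
        cfg = CVConfig(k_grid=(3, 5, 8), seed=42)
        assert select_components_nested(Z, y, cfg) == select_components_nested(Z, y, cfg)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="inner folds"):
            select_components_nested(np.ones((5, 3)), np.arange(5), CVConfig())


class TestCrossValidate:
    def test_fold_arithmetic_matches_integer_partition(self):
        """5,184 trials over 10 folds -> sizes 518 or 519 (remainder first)."""
        folds = _partition(5184, 10, np.random.default_rng(0))
        sizes = [len(f) for f in folds]
        assert sorted(sizes) == sorted([519] * 4 + [518] * 6)
        assert sizes[:4] == [519] * 4  # remainders assigned to the first folds
        assert sum(sizes) == 5184
        all_idx = np.concatenate(folds)
        assert np.array_equal(np.sort(all_idx), np.arange(5184))

    def test_perfectly_separable_toy_gives_identity_confusion(self):
        rng = np.random.default_rng(7)
        n_per = 20
        X = np.vstack(
            [
                np.array([50.0, 0.0]) + 0.01 * rng.standard_normal((n_per, 2)),
                np.array([-50.0, 0.0]) + 0.01 * rng.standard_normal((n_per, 2)),
            ]
        )
        from eegrsa.dataio import TrialSpaceDataset

        ds = TrialSpaceDataset(
            X, np.repeat([0, 1], n_per), np.repeat([0, 1], n_per), 1, 2
        )
        cfg = CVConfig(k_min=1, k_grid=(1, 2), n_folds_inner=4, seed=0)
        res = crossvalidate(ds, "category", cfg)
        np.testing.assert_array_equal(res.confusion.counts, np.diag([n_per, n_per]))
        assert res.accuracy == 1.0

    def test_counts_conservation_and_row_sums(self, small_ds, fast_cv):
        res = crossvalidate(small_ds, "category", fast_cv)
        counts = res.confusion.counts
        assert counts.sum() == small_ds.n_trials
        np.testing.assert_array_equal(counts.sum(axis=1), [20] * 6)
        np.testing.assert_allclose(res.confusion.normalized.sum(axis=1), 1.0, atol=1e-12)
        assert res.confusion.accuracy == pytest.approx(
            np.mean(np.diag(res.confusion.normalized))
        )

    def test_shuffled_labels_decode_at_chance(self, small_ds, fast_cv):
        rng = np.random.default_rng(8)
        shuffled = small_ds.subset_trials(np.arange(small_ds.n_trials))
        perm = rng.permutation(small_ds.n_trials)
        shuffled.category_labels = small_ds.category_labels[perm]
        shuffled.exemplar_labels = small_ds.exemplar_labels[perm]
        res = crossvalidate(shuffled, "category", fast_cv)
        n = small_ds.n_trials
        lo = binom.ppf(0.005, n, 1 / 6) / n
        hi = binom.ppf(0.995, n, 1 / 6) / n
        assert lo <= res.accuracy <= hi

    def test_unbalanced_classes_rejected_without_flag(self, small_ds, fast_cv):
        ds = small_ds.subset_trials(np.arange(small_ds.n_trials - 3))
        with pytest.raises(ValueError, match="unbalanced"):
            crossvalidate(ds, "category", fast_cv)

    def test_deterministic_given_seed(self, small_ds, fast_cv):
        a = crossvalidate(small_ds, "category", fast_cv)
        b = crossvalidate(small_ds, "category", fast_cv)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
        assert a.fold_k == b.fold_k

    def test_fold_safe_svd_option(self, small_ds):
        cfg = CVConfig(k_grid=(3, 6), seed=1, fold_safe_svd=True)
        res = crossvalidate(small_ds, "category", cfg)
        assert res.confusion.n_trials == small_ds.n_trials
        assert res.accuracy > 0.5  # strong planted signal survives fold-safe SVD

    def test_every_trial_tested_once(self, small_ds, fast_cv):
        res = crossvalidate(small_ds, "category", fast_cv)
        assert sum(res.fold_sizes) == small_ds.n_trials
        assert len(res.fold_sizes) == 10


class TestConfusionMatrix:
    def test_normalization_requires_tested_classes(self):
        with pytest.raises(ValueError, match="no test trials"):
            ConfusionMatrix(np.array([[0, 0], [1, 1]]), np.array([0, 1])).normalized

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.zeros((2, 3)), np.array([0, 1]))
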