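"""Trial-space reshaping, feature selection and container round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegrsa.dataio import (
    DatasetFormatError,
    FeatureSelector,
    TrialSpaceDataset,
    export_csv,
    feature_column,
    load_dataset,
    load_mat,
    reshape_spacetime_to_trialspace,
    save_dataset,
    select_features,
    trialspace_to_spacetime,
)


def _ds(n_trials=6, n_e=4, n_t=8, seed=0):
    rng = np.random.default_rng(seed)
    epochs = rng.standard_normal((n_trials, n_e, n_t))
    ex = np.arange(n_trials) % 3
    cat = ex % 3
    return reshape_spacetime_to_trialspace(epochs, ex, cat), epochs


class TestReshape:
    def test_electrode_major_ordering(self):
        """A 2x2 epoch [[a,b],[c,d]] concatenates to the row (a,b,c,d)."""
        epochs = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        ds = reshape_spacetime_to_trialspace(epochs, [0], [0])
        np.testing.assert_array_equal(ds.X1, [[1.0, 2.0, 3.0, 4.0]])

    def test_roundtrip_is_identity(self):
        ds, epochs = _ds()
        np.testing.assert_array_equal(trialspace_to_spacetime(ds), epochs)

    def test_single_electrode_is_identity(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((5, 1, 12))
        ds = reshape_spacetime_to_trialspace(epochs, np.zeros(5), np.zeros(5))
        np.testing.assert_array_equal(ds.X1, epochs[:, 0, :])

    def test_reference_design_row_length(self):
        """124 electrodes x 32 samples concatenate to 3,968 features."""
        epochs = np.zeros((2, 124, 32))
        ds = reshape_spacetime_to_trialspace(epochs, [0, 1], [0, 1])
        assert ds.n_features == 124 * 32 == 3968

    def test_ragged_stack_rejected(self):
        with pytest.raises(DatasetFormatError):
            reshape_spacetime_to_trialspace(np.zeros((2, 3)), [0, 1], [0, 1])


class TestValidation:
    def test_label_length_mismatch(self):
        with pytest.raises(DatasetFormatError, match="exemplar"):
            TrialSpaceDataset(
                X1=np.zeros((6, 8)),
                exemplar_labels=np.zeros(5),
                category_labels=np.zeros(6),
                n_electrodes=2,
                n_time_samples=4,
            )

    def test_feature_count_mismatch(self):
        with pytest.raises(DatasetFormatError, match="columns"):
            TrialSpaceDataset(
                X1=np.zeros((2, 7)),
                exemplar_labels=[0, 1],
                category_labels=[0, 1],
                n_electrodes=2,
                n_time_samples=4,
            )

    def test_exemplar_category_must_be_function(self):
        with pytest.raises(DatasetFormatError, match="more than one category"):
            TrialSpaceDataset(
                X1=np.zeros((2, 4)),
                exemplar_labels=[5, 5],
                category_labels=[0, 1],
                n_electrodes=1,
                n_time_samples=4,
            )


class TestSelectFeatures:
    def test_single_electrode_full_window(self):
        ds, _ = _ds(n_e=4, n_t=8)
        sub = select_features(ds, FeatureSelector((2,), (0, 8)))
        assert sub.n_features == 8
        np.testing.assert_array_equal(sub.X1, ds.X1[:, 16:24])

    def test_all_electrodes_window_matches_brute_force(self):
        """Column identity against explicit (electrode, sample) enumeration."""
        n_e, n_t, win = 124, 32, (9, 15)
        rng = np.random.default_rng(2)
        X1 = rng.standard_normal((3, n_e * n_t))
        ds = TrialSpaceDataset(X1, np.arange(3), np.arange(3), n_e, n_t)
        sub = select_features(ds, FeatureSelector(tuple(range(n_e)), win))
        assert sub.n_features == 124 * 6 == 744
        cols = [
            feature_column(e, s, n_t)
            for e in range(n_e)
            for s in range(win[0], win[1])
        ]
        np.testing.assert_array_equal(sub.X1, X1[:, cols])

    def test_full_selector_is_identity(self):
        ds, _ = _ds()
        sub = select_features(ds, FeatureSelector(tuple(range(4)), (0, 8)))
        np.testing.assert_array_equal(sub.X1, ds.X1)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            FeatureSelector((), (0, 4))
        with pytest.raises(ValueError):
            FeatureSelector((0,), (3, 3))

    def test_out_of_bounds_rejected(self):
        ds, _ = _ds()
        with pytest.raises(ValueError):
            select_features(ds, FeatureSelector((9,), (0, 8)))
        with pytest.raises(ValueError):
            select_features(ds, FeatureSelector((0,), (0, 99)))

    def test_commutes_with_trial_permutation(self):
        ds, _ = _ds(n_trials=8)
        sel = FeatureSelector((1, 3), (2, 6))
        perm = np.random.default_rng(3).permutation(8)
        a = select_features(ds.subset_trials(perm), sel).X1
        b = select_features(ds, sel).X1[perm]
        np.testing.assert_array_equal(a, b)

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=4, unique=True),
        st.integers(0, 6),
        st.integers(1, 2),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_feature_column_map_is_bijective(self, electrodes, start, length):
        """(electrode, sample) -> output column is a bijection for any selector."""
        ds, _ = _ds()
        stop = min(start + length, 8)
        if stop <= start:
            return
        sel = FeatureSelector(tuple(electrodes), (start, stop))
        sub = select_features(ds, sel)
        cols = [
            feature_column(e, s, 8) for e in electrodes for s in range(start, stop)
        ]
        assert len(set(cols)) == sub.n_features
        np.testing.assert_array_equal(sub.X1, ds.X1[:, cols])


class TestContainers:
    def test_hdf5_roundtrip_bit_identical(self, tmp_path):
        ds, _ = _ds(n_trials=10, n_e=2, n_t=4)
        path = tmp_path / "ds.h5"
        save_dataset(ds, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.X1, ds.X1)
        np.testing.assert_array_equal(back.exemplar_labels, ds.exemplar_labels)
        np.testing.assert_array_equal(back.category_labels, ds.category_labels)
        assert back.n_electrodes == 2 and back.n_time_samples == 4
        assert back.sampling_rate_hz == ds.sampling_rate_hz

    def test_missing_key_named_in_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("X1", data=np.zeros((2, 4)))
        with pytest.raises(DatasetFormatError, match="exemplar"):
            load_dataset(path)

    def test_mat_import_with_key_map(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "ds.mat"
        X = np.arange(12.0).reshape(3, 4)
        savemat(path, {"trials": X, "ex": [1, 2, 1], "cat": [0, 1, 0]})
        ds = load_mat(
            path,
            n_electrodes=2,
            n_time_samples=2,
            key_map={"X1": "trials", "exemplar": "ex", "category": "cat"},
        )
        np.testing.assert_array_equal(ds.X1, X)
        np.testing.assert_array_equal(ds.exemplar_labels, [1, 2, 1])

    def test_mat_category_derived_from_exemplar_map(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "ds.mat"
        savemat(path, {"X1": np.zeros((4, 4)), "exemplar": [3, 4, 3, 4]})
        ds = load_mat(
            path,
            n_electrodes=2,
            n_time_samples=2,
            exemplar_to_category={3: 0, 4: 1},
        )
        np.testing.assert_array_equal(ds.category_labels, [0, 1, 0, 1])

    def test_mat_missing_matrix_key(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "ds.mat"
        savemat(path, {"whatever": np.zeros((2, 2))})
        with pytest.raises(DatasetFormatError, match="X1"):
            load_mat(path, n_electrodes=1, n_time_samples=2)

    def test_csv_export(self, tmp_path):
        import pandas as pd

        ds, _ = _ds(n_trials=4, n_e=1, n_t=3)
        path = tmp_path / "ds.csv"
        export_csv(ds, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["exemplar", "category", "f0", "f1", "f2"]
        np.testing.assert_allclose(df[["f0", "f1", "f2"]].to_numpy(), ds.X1)
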