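"""Trial-space data model, reshaping conventions, feature subsetting and I/O.

The central container is the trial-space matrix: one row per trial, whose
columns are the electrode-major concatenation of that trial's per-electrode
time courses (electrode ``e``'s samples occupy columns
``[e * n_time_samples, (e + 1) * n_time_samples)``).  A 124-electrode,
32-sample epoch therefore yields a 3,968-long feature vector.

Datasets round-trip through an HDF5 container (keys ``/X1``, ``/exemplar``,
``/category``, ``/meta/*``) and can be imported from MAT-style containers
with a configurable key map, or exported to CSV for small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TrialSpaceDataset",
    "FeatureSelector",
    "DatasetFormatError",
    "reshape_spacetime_to_trialspace",
    "trialspace_to_spacetime",
    "select_features",
    "feature_column",
    "save_dataset",
    "load_dataset",
    "load_mat",
    "export_csv",
]


class DatasetFormatError(ValueError):
    """A container is missing required fields or fields are inconsistent."""


@dataclass
class TrialSpaceDataset:
    """Trials x features EEG matrix with labels and epoch layout metadata.

    Parameters
    ----------
    X1 : ndarray, shape (n_trials, n_electrodes * n_time_samples)
        Voltage features in electrode-major column order.
    exemplar_labels : ndarray of int, shape (n_trials,)
        Image-exemplar label per trial.
    category_labels : ndarray of int, shape (n_trials,)
        Category label per trial; must be a function of the exemplar label.
    n_electrodes, n_time_samples : int
        Epoch layout; their product must equal ``X1.shape[1]``.
    sampling_rate_hz : float
        Sampling rate of the epoched data (62.5 Hz in the reference design,
        i.e. 16 ms per sample).
    epoch_start_ms : float
        Time of sample 0 relative to stimulus onset (0 = stimulus-locked).
    """

    X1: np.ndarray
    exemplar_labels: np.ndarray
    category_labels: np.ndarray
    n_electrodes: int
    n_time_samples: int
    sampling_rate_hz: float = 62.5
    epoch_start_ms: float = 0.0
    electrode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=np.float64)
        self.exemplar_labels = np.asarray(self.exemplar_labels).ravel().astype(np.int64)
        self.category_labels = np.asarray(self.category_labels).ravel().astype(np.int64)
        if self.X1.ndim != 2:
            raise DatasetFormatError("X1 must be a 2-D trials x features matrix")
        n, k = self.X1.shape
        if k != self.n_electrodes * self.n_time_samples:
            raise DatasetFormatError(
                f"X1 has {k} columns but n_electrodes * n_time_samples = "
                f"{self.n_electrodes * self.n_time_samples}"
            )
        for name, lab in (("exemplar", self.exemplar_labels), ("category", self.category_labels)):
            if lab.shape[0] != n:
                raise DatasetFormatError(
                    f"{name} labels have length {lab.shape[0]} for {n} trials"
                )
        # exemplar -> category must be a function
        mapping: dict[int, int] = {}
        for e, c in zip(self.exemplar_labels, self.category_labels):
            if mapping.setdefault(int(e), int(c)) != int(c):
                raise DatasetFormatError(
                    f"exemplar {int(e)} maps to more than one category"
                )
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.n_electrodes)
        else:
            self.electrode_ids = np.asarray(self.electrode_ids).ravel().astype(np.int64)
            if self.electrode_ids.shape[0] != self.n_electrodes:
                raise DatasetFormatError("electrode_ids length must equal n_electrodes")

    @property
    def n_trials(self) -> int:
        return self.X1.shape[0]

    @property
    def n_features(self) -> int:
        return self.X1.shape[1]

    @property
    def exemplar_to_category(self) -> dict[int, int]:
        return {
            int(e): int(c)
            for e, c in zip(self.exemplar_labels, self.category_labels)
        }

    def labels(self, level: str) -> np.ndarray:
        """Return the label vector for ``level`` ('category' or 'exemplar')."""
        if level == "category":
            return self.category_labels
        if level == "exemplar":
            return self.exemplar_labels
        raise ValueError(f"unknown level {level!r}; use 'category' or 'exemplar'")

    def subset_trials(self, rows: np.ndarray) -> "TrialSpaceDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            X1=self.X1[rows],
            exemplar_labels=self.exemplar_labels[rows],
            category_labels=self.category_labels[rows],
        )


@dataclass(frozen=True)
class FeatureSelector:
    """Electrode subset and half-open sample window selecting feature columns."""

    electrodes: tuple[int, ...]
    sample_window: tuple[int, int]  # half-open [start, stop)

    def __post_init__(self) -> None:
        if len(self.electrodes) == 0:
            raise ValueError("empty electrode selection")
        start, stop = self.sample_window
        if stop <= start:
            raise ValueError(f"empty sample window [{start}, {stop})")

    @property
    def window_length(self) -> int:
        return self.sample_window[1] - self.sample_window[0]


def reshape_spacetime_to_trialspace(
    epochs: np.ndarray,
    exemplar_labels: np.ndarray,
    category_labels: np.ndarray,
    sampling_rate_hz: float = 62.5,
    epoch_start_ms: float = 0.0,
) -> TrialSpaceDataset:
    """Stack space-time epochs into a trial-space matrix.

    ``epochs`` is an array of shape (n_trials, n_electrodes, n_time_samples);
    row ``t`` of the result is the row-wise (electrode-major) concatenation of
    epoch ``t``, so a 2x2 epoch ``[[a, b], [c, d]]`` becomes ``(a, b, c, d)``.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 3:
        raise DatasetFormatError(
            f"expected a (n_trials, n_electrodes, n_time_samples) stack, got ndim={epochs.ndim}"
        )
    n_trials, n_e, n_t = epochs.shape
    X1 = epochs.reshape(n_trials, n_e * n_t)  # C order = electrode-major
    return TrialSpaceDataset(
        X1=X1,
        exemplar_labels=exemplar_labels,
        category_labels=category_labels,
        n_electrodes=n_e,
        n_time_samples=n_t,
        sampling_rate_hz=sampling_rate_hz,
        epoch_start_ms=epoch_start_ms,
    )


def trialspace_to_spacetime(ds: TrialSpaceDataset) -> np.ndarray:
    """Inverse reshape: recover the (n_trials, n_electrodes, n_time_samples) stack."""
    return ds.X1.reshape(ds.n_trials, ds.n_electrodes, ds.n_time_samples)


def feature_column(electrode: int, sample: int, n_time_samples: int) -> int:
    """Column index of (electrode, sample) under the electrode-major convention."""
    return electrode * n_time_samples + sample


def select_features(ds: TrialSpaceDataset, sel: FeatureSelector) -> TrialSpaceDataset:
    """Restrict the feature columns to ``sel``'s electrodes x sample window.

    Output columns follow the same electrode-major convention over the selected
    electrodes (in the order given) and window samples.  Labels are unchanged.
    """
    start, stop = sel.sample_window
    if start < 0 or stop > ds.n_time_samples:
        raise ValueError(
            f"sample window [{start}, {stop}) outside [0, {ds.n_time_samples})"
        )
    for e in sel.electrodes:
        if e < 0 or e >= ds.n_electrodes:
            raise ValueError(f"electrode {e} outside [0, {ds.n_electrodes})")
    cols = np.concatenate(
        [
            np.arange(
                feature_column(e, start, ds.n_time_samples),
                feature_column(e, stop, ds.n_time_samples),
            )
            for e in sel.electrodes
        ]
    )
    return TrialSpaceDataset(
        X1=ds.X1[:, cols],
        exemplar_labels=ds.exemplar_labels,
        category_labels=ds.category_labels,
        n_electrodes=len(sel.electrodes),
        n_time_samples=sel.window_length,
        sampling_rate_hz=ds.sampling_rate_hz,
        epoch_start_ms=ds.epoch_start_ms + start * 1000.0 / ds.sampling_rate_hz,
        electrode_ids=np.asarray(ds.electrode_ids)[list(sel.electrodes)],
    )


# ---------------------------------------------------------------------------
# Containers

_H5_KEYS = ("X1", "exemplar", "category")


def save_dataset(ds: TrialSpaceDataset, path: str | Path) -> None:
    """Write the native HDF5 container (/X1, /exemplar, /category, /meta/*)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X1", data=ds.X1)
        f.create_dataset("exemplar", data=ds.exemplar_labels)
        f.create_dataset("category", data=ds.category_labels)
        meta = f.create_group("meta")
        meta.attrs["n_electrodes"] = ds.n_electrodes
        meta.attrs["n_time_samples"] = ds.n_time_samples
        meta.attrs["sampling_rate_hz"] = ds.sampling_rate_hz
        meta.attrs["epoch_start_ms"] = ds.epoch_start_ms
        meta.create_dataset("electrode_ids", data=np.asarray(ds.electrode_ids))


def load_dataset(path: str | Path) -> TrialSpaceDataset:
    """Read the native HDF5 container written by :func:`save_dataset`."""
    import h5py

    with h5py.File(path, "r") as f:
        for key in _H5_KEYS:
            if key not in f:
                raise DatasetFormatError(f"container {path} is missing key /{key}")
        meta = f["meta"].attrs if "meta" in f else {}
        electrode_ids = (
            f["meta/electrode_ids"][()] if "meta" in f and "electrode_ids" in f["meta"] else None
        )
        return TrialSpaceDataset(
            X1=f["X1"][()],
            exemplar_labels=f["exemplar"][()],
            category_labels=f["category"][()],
            n_electrodes=int(meta.get("n_electrodes", 0) or f["X1"].shape[1]),
            n_time_samples=int(meta.get("n_time_samples", 1)),
            sampling_rate_hz=float(meta.get("sampling_rate_hz", 62.5)),
            epoch_start_ms=float(meta.get("epoch_start_ms", 0.0)),
            electrode_ids=electrode_ids,
        )


DEFAULT_MAT_KEYS = {"X1": "X1", "exemplar": "exemplar", "category": "category"}


def load_mat(
    path: str | Path,
    n_electrodes: int,
    n_time_samples: int,
    key_map: dict[str, str] | None = None,
    exemplar_to_category: dict[int, int] | None = None,
    sampling_rate_hz: float = 62.5,
) -> TrialSpaceDataset:
    """Import a MAT-style container holding a trials x features matrix.

    The deposited-repository key names are not standardized, so ``key_map``
    maps the logical names ``X1``/``exemplar``/``category`` onto the keys of
    the file at hand.  If the category vector is absent but an
    ``exemplar_to_category`` map is supplied, categories are derived by
    composition.
    """
    from scipy.io import loadmat

    keys = dict(DEFAULT_MAT_KEYS)
    if key_map:
        keys.update(key_map)
    raw = loadmat(str(path))
    if keys["X1"] not in raw:
        raise DatasetFormatError(f"MAT container is missing matrix key {keys['X1']!r}")
    X1 = np.asarray(raw[keys["X1"]], dtype=np.float64)
    if keys["exemplar"] not in raw:
        raise DatasetFormatError(f"MAT container is missing label key {keys['exemplar']!r}")
    exemplar = np.asarray(raw[keys["exemplar"]]).ravel().astype(np.int64)
    if keys["category"] in raw:
        category = np.asarray(raw[keys["category"]]).ravel().astype(np.int64)
    elif exemplar_to_category is not None:
        try:
            category = np.array([exemplar_to_category[int(e)] for e in exemplar])
        except KeyError as err:
            raise DatasetFormatError(f"exemplar {err} missing from exemplar_to_category map")
    else:
        raise DatasetFormatError(
            f"MAT container has no category key {keys['category']!r} and no "
            "exemplar_to_category map was given"
        )
    return TrialSpaceDataset(
        X1=X1,
        exemplar_labels=exemplar,
        category_labels=category,
        n_electrodes=n_electrodes,
        n_time_samples=n_time_samples,
        sampling_rate_hz=sampling_rate_hz,
    )


def export_csv(ds: TrialSpaceDataset, path: str | Path) -> None:
    """CSV export for small fixtures: label columns followed by features."""
    import pandas as pd

    df = pd.DataFrame(ds.X1, columns=[f"f{j}" for j in range(ds.n_features)])
    df.insert(0, "category", ds.category_labels)
    df.insert(0, "exemplar", ds.exemplar_labels)
    df.to_csv(path, index=False)
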