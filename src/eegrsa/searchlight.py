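"""Spatially, temporally and spatiotemporally resolved decoding.

Three searchlight variants repeat the full cross-validated decoding on
restricted feature subsets:

- per electrode: all time samples of one electrode at a time (K = n_samples),
  localizing which electrodes carry decodable signal;
- per temporal window: all electrodes within a sliding window (default
  6 samples = 80 ms, advancing 3 samples = 48 ms), tracing decodability over
  time, with the full confusion -> RDM -> MDS/UPGMA chain per window;
- per electrode x window: single-electrode, single-window cells
  (K = window length), mapping topography over time.

Windows are labeled in ms by the inclusive first-to-last-sample span at
16 ms/sample (62.5 Hz): the standard 32-sample epoch yields nine windows
0-80, 48-128, ..., 384-464 ms.  Each cell is a bona fide cross-validated
run with its own RNG stream derived from the master seed; cells whose SVD
fails are recorded as missing with the cause rather than aborting the map.
Per-cell binomial reports carry no multiple-comparison correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .classify import CVConfig, CVResult, SVDError, crossvalidate
from .dataio import FeatureSelector, TrialSpaceDataset, select_features
from .embedding import Dendrogram, Embedding, classical_mds, upgma
from .rdm import SimilaritySpace, confusion_to_distance
from .stats import BinomialReport, binomial_pvalue

__all__ = [
    "TemporalWindow",
    "RateMap",
    "WindowResult",
    "temporal_windows",
    "per_electrode",
    "per_window",
    "per_electrode_window",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalWindow:
    """Half-open sample window with its inclusive ms display label."""

    start_sample: int
    stop_sample: int
    start_ms: float
    end_ms: float

    @property
    def length(self) -> int:
        return self.stop_sample - self.start_sample

    @property
    def label(self) -> str:
        return f"{self.start_ms:g}-{self.end_ms:g} ms"


def temporal_windows(
    n_samples: int = 32,
    win_len: int = 6,
    step: int = 3,
    sampling_rate_hz: float = 62.5,
    epoch_start_ms: float = 0.0,
) -> list[TemporalWindow]:
    """Sliding-window schedule over the epoch.

    Windows start at 0, step, 2*step, ... while they fit inside the epoch.
    The ms label spans the first to the last sample inclusively, so a
    6-sample window at 62.5 Hz is labeled as 80 ms long (e.g. 144-224 ms for
    samples 9-14).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if win_len > n_samples:
        raise ValueError("window longer than the epoch")
    ms_per_sample = 1000.0 / sampling_rate_hz
    out = []
    start = 0
    while start + win_len <= n_samples:
        out.append(
            TemporalWindow(
                start_sample=start,
                stop_sample=start + win_len,
                start_ms=epoch_start_ms + start * ms_per_sample,
                end_ms=epoch_start_ms + (start + win_len - 1) * ms_per_sample,
            )
        )
        start += step
    return out


@dataclass
class RateMap:
    """Accuracy map over electrodes and/or temporal windows.

    ``accuracies`` has one entry per cell (NaN for failed cells);
    ``reports`` holds the per-cell exact binomial report (None if failed);
    ``failures`` maps cell index -> cause for cells whose SVD failed.
    """

    electrodes: list[int] | None
    windows: list[TemporalWindow] | None
    accuracies: np.ndarray
    reports: list
    failures: dict

    @property
    def shape(self) -> tuple[int, ...]:
        return self.accuracies.shape


@dataclass
class WindowResult:
    """Full representational chain for one temporal window."""

    window: TemporalWindow
    result: CVResult
    similarity: SimilaritySpace
    embedding: Embedding
    dendrogram: Dendrogram
    report: BinomialReport


def _cell_cfg(cfg: CVConfig, seed_seq: np.random.SeedSequence) -> CVConfig:
    # derive an independent 31-bit seed for this cell from the master seed
    child = int(seed_seq.generate_state(1)[0] % (2 ** 31))
    return replace(cfg, seed=child)


def _report(res: CVResult, level: str, ds: TrialSpaceDataset, cfg: CVConfig) -> BinomialReport:
    n_classes = np.unique(ds.labels(level)).size
    return binomial_pvalue(
        res.confusion.total_correct, res.confusion.n_trials, cfg.n_folds_outer, 1.0 / n_classes
    )


def per_electrode(ds: TrialSpaceDataset, level: str, cfg: CVConfig | None = None) -> RateMap:
    """Independent decoding from each electrode's full time course."""
    if cfg is None:
        cfg = CVConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(ds.n_electrodes)
    acc = np.full(ds.n_electrodes, np.nan)
    reports: list = [None] * ds.n_electrodes
    failures: dict = {}
    for e in range(ds.n_electrodes):
        sub = select_features(ds, FeatureSelector((e,), (0, ds.n_time_samples)))
        try:
            res = crossvalidate(sub, level, _cell_cfg(cfg, seeds[e]))
        except SVDError as err:
            logger.warning("electrode %d: SVD failed (%s); cell left missing", e, err)
            failures[e] = str(err)
            continue
        acc[e] = res.accuracy
        reports[e] = _report(res, level, sub, cfg)
    return RateMap(
        electrodes=list(range(ds.n_electrodes)),
        windows=None,
        accuracies=acc,
        reports=reports,
        failures=failures,
    )


def per_window(
    ds: TrialSpaceDataset,
    level: str,
    cfg: CVConfig | None = None,
    win_len: int = 6,
    step: int = 3,
) -> list[WindowResult]:
    """Decoding over sliding temporal windows, all electrodes together.

    Each window runs the full chain: cross-validated confusion matrix,
    similarity/distance conversion, classical MDS and UPGMA.
    """
    if cfg is None:
        cfg = CVConfig()
    windows = temporal_windows(
        ds.n_time_samples, win_len, step, ds.sampling_rate_hz, ds.epoch_start_ms
    )
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(windows))
    out: list[WindowResult] = []
    for w, win in enumerate(windows):
        sub = select_features(
            ds,
            FeatureSelector(tuple(range(ds.n_electrodes)), (win.start_sample, win.stop_sample)),
        )
        res = crossvalidate(sub, level, _cell_cfg(cfg, seeds[w]))
        sim = confusion_to_distance(res.confusion.normalized)
        out.append(
            WindowResult(
                window=win,
                result=res,
                similarity=sim,
                embedding=classical_mds(sim.D),
                dendrogram=upgma(sim.D),
                report=_report(res, level, sub, cfg),
            )
        )
    return out


def per_electrode_window(
    ds: TrialSpaceDataset,
    level: str,
    cfg: CVConfig | None = None,
    win_len: int = 6,
    step: int = 3,
) -> RateMap:
    """Single-electrode, single-window decoding grid (electrodes x windows)."""
    if cfg is None:
        cfg = CVConfig()
    windows = temporal_windows(
        ds.n_time_samples, win_len, step, ds.sampling_rate_hz, ds.epoch_start_ms
    )
    n_e, n_w = ds.n_electrodes, len(windows)
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_e * n_w)
    acc = np.full((n_e, n_w), np.nan)
    reports = [[None] * n_w for _ in range(n_e)]
    failures: dict = {}
    for e in range(n_e):
        for w, win in enumerate(windows):
            sub = select_features(
                ds, FeatureSelector((e,), (win.start_sample, win.stop_sample))
            )
            try:
                res = crossvalidate(sub, level, _cell_cfg(cfg, seeds[e * n_w + w]))
            except SVDError as err:
                logger.warning(
                    "electrode %d window %d: SVD failed (%s); cell left missing", e, w, err
                )
                failures[(e, w)] = str(err)
                continue
            acc[e, w] = res.accuracy
            reports[e][w] = _report(res, level, sub, cfg)
    return RateMap(
        electrodes=list(range(n_e)),
        windows=windows,
        accuracies=acc,
        reports=reports,
        failures=failures,
    )
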