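"""Synthetic trial-space EEG with a planted category hierarchy.

The generator emulates the reference design: 6 categories x 12 exemplars x
72 trials recorded over 124 electrodes at 62.5 Hz (32 post-stimulus samples),
i.e. 5,184 trials of 3,968 features.  Signal is planted as a three-level
hierarchy of spatiotemporal templates — superordinate (Animate/Inanimate),
category, exemplar — with configurable variance at each level, optionally
confined to an electrode subset and sample window, plus i.i.d. (or AR(1)
temporally / spatially correlated) Gaussian trial noise.  Every downstream
stage of the decoding/RSA chain is thereby testable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import TrialSpaceDataset, reshape_spacetime_to_trialspace

__all__ = ["GeneratorConfig", "TemplateSet", "make_templates", "simulate_dataset"]

# Reference hierarchy: Human Body, Human Face, Animal Body, Animal Face are
# Animate (superordinate 0); Fruit Vegetable, Inanimate Object are Inanimate (1).
DEFAULT_HIERARCHY: dict[int, int] = {0: 0, 1: 0, 2: 0, 3: 0, 4: 1, 5: 1}

# refuse to allocate more than ~4 GiB for the trial matrix
_MAX_BYTES = 4 << 30


class InvalidConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study-design and signal parameters for the synthetic generator.

    Variance components are per-entry template variances (arbitrary squared
    voltage units) at each hierarchy level; ``var_noise`` is the per-feature
    trial-noise variance.  ``signal_electrodes`` / ``signal_window`` confine
    all templates to an electrode subset x half-open sample window (for
    searchlight localization tests); outside that mask templates are zero.
    """

    n_electrodes: int = 124
    n_time_samples: int = 32
    sampling_rate_hz: float = 62.5
    n_categories: int = 6
    n_exemplars_per_category: int = 12
    n_trials_per_exemplar: int = 72
    hierarchy: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_HIERARCHY))
    var_superordinate: float = 1.0
    var_category: float = 1.0
    var_exemplar: float = 0.5
    var_noise: float = 4.0
    signal_electrodes: tuple[int, ...] | None = None
    signal_window: tuple[int, int] | None = None
    temporal_smoothness: int = 3
    noise_model: str = "iid"  # "iid" or "ar1"
    noise_ar1_rho: float = 0.5
    noise_spatial_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_electrodes",
            "n_time_samples",
            "n_categories",
            "n_exemplars_per_category",
            "n_trials_per_exemplar",
        ):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        for name in ("var_superordinate", "var_category", "var_exemplar", "var_noise"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if set(self.hierarchy) != set(range(self.n_categories)):
            raise InvalidConfigError(
                "hierarchy must assign every category index 0..n_categories-1 "
                "to a superordinate"
            )
        if self.signal_window is not None:
            lo, hi = self.signal_window
            if not (0 <= lo < hi <= self.n_time_samples):
                raise InvalidConfigError(
                    f"signal_window [{lo}, {hi}) outside [0, {self.n_time_samples})"
                )
        if self.signal_electrodes is not None:
            if any(e < 0 or e >= self.n_electrodes for e in self.signal_electrodes):
                raise InvalidConfigError("signal_electrodes outside electrode range")
        if self.temporal_smoothness < 1:
            raise InvalidConfigError("temporal_smoothness must be >= 1")
        if self.noise_model not in ("iid", "ar1"):
            raise InvalidConfigError("noise_model must be 'iid' or 'ar1'")

    @property
    def n_exemplars(self) -> int:
        return self.n_categories * self.n_exemplars_per_category

    @property
    def n_trials(self) -> int:
        return self.n_exemplars * self.n_trials_per_exemplar

    @property
    def n_features(self) -> int:
        return self.n_electrodes * self.n_time_samples

    @property
    def n_superordinates(self) -> int:
        return len(set(self.hierarchy.values()))

    def exemplar_category(self, exemplar: int) -> int:
        """Category of exemplar index (exemplars are numbered category-major)."""
        return exemplar // self.n_exemplars_per_category


@dataclass
class TemplateSet:
    """Expected spatiotemporal patterns at the three hierarchy levels.

    Each entry is an n_electrodes x n_time_samples matrix in trial-data
    (arbitrary voltage) units.  The expected pattern of exemplar ``e`` in
    category ``c`` under superordinate ``s`` is
    ``superordinate[s] + category[c] + exemplar[e]``.
    """

    superordinate: np.ndarray  # (n_super, n_e, n_t)
    category: np.ndarray  # (n_cat, n_e, n_t)
    exemplar: np.ndarray  # (n_ex, n_e, n_t)
    config: GeneratorConfig

    def exemplar_pattern(self, exemplar: int) -> np.ndarray:
        cfg = self.config
        c = cfg.exemplar_category(exemplar)
        s = cfg.hierarchy[c]
        return self.superordinate[s] + self.category[c] + self.exemplar[exemplar]


def _smooth_templates(
    rng: np.random.Generator, shape: tuple[int, ...], var: float, width: int
) -> np.ndarray:
    """White Gaussian draws, moving-averaged along time, rescaled to variance var.

    Averaging ``width`` i.i.d. draws scales the variance by 1/width, so the
    result is multiplied back up; entries near the epoch edges use a shorter
    (reflected) window, keeping the per-entry variance approximately var.
    """
    if var == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if width > 1:
        kernel = np.ones(width) / width
        padded = np.pad(white, [(0, 0)] * (white.ndim - 1) + [(width, width)], mode="reflect")
        smooth = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, padded
        )[..., width:-width]
        smooth *= np.sqrt(width)  # undo the variance shrink of the average
    else:
        smooth = white
    return smooth * np.sqrt(var)


def _mask(cfg: GeneratorConfig) -> np.ndarray | None:
    if cfg.signal_electrodes is None and cfg.signal_window is None:
        return None
    m = np.zeros((cfg.n_electrodes, cfg.n_time_samples))
    rows = (
        list(cfg.signal_electrodes)
        if cfg.signal_electrodes is not None
        else slice(None)
    )
    lo, hi = cfg.signal_window if cfg.signal_window is not None else (0, cfg.n_time_samples)
    m[rows, lo:hi] = 1.0
    return m


def make_templates(config: GeneratorConfig) -> TemplateSet:
    """Draw the hierarchy of spatiotemporal signal templates.

    Deterministic given ``config.seed``.  With all signal variances zero the
    templates are all-zero; with a signal mask set, entries outside
    ``signal_electrodes x signal_window`` are exactly zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n_e, n_t = config.n_electrodes, config.n_time_samples
    w = config.temporal_smoothness
    sup = _smooth_templates(rng, (config.n_superordinates, n_e, n_t), config.var_superordinate, w)
    cat = _smooth_templates(rng, (config.n_categories, n_e, n_t), config.var_category, w)
    ex = _smooth_templates(rng, (config.n_exemplars, n_e, n_t), config.var_exemplar, w)
    mask = _mask(config)
    if mask is not None:
        sup = sup * mask
        cat = cat * mask
        ex = ex * mask
    return TemplateSet(superordinate=sup, category=cat, exemplar=ex, config=config)


def _noise_epochs(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> np.ndarray:
    shape = (n, cfg.n_electrodes, cfg.n_time_samples)
    if cfg.var_noise == 0:
        return np.zeros(shape)
    z = rng.standard_normal(shape)
    if cfg.noise_model == "ar1":
        # AR(1) along time with unit marginal variance, then spatial mixing
        rho = cfg.noise_ar1_rho
        out = np.empty_like(z)
        out[..., 0] = z[..., 0]
        for t in range(1, cfg.n_time_samples):
            out[..., t] = rho * out[..., t - 1] + np.sqrt(1 - rho ** 2) * z[..., t]
        r = cfg.noise_spatial_rho
        C = np.full((cfg.n_electrodes, cfg.n_electrodes), r)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        z = np.einsum("ij,njt->nit", L, out)
    return z * np.sqrt(cfg.var_noise)


def simulate_dataset(config: GeneratorConfig) -> TrialSpaceDataset:
    """Simulate one participant's trial-space dataset.

    Each trial is its exemplar's expected pattern plus independent noise,
    reshaped to a feature row in electrode-major order.  Labels are balanced:
    exactly ``n_trials_per_exemplar`` rows per exemplar.  Multi-participant
    cohorts are produced by varying ``config.seed``.
    """
    needed = config.n_trials * config.n_features * 8
    if needed > _MAX_BYTES:
        raise MemoryError(
            f"requested dataset needs {needed / 2**30:.1f} GiB "
            f"({config.n_trials} trials x {config.n_features} features); "
            "reduce the design size"
        )
    templates = make_templates(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n_ex, n_rep = config.n_exemplars, config.n_trials_per_exemplar
    exemplar_labels = np.repeat(np.arange(n_ex), n_rep)
    category_labels = exemplar_labels // config.n_exemplars_per_category
    epochs = np.empty((config.n_trials, config.n_electrodes, config.n_time_samples))
    for e in range(n_ex):
        rows = slice(e * n_rep, (e + 1) * n_rep)
        epochs[rows] = templates.exemplar_pattern(e)
    epochs += _noise_epochs(rng, config, config.n_trials)
    return reshape_spacetime_to_trialspace(
        epochs,
        exemplar_labels,
        category_labels,
        sampling_rate_hz=config.sampling_rate_hz,
    )
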