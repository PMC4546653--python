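"""End-to-end analysis recipes over one or more participants.

A run executes a list of analyses — e.g. six-class category decoding,
72-class exemplar decoding, within-category (single-category exemplar) and
between-category (category-subset) classifications, optionally with
searchlight variants — independently for each participant, then aggregates a
cross-participant summary (mean accuracy, exact binomial p and effect size
from the floored mean per-fold correct count, unbiased sample SD).  Every
artifact (confusion CSV, similarity/distance CSV, MDS coordinates, Newick
dendrogram, JSON stats, manifest of seeds / per-fold component counts /
fold sizes) is written under one directory per analysis, and a fixed master
seed reproduces the bundle deterministically.

Participants are independent units: a participant whose decomposition fails
is excluded from the summary with an explicit count rather than aborting
the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classify import CVConfig, CVResult, SVDError, crossvalidate
from .dataio import TrialSpaceDataset, load_dataset
from .embedding import classical_mds, upgma
from .rdm import confusion_to_distance
from .searchlight import per_electrode, per_electrode_window, per_window
from .simulate import GeneratorConfig, simulate_dataset
from .stats import binomial_pvalue, sample_std, significance_threshold

__all__ = ["AnalysisSpec", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisSpec:
    """One classification recipe.

    ``level`` is 'category' or 'exemplar'; ``categories`` optionally restricts
    trials to a category subset first (a single category + level='exemplar'
    is a within-category analysis; a pair + level='category' is a
    between-category analysis).  ``searchlight`` lists any of 'electrode',
    'window', 'electrode_window'.
    """

    name: str
    level: str = "category"
    categories: tuple[int, ...] | None = None
    searchlight: tuple[str, ...] = ()


@dataclass
class RunConfig:
    """Inputs, analyses and cross-validation settings for a pipeline run."""

    analyses: list[AnalysisSpec]
    dataset_paths: list[str] | None = None
    generator: GeneratorConfig | None = None
    n_participants: int = 1
    cv: CVConfig = field(default_factory=CVConfig)
    alpha: float = 0.01
    out_dir: str | None = None
    master_seed: int = 0


def _participant_datasets(cfg: RunConfig):
    if cfg.dataset_paths:
        for p, path in enumerate(cfg.dataset_paths):
            yield p, load_dataset(path)
    elif cfg.generator is not None:
        seeds = np.random.SeedSequence(cfg.master_seed).spawn(cfg.n_participants)
        for p in range(cfg.n_participants):
            gen = GeneratorConfig(
                **{
                    **asdict(cfg.generator),
                    "seed": int(seeds[p].generate_state(1)[0] % (2 ** 31)),
                }
            )
            yield p, simulate_dataset(gen)
    else:
        raise ValueError("RunConfig needs dataset_paths or a generator")


def _subset(ds: TrialSpaceDataset, categories) -> TrialSpaceDataset:
    if categories is None:
        return ds
    mask = np.isin(ds.category_labels, list(categories))
    if not mask.any():
        raise ValueError(f"no trials in categories {categories}")
    return ds.subset_trials(np.flatnonzero(mask))


def _write_square_csv(path: Path, M: np.ndarray, labels) -> None:
    import pandas as pd

    pd.DataFrame(M, index=labels, columns=labels).to_csv(path)


def _analysis_outputs(res: CVResult, out: Path | None, labels) -> dict:
    """Run the representational chain on a confusion matrix; write artifacts.

    A zero confusion diagonal (a class never classified correctly) leaves the
    self-normalized similarity undefined; the chain is skipped for that
    classification with a logged cause and ``None`` entries.
    """
    CM = res.confusion.normalized
    try:
        sim = confusion_to_distance(CM)
    except ValueError as err:
        logger.warning("representational chain skipped: %s", err)
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            _write_square_csv(out / "confusion_counts.csv", res.confusion.counts, labels)
            _write_square_csv(out / "confusion_normalized.csv", CM, labels)
        return {"similarity": None, "embedding": None, "dendrogram": None}
    emb = classical_mds(sim.D)
    dend = upgma(sim.D)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _write_square_csv(out / "confusion_counts.csv", res.confusion.counts, labels)
        _write_square_csv(out / "confusion_normalized.csv", CM, labels)
        _write_square_csv(out / "similarity.csv", sim.S, labels)
        np.savetxt(out / "distance_condensed.csv", sim.D[None, :], delimiter=",")
        import pandas as pd

        pd.DataFrame(
            emb.coordinates,
            index=labels,
            columns=[f"dim{j + 1}" for j in range(emb.n_dims)],
        ).to_csv(out / "mds_coordinates.csv")
        np.savetxt(out / "mds_eigenvalues.csv", emb.eigenvalues[None, :], delimiter=",")
        (out / "dendrogram.newick").write_text(
            dend.to_newick([str(c) for c in labels]) + "\n"
        )
    return {"similarity": sim, "embedding": emb, "dendrogram": dend}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every analysis for every participant and summarize.

    Returns a results bundle: per analysis, the per-participant CV results
    and representational structures, plus a cross-participant summary row
    (mean accuracy %, binomial p, effect size d, sample SD s, threshold at
    ``cfg.alpha``) and a manifest of seeds and per-fold component choices.
    """
    out_root = Path(cfg.out_dir) if cfg.out_dir else None
    bundle: dict = {"analyses": {}, "manifest": {"master_seed": cfg.master_seed}}
    datasets = list(_participant_datasets(cfg))
    for spec in cfg.analyses:
        per_part = []
        failures = 0
        manifest_rows = []
        for p, ds in datasets:
            sub = _subset(ds, spec.categories)
            try:
                res = crossvalidate(sub, spec.level, cfg.cv)
            except SVDError as err:
                logger.warning(
                    "analysis %s participant %d excluded: %s", spec.name, p, err
                )
                failures += 1
                continue
            labels = [int(c) for c in res.confusion.class_list]
            out = out_root / spec.name / f"participant_{p}" if out_root else None
            chain = _analysis_outputs(res, out, labels)
            entry = {"participant": p, "result": res, **chain}
            for mode in spec.searchlight:
                if mode == "electrode":
                    entry["rate_map_electrode"] = per_electrode(sub, spec.level, cfg.cv)
                elif mode == "window":
                    entry["window_results"] = per_window(sub, spec.level, cfg.cv)
                elif mode == "electrode_window":
                    entry["rate_map_grid"] = per_electrode_window(sub, spec.level, cfg.cv)
                else:
                    raise ValueError(f"unknown searchlight mode {mode!r}")
            per_part.append(entry)
            manifest_rows.append(
                {
                    "participant": p,
                    "fold_k": res.fold_k,
                    "fold_correct": res.fold_correct,
                    "fold_sizes": res.fold_sizes,
                }
            )
        if not per_part:
            raise RuntimeError(f"analysis {spec.name}: all participants failed")
        accs = [e["result"].accuracy for e in per_part]
        first = per_part[0]["result"]
        n_trials = first.confusion.n_trials
        n_classes = first.confusion.class_list.size
        chance = 1.0 / n_classes
        mean_correct = int(np.floor(np.mean([e["result"].confusion.total_correct for e in per_part])))
        report = binomial_pvalue(mean_correct, n_trials, cfg.cv.n_folds_outer, chance)
        summary = {
            "analysis": spec.name,
            "level": spec.level,
            "n_classes": n_classes,
            "n_trials": n_trials,
            "chance_pct": round(100.0 * chance, 2),
            "mean_accuracy_pct": round(100.0 * float(np.mean(accs)), 2),
            "p": report.p_value,
            "d": report.d,
            "s": round(100.0 * sample_std(accs), 2) if len(accs) >= 2 else None,
            "threshold_pct": significance_threshold(
                n_trials, cfg.cv.n_folds_outer, chance, cfg.alpha
            ),
            "n_participants": len(per_part),
            "n_excluded": failures,
        }
        bundle["analyses"][spec.name] = {"participants": per_part, "summary": summary}
        bundle["manifest"][spec.name] = manifest_rows
        if out_root:
            (out_root / spec.name).mkdir(parents=True, exist_ok=True)
            (out_root / spec.name / "summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
    if out_root:
        out_root.mkdir(parents=True, exist_ok=True)
        (out_root / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2, default=str) + "\n"
        )
        (out_root / "summary_table.json").write_text(
            json.dumps(
                [a["summary"] for a in bundle["analyses"].values()], indent=2
            )
            + "\n"
        )
    return bundle
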