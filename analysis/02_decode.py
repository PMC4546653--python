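#!/usr/bin/env python
"""Cross-validated decoding recipes over the synthetic cohort.

Runs the classification suite on the datasets written by 01_simulate.py:
six-class category decoding, 36-class exemplar decoding, within-category
exemplar decoding for the first category, and a two-category (first vs.
last) classification — each with ten-fold CV and nested component selection.
Per-participant confusion matrices, similarity structures, MDS coordinates
and dendrograms land under results/decoding/<analysis>/participant_<p>/, and
the cross-participant summary (mean accuracy, exact binomial p, effect size
d, sample SD s, alpha = 0.01 threshold) in results/decoding/summary_table.json.
"""

import json
from pathlib import Path

from eegrsa import AnalysisSpec, CVConfig, RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "decoding"


def main() -> None:
    paths = sorted(str(p) for p in DATA.glob("participant_*.h5"))
    if not paths:
        raise SystemExit("no datasets found; run analysis/01_simulate.py first")
    cfg = RunConfig(
        analyses=[
            AnalysisSpec(name="category_6class", level="category"),
            AnalysisSpec(name="exemplar_36class", level="exemplar"),
            AnalysisSpec(name="within_category_0", level="exemplar", categories=(0,)),
            AnalysisSpec(name="between_0_vs_5", level="category", categories=(0, 5)),
        ],
        dataset_paths=paths,
        cv=CVConfig(k_grid=(3, 6, 12, 24, 48), seed=11),
        alpha=0.01,
        out_dir=str(OUT),
        master_seed=11,
    )
    bundle = run_pipeline(cfg)
    print(f"{len(paths)} participants, {len(cfg.analyses)} analyses -> {OUT}\n")
    for name, entry in bundle["analyses"].items():
        s = entry["summary"]
        print(
            f"{name}: mean accuracy {s['mean_accuracy_pct']}% "
            f"(chance {s['chance_pct']}%, threshold {s['threshold_pct']}%), "
            f"p = {s['p']:.3g}, d = {s['d']:.2f}, s = {s['s']}%"
        )
    print(f"\nsummary table: {OUT / 'summary_table.json'}")


if __name__ == "__main__":
    main()
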