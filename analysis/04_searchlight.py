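#!/usr/bin/env python
"""Spatially and temporally resolved decoding maps for one participant.

Runs the three searchlight variants on participant 0's dataset at the
category level: per-electrode (full time course per electrode), per temporal
window (all electrodes, 6-sample/80-ms windows advancing 3 samples/48 ms),
and the per-electrode x window grid.  Accuracy maps with exact binomial
reports are written as long-format CSV under results/searchlight/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eegrsa import CVConfig, load_dataset, per_electrode, per_electrode_window, per_window

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "searchlight"

CV = CVConfig(k_grid=(3, 6, 12), seed=31)


def main() -> None:
    path = ROOT / "data" / "participant_0.h5"
    if not path.exists():
        raise SystemExit("no datasets found; run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(path)

    rate_e = per_electrode(ds, "category", CV)
    pd.DataFrame(
        {
            "electrode": rate_e.electrodes,
            "accuracy": rate_e.accuracies,
            "p": [r.p_value if r else np.nan for r in rate_e.reports],
            "d": [r.d if r else np.nan for r in rate_e.reports],
        }
    ).to_csv(OUT / "per_electrode.csv", index=False)
    best_e = int(np.nanargmax(rate_e.accuracies))
    print(
        f"per-electrode: best electrode {best_e} at "
        f"{100 * rate_e.accuracies[best_e]:.2f}% accuracy"
    )

    window_results = per_window(ds, "category", CV)
    pd.DataFrame(
        {
            "window": [r.window.label for r in window_results],
            "accuracy": [r.result.accuracy for r in window_results],
            "p": [r.report.p_value for r in window_results],
            "d": [r.report.d for r in window_results],
        }
    ).to_csv(OUT / "per_window.csv", index=False)
    best_w = max(window_results, key=lambda r: r.result.accuracy)
    print(
        f"per-window: peak {100 * best_w.result.accuracy:.2f}% in {best_w.window.label} "
        f"across {len(window_results)} windows"
    )

    grid = per_electrode_window(ds, "category", CV)
    rows = []
    for e in grid.electrodes:
        for w, win in enumerate(grid.windows):
            rep = grid.reports[e][w]
            rows.append(
                {
                    "electrode": e,
                    "window": win.label,
                    "accuracy": grid.accuracies[e, w],
                    "p": rep.p_value if rep else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(OUT / "per_electrode_window.csv", index=False)
    ge, gw = np.unravel_index(np.nanargmax(grid.accuracies), grid.accuracies.shape)
    print(
        f"grid: best cell electrode {ge} x {grid.windows[gw].label} at "
        f"{100 * grid.accuracies[ge, gw]:.2f}%"
    )
    if grid.failures:
        print(f"{len(grid.failures)} grid cells failed and were left missing")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
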