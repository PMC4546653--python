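#!/usr/bin/env python
"""Simulate a small synthetic cohort with the planted category hierarchy.

Generates three "participants" at a scaled-down version of the reference
design (16 electrodes x 32 samples at 62.5 Hz; 6 categories x 6 exemplars x
24 trials = 864 trials of 512 features each) with the default Animate /
Inanimate superordinate structure, and writes one HDF5 container per
participant under results/data/.  Downstream drivers load these files.
"""

from pathlib import Path

import numpy as np

from eegrsa import GeneratorConfig, save_dataset, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
MASTER_SEED = 2026
N_PARTICIPANTS = 3


def participant_config(seed: int) -> GeneratorConfig:
    return GeneratorConfig(
        n_electrodes=16,
        n_time_samples=32,
        n_categories=6,
        n_exemplars_per_category=6,
        n_trials_per_exemplar=24,
        var_superordinate=1.0,
        var_category=1.0,
        var_exemplar=0.5,
        # heavy trial noise keeps the cohort's decoding well below ceiling,
        # in the mid-range regime typical of single-trial EEG
        var_noise=80.0,
        seed=seed,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in np.random.SeedSequence(MASTER_SEED).spawn(N_PARTICIPANTS)
    ]
    for p, seed in enumerate(seeds):
        ds = simulate_dataset(participant_config(seed))
        path = OUT / f"participant_{p}.h5"
        save_dataset(ds, path)
        print(
            f"participant {p}: {ds.n_trials} trials x {ds.n_features} features "
            f"({ds.n_electrodes} electrodes x {ds.n_time_samples} samples), "
            f"seed {seed} -> {path}"
        )
    print(f"wrote {N_PARTICIPANTS} datasets to {OUT}")


if __name__ == "__main__":
    main()
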