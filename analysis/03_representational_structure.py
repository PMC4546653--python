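#!/usr/bin/env python
"""Representational structure of the exemplar-level confusions.

Loads participant 0's dataset, runs the 36-class exemplar decoding, converts
the confusion matrix into the similarity space and distance vector, embeds
the exemplars with classical MDS, clusters them with UPGMA, reorders the
confusion matrix into dendrogram leaf order, and tests category separation
along each MDS dimension with two-tailed rank-sum tests.  Outputs under
results/rsa/: the reordered confusion, MDS coordinates with eigenvalues, a
Newick dendrogram, and the separability table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eegrsa import (
    CVConfig,
    classical_mds,
    confusion_to_distance,
    crossvalidate,
    load_dataset,
    ranksum_separability,
    reorder_confusion,
    upgma,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "rsa"


def main() -> None:
    path = ROOT / "data" / "participant_0.h5"
    if not path.exists():
        raise SystemExit("no datasets found; run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(path)
    res = crossvalidate(ds, "exemplar", CVConfig(k_grid=(3, 6, 12, 24, 48), seed=23))
    chance = 100.0 / np.unique(ds.exemplar_labels).size
    print(f"exemplar decoding accuracy: {100 * res.accuracy:.2f}% (chance {chance:.2f}%)")

    sim = confusion_to_distance(res.confusion.normalized)
    if sim.clipped:
        print("note: some negative raw distances were clipped to 0")
    emb = classical_mds(sim.D)
    dend = upgma(sim.D)
    exemplars = [int(c) for c in res.confusion.class_list]
    categories = [e // 6 for e in exemplars]  # 6 exemplars per category here

    pd.DataFrame(
        emb.coordinates,
        index=exemplars,
        columns=[f"dim{j + 1}" for j in range(emb.n_dims)],
    ).to_csv(OUT / "mds_coordinates.csv")
    np.savetxt(OUT / "mds_eigenvalues.csv", emb.eigenvalues[None, :], delimiter=",")
    (OUT / "dendrogram.newick").write_text(
        dend.to_newick([f"c{c}e{e}" for e, c in zip(exemplars, categories)]) + "\n"
    )
    reordered = reorder_confusion(res.confusion.normalized, dend)
    order = dend.leaf_order
    pd.DataFrame(
        reordered,
        index=[exemplars[i] for i in order],
        columns=[exemplars[i] for i in order],
    ).to_csv(OUT / "confusion_dendrogram_order.csv")

    table = ranksum_separability(emb, categories, dims=range(min(4, emb.n_dims)))
    rows = [
        {"cat_a": a, "cat_b": b, "dim": dim + 1, "p": p}
        for (a, b), per_dim in table.p_values.items()
        for dim, p in per_dim.items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "separability_ranksum.csv", index=False)
    n_sep = (
        df.groupby(["cat_a", "cat_b"])["p"].min() < 0.01
    ).sum()
    print(
        f"{n_sep}/{df.groupby(['cat_a', 'cat_b']).ngroups} category pairs separable "
        f"at alpha = 0.01 on at least one of the first {df['dim'].max()} MDS dimensions"
    )
    top = dend.top_cut()
    top_cats = tuple(sorted({categories[i] for i in cut}) for cut in top)
    print(f"dendrogram top cut splits categories {top_cats[0]} | {top_cats[1]}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
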