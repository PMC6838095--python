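#!/usr/bin/env python
"""Phylogenetic signal and evolutionary allometry of the study dataset.

Multivariate Blomberg's K (permutation test, 1000 rounds) for PC1-3,
PC1-3 + lnCS, lnCS, CS and the full tangent coordinates, plus a D-PGLS
regression of shape on lnCS.  Run 01 and 02 first.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from shapeshift.morphometrics import gpa, read_landmarks_csv
from shapeshift.phylo_stats import (TraitMatrix, dpgls_shape_size, kmult)
from shapeshift.trees import read_tree

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 4242
N_PERM = 1000


def main() -> None:
    tree = read_tree((ROOT / "dataset" / "tree.nwk").read_text())
    scores = pd.read_csv(ROOT / "shape_space" / "specimen_scores.csv", index_col=0)
    lm = read_landmarks_csv(ROOT / "dataset" / "landmarks.csv")
    aligned = gpa(lm)

    sp = np.asarray(aligned.species, dtype=object)
    order = list(dict.fromkeys(aligned.species))
    mean = lambda col: np.array([scores.loc[sp == s, col].mean() for s in order])
    coords = np.stack([aligned.flat[sp == s].mean(axis=0) for s in order])

    inputs = {
        "PC1-3": np.column_stack([mean(c) for c in ("PC1", "PC2", "PC3")]),
        "PC1-3+lnCS": np.column_stack([mean(c) for c in ("PC1", "PC2", "PC3", "lnCS")]),
        "lnCS": mean("lnCS")[:, None],
        "CS": mean("CS")[:, None],
        "coords": coords,
    }
    out = {}
    for i, (name, vals) in enumerate(inputs.items()):
        res = kmult(tree, TraitMatrix(order, vals), n_perm=N_PERM, seed=SEED + i)
        out[name] = {"K": round(res.K, 3), "p": res.p_value}
        print(f"K({name}) = {res.K:.3f}  (p = {res.p_value:.4g}, "
              f"{N_PERM} permutation rounds)")

    r2, p = dpgls_shape_size(tree, TraitMatrix(order, coords),
                             TraitMatrix(order, mean("lnCS")[:, None]),
                             n_perm=N_PERM, seed=SEED + 99)
    out["allometry"] = {"r2": round(r2, 4), "p": p}
    print(f"D-PGLS shape ~ lnCS: r2 = {r2:.4f}, p = {p:.4g}")

    (ROOT / "signal").mkdir(parents=True, exist_ok=True)
    (ROOT / "signal" / "kmult.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {ROOT / 'signal'}")


if __name__ == "__main__":
    main()
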