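"""End-to-end orchestration: landmarks + trees -> shape space -> signal
tests -> adaptive-regime reconstruction -> model comparison.

The pipeline reproduces the analysis design of a multi-regime,
multivariate evolutionary-modelling study: generalized Procrustes
alignment, between-group PCA (species means in the eigenanalysis,
individuals and optionally fossils projected post hoc), multivariate
phylogenetic signal (Blomberg's K generalization) and allometry
(D-PGLS), then the stepwise OU surface analysis per candidate tree plus
an AICc comparison against Brownian motion and single-optimum OU.

Every stage's output is written as a plain-text artifact and the summary
JSON is assembled from those artifacts only, so identical configs and
seeds give byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics as gm
from . import ou
from . import phylo_stats as ps
from .trees import TimeTree, read_tree, write_tree

__all__ = ["PipelineConfig", "run_pipeline", "sensitivity_over_trees"]


class ReconciliationError(ValueError):
    """Species names in the landmark data and tree tips do not match."""


@dataclass
class PipelineConfig:
    landmarks: "gm.LandmarkSet | str"
    trees: list            # TimeTree objects or paths, first is primary
    bgpca_variant: str = "fossils_in_eigen"   # or "fossils_projected"
    traits: list[str] = field(default_factory=lambda: ["PC1", "PC2", "PC3", "lnCS"])
    n_perm: int = 1000
    seed: int = 0
    outdir: str | None = None
    n_grid: int = 40
    standardize_traits: bool = False
    kmult_scores_from: str = "group_means"    # or "specimen_means"
    n_convention: str = "tips_x_traits"

    def __post_init__(self):
        if not self.traits:
            raise ValueError("trait list must be non-empty")
        if self.bgpca_variant not in ("fossils_in_eigen", "fossils_projected"):
            raise ValueError(f"unknown bgpca variant {self.bgpca_variant!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML mapping of the dataclass fields."""
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        for f in [cfg.landmarks, *cfg.trees]:
            if isinstance(f, str) and not Path(f).exists():
                raise FileNotFoundError(f"configured input does not exist: {f}")
        return cfg


def _load_tree(t) -> TimeTree:
    if isinstance(t, TimeTree):
        return t
    return read_tree(Path(t).read_text())


def _load_landmarks(lm) -> "gm.LandmarkSet":
    if isinstance(lm, gm.LandmarkSet):
        return lm
    return gm.read_landmarks_csv(lm)


def _species_table(aligned: "gm.AlignedShapes", space: "gm.ShapeSpace",
                   scores_from: str) -> pd.DataFrame:
    """One row per species: PC scores, lnCS, CS and mean tangent coords."""
    sp = np.asarray(aligned.species, dtype=object)
    rows = {}
    for s in dict.fromkeys(aligned.species):
        m = sp == s
        if scores_from == "specimen_means":
            sc = gm.project(space, aligned.flat[m].mean(axis=0))[0]
        else:
            sc = space.specimen_scores[m].mean(axis=0)
        rows[s] = {
            **{f"PC{j + 1}": sc[j] for j in range(sc.size)},
            "CS": float(aligned.centroid_sizes[m].mean()),
            "lnCS": float(aligned.ln_centroid_sizes[m].mean()),
        }
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary dict."""
    rng = np.random.default_rng(config.seed)
    landmarks = _load_landmarks(config.landmarks)
    trees = [_load_tree(t) for t in config.trees]
    out = Path(config.outdir) if config.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: superimposition -----------------------------------------
    aligned = gm.gpa(landmarks)

    # --- stage 2: ordination ----------------------------------------------
    species_order = list(dict.fromkeys(aligned.species))
    fossil_species = sorted({s for s, f in zip(aligned.species, aligned.is_fossil) if f})
    if config.bgpca_variant == "fossils_in_eigen":
        eigen_groups = species_order
    else:
        eigen_groups = [s for s in species_order if s not in fossil_species]
    space = gm.bgpca(aligned, groups=aligned.species,
                     include_in_eigenanalysis=eigen_groups)

    table = _species_table(aligned, space, config.kmult_scores_from)
    mean_coords = pd.DataFrame(
        np.stack([aligned.flat[np.asarray(aligned.species, dtype=object) == s].mean(axis=0)
                  for s in table.index]),
        index=table.index)

    # --- stage 3: reconcile with the tree(s) --------------------------------
    tip_sets = [set(t.tip_labels) for t in trees]
    if any(s != tip_sets[0] for s in tip_sets[1:]):
        raise ReconciliationError("alternative trees have different tip sets")
    offenders = sorted(tip_sets[0] ^ set(table.index))
    if offenders:
        raise ReconciliationError(
            f"species/tip mismatch between landmarks and tree: {offenders}")
    order = [s for s in table.index]

    missing = [t for t in config.traits if t not in table.columns]
    if missing:
        raise ValueError(f"unknown traits requested: {missing}")
    tvals = table.loc[order, config.traits].to_numpy(dtype=float)
    if config.standardize_traits:
        tvals = (tvals - tvals.mean(axis=0)) / tvals.std(axis=0, ddof=1)
    traits = ps.TraitMatrix(species=order, values=tvals,
                            trait_names=list(config.traits))

    # --- stage 4: phylogenetic signal + allometry ---------------------------
    tree0 = trees[0]
    pc_names = [c for c in table.columns if c.startswith("PC")]
    coords_tm = ps.TraitMatrix(order, mean_coords.loc[order].to_numpy(),
                               [f"c{i}" for i in range(mean_coords.shape[1])])
    k_inputs = {
        "PC1-3": ps.TraitMatrix(order, table.loc[order, pc_names[:3]].to_numpy(), pc_names[:3]),
        "PC1-3+lnCS": ps.TraitMatrix(order, table.loc[order, pc_names[:3] + ["lnCS"]].to_numpy(),
                                     pc_names[:3] + ["lnCS"]),
        "lnCS": ps.TraitMatrix(order, table.loc[order, ["lnCS"]].to_numpy(), ["lnCS"]),
        "CS": ps.TraitMatrix(order, table.loc[order, ["CS"]].to_numpy(), ["CS"]),
        "coords": coords_tm,
    }
    k_results = {}
    for name, tm in k_inputs.items():
        res = ps.kmult(tree0, tm, n_perm=config.n_perm,
                       seed=int(rng.integers(2 ** 31)))
        k_results[name] = {"K": res.K, "p": res.p_value, "n_perm": res.n_permutations}
    size_tm = ps.TraitMatrix(order, table.loc[order, ["lnCS"]].to_numpy(), ["lnCS"])
    r2, p_allom = ps.dpgls_shape_size(tree0, coords_tm, size_tm,
                                      n_perm=config.n_perm,
                                      seed=int(rng.integers(2 ** 31)))
    # independence check among the modelled PC axes: the multi-regime OU
    # analysis treats traits as independent, so cross-axis PGLS r2 should
    # be negligible
    cross_pgls = {}
    for a, b in (("PC1", "PC2"), ("PC1", "PC3"), ("PC2", "PC3")):
        if a in table.columns and b in table.columns:
            r2ab, pab = ps.dpgls(
                tree0,
                ps.TraitMatrix(order, table.loc[order, [a]].to_numpy(), [a]),
                ps.TraitMatrix(order, table.loc[order, [b]].to_numpy(), [b]),
                n_perm=config.n_perm, seed=int(rng.integers(2 ** 31)))
            cross_pgls[f"{a}-{b}"] = {"r2": float(r2ab), "p": float(pab)}

    # --- stage 5: adaptive-regime search per tree ---------------------------
    per_tree = []
    for i, tree in enumerate(trees):
        res = ou.surface(tree, traits, n_grid=config.n_grid,
                         n_convention=config.n_convention)
        comp = ou.compare_models(tree, traits, surface_result=res,
                                 n_convention=config.n_convention)
        per_tree.append((res, comp))
        if out:
            regs = {int(v): int(r) for v, r in
                    zip(range(tree.n_nodes), res.painting.branch_regimes(tree))}
            (out / f"tree{i + 1}_regimes.nwk").write_text(
                write_tree(tree, regimes=regs))
            comp.to_csv(out / f"tree{i + 1}_model_comparison.csv")

    res0, comp0 = per_tree[0]
    summary = {
        "seed": config.seed,
        "n_specimens": landmarks.n_specimens,
        "n_species": len(order),
        "n_trees": len(trees),
        "bgpca_variant": config.bgpca_variant,
        "traits": list(config.traits),
        "bgpca_eigenvalues": [float(v) for v in space.eigenvalues],
        "kmult": k_results,
        "allometry": {"r2": float(r2), "p": float(p_allom), "n_perm": config.n_perm},
        "pc_cross_pgls": cross_pgls,
        "surface": res0.summary(),
        "regime_count": res0.k_prime,
        "half_lives": res0.summary()["half_lives"],
        "convergent_regimes": res0.convergent_regimes,
        "delta_aicc_bm": float(comp0.loc["BM", "AICc"] - comp0.loc["surface", "AICc"]),
        "delta_aicc_ou1": float(comp0.loc["OU1", "AICc"] - comp0.loc["surface", "AICc"]),
        "regime_count_per_tree": [r.k_prime for r, _ in per_tree],
    }
    if out:
        pd.DataFrame(space.specimen_scores,
                     index=aligned.specimen_ids).to_csv(out / "specimen_scores.csv")
        table.to_csv(out / "species_traits.csv")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def sensitivity_over_trees(config: PipelineConfig,
                           trees: list | None = None) -> pd.DataFrame:
    """Repeat the surface analysis over alternative trees and compare.

    Returns one row per tree with the regime count, shift placements
    (each shift identified by the tip set of its subtended clade) and an
    agreement flag against the first tree.
    """
    trees = [_load_tree(t) for t in (trees if trees is not None else config.trees)]
    if len(trees) < 2:
        raise ValueError("sensitivity analysis needs >= 2 trees")
    tip_sets = [set(t.tip_labels) for t in trees]
    if any(s != tip_sets[0] for s in tip_sets[1:]):
        raise ReconciliationError("trees must share one tip set")

    # traits do not depend on the tree: compute the shape space once
    landmarks = _load_landmarks(config.landmarks)
    aligned = gm.gpa(landmarks)
    space = gm.bgpca(aligned, groups=aligned.species)
    table = _species_table(aligned, space, config.kmult_scores_from)
    order = list(table.index)
    offenders = sorted(tip_sets[0] ^ set(order))
    if offenders:
        raise ReconciliationError(
            f"species/tip mismatch between landmarks and trees: {offenders}")
    traits = ps.TraitMatrix(order, table.loc[order, config.traits].to_numpy(),
                            list(config.traits))

    rows, placements = [], []
    for tree in trees:
        res = ou.surface(tree, traits, n_grid=config.n_grid,
                         n_convention=config.n_convention)
        clades = frozenset(
            frozenset(tree.labels[t] for t in tree.clade_tips(v))
            for v in res.painting.shift_nodes)
        placements.append(clades)
        rows.append({
            "regime_count": res.k_prime,
            "n_shifts": res.painting.n_shifts,
            "n_convergent": len(res.convergent_regimes),
            "aicc": res.aicc,
        })
    df = pd.DataFrame(rows, index=[f"tree{i + 1}" for i in range(len(trees))])
    df["same_placements_as_tree1"] = [p == placements[0] for p in placements]
    return df
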