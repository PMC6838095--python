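"""Phylogenetic signal and phylogenetic regression for multivariate traits.

Implements the multivariate generalization of Blomberg's K (a ratio of
mean squared tip-to-root distances in raw versus phylogenetically
transformed space, scaled by its Brownian-motion expectation, so that
K = 1 under Brownian motion) and distance-based phylogenetic GLS
regression of a multivariate response (shape) on predictors (size),
both with permutation tests.

Trees may contain fossil (non-contemporaneous) tips: the phylogenetic
covariance matrix C simply has unequal diagonal entries and enters every
formula unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .trees import TimeTree

__all__ = [
    "TraitMatrix",
    "SignalResult",
    "phylo_covariance",
    "kmult",
    "dpgls",
    "dpgls_shape_size",
]


@dataclass
class TraitMatrix:
    """Species-by-trait values matched to tree tips (one row per tip)."""

    species: list[str]
    values: np.ndarray            # (n_species, n_traits)
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.species):
            if self.values.shape[1] == len(self.species):
                self.values = self.values.T
            else:
                raise ValueError("values must have one row per species")
        if not self.trait_names:
            self.trait_names = [f"trait_{j}" for j in range(self.values.shape[1])]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(species=[str(s) for s in df.index],
                   values=df.to_numpy(dtype=float),
                   trait_names=[str(c) for c in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.trait_names)

    def select(self, names: list[str]) -> "TraitMatrix":
        idx = [self.trait_names.index(n) for n in names]
        return TraitMatrix(self.species, self.values[:, idx], list(names))

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class SignalResult:
    K: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def phylo_covariance(tree: TimeTree, order: list[str] | None = None) -> np.ndarray:
    """Phylogenetic covariance C: C[i,j] = root-to-MRCA(i,j) path length.

    The diagonal holds root-to-tip distances, unequal when fossil tips
    are present.  Rows/columns follow ``order`` (tip labels) or the
    tree's own tip order.
    """
    tips = tree.tip_indices()
    labels = [tree.labels[i] for i in tips]
    pos = {node: j for j, node in enumerate(tips)}
    depth = tree.depths()
    n = len(tips)
    C = np.zeros((n, n))
    for node, j in pos.items():
        C[j, j] = depth[node]
    # MRCA depth for cross pairs: at each internal node, pairs of tips
    # drawn from different child subtrees coalesce exactly there.
    tipsets: dict[int, list[int]] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            tipsets[v] = [pos[v]]
            continue
        kids = [tipsets.pop(c) for c in tree.children[v]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.array(kids[a])[:, None]
                ib = np.array(kids[b])[None, :]
                C[ia, ib] = depth[v]
                C[ib.T, ia.T] = depth[v]
        tipsets[v] = [t for kid in kids for t in kid]
    if order is not None:
        perm = [labels.index(lab) for lab in order]
        C = C[np.ix_(perm, perm)]
    return C


def _match(tree: TimeTree, traits: TraitMatrix) -> np.ndarray:
    tips = set(tree.tip_labels)
    sp = set(traits.species)
    if tips != sp:
        missing = sorted(tips ^ sp)
        raise ValueError(f"species/tip mismatch: {missing}")
    return phylo_covariance(tree, order=traits.species)


def _gls_root(C_inv_ones: np.ndarray, denom: float, Y: np.ndarray) -> np.ndarray:
    """GLS estimate of the root state a = (1'C^-1 1)^-1 1'C^-1 Y."""
    return (C_inv_ones @ Y) / denom


def _kstat(Y: np.ndarray, C_inv_ones: np.ndarray, one_C_one: float,
           inv_sqrt: np.ndarray, k_denom: float) -> float:
    a = _gls_root(C_inv_ones, one_C_one, Y)
    R = Y - a[None, :]
    mse_obs = float((R ** 2).sum())
    U = inv_sqrt @ R
    mse_phylo = float((U ** 2).sum())
    if mse_phylo <= 0:
        raise ZeroDivisionError("constant traits across tips: K undefined")
    return (mse_obs / mse_phylo) / k_denom


def kmult(tree: TimeTree, traits: TraitMatrix, n_perm: int = 1000,
          seed: int | None = None) -> SignalResult:
    """Multivariate Blomberg's K with a permutation test.

    K is the ratio of summed squared distances of the tip data from the
    GLS root estimate in the raw space versus the phylogenetically
    transformed space (premultiplied by C^{-1/2}), scaled by the
    Brownian expectation (tr C - n / (1'C^-1 1)) / (n - 1).  K = 1 is
    the Brownian expectation; the statistic is invariant to rotation and
    rescaling of the trait matrix.  Significance: tip rows are permuted
    relative to the tree; p = (#{K_perm >= K_obs} + 1) / (n_perm + 1).
    """
    if traits.n_species < 4:
        raise ValueError("need at least 4 species")
    C = _match(tree, traits)
    n = C.shape[0]
    cho = cho_factor(C)
    C_inv_ones = cho_solve(cho, np.ones(n))
    one_C_one = float(C_inv_ones.sum())
    evals, evecs = np.linalg.eigh(C)
    if evals.min() <= 0:
        raise np.linalg.LinAlgError("phylogenetic covariance not positive definite")
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    k_denom = (float(np.trace(C)) - n / one_C_one) / (n - 1)

    Y = traits.values
    k_obs = _kstat(Y, C_inv_ones, one_C_one, inv_sqrt, k_denom)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        k_perm = _kstat(Y[rng.permutation(n)], C_inv_ones, one_C_one,
                        inv_sqrt, k_denom)
        if k_perm >= k_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return SignalResult(K=k_obs, p_value=p, n_permutations=n_perm, seed=seed)


def dpgls(tree: TimeTree, response: TraitMatrix, predictors: TraitMatrix,
          n_perm: int = 1000, seed: int | None = None) -> tuple[float, float]:
    """Distance-based phylogenetic GLS regression with a permutation test.

    Both sides are premultiplied by the inverse Cholesky factor of C;
    r^2 is the explained fraction of the transformed total sum of
    squares (relative to the transformed intercept-only fit).  The null
    distribution permutes the predictor rows across tips.
    Returns ``(r2, p_value)``.
    """
    if response.species != predictors.species:
        raise ValueError("response and predictors must list species in the same order")
    C = _match(tree, response)
    L = np.linalg.cholesky(C)
    n = C.shape[0]
    Zy = solve_triangular(L, response.values, lower=True)
    Zones = solve_triangular(L, np.ones((n, 1)), lower=True)
    X = predictors.values

    def r2_of(Xp: np.ndarray) -> float:
        Zx = solve_triangular(L, np.column_stack([np.ones(n), Xp]), lower=True)
        _, sse_full, *_ = np.linalg.lstsq(Zx, Zy, rcond=None)
        sse_full = _sse(Zx, Zy, sse_full)
        sse_0 = _sse(Zones, Zy, None)
        if sse_0 <= 0:
            raise ZeroDivisionError("constant response: r2 undefined")
        return max(0.0, 1.0 - sse_full / sse_0)

    r2_obs = r2_of(X)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r2_of(X[rng.permutation(n)]) >= r2_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return r2_obs, p


def _sse(Zx: np.ndarray, Zy: np.ndarray, resid) -> float:
    if resid is not None and resid.size:
        return float(resid.sum())
    beta, *_ = np.linalg.lstsq(Zx, Zy, rcond=None)
    return float(((Zy - Zx @ beta) ** 2).sum())


def dpgls_shape_size(tree: TimeTree, shape: TraitMatrix, size: TraitMatrix,
                     n_perm: int = 1000, seed: int | None = None) -> tuple[float, float]:
    """Phylogenetic multivariate regression of shape on size (allometry test)."""
    return dpgls(tree, shape, size, n_perm=n_perm, seed=seed)
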