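"""Brownian-motion and multi-regime Ornstein-Uhlenbeck models on time trees.

The OU process dX = alpha * (theta - X) dt + sigma dB pulls a trait
toward an adaptive optimum theta at rate alpha; alpha = 0 recovers
Brownian motion dX = sigma dB.  A *regime painting* assigns every branch
of the phylogeny to an adaptive regime (optimum); the expected tip value
is then a weighted sum of the optima along each root-to-tip path, with
weights given by exponentially discounted residence times.

The stepwise ("surface") procedure starts from a single-optimum OU
model, greedily adds the regime shift that most lowers the summed
finite-sample AICc across all traits, stops when no shift improves the
score, and then greedily collapses pairs of regimes into shared
(convergent) regimes while the AICc keeps improving.  A single alpha and
sigma^2 per trait are shared across regimes; only the optima differ.
Traits are modelled independently (shared painting, summed
log-likelihoods).

Trees need not be ultrametric: fossil tips enter the optimum weights
through their own root-to-tip depths and the covariance through shared
path lengths, with no special handling.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from .phylo_stats import TraitMatrix, phylo_covariance
from .trees import TimeTree

__all__ = [
    "RegimePainting",
    "EvolutionaryParameters",
    "HansenFit",
    "SurfaceResult",
    "bm_loglik",
    "bm_fit",
    "ou_weight_matrix",
    "ou_covariance",
    "hansen_fit",
    "aicc",
    "half_life",
    "surface_forward",
    "surface_backward",
    "surface",
    "compare_models",
]

ALPHA_MIN, ALPHA_MAX = 1e-8, 1e3


# ---------------------------------------------------------------------------
# paintings and parameters
# ---------------------------------------------------------------------------

@dataclass
class RegimePainting:
    """Branch -> adaptive-regime map defined by shift edges.

    A branch is identified by its child node id.  Each shift edge starts
    a regime that paints down the subtree until overridden by a deeper
    shift; everything else carries the root regime.  After convergence
    collapse, several shift edges may share one regime id.
    """

    shift_nodes: dict[int, int] = field(default_factory=dict)
    root_regime: int = 0

    @classmethod
    def single_regime(cls) -> "RegimePainting":
        return cls(shift_nodes={}, root_regime=0)

    @property
    def n_shifts(self) -> int:
        return len(self.shift_nodes)

    @property
    def regime_ids(self) -> list[int]:
        return sorted({self.root_regime, *self.shift_nodes.values()})

    @property
    def n_regimes(self) -> int:
        return len(self.regime_ids)

    def branch_regimes(self, tree: TimeTree) -> np.ndarray:
        """Regime id per node (the branch above it; root gets root_regime)."""
        reg = np.empty(tree.n_nodes, dtype=np.int64)
        for v in tree.preorder():
            if v == tree.root:
                reg[v] = self.root_regime
            else:
                reg[v] = self.shift_nodes.get(v, reg[tree.parent[v]])
        return reg

    def convergent_regimes(self) -> list[int]:
        """Regimes reached independently from more than one origin."""
        counts: dict[int, int] = {self.root_regime: 1}
        for r in self.shift_nodes.values():
            counts[r] = counts.get(r, 0) + 1
        return sorted(r for r, c in counts.items() if c > 1)

    def collapse(self, keep: int, drop: int) -> "RegimePainting":
        """Merge regime `drop` into regime `keep`."""
        shifts = {v: (keep if r == drop else r) for v, r in self.shift_nodes.items()}
        root = keep if self.root_regime == drop else self.root_regime
        return RegimePainting(shift_nodes=shifts, root_regime=root)


@dataclass
class EvolutionaryParameters:
    """Shared-alpha/sigma multi-optimum OU parameters for one trait."""

    alpha: float                    # adaptation rate, 1/Ma
    sigma2: float                   # Brownian intensity, trait^2/Ma
    thetas: dict[int, float]        # optimum per regime id
    x0_policy: str = "root_theta"   # root state = root regime's optimum

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def stationary_sd(self) -> float:
        return float(np.sqrt(self.sigma2 / (2 * self.alpha))) if self.alpha > 0 else np.inf


@dataclass
class HansenFit:
    """Fitted shared-alpha OU model: one (alpha, sigma2, thetas) per trait."""

    trait_names: list[str]
    regime_ids: list[int]
    alphas: np.ndarray              # (t,)
    sigma2s: np.ndarray             # (t,)
    thetas: np.ndarray              # (t, r); NaN where unestimable
    logLs: np.ndarray               # (t,)
    n_params: int
    n_obs: int
    aicc: float

    @property
    def total_logL(self) -> float:
        return float(self.logLs.sum())

    @property
    def half_lives(self) -> np.ndarray:
        return np.log(2.0) / self.alphas

    def params_for(self, trait: str, x0_policy: str = "root_theta") -> EvolutionaryParameters:
        t = self.trait_names.index(trait)
        return EvolutionaryParameters(
            alpha=float(self.alphas[t]), sigma2=float(self.sigma2s[t]),
            thetas={r: float(self.thetas[t, j]) for j, r in enumerate(self.regime_ids)},
            x0_policy=x0_policy,
        )


@dataclass
class SurfaceResult:
    """Outcome of the stepwise shift search and convergence collapse."""

    forward_history: list[float]        # summed AICc after each accepted shift
    backward_history: list[float]       # summed AICc after each accepted collapse
    forward_painting: RegimePainting
    painting: RegimePainting            # final, after collapse
    k: int                              # regimes before collapse (shifts + 1)
    k_prime: int                        # distinct regimes after collapse
    convergent_regimes: list[int]
    fit: HansenFit                      # refined fit under the final painting

    @property
    def aicc(self) -> float:
        return self.fit.aicc

    @property
    def half_lives(self) -> dict[str, float]:
        return dict(zip(self.fit.trait_names, self.fit.half_lives))

    def summary(self) -> dict:
        return {
            "n_shifts": self.painting.n_shifts,
            "k": self.k,
            "k_prime": self.k_prime,
            "regime_count": self.k_prime,
            "convergent_regimes": self.convergent_regimes,
            "aicc": self.aicc,
            "half_lives": {k: float(v) for k, v in self.half_lives.items()},
            "alphas": {t: float(a) for t, a in zip(self.fit.trait_names, self.fit.alphas)},
            "sigma2s": {t: float(s) for t, s in zip(self.fit.trait_names, self.fit.sigma2s)},
        }


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def aicc(logL: float, p: int, n: int) -> float:
    """Finite-sample Akaike information criterion."""
    if n <= p + 1:
        raise ValueError(f"AICc undefined: n={n} <= p+1={p + 1}")
    return -2.0 * logL + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def half_life(alpha: float) -> float:
    """Phylogenetic half-life t_1/2 = ln(2)/alpha (Ma).

    The expected time to move half-way to a new optimum after a regime
    shift.  alpha <= 0 is the Brownian limit: +inf, with a warning.
    """
    if alpha <= 0:
        warnings.warn("alpha <= 0: Brownian limit, half-life is infinite", stacklevel=2)
        return np.inf
    return float(np.log(2.0) / alpha)


def bm_fit(tree: TimeTree, trait: TraitMatrix | np.ndarray,
           species: list[str] | None = None) -> tuple[float, float, float]:
    """Maximum-likelihood Brownian fit of one trait.

    Returns ``(logL, sigma2_hat, root_hat)`` where the root state is the
    GLS mean and sigma2 its closed-form MLE.
    """
    y, C = _trait_and_cov(tree, trait, species)
    n = y.size
    L = cholesky(C, lower=True)
    z = solve_triangular(L, y, lower=True)
    u = solve_triangular(L, np.ones(n), lower=True)
    root = float(u @ z / (u @ u))
    resid = z - root * u
    sse = float(resid @ resid)
    sigma2 = sse / n
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    logL = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return float(logL), float(sigma2), root


def bm_loglik(tree: TimeTree, trait: TraitMatrix | np.ndarray,
              sigma2: float | str = "mle",
              species: list[str] | None = None) -> float:
    """Brownian-motion log-likelihood (root state estimated by GLS).

    ``sigma2="mle"`` profiles the rate out in closed form; a numeric
    value evaluates the density at that rate.
    """
    if sigma2 == "mle":
        return bm_fit(tree, trait, species)[0]
    y, C = _trait_and_cov(tree, trait, species)
    n = y.size
    L = cholesky(C, lower=True)
    z = solve_triangular(L, y, lower=True)
    u = solve_triangular(L, np.ones(n), lower=True)
    root = float(u @ z / (u @ u))
    resid = z - root * u
    sse = float(resid @ resid)
    logdet = 2.0 * float(np.log(np.diag(L)).sum()) + n * np.log(sigma2)
    return float(-0.5 * n * np.log(2 * np.pi) - 0.5 * logdet - 0.5 * sse / sigma2)


def _trait_and_cov(tree, trait, species):
    if isinstance(trait, TraitMatrix):
        if trait.values.shape[1] != 1:
            raise ValueError("bm_loglik expects a single trait")
        y = trait.values[:, 0]
        order = trait.species
    else:
        y = np.asarray(trait, dtype=float).ravel()
        order = species
    C = phylo_covariance(tree, order=order)
    if y.size != C.shape[0]:
        raise ValueError("trait length does not match tip count")
    return y, C


# ---------------------------------------------------------------------------
# tree geometry cache
# ---------------------------------------------------------------------------

class _TreeGeometry:
    """Per-tree arrays used by OU means and covariances."""

    def __init__(self, tree: TimeTree, order: list[str] | None = None):
        self.tree = tree
        tips = tree.tip_indices()
        labels = [tree.labels[i] for i in tips]
        if order is not None:
            perm = [labels.index(lab) for lab in order]
            tips = [tips[i] for i in perm]
            labels = order
        self.tips = tips
        self.labels = labels
        self.n = len(tips)
        depth = tree.depths()
        self.depth = depth
        self.T = depth[np.array(tips)]            # root-to-tip depths
        # branch depth intervals [d_parent, d_child] per node
        self.d_child = depth.copy()
        self.d_parent = np.where(tree.parent >= 0, depth[tree.parent], 0.0)
        # path membership: P[i, v] = branch above v lies on root path of tip i
        P = np.zeros((self.n, tree.n_nodes), dtype=bool)
        for i, t in enumerate(tips):
            v = t
            while v != tree.root:
                P[i, v] = True
                v = int(tree.parent[v])
        self.P = P
        self.tmat = phylo_covariance(tree, order=labels)   # MRCA depths
        self.dmat = self.T[:, None] + self.T[None, :] - 2 * self.tmat
        # exponent arguments for branch weights, clipped to the path
        self.M1 = np.where(P, self.T[:, None] - self.d_child[None, :], 0.0)
        self.M2 = np.where(P, self.T[:, None] - self.d_parent[None, :], 0.0)

    def branch_weights(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """(B, g): B[i,v] = regime weight of branch v for tip i; g = root weight."""
        B = np.where(self.P, np.exp(-alpha * self.M1) - np.exp(-alpha * self.M2), 0.0)
        g = np.exp(-alpha * self.T)
        return B, g

    def v0(self, alpha: float) -> np.ndarray:
        """OU tip correlation structure (covariance divided by sigma^2)."""
        if alpha == 0:
            return self.tmat.copy()
        return np.exp(-alpha * self.dmat) * (-np.expm1(-2 * alpha * self.tmat)) / (2 * alpha)

    def descendants_same_regime(self, v: int, regimes: np.ndarray) -> list[int]:
        """Branches repainted when a shift is placed at branch v."""
        target = regimes[v]
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if regimes[u] != target:
                continue
            out.append(u)
            stack.extend(self.tree.children[u])
        return out


# ---------------------------------------------------------------------------
# public OU primitives
# ---------------------------------------------------------------------------

def ou_weight_matrix(tree: TimeTree, painting: RegimePainting, alpha: float,
                     x0_policy: str = "root_theta",
                     order: list[str] | None = None) -> tuple[np.ndarray, list[int]]:
    """Expected-value weights of each regime's optimum at each tip.

    ``W[i, r]`` integrates alpha * e^{-alpha (T_i - t)} over the parts of
    tip i's root path painted with regime r.  Under ``x0_policy=
    "root_theta"`` the residual root weight e^{-alpha T_i} is credited to
    the root regime; under ``"estimate"`` it forms an extra final column
    for a free ancestral state.  Rows sum to 1.  Returns ``(W,
    regime_ids)`` giving the column order.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0; use the Brownian-motion model for alpha = 0")
    geom = _TreeGeometry(tree, order=order)
    B, g = geom.branch_weights(alpha)
    regimes = painting.branch_regimes(tree)
    ids = painting.regime_ids
    W = np.zeros((geom.n, len(ids) + (1 if x0_policy == "estimate" else 0)))
    for j, r in enumerate(ids):
        cols = np.flatnonzero(regimes == r)
        cols = cols[cols != tree.root]
        if cols.size:
            W[:, j] = B[:, cols].sum(axis=1)
    if x0_policy == "estimate":
        W[:, -1] = g
    elif x0_policy == "root_theta":
        W[:, ids.index(painting.root_regime)] += g
    else:
        raise ValueError(f"unknown x0_policy {x0_policy!r}")
    return W, ids


def ou_covariance(tree: TimeTree, alpha: float, sigma2: float,
                  order: list[str] | None = None) -> np.ndarray:
    """OU tip covariance V[i,j] = (sigma^2/2a) e^{-a d_ij} (1 - e^{-2a t_a}).

    ``t_a`` is the root-to-MRCA depth and ``d_ij`` the patristic distance
    between tips; at alpha = 0 this is the Brownian limit sigma^2 * C.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    geom = _TreeGeometry(tree, order=order)
    return sigma2 * geom.v0(alpha)


# ---------------------------------------------------------------------------
# single-painting Hansen fit
# ---------------------------------------------------------------------------

def _profile_eval(geom: _TreeGeometry, regimes: np.ndarray, ids: list[int],
                  root_idx: int | None, y: np.ndarray, alpha: float,
                  x0_policy: str):
    """Profile log-likelihood over (theta, sigma2) at fixed alpha."""
    B, g = geom.branch_weights(alpha)
    r = len(ids) + (1 if x0_policy == "estimate" else 0)
    W = np.zeros((geom.n, r))
    for j, rid in enumerate(ids):
        cols = np.flatnonzero(regimes == rid)
        cols = cols[cols != geom.tree.root]
        if cols.size:
            W[:, j] = B[:, cols].sum(axis=1)
    if x0_policy == "estimate":
        W[:, -1] = g
    else:
        W[:, root_idx] += g
    L = cholesky(geom.v0(alpha), lower=True)
    Z = solve_triangular(L, W, lower=True)
    z = solve_triangular(L, y, lower=True)
    theta, _, rank, _ = np.linalg.lstsq(Z, z, rcond=None)
    resid = z - Z @ theta
    sse = float(resid @ resid)
    n = geom.n
    sigma2 = max(sse / n, 1e-300)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    logL = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return logL, sigma2, theta, W


def hansen_fit(tree: TimeTree, painting: RegimePainting, traits: TraitMatrix,
               x0_policy: str = "root_theta", alpha: float | None = None,
               alpha_bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
               n_grid: int = 40, refine: bool = True,
               n_convention: str = "tips_x_traits") -> HansenFit:
    """Fit a shared-alpha, shared-sigma multi-optimum OU model.

    Per trait, alpha is profiled by a bounded log-scale search (grid of
    ``n_grid`` points, optionally refined by Brent around the best grid
    point); theta is the GLS solution and sigma^2 its closed-form MLE at
    each alpha.  Log-likelihoods are summed over traits; the AICc counts
    2 + (#regimes) parameters per trait (+1 with a free root state) plus
    one per shift edge for the shift locations, with n = tips x traits
    (or tips, per ``n_convention``).

    ``alpha`` fixes the adaptation rate instead of optimizing it (used
    e.g. to verify the Brownian limit alpha -> 0).
    """
    geom = _TreeGeometry(tree, order=traits.species)
    regimes = painting.branch_regimes(tree)
    ids = painting.regime_ids
    root_idx = ids.index(painting.root_regime)
    nt = traits.values.shape[1]
    grid = np.geomspace(alpha_bounds[0], alpha_bounds[1], n_grid)

    alphas = np.empty(nt)
    sigma2s = np.empty(nt)
    thetas = np.full((nt, len(ids)), np.nan)
    logLs = np.empty(nt)
    for t in range(nt):
        y = traits.values[:, t]

        def nll(log_a):
            return -_profile_eval(geom, regimes, ids, root_idx, y,
                                  float(np.exp(log_a)), x0_policy)[0]

        if alpha is not None:
            a_best = float(alpha)
        else:
            vals = [nll(np.log(a)) for a in grid]
            i = int(np.argmin(vals))
            a_best = grid[i]
            if refine:
                lo = np.log(grid[max(i - 1, 0)])
                hi = np.log(grid[min(i + 1, n_grid - 1)])
                if hi > lo:
                    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                          options={"xatol": 1e-6})
                    if res.fun <= vals[i]:
                        a_best = float(np.exp(res.x))
        logL, s2, th, W = _profile_eval(geom, regimes, ids, root_idx, y,
                                        a_best, x0_policy)
        alphas[t], sigma2s[t], logLs[t] = a_best, s2, logL
        estim = W[:, :len(ids)].max(axis=0) > 1e-12
        if not estim.all():
            dead = [ids[j] for j in np.flatnonzero(~estim)]
            warnings.warn(f"regimes {dead} carry no tip weight; optima unestimable",
                          stacklevel=2)
        thetas[t, estim] = th[:len(ids)][estim]

    p = _param_count(len(ids), painting.n_shifts, nt, x0_policy)
    n_obs = geom.n * nt if n_convention == "tips_x_traits" else geom.n
    # AICc is undefined for fewer observations than parameters + 1
    # (tiny trees used in likelihood checks): report NaN rather than fail
    score = aicc(float(logLs.sum()), p, n_obs) if n_obs > p + 1 else np.nan
    return HansenFit(
        trait_names=list(traits.trait_names), regime_ids=list(ids),
        alphas=alphas, sigma2s=sigma2s, thetas=thetas, logLs=logLs,
        n_params=p, n_obs=n_obs, aicc=score,
    )


def _param_count(n_regimes: int, n_shifts: int, n_traits: int, x0_policy: str) -> int:
    per_trait = 2 + n_regimes + (1 if x0_policy == "estimate" else 0)
    return n_traits * per_trait + n_shifts


# ---------------------------------------------------------------------------
# stepwise surface search
# ---------------------------------------------------------------------------

class _SurfaceEngine:
    """Grid-cached likelihood evaluations shared across candidate paintings.

    For each alpha on a fixed log grid the Cholesky factor of the OU
    correlation structure, the whitened per-branch weight columns and the
    whitened data are precomputed once; any candidate painting's profile
    likelihood then reduces to summing cached columns and solving a tiny
    normal-equation system, batched over the whole grid.
    """

    def __init__(self, tree: TimeTree, traits: TraitMatrix,
                 x0_policy: str = "root_theta",
                 alpha_bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
                 n_grid: int = 40, n_convention: str = "tips_x_traits"):
        self.tree = tree
        self.traits = traits
        self.x0_policy = x0_policy
        self.n_convention = n_convention
        self.geom = _TreeGeometry(tree, order=traits.species)
        self.Y = traits.values
        self.n, self.nt = self.Y.shape
        self.grid = np.geomspace(alpha_bounds[0], alpha_bounds[1], n_grid)
        na = n_grid
        nn = tree.n_nodes
        self.LB = np.empty((na, self.n, nn))
        self.Lg = np.empty((na, self.n))
        self.LY = np.empty((na, self.n, self.nt))
        self.logdet = np.empty(na)
        for a_i, a in enumerate(self.grid):
            B, g = self.geom.branch_weights(a)
            L = cholesky(self.geom.v0(a), lower=True)
            self.LB[a_i] = solve_triangular(L, B, lower=True)
            self.Lg[a_i] = solve_triangular(L, g, lower=True)
            self.LY[a_i] = solve_triangular(L, self.Y, lower=True)
            self.logdet[a_i] = 2.0 * float(np.log(np.diag(L)).sum())
        self.yty = np.einsum("ant,ant->at", self.LY, self.LY)

    # -- likelihood of a candidate column set ------------------------------

    def loglik_columns(self, Z: np.ndarray) -> np.ndarray:
        """Best-over-grid profile logL per trait for whitened design Z.

        Z has shape (n_grid, n_tips, n_regime_columns).
        """
        G = np.einsum("anr,ans->ars", Z, Z)
        Bm = np.einsum("anr,ant->art", Z, self.LY)
        # tiny ridge keeps momentarily unidentifiable regimes from aborting
        # a candidate evaluation; final fits use exact least squares
        d = G.reshape(G.shape[0], -1)[:, ::G.shape[1] + 1]
        eps = 1e-10 * d.max(axis=1) + 1e-300
        Gr = G + eps[:, None, None] * np.eye(G.shape[1])
        theta = np.linalg.solve(Gr, Bm)
        sse = np.clip(self.yty - np.einsum("art,art->at", theta, Bm), 1e-300, None)
        logL = (-0.5 * self.n * (np.log(2 * np.pi * sse / self.n) + 1.0)
                - 0.5 * self.logdet[:, None])
        return logL.max(axis=0)

    def score(self, Z: np.ndarray, n_regimes: int, n_shifts: int) -> float:
        """Summed AICc of a candidate painting given its whitened columns."""
        logLs = self.loglik_columns(Z)
        p = _param_count(n_regimes, n_shifts, self.nt, self.x0_policy)
        n_obs = self.n * self.nt if self.n_convention == "tips_x_traits" else self.n
        return aicc(float(logLs.sum()), p, n_obs)

    # -- column assembly -----------------------------------------------------

    def columns_for(self, painting: RegimePainting) -> tuple[np.ndarray, list[int]]:
        regimes = painting.branch_regimes(self.tree)
        ids = painting.regime_ids
        extra = 1 if self.x0_policy == "estimate" else 0
        Z = np.zeros((self.grid.size, self.n, len(ids) + extra))
        for j, r in enumerate(ids):
            cols = np.flatnonzero(regimes == r)
            cols = cols[cols != self.tree.root]
            if cols.size:
                Z[:, :, j] = self.LB[:, :, cols].sum(axis=2)
        if extra:
            Z[:, :, -1] = self.Lg
        else:
            Z[:, :, ids.index(painting.root_regime)] += self.Lg
        return Z, ids


def surface_forward(tree: TimeTree, traits: TraitMatrix,
                    x0_policy: str = "root_theta",
                    alpha_bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
                    n_grid: int = 40, max_shifts: int | None = None,
                    n_convention: str = "tips_x_traits",
                    _engine: "_SurfaceEngine | None" = None,
                    ) -> tuple[RegimePainting, list[float], "_SurfaceEngine"]:
    """Greedy forward phase: add the shift that most lowers summed AICc.

    Every non-root branch is a candidate (shifts sit at branch origins);
    ties break toward the earliest branch in a fixed post-order.  Stops
    when no candidate lowers the AICc.  Returns the forward painting, the
    AICc history (single-regime model first), and the reusable engine.
    """
    eng = _engine or _SurfaceEngine(tree, traits, x0_policy=x0_policy,
                                    alpha_bounds=alpha_bounds, n_grid=n_grid,
                                    n_convention=n_convention)
    painting = RegimePainting.single_regime()
    Z, ids = eng.columns_for(painting)
    cur = eng.score(Z, painting.n_regimes, painting.n_shifts)
    history = [cur]
    post = [v for v in tree.postorder() if v != tree.root]
    if max_shifts is None:
        max_shifts = len(post) - 1
    next_id = 1
    while painting.n_shifts < max_shifts:
        regimes = painting.branch_regimes(tree)
        id_index = {r: j for j, r in enumerate(painting.regime_ids)}
        best_v, best_score, best_cols = None, cur, None
        for v in post:
            if v in painting.shift_nodes:
                continue
            affected = eng.geom.descendants_same_regime(v, regimes)
            j_old = id_index[regimes[v]]
            s = eng.LB[:, :, affected].sum(axis=2)
            Zc = np.concatenate([Z, (Z[:, :, j_old] )[..., None]], axis=2)
            Zc[:, :, j_old] -= s
            Zc[:, :, -1] = s
            try:
                sc = eng.score(Zc, painting.n_regimes + 1, painting.n_shifts + 1)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if sc < best_score - 1e-9:
                best_v, best_score, best_cols = v, sc, Zc
        if best_v is None:
            break
        painting = RegimePainting(
            shift_nodes={**painting.shift_nodes, best_v: next_id},
            root_regime=painting.root_regime,
        )
        next_id += 1
        # rebuild columns so ordering matches painting.regime_ids
        Z, ids = eng.columns_for(painting)
        cur = best_score
        history.append(cur)
    return painting, history, eng


def surface_backward(tree: TimeTree, traits: TraitMatrix,
                     forward_painting: RegimePainting,
                     forward_history: list[float] | None = None,
                     x0_policy: str = "root_theta",
                     alpha_bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
                     n_grid: int = 40, n_convention: str = "tips_x_traits",
                     _engine: "_SurfaceEngine | None" = None) -> SurfaceResult:
    """Collapse phase: merge regime pairs into shared (convergent) regimes.

    All unordered pairs of current regimes are candidate merges; the best
    AICc-improving merge is applied greedily until none improves.  A
    regime painted from more than one origin after collapsing is reported
    as convergent.
    """
    eng = _engine or _SurfaceEngine(tree, traits, x0_policy=x0_policy,
                                    alpha_bounds=alpha_bounds, n_grid=n_grid,
                                    n_convention=n_convention)
    painting = forward_painting
    Z, ids = eng.columns_for(painting)
    cur = eng.score(Z, painting.n_regimes, painting.n_shifts)
    if forward_history is None:
        forward_history = [cur]
    history = [cur]
    while painting.n_regimes > 1:
        ids = painting.regime_ids
        best_pair, best_score = None, cur
        for a, b in itertools.combinations(range(len(ids)), 2):
            Zc = np.delete(Z, b, axis=2)
            Zc[:, :, a] += Z[:, :, b]
            try:
                sc = eng.score(Zc, painting.n_regimes - 1, painting.n_shifts)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if sc < best_score - 1e-9:
                best_pair, best_score = (a, b), sc
        if best_pair is None:
            break
        a, b = best_pair
        painting = painting.collapse(keep=ids[a], drop=ids[b])
        Z, _ = eng.columns_for(painting)
        cur = best_score
        history.append(cur)

    fit = hansen_fit(tree, painting, traits, x0_policy=x0_policy,
                     alpha_bounds=alpha_bounds, n_grid=n_grid,
                     n_convention=n_convention)
    return SurfaceResult(
        forward_history=list(forward_history),
        backward_history=history,
        forward_painting=forward_painting,
        painting=painting,
        k=forward_painting.n_shifts + 1,
        k_prime=painting.n_regimes,
        convergent_regimes=painting.convergent_regimes(),
        fit=fit,
    )


def surface(tree: TimeTree, traits: TraitMatrix, x0_policy: str = "root_theta",
            alpha_bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
            n_grid: int = 40, max_shifts: int | None = None,
            n_convention: str = "tips_x_traits") -> SurfaceResult:
    """Full stepwise analysis: forward shift search then convergence collapse."""
    painting, history, eng = surface_forward(
        tree, traits, x0_policy=x0_policy, alpha_bounds=alpha_bounds,
        n_grid=n_grid, max_shifts=max_shifts, n_convention=n_convention)
    return surface_backward(tree, traits, painting, forward_history=history,
                            x0_policy=x0_policy, alpha_bounds=alpha_bounds,
                            n_grid=n_grid, n_convention=n_convention,
                            _engine=eng)


def compare_models(tree: TimeTree, traits: TraitMatrix,
                   surface_result: SurfaceResult | None = None,
                   x0_policy: str = "root_theta",
                   n_convention: str = "tips_x_traits",
                   **surface_kwargs) -> pd.DataFrame:
    """AICc comparison of Brownian motion, single-optimum OU and surface.

    Returns a table with per-model summed log-likelihood, parameter
    count, AICc and delta-AICc relative to the best model (0 for the best
    by construction).
    """
    nt = traits.values.shape[1]
    n_tips = traits.n_species
    n_obs = n_tips * nt if n_convention == "tips_x_traits" else n_tips

    bm_logL = sum(bm_fit(tree, traits.values[:, t], species=traits.species)[0]
                  for t in range(nt))
    bm_p = 2 * nt
    rows = {"BM": (bm_logL, bm_p, aicc(bm_logL, bm_p, n_obs))}

    ou1 = hansen_fit(tree, RegimePainting.single_regime(), traits,
                     x0_policy=x0_policy, n_convention=n_convention)
    rows["OU1"] = (ou1.total_logL, ou1.n_params, ou1.aicc)

    if surface_result is None:
        surface_result = surface(tree, traits, x0_policy=x0_policy,
                                 n_convention=n_convention, **surface_kwargs)
    fit = surface_result.fit
    rows["surface"] = (fit.total_logL, fit.n_params, fit.aicc)

    df = pd.DataFrame(rows, index=["logL", "n_params", "AICc"]).T
    df["n_params"] = df["n_params"].astype(int)
    df["delta_AICc"] = df["AICc"] - df["AICc"].min()
    return df
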