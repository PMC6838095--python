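# Methods

This note documents the models, numerical choices and known limitations
of the package. It is written for users who need to judge what the
implementation assumes and what its tests do and do not demonstrate.

## Superimposition and ordination

Generalized Procrustes analysis centres each k×3 configuration, scales
it to unit centroid size, and iteratively rotates it onto the running
consensus by the orthogonal (Kabsch) solution with `det(R) = +1`
enforced — reflections are never used, so left/right structures cannot
be superimposed by mirroring. The consensus is the rescaled mean of the
aligned set; iteration stops when it moves less than `tol = 1e-8`
(maximum 100 iterations, an error on non-convergence). Because a GPA
solution is defined only up to one global rotation, the consensus is
pinned to its principal axes with deterministic signs (largest-magnitude
loading positive, reflection corrected on the third axis); this makes
the output exactly invariant to rigid motion and rescaling of the
inputs. Aligned shapes are projected orthogonally onto the tangent
plane normal to the consensus vector (the linear projection
x → x − c(cᵀx − 1)); the stereographic alternative was considered and
rejected in favour of the orthogonal projection. Tangent projection is
exact only to second order in shape dispersion, which is why the
idempotence test allows a second-order residual.

Between-group PCA eigen-analyses the covariance matrix (divisor g−1) of
the group-mean tangent coordinates; group means are arithmetic means of
aligned coordinates per species. At most g−1 axes are non-null.
Individuals are always projected post hoc; fossils can either enter the
eigenanalysis as their own groups or be excluded and projected
afterwards (both variants are exposed because either design is
defensible; they give different numeric scores but preserve ordinal
neighbourhood relations in well-separated data). Fossils may be aligned
inside the common GPA or fitted to the fixed consensus by ordinary
Procrustes analysis (`opa_to_consensus`) — both paths are provided
because joint versus a-posteriori alignment is a genuine design fork.
Eigenvector signs are fixed by making each axis's largest-magnitude
loading positive, so axis orientation is reproducible (the well-known
"reversed PC" phenomenon between software packages is thereby pinned).

## Time trees, fossils, supertrees

`TimeTree` stores a rooted tree with branch lengths in Ma; node ages are
root height minus path length, so the deepest tip sits at age 0 and
ultrametricity checks use a 1e-6 Ma tolerance (fossil tips make exact
zero-age checks wrong). Fossil grafting follows the rule: attachment
node age = max(adjacent crown node age, fossil tip age) + 1 Ma, with the
fossil's pendant branch running down to its geological age; grafts at
distinct attachments commute, and a graft that would invert parent/child
ages raises a conflict error. Because "adjacent crown node" can be
ambiguous for nested placements, the attachment is always named
explicitly (a taxon or a clade whose MRCA is used).

MRP supertrees use the Baum/Ragan encoding with equal column weights
(no weighting scheme is imposed); polytomies contribute only the clades
actually present. Parsimony lengths are Fitch counts with missing
entries as wildcards. The search is exhaustive for ≤ 9 taxa (unrooted
topologies enumerated by stepwise addition) and seeded NNI hill-climbing
with random-addition restarts above that, with a round guard that warns
and returns the best tree found. With sparse taxon overlap several
topologies can tie at the minimum length; ties resolve to the first
optimum in enumeration order (deterministic given the seed).

## Evolutionary models

Brownian motion and the multi-optimum OU (Hansen) model are fitted by
maximum likelihood on the tip covariance structure:

* OU mean: each tip's expectation is a weighted sum of regime optima,
  the weight of a branch segment [t₀, t₁] on the path to a tip of depth
  T being e^{−α(T−t₁)} − e^{−α(T−t₀)}; the residual root weight e^{−αT}
  is credited to the root regime's optimum (`x0_policy="root_theta"`,
  the convention of stepwise regime-fitting methods) or given a free
  ancestral-state column (`"estimate"`).
* OU covariance: V_ij = (σ²/2α)·e^{−α d_ij}·(1 − e^{−2α t_a}) with t_a
  the root-to-MRCA depth and d_ij the patristic distance; α → 0
  recovers σ²C. Fossil tips simply enter through their own depths.
* Per trait, θ̂ is the GLS solution given α, σ̂² its closed-form MLE,
  and α is profiled on a log-spaced grid over [1e-8, 1e3] /Ma, refined
  by bounded Brent minimization around the best grid point for reported
  fits. During the stepwise search only the grid is used: the Cholesky
  factor, whitened branch-weight columns and whitened data are cached
  per grid point once and shared across all candidate paintings, which
  is what makes scanning every branch at every step affordable. The
  same grid for every candidate means profile-bias cancels in
  comparisons, and the accept/reject decisions are deterministic.

Traits are modelled independently (a shared painting, per-trait α, σ²,
θ; log-likelihoods summed). The AICc parameter count is
p = m(2 + r) + k for m traits, r regimes and k shift edges (shift
locations counted once), with sample size n = (#tips)·(#traits) by
default; `n_convention="tips"` is available since either reading of the
finite-sample correction is defensible. AICc is undefined (reported as
NaN) when n ≤ p + 1, which matters only for the tiny trees used in
likelihood verification.

The forward phase considers a shift on every non-root branch (shifts sit
at branch origins), accepts the candidate that most lowers the summed
AICc, and stops when none improves it; ties break toward the earliest
branch in a fixed post-order. The backward phase greedily merges the
regime pair whose collapse most lowers the AICc; a regime painted from
more than one origin after collapsing is reported as convergent.
Candidate fits that fail numerically are skipped. A tiny ridge
(1e-10 of the Gram diagonal) stabilizes candidate evaluations whose
regimes momentarily carry no tip weight; final fits use exact least
squares and flag unestimable optima as NaN with a warning.

**Behaviour under the null, honestly stated.** Greedy stepwise AICc
selection takes a maximum over ~2·(#tips) candidate branches. Under a
single-regime null each candidate's gain in 2·logL is approximately
χ²(m); the maximum over candidates is therefore typically 12–30 for
m = 3 traits, while the AICc penalty per shift is ≈ 8.5 under the
default convention. The search consequently accepts a few spurious
shifts beyond the true ones before stopping — a documented property of
stepwise shift selection, not of this implementation (the per-candidate
gain distribution was verified against its χ² reference, and the
likelihood against a direct multivariate-normal oracle). In recovery
simulations the *true* shift branches are found first, with large AICc
drops, in essentially every replicate; the final regime count, however,
overshoots the truth by a median of a few regimes. Users should read
the regime count as an upper bound and the early, large-drop shifts as
the robust signal; the model comparison (ΔAICc against BM/OU1) and the
convergence collapse of genuinely shared optima are unaffected.

Phylogenetic half-life t½ = ln 2/α is reported per trait; α at the
lower search bound means "Brownian-like" and yields an astronomically
large half-life rather than an error (α ≤ 0 returns +inf with a
warning).

## Phylogenetic signal and allometry

The multivariate K statistic is the ratio of summed squared distances of
tip data from the GLS root estimate in raw versus phylogenetically
whitened (C^{−1/2}) space, scaled by its Brownian expectation
(tr C − n/(1ᵀC⁻¹1))/(n − 1); it reduces to classic Blomberg's K for one
trait (cross-checked in the tests against an independent R
implementation) and is invariant to rotation and rescaling of the trait
matrix. Significance permutes tip rows against the tree;
p = (#{K_perm ≥ K_obs} + 1)/(n_perm + 1) so p is never 0 and the
smallest attainable value at 1000 rounds is ≈ 0.001. D-PGLS whitens
response and design by the inverse Cholesky factor of C and reports
r² = 1 − SSE_full/SSE_intercept in the whitened space; the permutation
scheme randomizes the predictor across tips (the simplest exchangeable
null; 1000 rounds by default). Its type-I error at α = 0.05 is verified
to sit inside the exact binomial interval over 500 null replicates.

## Synthetic data

The generator is first-class, tested code. Defaults mirror an
anthropoid-scale design: a pure-birth chronogram scaled to a 40-Ma root,
53 tips with 13 truncated to positive ages (fossils), 14 landmarks,
3 specimens per species, three shape axes plus log centroid size,
α = 3/Ma, σ² = 1/Ma and optima separated by 5 stationary standard
deviations √(σ²/2α) — adaptation fast enough (t½ ≈ 0.23 Ma) to be
realistic for the motivating system, where fitted half-lives are 0.3–2.3
Ma. OU traits use exact per-branch transition sampling (no Euler
discretization bias); landmark noise is isotropic per coordinate, the
simplest model of intraspecific variation; species mean shapes displace
a fixed template along fixed orthonormal basis vectors (template and
basis are pinned by their own seed so scenarios differ only in the
evolutionary draws); lnCS evolves as Brownian motion around ln(50 mm).
All generators are pure functions of (scenario, seed).

What the generator does *not* emulate: correlated landmark noise,
allometric shape–size covariation, measurement error on fossils,
non-isotropic within-species variation, and diversification dynamics
beyond pure birth. Passing tests therefore demonstrate correctness of
the inference chain under its own model assumptions, not robustness of
the method to real-data violations of them.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tested effect while keeping the default suite fast:
K calibration, 200 Brownian replicates on one 50-tip tree; shift
recovery, 100 replicates of 128 tips; convergence collapse, 100
replicates of 64 tips; D-PGLS type-I error, 500 replicates of 32 tips
with 99 permutations each; the acceptance script scales replicate counts
down (30–200) since it recomputes many quantities in one run.

## Known limitations

* No multivariate-OU with trait covariance: traits are assumed
  independent, as in the reference design; the near-zero D-PGLS r²
  among PC axes is the package's own check on that assumption.
* No measurement-error model for tip means; no sliding semilandmarks,
  missing-landmark estimation or bilateral-symmetry handling.
* The stepwise search is greedy and, as documented above, tends to
  overshoot the number of regimes; penalized or Bayesian shift detection
  is out of scope.
* MRP searches above 9 taxa are heuristic; optimality is not guaranteed
  and ties are seed-resolved.
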