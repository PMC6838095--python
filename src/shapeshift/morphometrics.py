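"""Generalized Procrustes analysis and between-group PCA for 3D landmarks.

Landmark configurations (k landmarks x 3 coordinates, in mm) are
superimposed by iterative translation, scaling to unit centroid size and
least-squares rotation to a consensus, then projected orthogonally onto
the tangent space at the consensus so that linear multivariate statistics
apply.  Ordination is by between-group PCA: the eigenanalysis is carried
out on group (species) mean shapes and every individual specimen -- and
optionally each fossil -- is projected onto those axes a posteriori.

Reflections are never used in the superimposition (det(R) = +1 is
enforced), so left and right structures cannot be matched by mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "ShapeSpace",
    "centroid_size",
    "gpa",
    "bgpca",
    "project",
    "opa_to_consensus",
    "procrustes_distance",
    "read_landmarks_csv",
    "read_tps",
    "read_morphologika",
]


class DegenerateConfigurationError(ValueError):
    """Landmark configuration has zero size or fewer than 3 spatial dimensions."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LandmarkSet:
    """Raw landmark data: one k x 3 configuration per specimen (mm)."""

    specimen_ids: list[str]
    species: list[str]
    coordinates: np.ndarray  # (n_specimens, k, 3)
    groups: list[str] | None = None
    is_fossil: np.ndarray | None = None  # bool per specimen

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.coordinates.shape[0]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n, k, 3)")
        if np.isnan(self.coordinates).any():
            raise ValueError("missing landmarks are not supported")
        if len(self.specimen_ids) != n or len(self.species) != n:
            raise ValueError("specimen metadata length mismatch")
        if self.groups is None:
            self.groups = list(self.species)
        if self.is_fossil is None:
            self.is_fossil = np.zeros(n, dtype=bool)
        self.is_fossil = np.asarray(self.is_fossil, dtype=bool)

    @property
    def n_specimens(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class AlignedShapes:
    """Procrustes-aligned, tangent-projected shapes plus centroid sizes."""

    specimen_ids: list[str]
    species: list[str]
    coordinates: np.ndarray       # (n, k, 3) tangent-space Procrustes coords
    centroid_sizes: np.ndarray    # (n,), mm
    consensus: np.ndarray         # (k, 3), unit centroid size
    groups: list[str] = field(default_factory=list)
    is_fossil: np.ndarray | None = None
    n_iterations: int = 0

    @property
    def ln_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def flat(self) -> np.ndarray:
        """Specimens as row vectors in tangent space (n, 3k)."""
        return self.coordinates.reshape(self.coordinates.shape[0], -1)


@dataclass
class ShapeSpace:
    """Between-group PCA eigenbasis with specimen scores."""

    eigenvectors: np.ndarray      # (3k, n_axes), orthonormal columns
    eigenvalues: np.ndarray       # (n_axes,), descending
    grand_mean: np.ndarray        # (3k,) mean of the eigenanalysis set
    group_names: list[str]        # groups entering the eigenanalysis
    group_mean_scores: np.ndarray  # (g, n_axes)
    specimen_scores: np.ndarray   # (n, n_axes), all specimens, post hoc
    specimen_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# superimposition
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _centre_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centred = config - config.mean(axis=0)
    cs = np.sqrt((centred ** 2).sum())
    if cs <= 0:
        raise DegenerateConfigurationError("all landmarks coincide (centroid size 0)")
    return centred / cs, float(cs)


def _rotate_onto(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation of `config` onto `target`, no reflection."""
    u, _, vt = np.linalg.svd(config.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return config @ (u @ vt)


def _canonicalize(consensus: np.ndarray) -> np.ndarray:
    """Rotate the consensus to its principal axes with deterministic signs.

    GPA solutions are defined only up to a global rotation; pinning the
    consensus orientation makes the output invariant to rigid motion of
    the inputs.  Signs: the largest-|coordinate| landmark on each axis is
    positive; reflections are corrected on the third axis.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    R = vt.T
    X = consensus @ R
    for j in range(3):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            R[:, j] = -R[:, j]
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return consensus @ R


def gpa(raw: LandmarkSet, tol: float = 1e-8, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes analysis with tangent-space projection.

    Each configuration is centred, scaled to unit centroid size and
    rotated to the running consensus; the consensus is the rescaled mean
    of the aligned set and iteration stops when it moves less than
    ``tol``.  Aligned shapes are then projected orthogonally onto the
    tangent plane normal to the consensus vector.
    """
    if raw.n_landmarks < 4:
        raise ValueError("need at least 4 landmarks")
    n, k = raw.n_specimens, raw.n_landmarks
    scaled = np.empty((n, k, 3))
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _centre_scale(raw.coordinates[i])
        if np.linalg.matrix_rank(scaled[i]) < 3:
            raise DegenerateConfigurationError(
                f"specimen {raw.specimen_ids[i]!r} is degenerate (coplanar landmarks)"
            )

    consensus = _canonicalize(scaled[0].copy())
    aligned = scaled.copy()
    last_change = np.inf
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = _rotate_onto(scaled[i], consensus)
        new_consensus, _ = _centre_scale(aligned.mean(axis=0))
        new_consensus = _canonicalize(new_consensus)
        last_change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if last_change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {last_change:.3g})"
        )

    # orthogonal projection onto the tangent plane at the consensus
    c = consensus.reshape(-1)
    flat = aligned.reshape(n, -1)
    flat = flat - np.outer(flat @ c - 1.0, c)
    return AlignedShapes(
        specimen_ids=list(raw.specimen_ids),
        species=list(raw.species),
        coordinates=flat.reshape(n, k, 3),
        centroid_sizes=sizes,
        consensus=consensus,
        groups=list(raw.groups),
        is_fossil=raw.is_fossil.copy(),
        n_iterations=it,
    )


def opa_to_consensus(config: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes fit of one configuration onto a fixed consensus.

    Centres, scales to unit centroid size, rotates onto the consensus and
    applies the same tangent projection as :func:`gpa`.  Used to place
    specimens (e.g. fossils) into an existing Procrustes frame without
    re-running the joint superimposition.
    """
    scaled, _ = _centre_scale(np.asarray(config, dtype=float))
    ali = _rotate_onto(scaled, consensus)
    c = consensus.reshape(-1)
    flat = ali.reshape(-1)
    flat = flat - (flat @ c - 1.0) * c
    return flat.reshape(consensus.shape)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared difference after optimal superimposition of b on a."""
    sa, _ = _centre_scale(np.asarray(a, float))
    sb, _ = _centre_scale(np.asarray(b, float))
    sb = _rotate_onto(sb, sa)
    return float(np.sqrt(((sa - sb) ** 2).sum()))


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def bgpca(aligned: AlignedShapes, groups: list[str] | None = None,
          include_in_eigenanalysis: list[str] | None = None) -> ShapeSpace:
    """Between-group PCA of group mean shapes with post-hoc projection.

    The eigenanalysis is of the covariance matrix (divisor g-1) of the
    group mean tangent coordinates for the groups named in
    ``include_in_eigenanalysis`` (default: all groups).  Every specimen
    then receives scores by projecting its coordinates, centred on the
    grand mean of the eigenanalysis set, onto the eigenvectors.  At most
    g-1 axes are non-null.  Each eigenvector's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    groups = list(groups) if groups is not None else list(aligned.groups)
    if len(groups) != aligned.flat.shape[0]:
        raise ValueError("one group label per specimen required")
    flat = aligned.flat
    unique = list(dict.fromkeys(groups))
    eigen_groups = unique if include_in_eigenanalysis is None else list(include_in_eigenanalysis)
    for gname in eigen_groups:
        if gname not in unique:
            raise ValueError(f"group {gname!r} absent from data")
    if len(eigen_groups) < 2:
        raise ValueError("between-group PCA needs >= 2 groups in the eigenanalysis")

    garr = np.asarray(groups, dtype=object)
    means = np.stack([flat[garr == gname].mean(axis=0) for gname in eigen_groups])
    grand = means.mean(axis=0)
    centred = means - grand
    # SVD of the centred mean matrix == eigenanalysis of its covariance
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    g = len(eigen_groups)
    n_axes = min(g - 1, vt.shape[0])
    vecs = vt[:n_axes].T
    vals = svals[:n_axes] ** 2 / (g - 1)
    # null axes beyond rank carry no variance; drop numerically-zero ones
    keep = vals > (vals[0] * 1e-12 if vals.size and vals[0] > 0 else 0)
    if keep.any():
        vecs, vals = vecs[:, keep], vals[keep]
    # deterministic sign: largest-|loading| positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return ShapeSpace(
        eigenvectors=vecs,
        eigenvalues=vals,
        grand_mean=grand,
        group_names=eigen_groups,
        group_mean_scores=(means - grand) @ vecs,
        specimen_scores=(flat - grand) @ vecs,
        specimen_ids=list(aligned.specimen_ids),
    )


def project(space: ShapeSpace, configs: np.ndarray) -> np.ndarray:
    """Scores of extra aligned configurations in an existing shape space.

    ``configs`` may be (m, k, 3) aligned coordinates or (m, 3k) row
    vectors, in the same Procrustes frame as the eigenanalysis (aligned
    jointly or via :func:`opa_to_consensus`).  Projection never alters
    the eigenbasis.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    elif arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != space.grand_mean.size:
        raise ValueError(
            f"dimension mismatch: configs have {arr.shape[1]} coordinates, "
            f"space expects {space.grand_mean.size}"
        )
    return (arr - space.grand_mean) @ space.eigenvectors


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_landmarks_csv(path_or_buf, species_map: dict[str, str] | None = None,
                       sep: str = ",") -> LandmarkSet:
    """Long-format landmark table: specimen, landmark_index, x, y, z.

    Optional columns ``species``, ``group`` and ``is_fossil`` are used if
    present; otherwise ``species_map`` supplies specimen -> species.
    """
    df = pd.read_csv(path_or_buf, sep=sep)
    required = {"specimen", "landmark_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark table needs columns {sorted(required)}")
    ids = list(dict.fromkeys(df["specimen"].astype(str)))
    k = df["landmark_index"].nunique()
    coords = np.empty((len(ids), k, 3))
    meta: dict[str, dict] = {}
    for i, sid in enumerate(ids):
        sub = df[df["specimen"].astype(str) == sid].sort_values("landmark_index")
        if len(sub) != k:
            raise ValueError(f"specimen {sid!r} has {len(sub)} landmarks, expected {k}")
        coords[i] = sub[["x", "y", "z"]].to_numpy()
        meta[sid] = sub.iloc[0].to_dict()
    if "species" in df.columns:
        species = [str(meta[s]["species"]) for s in ids]
    elif species_map is not None:
        species = [species_map[s] for s in ids]
    else:
        species = list(ids)
    groups = [str(meta[s]["group"]) for s in ids] if "group" in df.columns else None
    fossil = (np.array([bool(meta[s]["is_fossil"]) for s in ids])
              if "is_fossil" in df.columns else None)
    return LandmarkSet(specimen_ids=ids, species=species, coordinates=coords,
                       groups=groups, is_fossil=fossil)


def read_tps(text: str, species_map: dict[str, str] | None = None) -> LandmarkSet:
    """Minimal TPS reader for 3D data (LM3 blocks with ID= lines)."""
    ids, configs = [], []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM3"):
            raise ValueError(f"expected LM3 header, got {lines[i]!r}")
        k = int(lines[i].split("=")[1])
        pts = [tuple(map(float, lines[i + 1 + j].split())) for j in range(k)]
        i += 1 + k
        sid = f"specimen_{len(ids)}"
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3"):
            key, val = lines[i].split("=", 1)
            if key.strip().upper() == "ID":
                sid = val.strip()
            i += 1
        ids.append(sid)
        configs.append(pts)
    coords = np.array(configs, dtype=float)
    species = [species_map.get(s, s) for s in ids] if species_map else list(ids)
    return LandmarkSet(specimen_ids=ids, species=species, coordinates=coords)


def read_morphologika(text: str) -> LandmarkSet:
    """Minimal Morphologika reader ([individuals]/[landmarks]/[dimensions]/
    [names]/[rawpoints] sections, 3D only)."""
    sections: dict[str, list[str]] = {}
    current = None
    for ln in text.splitlines():
        s = ln.strip()
        if not s:
            continue
        if s.startswith("["):
            current = s.strip("[]").lower()
            sections[current] = []
        elif current is not None:
            sections[current].append(s)
    n = int(sections["individuals"][0])
    k = int(sections["landmarks"][0])
    dim = int(sections["dimensions"][0])
    if dim != 3:
        raise ValueError("only 3D Morphologika data supported")
    names = sections.get("names", [f"specimen_{i}" for i in range(n)])[:n]
    rows = [list(map(float, s.split())) for s in sections["rawpoints"]
            if not s.startswith("'")]
    coords = np.array(rows, dtype=float).reshape(n, k, 3)
    return LandmarkSet(specimen_ids=list(names), species=list(names),
                       coordinates=coords)
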