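"""Time-calibrated phylogenies: IO, fossil grafting, and MRP supertrees.

A :class:`TimeTree` is a rooted tree with branch lengths in millions of
years (Ma).  Node ages (Ma before present) are derived from the root
height: the deepest tip sits at age 0 and every other node's age is the
root age minus its depth.  Trees need not be ultrametric -- fossil tips
sit at positive ages and all downstream covariance computations handle
unequal root-to-tip path lengths.

Newick/Nexus parsing and serialisation are delegated to dendropy; the
in-memory representation is array-backed (parent pointers + branch
lengths) because grafting and the evolutionary-model machinery need
direct access to paths and depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "FossilCalibration",
    "MRPMatrix",
    "TreeParseError",
    "TreeValidationError",
    "GraftConflictError",
    "read_tree",
    "write_tree",
    "midpoint_age",
    "graft_fossil",
    "mrp_encode",
    "parsimony_score",
    "mrp_supertree",
]

MISSING = -1  # missing-state code in MRP matrices


class TreeParseError(ValueError):
    """Raised when Newick/Nexus text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates TimeTree invariants."""


class GraftConflictError(ValueError):
    """Raised when a fossil graft would invert parent/child ages."""


class TimeTree:
    """Rooted phylogeny with branch lengths in Ma.

    Parameters
    ----------
    parent
        Integer array, ``parent[i]`` is the parent node id of node ``i``
        (``-1`` for the root).  Node 0 is the root by convention.
    lengths
        Branch length above each node in Ma (0.0 for the root).
    labels
        Node labels; every tip must be labelled, internal labels optional.
    """

    def __init__(self, parent, lengths, labels, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                if root >= 0:
                    raise TreeValidationError("more than one root")
                root = i
            else:
                self.children[p].append(i)
        if root != 0:
            raise TreeValidationError("root must be node 0")
        self.root = root
        if validate:
            self._validate()

    # -- basic structure -------------------------------------------------

    def _validate(self) -> None:
        if np.any(self.lengths[1:] < 0):
            bad = int(np.argmin(self.lengths[1:])) + 1
            raise TreeValidationError(
                f"negative branch length {self.lengths[bad]} above node {bad}"
            )
        tips = self.tip_indices()
        for i in tips:
            if self.labels[i] is None:
                raise TreeValidationError(f"unlabelled tip node {i}")
        names = [self.labels[i] for i in tips]
        if len(set(names)) != len(names):
            raise TreeValidationError("duplicate tip labels")
        # reachability / acyclicity: preorder must visit every node once
        if len(self.preorder()) != self.n_nodes:
            raise TreeValidationError("disconnected or cyclic parent map")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    # -- time calibration -------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (Ma since the root)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    @property
    def root_age(self) -> float:
        """Age of the root in Ma before present (deepest tip at age 0)."""
        d = self.depths()
        return float(max(d[i] for i in self.tip_indices()))

    def node_ages(self) -> np.ndarray:
        """Ages in Ma before present, root height minus path length."""
        return self.root_age - self.depths()

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        ages = self.node_ages()
        return all(abs(ages[i]) < tol for i in self.tip_indices())

    # -- queries -----------------------------------------------------------

    def tip_index(self, label: str) -> int:
        for i in self.tip_indices():
            if self.labels[i] == label:
                return i
        raise KeyError(f"no tip labelled {label!r}")

    def mrca(self, labels) -> int:
        """Most recent common ancestor node id of a set of tip labels."""
        sets = []
        for lab in labels:
            i = self.tip_index(lab)
            anc = [i]
            while self.parent[anc[-1]] >= 0:
                anc.append(int(self.parent[anc[-1]]))
            sets.append(anc)
        common = set(sets[0])
        for s in sets[1:]:
            common &= set(s)
        # the common ancestor of greatest depth
        d = self.depths()
        return max(common, key=lambda v: d[v])

    def clade_tips(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.lengths.copy(),
                        list(self.labels), validate=False)

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeParseError(
                        f"missing branch length above node {nd}"
                    )
                lengths[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label.replace(" ", "_")
            elif nd.label:
                labels[i] = str(nd.label).replace(" ", "_")
        return cls(parent, lengths, labels)

    def to_dendropy(self, regimes: dict[int, int] | None = None) -> dendropy.Tree:
        """Convert to dendropy; optional node->regime map emitted as comments."""
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {self.root: dtree.seed_node}
        for v in self.preorder():
            if v == self.root:
                nd = dtree.seed_node
            else:
                nd = dnodes[self.parent[v]].new_child()
                nd.edge.length = float(self.lengths[v])
                dnodes[v] = nd
            if self.is_tip(v):
                nd.taxon = taxa.new_taxon(self.labels[v])
            if regimes is not None and v in regimes:
                nd.comments.append(f"&regime={regimes[v]}")
        return dtree

    def newick(self, regimes: dict[int, int] | None = None) -> str:
        dtree = self.to_dendropy(regimes=regimes)
        return dtree.as_string(
            schema="newick", suppress_rooting=True,
            suppress_annotations=False, suppress_item_comments=False,
        ).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {len(self.tip_labels)} tips, root age {self.root_age:.3g} Ma>"


@dataclass
class FossilCalibration:
    """A fossil tip to graft onto an extant backbone.

    ``attachment`` names the adjacent crown node: either a single taxon
    (graft onto that tip's branch, i.e. as its sister) or a collection
    of taxa whose MRCA's subtending branch receives the graft.
    """

    taxon: str
    tip_age: float
    attachment: str | tuple | list

    def __post_init__(self):
        if self.tip_age <= 0:
            raise TreeValidationError("fossil tip_age must be positive")


@dataclass
class MRPMatrix:
    """Baum/Ragan matrix representation: one 0/1/missing column per clade."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_columns), int8, MISSING = -1
    source_tree_ids: list[int] = field(default_factory=list)

    def column(self, j: int) -> dict[str, int]:
        return {t: int(self.matrix[i, j]) for i, t in enumerate(self.taxa)}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_tree(text: str, schema: str | None = None) -> TimeTree:
    """Parse Newick or Nexus text into a :class:`TimeTree`.

    The schema is auto-detected (``#NEXUS`` header) unless given.
    """
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(data=text, schema=schema,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
    return TimeTree.from_dendropy(dtree)


def write_tree(tree: TimeTree, schema: str = "newick",
               regimes: dict[int, int] | None = None) -> str:
    """Serialise to Newick or Nexus text.

    ``regimes`` (node id -> regime id) is written as ``[&regime=k]``
    branch comments in Newick output.
    """
    dtree = tree.to_dendropy(regimes=regimes)
    out = dtree.as_string(schema=schema, suppress_rooting=(schema == "newick"),
                          suppress_annotations=False, suppress_item_comments=False)
    return out.strip() + "\n"


# ---------------------------------------------------------------------------
# Fossil calibration
# ---------------------------------------------------------------------------

def midpoint_age(lower: float, upper: float) -> float:
    """Midpoint of a geological age bracket (Ma)."""
    if lower > upper:
        raise TreeValidationError(f"reversed age bounds ({lower}, {upper})")
    return 0.5 * (lower + upper)


def graft_fossil(backbone: TimeTree, cal: FossilCalibration) -> TimeTree:
    """Attach a fossil tip next to its adjacent crown node.

    The new attachment node is placed 1 Ma older than the adjacent crown
    node, or 1 Ma older than the fossil's own geological age if the
    fossil is older than that node:

        attachment node age = max(crown node age, fossil tip age) + 1 Ma

    The fossil's pendant branch spans from the attachment node down to
    its geological tip age.  Grafts at distinct attachments commute.
    """
    tree = backbone
    if isinstance(cal.attachment, str):
        att = tree.tip_index(cal.attachment)
    else:
        att = tree.mrca(cal.attachment)
    ages = tree.node_ages()
    new_age = max(float(ages[att]), cal.tip_age) + 1.0
    par = int(tree.parent[att])
    if par >= 0 and new_age >= ages[par]:
        raise GraftConflictError(
            f"graft of {cal.taxon!r}: attachment node at {new_age:.4g} Ma would be "
            f"older than its parent at {ages[par]:.4g} Ma; choose a deeper attachment"
        )

    n = tree.n_nodes
    old_parent = tree.parent
    old_lengths = tree.lengths
    if par >= 0:
        # insert internal node on the branch above `att`
        # new node ids: keep node 0 as root, append internal at n, tip at n+1
        parent = np.concatenate([old_parent, [par, n]])
        lengths = np.concatenate([old_lengths, [float(ages[par] - new_age),
                                                float(new_age - cal.tip_age)]])
        parent[att] = n
        lengths = lengths.copy()
        lengths[att] = float(new_age - ages[att])
        labels = list(tree.labels) + [None, cal.taxon]
    else:
        # attachment is the root: new node becomes the root (node 0)
        parent = np.concatenate([[-1], old_parent + 1, [0]])
        parent[1] = 0  # old root hangs from the new root
        lengths = np.concatenate([[0.0], old_lengths,
                                  [float(new_age - cal.tip_age)]])
        lengths[1] = float(new_age - ages[att])
        labels = [None] + list(tree.labels) + [cal.taxon]
    return TimeTree(parent, lengths, labels)


# ---------------------------------------------------------------------------
# MRP supertrees
# ---------------------------------------------------------------------------

def mrp_encode(source_trees: list[TimeTree]) -> MRPMatrix:
    """Baum/Ragan encoding of source-tree clades as binary characters.

    Each non-trivial clade (2 <= size < n tips of its source) becomes a
    column: 1 inside the clade, 0 for other taxa in the same source,
    missing for taxa absent from that source.  Polytomies contribute
    only the clades actually present (soft-polytomy convention).
    """
    if not source_trees:
        raise ValueError("need at least one source tree")
    taxa: list[str] = []
    for t in source_trees:
        labs = t.tip_labels
        if len(labs) != len(set(labs)):
            raise TreeValidationError("duplicate tip labels within one source tree")
        if len(labs) < 3:
            raise ValueError("each source tree needs >= 3 tips")
        for lab in labs:
            if lab not in taxa:
                taxa.append(lab)
    taxa = sorted(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    columns, src_ids = [], []
    for sid, t in enumerate(source_trees):
        present = [index[lab] for lab in t.tip_labels]
        ntips = len(present)
        for v in t.preorder():
            if v == t.root or t.is_tip(v):
                continue
            clade = [index[t.labels[i]] for i in t.clade_tips(v)]
            if len(clade) < 2 or len(clade) >= ntips:
                continue
            col = np.full(len(taxa), MISSING, dtype=np.int8)
            col[present] = 0
            col[clade] = 1
            columns.append(col)
            src_ids.append(sid)
    mat = (np.stack(columns, axis=1) if columns
           else np.zeros((len(taxa), 0), dtype=np.int8))
    return MRPMatrix(taxa=taxa, matrix=mat, source_tree_ids=src_ids)


# Bitmask Fitch: state 0 -> 0b01, state 1 -> 0b10, missing -> 0b11.
_STATE_MASK = {0: 1, 1: 2, MISSING: 3}


def _fitch_masks(matrix: np.ndarray) -> np.ndarray:
    masks = np.empty(matrix.shape, dtype=np.int8)
    masks[matrix == 0] = 1
    masks[matrix == 1] = 2
    masks[matrix == MISSING] = 3
    return masks


def parsimony_score(tree, matrix: MRPMatrix) -> int:
    """Fitch parsimony length of a topology on an MRP matrix.

    ``tree`` is a :class:`TimeTree` (branch lengths ignored) or a nested
    tuple topology over taxon indices into ``matrix.taxa``.  Missing
    entries act as wildcards and never force a step.
    """
    if isinstance(tree, TimeTree):
        idx = {t: i for i, t in enumerate(matrix.taxa)}
        for lab in tree.tip_labels:
            if lab not in idx:
                raise KeyError(f"tip {lab!r} absent from MRP matrix")
        topo = _timetree_to_tuple(tree, idx)
    else:
        topo = tree
    masks = _fitch_masks(matrix.matrix)
    _, steps = _fitch(topo, masks)
    return int(steps.sum())


def _timetree_to_tuple(tree: TimeTree, idx: dict[str, int]):
    def rec(v):
        if tree.is_tip(v):
            return idx[tree.labels[v]]
        subs = [rec(c) for c in tree.children[v]]
        node = subs[0]
        for s in subs[1:]:
            node = (node, s)
        return node
    return rec(tree.root)


def _fitch(node, masks: np.ndarray):
    """Return (state-mask vector over columns, per-column step counts)."""
    if isinstance(node, (int, np.integer)):
        return masks[node], np.zeros(masks.shape[1], dtype=np.int64)
    left, right = node
    m1, s1 = _fitch(left, masks)
    m2, s2 = _fitch(right, masks)
    inter = m1 & m2
    steps = s1 + s2 + (inter == 0)
    out = np.where(inter == 0, m1 | m2, inter)
    return out, steps


def _tuple_to_timetree(topo, taxa: list[str]) -> TimeTree:
    parent, lengths, labels = [-1], [0.0], [None]

    def rec(node, par):
        i = len(parent)
        parent.append(par)
        lengths.append(1.0)
        if isinstance(node, (int, np.integer)):
            labels.append(taxa[node])
        else:
            labels.append(None)
            rec(node[0], i)
            rec(node[1], i)
        return i

    if isinstance(topo, (int, np.integer)):
        raise ValueError("topology must have >= 2 taxa")
    labels[0] = None
    rec(topo[0], 0)
    rec(topo[1], 0)
    return TimeTree(np.array(parent), np.array(lengths), labels)


def _insertions(tree, leaf):
    """All trees obtained by inserting `leaf` into every edge, plus above root."""
    out = [(tree, leaf)]

    def rec(node, rebuild):
        out.append(rebuild((node, leaf)))
        if not isinstance(node, (int, np.integer)):
            l, r = node
            rec(l, lambda sub, r=r, rebuild=rebuild: rebuild((sub, r)))
            rec(r, lambda sub, l=l, rebuild=rebuild: rebuild((l, sub)))

    if not isinstance(tree, (int, np.integer)):
        l, r = tree
        rec(l, lambda sub, r=r: (sub, r))
        rec(r, lambda sub, l=l: (l, sub))
    return out


def _all_rooted(leaves: list[int]):
    """All rooted binary topologies over the given leaves (stepwise addition)."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return trees


def _random_addition_tree(leaves: list[int], rng: np.random.Generator):
    order = list(rng.permutation(leaves))
    tree = order[0]
    for leaf in order[1:]:
        opts = _insertions(tree, leaf)
        tree = opts[rng.integers(len(opts))]
    return tree


def _nni_neighbors(tree):
    """All NNI rearrangements of a rooted tuple topology."""
    out = []

    def rec(node, rebuild):
        if isinstance(node, (int, np.integer)):
            return
        l, r = node
        # edge between `node` and `l` (if internal): swap l's children with r
        if not isinstance(l, (int, np.integer)):
            ll, lr = l
            out.append(rebuild(((ll, r), lr)))
            out.append(rebuild(((lr, r), ll)))
        if not isinstance(r, (int, np.integer)):
            rl, rr = r
            out.append(rebuild((rl, (rr, l))))
            out.append(rebuild((rr, (rl, l))))
        rec(l, lambda sub, r=r, rebuild=rebuild: rebuild((sub, r)))
        rec(r, lambda sub, l=l, rebuild=rebuild: rebuild((l, sub)))

    rec(tree, lambda x: x)
    return out


def mrp_supertree(matrix: MRPMatrix, seed: int = 42, n_restarts: int = 8,
                  max_rounds: int = 200, exhaustive_limit: int = 9) -> TimeTree:
    """Minimum-length supertree for an MRP matrix.

    Exhaustive search over all unrooted binary topologies for up to
    ``exhaustive_limit`` taxa (an unrooted tree on n taxa is enumerated
    as a rooted tree on n-1 taxa with the first taxon attached at the
    root); NNI hill-climbing with seeded random-addition restarts
    otherwise.  Returns a :class:`TimeTree` with unit branch lengths
    (a topology, not a chronogram).  If the heuristic hits the round
    guard a warning is issued and the best tree found is returned.
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("supertree search needs >= 4 taxa")
    masks = _fitch_masks(matrix.matrix)
    anchor = 0
    rest = list(range(1, n))

    def score(sub):
        _, steps = _fitch((sub, anchor), masks)
        return int(steps.sum())

    if n <= exhaustive_limit:
        best, best_s = None, None
        for t in _all_rooted(rest):
            s = score(t)
            if best_s is None or s < best_s:
                best, best_s = t, s
        return _tuple_to_timetree((best, anchor), matrix.taxa)

    rng = np.random.default_rng(seed)
    best, best_s = None, None
    guard_hit = False
    for _ in range(n_restarts):
        cur = _random_addition_tree(rest, rng)
        cur_s = score(cur)
        for _round in range(max_rounds):
            nbrs = _nni_neighbors(cur)
            scored = [(score(t), i) for i, t in enumerate(nbrs)]
            s_min, i_min = min(scored)
            if s_min < cur_s:
                cur, cur_s = nbrs[i_min], s_min
            else:
                break
        else:
            guard_hit = True
        if best_s is None or cur_s < best_s:
            best, best_s = cur, cur_s
    if guard_hit:
        warnings.warn("NNI search hit the round guard; returning best tree found",
                      stacklevel=2)
    return _tuple_to_timetree((best, anchor), matrix.taxa)
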