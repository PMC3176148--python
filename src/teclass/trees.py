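"""Distance-based tree construction and bootstrap support.

Trees are built from an evolutionary distance matrix by neighbor joining
(NJ) and refined under the minimum-evolution (ME) criterion: branch lengths
are fitted by ordinary least squares (OLS) on the path-length system, and
greedy nearest-neighbor-interchange (NNI) moves are accepted while the total
(OLS) tree length strictly decreases.  Edge supports come from a seeded
nonparametric bootstrap over alignment columns, with distances in every
replicate recomputed under that replicate's own pairwise-deletion masks.

The tree container is deliberately lightweight: an undirected graph over
node indices, tips first.  Newick serialization (with supports as internal
node labels) and dendropy interchange are provided for interoperability.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import DistanceError, TreeError
from .jtt import (
    JTT,
    EvolutionaryDistanceMatrix,
    SubstitutionModel,
    distance_matrix,
)


@dataclass
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise TreeError("bootstrap replicates must be >= 1")


class PhylogeneticTree:
    """Unrooted (optionally rooted) binary tree with branch lengths.

    Nodes are integers; tips are ``0..n_tips-1`` and carry labels.  Edges
    are stored once with an id; ``supports`` maps edge id to a bootstrap
    percentage in [0, 100].
    """

    def __init__(self, tip_labels: list[str]):
        self.tip_labels = list(tip_labels)
        self.adj: dict[int, dict[int, int]] = {
            i: {} for i in range(len(tip_labels))
        }
        self.edges: list[tuple[int, int]] = []
        self.lengths: list[float] = []
        self.supports: dict[int, float] = {}
        self.root: int | None = None
        self._next_node = len(tip_labels)

    # -- construction ------------------------------------------------------
    def new_node(self) -> int:
        node = self._next_node
        self.adj[node] = {}
        self._next_node += 1
        return node

    def add_edge(self, u: int, v: int, length: float = 0.0) -> int:
        eid = len(self.edges)
        self.edges.append((u, v))
        self.lengths.append(float(length))
        self.adj[u][v] = eid
        self.adj[v][u] = eid
        return eid

    def remove_edge(self, u: int, v: int) -> None:
        eid = self.adj[u].pop(v)
        self.adj[v].pop(u)
        # keep edge ids stable: mark as dead
        self.edges[eid] = None  # type: ignore[assignment]

    # -- basic queries -----------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def live_edges(self) -> list[tuple[int, tuple[int, int]]]:
        return [(i, e) for i, e in enumerate(self.edges) if e is not None]

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def is_binary_unrooted(self) -> bool:
        return all(
            self.degree(n) in (1, 3)
            for n in self.adj
            if self.adj[n]
        )

    def copy(self) -> "PhylogeneticTree":
        t = PhylogeneticTree(self.tip_labels)
        t.adj = {n: dict(nbrs) for n, nbrs in self.adj.items()}
        t.edges = list(self.edges)
        t.lengths = list(self.lengths)
        t.supports = dict(self.supports)
        t.root = self.root
        t._next_node = self._next_node
        return t

    # -- bipartitions ------------------------------------------------------
    def edge_side(self, eid: int) -> frozenset[int]:
        """Tip indices on the side of edge ``eid`` away from tip 0."""
        u, v = self.edges[eid]
        # BFS from v without crossing (u, v); if tip 0 ends up inside,
        # return the complement so the canonical side excludes tip 0.
        side = self._component(v, forbid=(u, v))
        if 0 in side:
            side = frozenset(range(self.n_tips)) - side
        return frozenset(side)

    def _component(self, start: int, forbid: tuple[int, int]) -> frozenset[int]:
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in self.adj[node]:
                if (node, nbr) in (forbid, forbid[::-1]):
                    continue
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(t for t in seen if t < self.n_tips)

    def bipartitions(self) -> dict[frozenset[int], int]:
        """Non-trivial bipartitions (internal edges) -> edge id."""
        out = {}
        for eid, (u, v) in self.live_edges():
            side = self.edge_side(eid)
            if 1 <= len(side) <= self.n_tips - 1:
                if len(side) > 1 and len(side) < self.n_tips - 1:
                    out[side] = eid
        return out

    def clade_sets(self) -> set[frozenset[str]]:
        """All tip-label sets that form one side of some edge."""
        all_tips = frozenset(range(self.n_tips))
        sides = set()
        for eid, _ in self.live_edges():
            s = self.edge_side(eid)
            sides.add(s)
            sides.add(all_tips - s)
        return {
            frozenset(self.tip_labels[i] for i in s) for s in sides if s
        }

    # -- Newick ------------------------------------------------------------
    def newick(self, include_supports: bool = True) -> str:
        if self.root is not None:
            start = self.root
        else:
            start = next(
                (n for n in self.adj if self.adj[n] and n >= self.n_tips),
                0,
            )

        def fmt(x: float) -> str:
            return f"{x:.10g}"

        def recurse(node: int, parent: int | None) -> str:
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                return self.tip_labels[node] if node < self.n_tips else ""
            parts = []
            for ch in children:
                eid = self.adj[node][ch]
                sub = recurse(ch, node)
                label = ""
                if (
                    include_supports
                    and ch >= self.n_tips
                    and eid in self.supports
                ):
                    label = fmt(self.supports[eid])
                parts.append(f"{sub}{label}:{fmt(self.lengths[eid])}")
            inner = ",".join(parts)
            if node < self.n_tips:  # rooted display on a tip (degenerate)
                return f"({inner}){self.tip_labels[node]}"
            return f"({inner})"

        return recurse(start, None) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhylogeneticTree":
        """Parse a Newick string (supports read as internal-node labels)."""
        import dendropy

        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        tree = cls(labels)
        index = {lbl: i for i, lbl in enumerate(labels)}
        node_id: dict = {}

        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                node_id[nd] = index[nd.taxon.label]
            else:
                node_id[nd] = tree.new_node()
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            eid = tree.add_edge(
                node_id[nd.parent_node],
                node_id[nd],
                nd.edge.length or 0.0,
            )
            if not nd.is_leaf() and nd.label not in (None, ""):
                try:
                    tree.supports[eid] = float(nd.label)
                except ValueError:
                    pass
        # collapse a degree-2 dendropy root to keep the tree unrooted-binary
        root = node_id[dtree.seed_node]
        if tree.degree(root) == 2:
            (a, ea), (b, eb) = [
                (n, tree.adj[root][n]) for n in list(tree.adj[root])
            ]
            la, lb = tree.lengths[ea], tree.lengths[eb]
            sup = tree.supports.get(ea, tree.supports.get(eb))
            tree.remove_edge(root, a)
            tree.remove_edge(root, b)
            eid = tree.add_edge(a, b, la + lb)
            if sup is not None:
                tree.supports[eid] = sup
        return tree

    def total_length(self) -> float:
        return float(sum(self.lengths[i] for i, e in self.live_edges()))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, EvolutionaryDistanceMatrix):
        return np.array(D.d, dtype=float), list(D.ids)
    raise TreeError("expected an EvolutionaryDistanceMatrix")


def neighbor_joining(
    D: EvolutionaryDistanceMatrix | np.ndarray,
    ids: list[str] | None = None,
) -> PhylogeneticTree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    Ties in the Q criterion are broken by the smallest (row, column) index
    pair of the working matrix, so the result is invariant to how exact
    ties arise.  Negative branch-length estimates are clamped to zero.
    """
    if isinstance(D, EvolutionaryDistanceMatrix):
        mat, labels = _as_matrix(D)
    else:
        mat = np.array(D, dtype=float)
        labels = list(ids) if ids else [f"t{i}" for i in range(len(mat))]
    j = len(labels)
    if j < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {j}")
    tree = PhylogeneticTree(labels)
    nodes = list(range(j))  # tree-node id for each working-matrix row
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = mat.sum(axis=1)
        Q = (r - 2) * mat - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first occurrence == smallest (row, col)
        flat = int(np.argmin(Q))
        a, b = divmod(flat, r)
        if a > b:
            a, b = b, a
        dab = mat[a, b]
        la = 0.5 * dab + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = tree.new_node()
        tree.add_edge(parent, nodes[a], la)
        tree.add_edge(parent, nodes[b], lb)
        dnew = 0.5 * (mat[a] + mat[b] - dab)
        keep = [i for i in range(r) if i not in (a, b)]
        new_mat = np.empty((r - 1, r - 1))
        new_mat[: r - 2, : r - 2] = mat[np.ix_(keep, keep)]
        new_mat[-1, : r - 2] = dnew[keep]
        new_mat[: r - 2, -1] = dnew[keep]
        new_mat[-1, -1] = 0.0
        mat = new_mat
        nodes = [nodes[i] for i in keep] + [parent]
    # final three-taxon star: closed-form pendant lengths
    (x, y, z) = nodes
    dxy, dxz, dyz = mat[0, 1], mat[0, 2], mat[1, 2]
    center = tree.new_node()
    tree.add_edge(center, x, max(0.0, 0.5 * (dxy + dxz - dyz)))
    tree.add_edge(center, y, max(0.0, 0.5 * (dxy + dyz - dxz)))
    tree.add_edge(center, z, max(0.0, 0.5 * (dxz + dyz - dxy)))
    return tree


# ---------------------------------------------------------------------------
# OLS branch lengths and minimum-evolution NNI refinement
# ---------------------------------------------------------------------------

def _edge_tip_masks(tree: PhylogeneticTree) -> tuple[list[int], np.ndarray]:
    """Tip-membership mask of one side of every live edge, in one pass."""
    n = tree.n_tips
    start = next(
        (node for node in tree.adj if tree.adj[node] and node >= n), 0
    )
    # iterative postorder from `start`; mask of the subtree below each edge
    eids: list[int] = []
    masks: list[np.ndarray] = []
    node_mask: dict[int, np.ndarray] = {}
    stack: list[tuple[int, int | None, bool]] = [(start, None, False)]
    while stack:
        node, parent, processed = stack.pop()
        if not processed:
            stack.append((node, parent, True))
            for child in tree.adj[node]:
                if child != parent:
                    stack.append((child, node, False))
        else:
            mask = np.zeros(n, dtype=bool)
            if node < n:
                mask[node] = True
            for child in tree.adj[node]:
                if child != parent:
                    mask |= node_mask.pop(child)
            node_mask[node] = mask
            if parent is not None:
                eids.append(tree.adj[parent][node])
                masks.append(mask)
    return eids, np.array(masks)


def _ols_fit(tree: PhylogeneticTree, mat: np.ndarray, order: list[int]):
    """OLS branch-length estimates for a fixed topology.

    ``order[i]`` is the tip index in ``tree`` for row i of ``mat``.
    Returns (edge ids, estimates, total length = sum of estimates).
    """
    n = len(order)
    eids, masks = _edge_tip_masks(tree)
    # reorder mask columns to the distance-matrix row order
    masks = masks[:, order]
    iu = np.triu_indices(n, 1)
    X = (masks[:, iu[0]] ^ masks[:, iu[1]]).astype(float)  # E x pairs
    dvec = mat[iu]
    G = X @ X.T
    rhs = X @ dvec
    try:
        est = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        est, *_ = np.linalg.lstsq(X.T, dvec, rcond=None)
    return eids, est, float(est.sum())


def ols_branch_lengths(
    tree: PhylogeneticTree, D: EvolutionaryDistanceMatrix
) -> PhylogeneticTree:
    """Return a copy of ``tree`` with OLS-fitted branch lengths (clamped >= 0)."""
    mat, labels = _as_matrix(D)
    order = [tree.tip_labels.index(l) for l in labels]
    out = tree.copy()
    eids, est, _ = _ols_fit(out, mat, order)
    for eid, b in zip(eids, est):
        out.lengths[eid] = max(0.0, float(b))
    return out


def _nni_neighbors(tree: PhylogeneticTree, eid: int):
    """The two NNI rearrangements across internal edge ``eid``."""
    u, v = tree.edges[eid]
    if u < tree.n_tips or v < tree.n_tips:
        return
    a_nbrs = [n for n in tree.adj[u] if n != v]
    b_nbrs = [n for n in tree.adj[v] if n != u]
    if len(a_nbrs) != 2 or len(b_nbrs) != 2:
        raise TreeError("NNI requires a binary tree")
    for b_swap in b_nbrs:
        cand = tree.copy()
        a_swap = a_nbrs[1]
        la = cand.lengths[cand.adj[u][a_swap]]
        lb = cand.lengths[cand.adj[v][b_swap]]
        cand.remove_edge(u, a_swap)
        cand.remove_edge(v, b_swap)
        cand.add_edge(u, b_swap, lb)
        cand.add_edge(v, a_swap, la)
        yield cand


def minimum_evolution_refine(
    tree: PhylogeneticTree,
    D: EvolutionaryDistanceMatrix,
    tol: float = 1e-10,
) -> PhylogeneticTree:
    """Greedy NNI hill-climbing under the OLS minimum-evolution criterion.

    Accepts, per sweep, the best NNI move that strictly decreases the sum
    of OLS branch-length estimates; terminates at a local optimum.  The
    result carries OLS branch lengths clamped at zero and never has a
    larger ME length than the input topology.
    """
    mat, labels = _as_matrix(D)
    if not tree.is_binary_unrooted():
        raise TreeError("minimum-evolution refinement requires a binary tree")
    current = tree.copy()
    order = [current.tip_labels.index(l) for l in labels]
    _, _, cur_len = _ols_fit(current, mat, order)
    improved = True
    while improved:
        improved = False
        best: tuple[float, PhylogeneticTree] | None = None
        for eid, (u, v) in current.live_edges():
            if u < current.n_tips or v < current.n_tips:
                continue
            for cand in _nni_neighbors(current, eid):
                _, _, cand_len = _ols_fit(cand, mat, order)
                if cand_len < cur_len - tol and (
                    best is None or cand_len < best[0]
                ):
                    best = (cand_len, cand)
        if best is not None:
            cur_len, current = best
            improved = True
    eids, est, _ = _ols_fit(current, mat, order)
    for eid, b in zip(eids, est):
        current.lengths[eid] = max(0.0, float(b))
    return current


def build_tree(
    D: EvolutionaryDistanceMatrix, refine: bool = True
) -> PhylogeneticTree:
    """NJ starting tree, optionally ME-refined (the package default)."""
    tree = neighbor_joining(D)
    if refine and D.size > 3:
        tree = minimum_evolution_refine(tree, D)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    aln,
    model: SubstitutionModel = JTT,
    cfg: BootstrapConfig = BootstrapConfig(),
    refine: bool = True,
    keep_replicates: bool = False,
):
    """Column-resampling bootstrap supports on the point-estimate tree.

    For each replicate, alignment columns are resampled with replacement
    (seeded), distances are recomputed under the replicate's own
    pairwise-deletion masks, and a tree is built with the same NJ(+ME)
    procedure as the point estimate.  The support of each internal edge of
    the point-estimate tree is the percentage of replicate trees containing
    that bipartition.  A replicate whose resampled columns leave some pair
    with zero shared sites is redrawn (at most 10 times, then an error).
    """
    if len(aln) < 4:
        raise TreeError("bootstrap supports need >= 4 sequences")
    D = distance_matrix(aln, model)
    point = build_tree(D, refine=refine)
    rng = np.random.default_rng(cfg.seed)
    splits = point.bipartitions()
    counts = {s: 0 for s in splits}
    replicate_trees: list[PhylogeneticTree] = []
    L = aln.length
    for _ in range(cfg.replicates):
        rep_tree = None
        for _attempt in range(10):
            cols = rng.integers(0, L, size=L)
            try:
                rep_D = distance_matrix(aln.subset_columns(cols), model)
            except DistanceError:
                continue
            rep_tree = build_tree(rep_D, refine=refine)
            break
        if rep_tree is None:
            raise TreeError(
                "bootstrap replicate kept producing pairs with no shared "
                "sites after 10 redraws"
            )
        rep_splits = set(rep_tree.bipartitions())
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
        if keep_replicates:
            replicate_trees.append(rep_tree)
    for s, eid in splits.items():
        point.supports[eid] = 100.0 * counts[s] / cfg.replicates
    if keep_replicates:
        return point, replicate_trees
    return point


def majority_rule_consensus(
    trees: list[PhylogeneticTree], min_freq: float = 0.5
) -> str:
    """Majority-rule consensus of replicate trees, as a Newick string."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.newick(include_supports=False),
                schema="newick",
                taxon_namespace=tns,
            )
        )
    cons = tl.consensus(min_freq=min_freq)
    return cons.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(
    tree: PhylogeneticTree, outgroup_ids: set[str]
) -> PhylogeneticTree:
    """Root the tree on the edge subtending a monophyletic outgroup.

    The root splits the subtending edge at its midpoint.  Raises
    :class:`TreeError` listing the outgroup taxa when they are not a clade.
    """
    out_idx = frozenset(
        i for i, lbl in enumerate(tree.tip_labels) if lbl in outgroup_ids
    )
    if len(out_idx) != len(outgroup_ids):
        missing = set(outgroup_ids) - set(tree.tip_labels)
        raise TreeError(f"outgroup taxa not in tree: {sorted(missing)}")
    all_tips = frozenset(range(tree.n_tips))
    target = None
    for eid, _ in tree.live_edges():
        side = tree.edge_side(eid)
        if side == out_idx or side == all_tips - out_idx:
            target = eid
            break
    if target is None:
        raise TreeError(
            "outgroup is not monophyletic in the tree: "
            f"{sorted(outgroup_ids)}"
        )
    rooted = tree.copy()
    u, v = rooted.edges[target]
    half = 0.5 * rooted.lengths[target]
    sup = rooted.supports.get(target)
    rooted.remove_edge(u, v)
    root = rooted.new_node()
    e1 = rooted.add_edge(root, u, half)
    e2 = rooted.add_edge(root, v, half)
    if sup is not None:
        rooted.supports[e1] = sup
        rooted.supports[e2] = sup
    rooted.root = root
    return rooted


def unroot(tree: PhylogeneticTree) -> PhylogeneticTree:
    """Remove a degree-2 root, restoring the unrooted binary tree."""
    if tree.root is None:
        return tree.copy()
    out = tree.copy()
    root = out.root
    if out.degree(root) == 2:
        (a, ea), (b, eb) = [(n, out.adj[root][n]) for n in list(out.adj[root])]
        la, lb = out.lengths[ea], out.lengths[eb]
        sup = out.supports.get(ea, out.supports.get(eb))
        out.remove_edge(root, a)
        out.remove_edge(root, b)
        eid = out.add_edge(a, b, la + lb)
        if sup is not None:
            out.supports[eid] = sup
    out.root = None
    return out
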