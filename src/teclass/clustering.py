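"""Substrate-specificity class discovery by hierarchical clustering.

Enzymes are clustered on their mol% composition vectors with Euclidean
distances and Ward's minimum-variance agglomeration; cluster support is
assessed by multiscale bootstrap resampling of the composition features,
yielding plain bootstrap probabilities (BP) at each scale and an
approximately unbiased (AU) p-value per dendrogram node from the standard
probit-regression correction.  Cutting the dendrogram at k clusters
(k = 3 by default) yields the specificity classes.

Ward's method is implemented as the classical Lance-Williams recursion on
squared distances; the merge height reported for each node is the increase
in total within-cluster sum of squares caused by that merge, and ties are
broken by the smallest pair of cluster indices (clusters are numbered in
scipy convention: leaves 0..n-1, then one new index per merge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .errors import ClusteringError
from .specificity import SpecificityProfile, molpct_matrix

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


def euclidean_distances(profiles) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between mol% profiles.

    Accepts a list of :class:`SpecificityProfile` or a 2-D array /
    DataFrame of composition vectors; species absent from a profile count
    as zero.  Returns (ids, full symmetric matrix).
    """
    ids, X = _as_feature_matrix(profiles)
    if len(ids) < 2:
        raise ClusteringError("need >= 2 profiles")
    return ids, squareform(pdist(X, metric="euclidean"))


def _as_feature_matrix(profiles) -> tuple[list[str], np.ndarray]:
    import pandas as pd

    if isinstance(profiles, pd.DataFrame):
        return list(profiles.index.astype(str)), profiles.to_numpy(float)
    if len(profiles) and isinstance(profiles[0], SpecificityProfile):
        frame = molpct_matrix(profiles)
        return list(frame.index), frame.to_numpy(float)
    X = np.asarray(profiles, dtype=float)
    return [f"p{i}" for i in range(len(X))], X


# ---------------------------------------------------------------------------
# Ward agglomeration (Lance-Williams on squared distances)
# ---------------------------------------------------------------------------

def ward_cluster(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Ward merge sequence from a Euclidean distance matrix.

    Returns ``[(i, j, height), ...]`` with i < j cluster indices in scipy
    numbering and height = the within-cluster sum-of-squares increase of
    the merge.  Each merge minimizes that increase; exact ties go to the
    smallest (i, j).
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if n < 2:
        raise ClusteringError("need >= 2 items to cluster")
    # work[i, j] = Ward's Lance-Williams distance (2x the SS increase of
    # merging i and j); initialized as squared Euclidean for singletons.
    # Retired rows/columns are set to +inf.
    work = D.astype(float) ** 2
    np.fill_diagonal(work, np.inf)
    alive = np.ones(n, dtype=bool)
    size = np.ones(n)
    cluster_of = np.arange(n)  # row position -> current cluster index
    merges: list[tuple[int, int, float]] = []
    next_idx = n
    for _ in range(n - 1):
        m = work.min()
        ti, tj = np.nonzero(work == m)
        best = None
        for ra, rb in zip(ti, tj):  # ties: smallest cluster-index pair
            if ra >= rb:
                continue
            ci, cj = cluster_of[ra], cluster_of[rb]
            key = (min(ci, cj), max(ci, cj))
            if best is None or key < best[0]:
                best = (key, ra, rb)
        (ci, cj), ra, rb = best
        height = m / 2.0  # within-cluster SS increase
        merges.append((int(ci), int(cj), float(height)))
        ni, nj = size[ra], size[rb]
        rows = np.nonzero(alive)[0]
        rows = rows[(rows != ra) & (rows != rb)]
        nk = size[rows]
        new = (
            (ni + nk) * work[ra, rows]
            + (nj + nk) * work[rb, rows]
            - nk * m
        ) / (ni + nj + nk)
        work[ra, rows] = new
        work[rows, ra] = new
        work[rb, :] = np.inf
        work[:, rb] = np.inf
        alive[rb] = False
        size[ra] = ni + nj
        cluster_of[ra] = next_idx
        next_idx += 1
    return merges


def node_members(
    merges: list[tuple[int, int, float]], n: int
) -> list[frozenset[int]]:
    """Leaf sets of the internal nodes, in merge order."""
    members: dict[int, frozenset[int]] = {
        i: frozenset([i]) for i in range(n)
    }
    out = []
    for t, (i, j, _) in enumerate(merges):
        members[n + t] = members[i] | members[j]
        out.append(members[n + t])
    return out


def cut_classes(
    merges: list[tuple[int, int, float]], n: int, k: int = 3
) -> dict[int, int]:
    """Cut the merge sequence at k clusters; label classes 1..k.

    Classes are numbered by decreasing size, ties by the smallest member
    index.  Returns leaf index -> class label.
    """
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in [1, {n}], got {k}")
    clusters = {i: frozenset([i]) for i in range(n)}
    for t, (i, j, _) in enumerate(merges[: n - k]):
        merged = clusters.pop(i) | clusters.pop(j)
        clusters[n + t] = merged
    ordered = sorted(
        clusters.values(), key=lambda s: (-len(s), min(s))
    )
    labels: dict[int, int] = {}
    for label, members in enumerate(ordered, start=1):
        for leaf in members:
            labels[leaf] = label
    return labels


# ---------------------------------------------------------------------------
# Multiscale bootstrap and AU p-values
# ---------------------------------------------------------------------------

@dataclass
class ClassDendrogram:
    """Ward merge tree with per-node bootstrap support and class labels."""

    ids: list[str]
    merges: list[tuple[int, int, float]]
    bp: dict[int, dict[float, float]] = field(default_factory=dict)
    au: dict[int, float] = field(default_factory=dict)
    bp_corrected: dict[int, float] = field(default_factory=dict)
    class_labels: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    def node_leafsets(self) -> list[frozenset[str]]:
        return [
            frozenset(self.ids[i] for i in s)
            for s in node_members(self.merges, self.n)
        ]

    def heights(self) -> list[float]:
        return [h for (_, _, h) in self.merges]

    def newick(self) -> str:
        """Dendrogram as Newick; node labels carry AU/BP annotations."""
        n = self.n
        names: dict[int, str] = {i: self.ids[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for t, (i, j, h) in enumerate(self.merges):
            node = n + t
            li = max(h - height[i], 0.0)
            lj = max(h - height[j], 0.0)
            label = ""
            if node in self.au:
                label = f"au{self.au[node]:.3f}_bp{self.bp_corrected.get(node, float('nan')):.3f}"
            names[node] = (
                f"({names[i]}:{li:.6g},{names[j]}:{lj:.6g}){label}"
            )
            height[node] = h
        return names[n + len(self.merges) - 1] + ";"


def multiscale_bootstrap(
    profiles,
    replicates: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    k: int | None = 3,
) -> ClassDendrogram:
    """Ward dendrogram with multiscale-bootstrap node support.

    For each scale r, ``ceil(r * m)`` of the m composition features are
    resampled with replacement ``replicates`` times; each resampled matrix
    is reclustered and the presence frequency BP(r) of every node of the
    point-estimate dendrogram is recorded.  The AU p-value per node comes
    from weighted least-squares probit regression of Phi^-1(1 - BP(r)) on
    {sqrt(r), 1/sqrt(r)}: AU = 1 - Phi(v - c) (and the corrected BP,
    1 - Phi(v + c), is kept alongside).  BP values are clipped to
    [1/(B+1), B/(B+1)] before the probit transform.

    A replicate drawing a zero-variance matrix is redrawn (at most 10
    times).  With ``k`` set, class labels from :func:`cut_classes` are
    attached.
    """
    ids, X = _as_feature_matrix(profiles)
    n, m = X.shape
    if n < 3:
        raise ClusteringError("need >= 3 profiles for bootstrap support")
    if m < 2:
        raise ClusteringError("need >= 2 feature columns")
    D = squareform(pdist(X))
    merges = ward_cluster(D)
    nodes = node_members(merges, n)
    # only non-trivial internal nodes get support (the root always exists)
    rng = np.random.default_rng(seed)
    B = int(replicates)
    node_ids = [n + t for t in range(len(nodes))]
    bp: dict[int, dict[float, float]] = {nid: {} for nid in node_ids}
    for r in scales:
        m_r = int(np.ceil(r * m))
        hits = {nid: 0 for nid in node_ids}
        for _ in range(B):
            for _attempt in range(10):
                cols = rng.integers(0, m, size=m_r)
                Xr = X[:, cols]
                Dr = squareform(pdist(Xr))
                if Dr.max() > 0:
                    break
            else:
                raise ClusteringError(
                    f"degenerate resamples at scale {r}: zero-variance "
                    "matrices after 10 redraws"
                )
            rep_nodes = set(node_members(ward_cluster(Dr), n))
            for nid, ns in zip(node_ids, nodes):
                if ns in rep_nodes:
                    hits[nid] += 1
        for nid in node_ids:
            bp[nid][float(r)] = hits[nid] / B
    dend = ClassDendrogram(ids, merges, bp=bp)
    for nid in node_ids:
        au, bpc = _au_from_bp(bp[nid], B)
        dend.au[nid] = au
        dend.bp_corrected[nid] = bpc
    if k is not None:
        labels = cut_classes(merges, n, min(k, n))
        dend.class_labels = {ids[i]: labels[i] for i in range(n)}
    return dend


def _au_from_bp(bp_by_scale: dict[float, float], B: int) -> tuple[float, float]:
    """AU and corrected-BP p-values from per-scale bootstrap probabilities.

    Weighted least squares of the probit-transformed BP values on
    {sqrt(r), 1/sqrt(r)} with binomial-variance weights, following the
    standard multiscale-bootstrap correction.
    """
    r = np.array(sorted(bp_by_scale))
    p = np.array([bp_by_scale[x] for x in r])
    lo, hi = 1.0 / (B + 1), B / (B + 1.0)
    # degenerate unanimity: a node present (absent) in every replicate at
    # every scale carries no curvature information; report the boundary
    # value directly instead of forcing the probit fit through clipped z's
    if (p >= 1.0).all():
        return hi, hi
    if (p <= 0.0).all():
        return lo, lo
    p = np.clip(p, lo, hi)
    zval = norm.ppf(1.0 - p)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = B * norm.pdf(zval) ** 2 / (p * (1.0 - p))
    W = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * W[:, None], zval * W, rcond=None)
    v, c = coef
    au = float(1.0 - norm.cdf(v - c))
    bp_corr = float(1.0 - norm.cdf(v + c))
    return au, bp_corr


def silhouette_diagnostics(
    profiles, k_range=range(2, 7)
) -> dict[int, float]:
    """Mean silhouette width of the Ward cut for each candidate k."""
    from sklearn.metrics import silhouette_score

    ids, X = _as_feature_matrix(profiles)
    D = squareform(pdist(X))
    merges = ward_cluster(D)
    out = {}
    for k in k_range:
        if not 2 <= k <= len(ids) - 1:
            continue
        labels = cut_classes(merges, len(ids), k)
        lab = [labels[i] for i in range(len(ids))]
        out[k] = float(silhouette_score(D, lab, metric="precomputed"))
    return out
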