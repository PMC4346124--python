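"""Hierarchical lineage clustering of copy-number profiles.

The core inference: samples are clustered by uncentred-correlation distance
(Pearson's formula without mean-centring, the Cluster 3.0 convention) under
complete linkage, repeated over a sweep of minimum-probes-per-gene
thresholds.  Two model-selection standards pick the working gene size:
samples of the same tumour must sit at neighbouring positions in the tree,
and the k-cluster sample constitution must be constant between neighbouring
thresholds.  The k=3 partition is then labelled stable / intermediate /
unstable from per-cluster CNA burden.

Agglomeration is deterministic: ties are broken toward the pair whose
smallest original item indices come first, so results are stable for a
given input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import GeneMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def uncentred_correlation_distance(x, y) -> float:
    """d = 1 - (sum x_i y_i) / (||x|| ||y||), in [0, 2].

    Pearson's correlation without mean-centring (cosine of the raw
    vectors).  Positions missing in either vector are dropped
    (pairwise-complete); at least two complete pairs are required, and an
    all-zero vector has no defined direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete pairs")
    x, y = x[ok], y[ok]
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0.0 or ny == 0.0:
        raise ValueError("undefined distance: all-zero vector")
    return float(np.clip(1.0 - (x * y).sum() / (nx * ny), 0.0, 2.0))


def pairwise_uncentred_distance(
    X: np.ndarray, labels: list[str] | None = None
) -> np.ndarray:
    """Full pairwise uncentred-correlation distance matrix for rows of X.

    Handles missing entries pairwise-complete; errors name the offending
    item (by label when given).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def name(i: int) -> str:
        return labels[i] if labels is not None else f"item {i}"

    if not np.isnan(X).any():
        norms = np.sqrt((X * X).sum(axis=1))
        zero = np.nonzero(norms == 0.0)[0]
        if zero.size:
            raise ValueError(f"undefined distance: all-zero vector for {name(zero[0])}")
        Xn = X / norms[:, None]
        D = 1.0 - Xn @ Xn.T
    else:
        M = (~np.isnan(X)).astype(float)
        X0 = np.nan_to_num(X, nan=0.0)
        pair_count = M @ M.T
        dot = X0 @ X0.T
        sqx = (X0 * X0) @ M.T  # ||x|| over positions complete in both
        sqy = M @ (X0 * X0).T
        few = np.nonzero(pair_count < 2)
        if few[0].size:
            i, j = int(few[0][0]), int(few[1][0])
            raise ValueError(
                f"fewer than 2 complete pairs between {name(i)} and {name(j)}"
            )
        norm = np.sqrt(sqx * sqy)
        zero = np.nonzero((norm == 0.0) & ~np.eye(n, dtype=bool))
        if zero[0].size:
            i, j = int(zero[0][0]), int(zero[1][0])
            raise ValueError(
                f"undefined distance: all-zero vector between {name(i)} and {name(j)}"
            )
        with np.errstate(invalid="ignore"):
            D = 1.0 - dot / np.where(norm == 0.0, 1.0, norm)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history.

    Leaves are nodes ``0..n-1`` in input order; merge *t* creates node
    ``n+t``.  ``merges`` rows are ``(left, right, height)`` with heights
    non-decreasing (complete linkage is monotone).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"expected {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _leaf_index(self, leaf: str) -> int:
        try:
            return self.leaves.index(leaf)
        except ValueError:
            raise KeyError(f"unknown leaf: {leaf}") from None

    def are_siblings(self, a: str, b: str) -> bool:
        """True iff *a* and *b* merge with each other before anything else.

        Equivalently: some merge joins the two singletons directly.  The
        relation is invariant under left/right flips of a drawn tree.
        """
        ia, ib = self._leaf_index(a), self._leaf_index(b)
        target = (min(ia, ib), max(ia, ib))
        n = self.n_leaves
        for left, right, _ in self.merges:
            if left < n and right < n and (min(left, right), max(left, right)) == target:
                return True
        return False

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition into *k* clusters by removing the k-1 highest merges.

        Clusters are returned ordered by their smallest leaf index.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        node_root = list(range(n))  # root leaf-set representative per node id
        for t, (left, right, _) in enumerate(self.merges[: n - k]):
            ra, rb = find(node_root[left]), find(node_root[right])
            parent[rb] = ra
            members[ra] |= members.pop(rb)
            node_root.append(ra)
        clusters = sorted(members.values(), key=min)
        return [frozenset(self.leaves[i] for i in c) for c in clusters]

    def partition_labels(self, k: int) -> pd.Series:
        """Leaf -> cluster index (clusters ordered by smallest leaf index)."""
        out: dict[str, int] = {}
        for ci, cluster in enumerate(self.cut(k)):
            for leaf in cluster:
                out[leaf] = ci
        return pd.Series(out).reindex(list(self.leaves))

    def leaf_order(self) -> list[str]:
        """Displayed leaf order (left child expanded first)."""
        n = self.n_leaves
        if n == 1:
            return [self.leaves[0]]

        children = {n + t: (l, r) for t, (l, r, _) in enumerate(self.merges)}
        order: list[int] = []
        stack = [2 * n - 2]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                l, r = children[node]
                stack.append(r)
                stack.append(l)
        return [self.leaves[i] for i in order]

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for plotting/interop)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for t, (l, r, h) in enumerate(self.merges):
            sizes[n + t] = sizes[l] + sizes[r]
            Z[t] = [l, r, h, sizes[n + t]]
        return Z


def complete_linkage(
    data: GeneMatrix | np.ndarray | pd.DataFrame,
    axis: str = "samples",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomerative complete-linkage tree under uncentred correlation.

    ``axis="samples"`` clusters matrix rows (samples over gene features);
    ``axis="genes"`` clusters columns.  Inter-cluster distance is the
    maximum pairwise member distance; ties are broken toward the pair with
    the smallest original item indices.
    """
    if isinstance(data, GeneMatrix):
        frame = data.values if axis == "samples" else data.values.T
        X = frame.to_numpy(dtype=float)
        labels = list(frame.index)
    elif isinstance(data, pd.DataFrame):
        frame = data if axis == "samples" else data.T
        X = frame.to_numpy(dtype=float)
        labels = list(frame.index)
    else:
        X = np.asarray(data, dtype=float)
        if axis == "genes":
            X = X.T
        if labels is None:
            labels = [f"item{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = pairwise_uncentred_distance(X, labels)
    return linkage_from_distance(D, labels)


def linkage_from_distance(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Complete-linkage agglomeration of a precomputed distance matrix."""
    n = D.shape[0]
    size = 2 * n - 1
    W = np.full((size, size), np.inf)
    W[:n, :n] = D
    np.fill_diagonal(W, np.inf)
    active = np.zeros(size, dtype=bool)
    active[:n] = True
    rep = np.full(size, -1, dtype=int)  # smallest original index in cluster
    rep[:n] = np.arange(n)

    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        idx = np.nonzero(active)[0]
        sub = W[np.ix_(idx, idx)]
        m = sub.min()
        ii, jj = np.nonzero(sub == m)
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            i, j = idx[a], idx[b]
            key = (min(rep[i], rep[j]), max(rep[i], rep[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        new = n + t
        if rep[j] < rep[i]:
            i, j = j, i  # child with smaller representative first
        merges.append((int(i), int(j), float(m)))
        # complete linkage: distance to the merged cluster is the max
        d_new = np.maximum(W[i], W[j])
        W[new, :] = d_new
        W[:, new] = d_new
        W[new, new] = np.inf
        active[i] = active[j] = False
        active[new] = True
        rep[new] = min(rep[i], rep[j])
    return Dendrogram(tuple(labels), tuple(merges))


# ---------------------------------------------------------------------------
# Gene-size sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplePair:
    a: str
    b: str
    kind: str  # "same_tumour" | "concurrent"


@dataclass
class SweepResult:
    """Outcome of the minimum-probes-per-gene model-selection sweep."""

    table: pd.DataFrame
    partitions: dict[int, frozenset[frozenset[str]]]
    trees: dict[int, Dendrogram]
    selected: int | None


def _adjacent(tree: Dendrogram, pair: SamplePair, mode: str) -> bool:
    if mode == "sibling":
        return tree.are_siblings(pair.a, pair.b)
    order = tree.leaf_order()
    return abs(order.index(pair.a) - order.index(pair.b)) == 1


def sweep_gene_size(
    matrix: GeneMatrix,
    min_probe_thresholds=(10, 6, 4, 3, 2),
    pairs: list[SamplePair] | None = None,
    k: int = 3,
    adjacency: str = "sibling",
) -> SweepResult:
    """Repeated clustering over gene-size thresholds with model selection.

    For each threshold (largest genes first) the matrix is restricted to
    genes with ``probe_count >= threshold`` and the samples are clustered;
    the pair-adjacency standard and the k-cluster partition are recorded.
    The selected threshold is the largest one whose partition is identical
    to the next smaller threshold's partition and whose same-tumour-pair
    adjacency is maximal across thresholds.
    """
    if adjacency not in ("sibling", "leaf-order"):
        raise ValueError(f"unknown adjacency mode: {adjacency}")
    pairs = pairs or []
    same = [p for p in pairs if p.kind == "same_tumour"]
    conc = [p for p in pairs if p.kind == "concurrent"]
    thresholds = sorted(set(int(t) for t in min_probe_thresholds), reverse=True)

    rows = []
    partitions: dict[int, frozenset[frozenset[str]]] = {}
    trees: dict[int, Dendrogram] = {}
    for t in thresholds:
        sub = matrix.filter_min_probes(t)
        if sub.n_genes < 2:
            logger.warning(
                "threshold >=%d probes leaves %d genes; skipped", t, sub.n_genes
            )
            continue
        tree = complete_linkage(sub)
        part = frozenset(tree.cut(k))
        partitions[t] = part
        trees[t] = tree
        rows.append(
            {
                "min_probes": t,
                "n_genes": sub.n_genes,
                "same_tumour_adjacent": sum(
                    _adjacent(tree, p, adjacency) for p in same
                ),
                "same_tumour_total": len(same),
                "concurrent_adjacent": sum(
                    _adjacent(tree, p, adjacency) for p in conc
                ),
                "concurrent_total": len(conc),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no threshold left >= 2 genes")

    kept = list(table["min_probes"])
    equal_next = []
    for i, t in enumerate(kept):
        if i + 1 < len(kept):
            equal_next.append(partitions[t] == partitions[kept[i + 1]])
        else:
            equal_next.append(False)  # nothing smaller to compare against
    table["partition_equal_next"] = equal_next

    max_adj = table["same_tumour_adjacent"].max() if same else 0
    selected = None
    for i, t in enumerate(kept):
        adj_ok = (not same) or table.loc[i, "same_tumour_adjacent"] == max_adj
        if table.loc[i, "partition_equal_next"] and adj_ok:
            selected = t
            break  # thresholds are descending: first hit is the largest
    if selected is None:
        logger.warning("no threshold fulfilled both selection standards")
    return SweepResult(table, partitions, trees, selected)


# ---------------------------------------------------------------------------
# Lineage labelling
# ---------------------------------------------------------------------------

@dataclass
class LineageAssignment:
    labels: pd.Series  # sample_id -> stable|intermediate|unstable
    cluster_burdens: pd.Series  # label -> mean burden
    cluster_sizes: pd.Series
    mode: str


def label_lineages(
    partition: list[frozenset[str]],
    burdens: pd.Series,
    mode: str = "auto",
    manual_map: dict[int, str] | None = None,
) -> LineageAssignment:
    """Name the three clusters stable / intermediate / unstable.

    Auto mode: the cluster with the lowest mean CNA burden is *stable*; of
    the remaining two, the larger is *unstable* (the dominant
    high-instability lineage) and the other *intermediate*.  Size ties fall
    back to higher burden = unstable; burden ties are an error demanding
    manual mode.
    """
    if len(partition) != 3:
        raise ValueError(f"need a k=3 partition, got k={len(partition)}")
    means = []
    for cluster in partition:
        miss = [s for s in cluster if s not in burdens.index]
        if miss:
            raise ValueError(f"burden missing for samples: {miss}")
        means.append(float(burdens.loc[list(cluster)].mean()))

    if mode == "manual":
        if manual_map is None or set(manual_map) != {0, 1, 2} or set(
            manual_map.values()
        ) != {"stable", "intermediate", "unstable"}:
            raise ValueError(
                "manual mode needs a complete {cluster index -> label} map"
            )
        names = [manual_map[i] for i in range(3)]
    elif mode == "auto":
        order = np.argsort(means)
        if means[order[0]] == means[order[1]]:
            raise ValueError(
                "burden tie between clusters; use manual labelling mode"
            )
        stable_i = int(order[0])
        rest = [i for i in range(3) if i != stable_i]
        s0, s1 = len(partition[rest[0]]), len(partition[rest[1]])
        if s0 != s1:
            unstable_i = rest[0] if s0 > s1 else rest[1]
        else:
            if means[rest[0]] == means[rest[1]]:
                raise ValueError(
                    "size and burden tie between clusters; use manual mode"
                )
            unstable_i = rest[0] if means[rest[0]] > means[rest[1]] else rest[1]
        names = ["", "", ""]
        names[stable_i] = "stable"
        names[unstable_i] = "unstable"
        names[[i for i in range(3) if not names[i]][0]] = "intermediate"
    else:
        raise ValueError(f"unknown mode: {mode}")

    labels = {}
    for name, cluster in zip(names, partition):
        for s in cluster:
            labels[s] = name
    return LineageAssignment(
        labels=pd.Series(labels).sort_index(),
        cluster_burdens=pd.Series(dict(zip(names, means))),
        cluster_sizes=pd.Series({n: len(c) for n, c in zip(names, partition)}),
        mode=mode,
    )


def lineage_recovery_score(truth: pd.Series, predicted: pd.Series) -> float:
    """Adjusted Rand index between a truth labelling and a partition."""
    from sklearn.metrics import adjusted_rand_score

    common = truth.index.intersection(predicted.index)
    return float(adjusted_rand_score(truth.loc[common], predicted.loc[common]))
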