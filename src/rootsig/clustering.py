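"""Binary gene matrix, Jaccard distances, hierarchical clustering, MDS.

The corpus of biosets is turned into a biosets x genes 0/1 membership matrix
over the union gene universe. Pairwise relatedness between biosets is the
Jaccard coefficient |A∩B| / |A∪B| on their gene sets — chosen because shared
*absence* of a gene carries no information about relatedness — and the
clustering distance is its complement d = 1 − J.

The agglomeration is a plain Lance–Williams loop (single / complete /
average linkage) with a documented deterministic tie-break: among pairs at
the minimal distance, the lexicographically lowest pair of cluster indices
(leaves 0..n−1 in input order, internal nodes numbered in merge order)
merges first. This makes trees bit-reproducible on the tied distances that
binary data routinely produce. The merge table uses the scipy linkage-matrix
layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Bioset, check_unique_ids

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "single")


def jaccard_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """|a∩b| / |a∪b|; two empty sets have similarity 0 by convention."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def jaccard_distance(a: Iterable[str], b: Iterable[str]) -> float:
    return 1.0 - jaccard_similarity(a, b)


@dataclass(frozen=True)
class BinaryGeneMatrix:
    """Biosets x gene-universe 0/1 membership matrix.

    Row order follows corpus input order; columns are the lexicographically
    sorted union of all gene sets (so there are no all-zero columns).
    """

    data: pd.DataFrame  # index: bioset_ids, columns: genes, values: 0/1 int
    metadata: pd.DataFrame  # index: bioset_ids; columns: experiment_id, tissue

    @property
    def bioset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def to_sets(self) -> dict[str, frozenset[str]]:
        cols = np.asarray(self.data.columns)
        vals = self.data.to_numpy(dtype=bool)
        return {
            bid: frozenset(cols[vals[i]].tolist())
            for i, bid in enumerate(self.data.index)
        }

    def to_corpus(self) -> list[Bioset]:
        sets = self.to_sets()
        return [
            Bioset(
                bioset_id=bid,
                experiment_id=self.metadata.loc[bid, "experiment_id"],
                tissue=self.metadata.loc[bid, "tissue"],
                genes=sets[bid],
            )
            for bid in self.bioset_ids
        ]


def build_matrix(corpus: Sequence[Bioset]) -> BinaryGeneMatrix:
    """Assemble the binary presence/absence matrix for a corpus."""
    if len(corpus) < 2:
        raise ValueError("need at least 2 biosets")
    check_unique_ids(corpus)
    universe = sorted(set().union(*(b.genes for b in corpus)))
    if not universe:
        raise ValueError("gene universe is empty (all biosets empty)")
    gene_pos = {g: j for j, g in enumerate(universe)}
    mat = np.zeros((len(corpus), len(universe)), dtype=np.int8)
    for i, b in enumerate(corpus):
        for g in b.genes:
            mat[i, gene_pos[g]] = 1
    data = pd.DataFrame(mat, index=[b.bioset_id for b in corpus], columns=universe)
    meta = pd.DataFrame(
        {
            "experiment_id": [b.experiment_id for b in corpus],
            "tissue": [b.tissue for b in corpus],
        },
        index=data.index,
    )
    return BinaryGeneMatrix(data=data, metadata=meta)


def jaccard_distance_matrix(matrix: BinaryGeneMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distances between matrix rows.

    Computed by matrix algebra: intersections from the boolean Gram matrix,
    unions from row sums. Pairs with an empty union (two empty biosets) get
    distance 1 per the empty-set convention; the diagonal is 0 regardless.
    """
    m = matrix.data.to_numpy(dtype=float)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.data.index, columns=matrix.data.index)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form.

    ``merges`` has one row per merge: (left child id, right child id, merge
    height, leaf count). Leaves are 0..n−1 in ``leaf_names`` order; the node
    created by merge row i has id n+i. Heights are nondecreasing.
    """

    merges: np.ndarray  # (n-1, 4) float
    leaf_names: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)


def _check_distance_matrix(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")


def hierarchical_cluster(
    distances: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    leaf_names: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerate under the chosen linkage with lowest-index tie-breaking."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if isinstance(distances, pd.DataFrame):
        if leaf_names is None:
            leaf_names = [str(x) for x in distances.index]
        d = distances.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(distances, dtype=float).copy()
        if leaf_names is None:
            leaf_names = [str(i) for i in range(d.shape[0])]
    _check_distance_matrix(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # active clusters: node id -> (row index in working matrix, leaf count)
    node_of_row = list(range(n))  # row -> node id
    size = {i: 1 for i in range(n)}
    active = d  # working matrix shrinks as clusters merge
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        m = active.shape[0]
        tri = np.triu_indices(m, k=1)
        flat = active[tri]
        h = flat.min()
        # tie-break: among minimal pairs choose lowest (node_i, node_j)
        best = None
        for a, b in zip(*(idx[flat <= h] for idx in tri)):
            ni, nj = sorted((node_of_row[a], node_of_row[b]))
            key = (ni, nj)
            if best is None or key < best[0]:
                best = (key, a, b)
        (ni, nj), ra, rb = best
        new_id = n + step
        merges[step] = (ni, nj, h, size[ni] + size[nj])
        size[new_id] = size[ni] + size[nj]

        # Lance–Williams update of distances to the merged cluster
        da, db = active[ra], active[rb]
        if linkage == "single":
            new_d = np.minimum(da, db)
        elif linkage == "complete":
            new_d = np.maximum(da, db)
        else:  # average (UPGMA)
            wa, wb = size[ni], size[nj]
            new_d = (wa * da + wb * db) / (wa + wb)

        keep = [r for r in range(m) if r not in (ra, rb)]
        reduced = active[np.ix_(keep, keep)]
        row = new_d[keep]
        active = np.zeros((len(keep) + 1, len(keep) + 1))
        active[: len(keep), : len(keep)] = reduced
        active[-1, : len(keep)] = row
        active[: len(keep), -1] = row
        node_of_row = [node_of_row[r] for r in keep] + [new_id]

    return Dendrogram(merges=merges, leaf_names=tuple(leaf_names))


@dataclass(frozen=True)
class ClusterPartition:
    """Assignment of every bioset to one of k clusters (labels 1..k)."""

    k: int
    assignment: dict[str, int]

    def members_of(self, label: int) -> list[str]:
        return [b for b, c in self.assignment.items() if c == label]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for b, c in self.assignment.items():
            out[c].append(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bioset_id": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def cut_tree(tree: Dendrogram, k: int) -> ClusterPartition:
    """Cut into k clusters by undoing the k−1 last merges (merge order).

    Because merge heights are nondecreasing, keeping the first n−k merges is
    the same as removing the k−1 highest ones, with ties resolved by merge
    order as documented.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        new_id = n + step
        parent[find(int(a))] = new_id
        parent[find(int(b))] = new_id

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf, name in enumerate(tree.leaf_names):
        r = find(leaf)
        if r not in root_label:
            root_label[r] = len(root_label) + 1
        labels[name] = root_label[r]
    return ClusterPartition(k=k, assignment=labels)


def classical_mds(
    distances: pd.DataFrame | np.ndarray, dims: int = 2
) -> pd.DataFrame:
    """Principal-coordinates embedding of a dissimilarity matrix.

    Double-centers −½ d², eigendecomposes, and returns the top-``dims``
    coordinates scaled by the square root of the eigenvalues. Negative
    eigenvalues (non-Euclidean dissimilarities) are truncated to zero with a
    warning; if fewer than ``dims`` positive dimensions exist, the remaining
    coordinates are zero.
    """
    if isinstance(distances, pd.DataFrame):
        names = [str(x) for x in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        names = [str(i) for i in range(d.shape[0])]
    _check_distance_matrix(d)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if (w < -1e-9).any():
        logger.warning(
            "classical_mds: %d negative eigenvalue(s) truncated to zero",
            int((w < -1e-9).sum()),
        )
    w = np.clip(w, 0.0, None)
    coords = v[:, :dims] * np.sqrt(w[:dims])
    if dims > n:
        coords = np.hstack([coords, np.zeros((n, dims - coords.shape[1]))])
        logger.warning("classical_mds: dims exceeds rank; padded with zeros")
    return pd.DataFrame(
        coords, index=names, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
    )


def to_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string.

    Branch lengths are parent merge height minus child merge height (leaves
    have height 0), so root-to-leaf path lengths equal merge heights.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, h, _) in enumerate(tree.merges):
        node = n + step
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{tree.leaf_names[node]}:{bl:.10g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{bl:.10g}"

    root = 2 * n - 2
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"
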