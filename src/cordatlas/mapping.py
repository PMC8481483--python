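"""Cross-atlas cluster relationships and embryonic lineage assignment.

Cluster geometry is summarized by centroids in PC space (per-cluster mean of
each component); relationships are expressed as pairwise Euclidean centroid
distances, a complete-linkage dendrogram over those distances, row-normalized
overlap (contingency) matrices between labelings of the same cells, and
correlation-based registration of mean-expression profiles over highly
variable genes.  Embryonic-to-postnatal lineage calls combine two evidence
streams computed in a shared co-integrated PC space: the rank of each
embryonic centroid by distance to the postnatal centroid, and the label votes
of the embryonic cells nearest that centroid.  Secondary lineages passing a
vote threshold are reported as convergences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CentroidSet",
    "LineageAssignment",
    "cluster_centroids",
    "centroid_distances",
    "build_dendrogram",
    "dendrogram_to_newick",
    "overlap_matrix",
    "register_by_correlation",
    "assign_lineage",
]


@dataclass
class CentroidSet:
    names: list[str]
    coords: np.ndarray  # (n_clusters, n_dims)
    n_cells: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.names)


@dataclass
class LineageAssignment:
    """Ranked lineage evidence per postnatal cluster."""

    table: pd.DataFrame  # postnatal, embryonic, distance_rank, vote_fraction, combined_rank
    primary: dict[str, str]  # postnatal cluster -> primary embryonic call
    secondary: dict[str, list[str]]  # additional calls above the vote threshold


def cluster_centroids(
    embedding: np.ndarray, labels: np.ndarray, n_dims: int = 50
) -> CentroidSet:
    """Per-cluster arithmetic mean over the first ``n_dims`` components."""
    X = np.asarray(embedding, float)
    if n_dims > X.shape[1]:
        raise ValueError("n_dims exceeds embedding width")
    X = X[:, :n_dims]
    labels = np.asarray(labels).astype(str)
    names = sorted(set(labels.tolist()))
    coords = np.vstack([X[labels == c].mean(axis=0) for c in names])
    n_cells = np.array([(labels == c).sum() for c in names])
    return CentroidSet(names=names, coords=coords, n_cells=n_cells)


def centroid_distances(a: CentroidSet, b: CentroidSet | None = None) -> pd.DataFrame:
    """Pairwise Euclidean distances between centroid sets."""
    B = a if b is None else b
    D = np.linalg.norm(a.coords[:, None] - B.coords[None], axis=2)
    return pd.DataFrame(D, index=a.names, columns=B.names)


def build_dendrogram(centroids: CentroidSet) -> np.ndarray:
    """Complete-linkage dendrogram over centroid Euclidean distances.

    Returns the scipy linkage matrix; leaf order follows ``centroids.names``
    (ties broken by that order, which is deterministic).
    """
    if len(centroids.names) < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    D = centroid_distances(centroids).to_numpy()
    return sch.linkage(squareform(D, checks=False), method="complete")


def dendrogram_to_newick(linkage: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def _rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = _rec(node.left, node.dist)
        right = _rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({_rec(tree.left, tree.dist)},{_rec(tree.right, tree.dist)});"


def overlap_matrix(labels_a: np.ndarray, labels_b: np.ndarray) -> pd.DataFrame:
    """Row-normalized contingency matrix of two labelings of the same cells.

    entry(i, j) = |cells with a=i and b=j| / |cells with a=i|.
    """
    labels_a = np.asarray(labels_a).astype(str)
    labels_b = np.asarray(labels_b).astype(str)
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same cells")
    tab = pd.crosstab(pd.Series(labels_a, name="a"), pd.Series(labels_b, name="b"))
    return tab.div(tab.sum(axis=1), axis=0)


def register_by_correlation(
    mean_expr_a: pd.DataFrame,
    mean_expr_b: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Match clusters across atlases by Pearson correlation of mean profiles.

    ``mean_expr_*`` are cluster-by-gene mean expression matrices (typically
    over the top-500 HVGs).  Each cluster in ``a`` is matched to its
    maximum-correlation cluster in ``b``; the full correlation matrix and the
    per-cluster best matches are returned.
    """
    shared = mean_expr_a.columns.intersection(mean_expr_b.columns)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    A = mean_expr_a[shared].to_numpy(float)
    B = mean_expr_b[shared].to_numpy(float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A /= np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    B /= np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    corr = pd.DataFrame(A @ B.T, index=mean_expr_a.index, columns=mean_expr_b.index)
    best = corr.idxmax(axis=1)
    return corr, best


def assign_lineage(
    co_embedding: np.ndarray,
    embryonic_mask: np.ndarray,
    embryonic_labels: np.ndarray,
    postnatal_labels: np.ndarray,
    k_cells: int = 50,
    vote_threshold: float = 0.2,
    n_dims: int = 50,
) -> LineageAssignment:
    """Assign embryonic lineages to postnatal clusters in a shared PC space.

    For each postnatal cluster: (a) embryonic centroids are ranked by
    Euclidean distance to the postnatal centroid; (b) the ``k_cells``
    embryonic cells nearest the postnatal centroid vote with their labels.
    The primary call minimizes the sum of the two ranks (ties broken by
    centroid distance); any other embryonic cluster whose vote fraction
    reaches ``vote_threshold`` is reported as a secondary lineage, i.e. a
    candidate convergence.
    """
    co_embedding = np.asarray(co_embedding, float)
    embryonic_mask = np.asarray(embryonic_mask, bool)
    if embryonic_mask.sum() == 0:
        raise ValueError("empty embryonic set")
    n_dims = min(n_dims, co_embedding.shape[1])
    X = co_embedding[:, :n_dims]

    emb_labels = np.asarray(embryonic_labels).astype(str)
    post_labels = np.asarray(postnatal_labels).astype(str)
    emb_cents = cluster_centroids(X[embryonic_mask], emb_labels, n_dims)
    post_cents = cluster_centroids(X[~embryonic_mask], post_labels, n_dims)

    emb_X = X[embryonic_mask]
    k = min(k_cells, emb_X.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(emb_X)

    rows = []
    primary: dict[str, str] = {}
    secondary: dict[str, list[str]] = {}
    for pi, pc in enumerate(post_cents.names):
        d = np.linalg.norm(emb_cents.coords - post_cents.coords[pi], axis=1)
        dist_rank = pd.Series(d, index=emb_cents.names).rank(method="min")
        idx = nn.kneighbors(post_cents.coords[pi][None], return_distance=False)[0]
        votes = pd.Series(emb_labels[idx]).value_counts() / k
        vote_frac = pd.Series(0.0, index=emb_cents.names)
        vote_frac[votes.index] = votes.values
        vote_rank = (-vote_frac).rank(method="min")
        combined = dist_rank + vote_rank
        order = sorted(
            emb_cents.names, key=lambda e: (combined[e], d[emb_cents.names.index(e)])
        )
        primary[pc] = order[0]
        secondary[pc] = [
            e for e in order[1:] if vote_frac[e] >= vote_threshold
        ]
        for e in emb_cents.names:
            rows.append(
                {
                    "postnatal": pc,
                    "embryonic": e,
                    "centroid_distance": d[emb_cents.names.index(e)],
                    "distance_rank": int(dist_rank[e]),
                    "vote_fraction": float(vote_frac[e]),
                    "combined_rank": float(combined[e]),
                    "call": "primary" if e == order[0] else
                            ("secondary" if e in secondary[pc] else "none"),
                }
            )
    table = pd.DataFrame(rows)
    return LineageAssignment(table=table, primary=primary, secondary=secondary)
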