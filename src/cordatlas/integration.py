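"""Anchor-based cross-study integration, PCA, and the LISI mixing metric.

Two batches are embedded in a shared low-dimensional space by diagonalized
canonical correlation analysis (SVD of the cross-product of their scaled HVG
matrices, row embeddings L2-normalized).  Anchors are mutual nearest
neighbor cell pairs across the batches in that space, scored by shared
neighborhood overlap.  Correction subtracts, from every query cell, a
weighted average of anchor difference vectors (Gaussian distance kernel over
the nearest anchors, multiplied by the anchor score).  Batches are merged
sequentially, largest first.  Integration quality is assessed with the Local
Inverse Simpson Index (LISI): the effective number of labels in each cell's
kernel-weighted neighborhood, ~n_batches for perfect mixing, 1 for none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "IntegrationParams",
    "AnchorSet",
    "Embedding",
    "reduce_pair",
    "find_anchors",
    "integrate",
    "pca",
    "lisi",
]


@dataclass
class IntegrationParams:
    n_cc: int = 20  # canonical components for anchoring
    k_anchor: int = 5  # mutual-neighbor size
    k_score: int = 30  # neighborhood size for anchor scoring
    k_weight: int = 100  # anchors used to weight each cell's correction
    n_pcs_out: int = 100

    def __post_init__(self) -> None:
        if min(self.n_cc, self.k_anchor, self.k_score, self.k_weight) < 1:
            raise ValueError("all integration sizes must be >= 1")


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor cell pairs across one dataset pair."""

    pairs: np.ndarray  # (n_anchors, 2) indices into (dataset_a, dataset_b)
    scores: np.ndarray  # in [0, 1]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Embedding:
    """PCA embedding with the loadings needed to project new data."""

    coords: np.ndarray  # (cells, k)
    loadings: np.ndarray  # (genes, k)
    explained_variance: np.ndarray
    mean: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings


def _fix_signs(U: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    M = U if ref is None else ref
    idx = np.argmax(np.abs(M), axis=0)
    signs = np.sign(M[idx, np.arange(M.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def reduce_pair(
    scaled_a: np.ndarray, scaled_b: np.ndarray, n_cc: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Joint CCA embedding of two scaled cells-by-genes matrices.

    Computes the SVD of ``A @ B.T`` over the shared (column-aligned) gene
    set; the left/right singular vectors are the two batches' coordinates in
    the shared space, L2-normalized per cell.  Column signs follow the
    convention that the largest-magnitude entry of each component (over both
    batches) is positive.
    """
    A = np.asarray(scaled_a, float)
    B = np.asarray(scaled_b, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("batches must share one aligned gene set")
    if A.shape[1] == 0:
        raise ValueError("empty (disjoint) gene set")
    n_cc = min(n_cc, min(A.shape[0], B.shape[0]))
    K = A @ B.T
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    U, V = U[:, :n_cc], Vt.T[:, :n_cc]
    both = np.vstack([U, V])
    idx = np.argmax(np.abs(both), axis=0)
    signs = np.sign(both[idx, np.arange(both.shape[1])])
    signs[signs == 0] = 1.0
    U, V = U * signs, V * signs
    U /= np.maximum(np.linalg.norm(U, axis=1, keepdims=True), 1e-12)
    V /= np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
    return U, V


def find_anchors(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    k_anchor: int = 5,
    k_score: int = 30,
) -> AnchorSet:
    """Mutual k-nearest-neighbor anchors between two embedded batches.

    A pair (a, b) is an anchor when b is among a's k_anchor nearest cells in
    batch B and vice versa.  Each anchor is scored by the shared-neighbor
    overlap of the two cells' k_score-neighborhoods in the combined space,
    min-max normalized to [0, 1].
    """
    na, nb = len(emb_a), len(emb_b)
    ka = min(k_anchor, nb)
    kb = min(k_anchor, na)
    nn_b = NearestNeighbors(n_neighbors=ka).fit(emb_b)
    nn_a = NearestNeighbors(n_neighbors=kb).fit(emb_a)
    ab = nn_b.kneighbors(emb_a, return_distance=False)
    ba = nn_a.kneighbors(emb_b, return_distance=False)
    ba_sets = [set(row) for row in ba]
    pairs = [
        (i, j) for i in range(na) for j in ab[i] if i in ba_sets[j]
    ]
    if not pairs:
        warnings.warn("no mutual nearest-neighbor anchors found")
        return AnchorSet(pairs=np.zeros((0, 2), dtype=int), scores=np.zeros(0))

    joint = np.vstack([emb_a, emb_b])
    ks = min(k_score, len(joint) - 1)
    nn_joint = NearestNeighbors(n_neighbors=ks).fit(joint)
    neigh = nn_joint.kneighbors(joint, return_distance=False)
    neigh_sets = [set(row) for row in neigh]
    raw = np.array(
        [len(neigh_sets[i] & neigh_sets[na + j]) for i, j in pairs], dtype=float
    )
    lo, hi = raw.min(), raw.max()
    scores = np.ones_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return AnchorSet(pairs=np.asarray(pairs, dtype=int), scores=scores)


def _correct_query(
    X_ref: np.ndarray,
    X_query: np.ndarray,
    emb_query: np.ndarray,
    anchors: AnchorSet,
    k_weight: int,
) -> np.ndarray:
    """Shift query expression by anchor-weighted batch difference vectors."""
    if len(anchors) == 0:
        return X_query
    diffs = X_ref[anchors.pairs[:, 0]] - X_query[anchors.pairs[:, 1]]
    anchor_pos = emb_query[anchors.pairs[:, 1]]
    kw = min(k_weight, len(anchors))
    if kw < k_weight:
        warnings.warn(f"k_weight lowered to {kw} (only {len(anchors)} anchors)")
    nn = NearestNeighbors(n_neighbors=kw).fit(anchor_pos)
    dist, idx = nn.kneighbors(emb_query)
    # Gaussian kernel over distance to the k-th anchor, times anchor score.
    bw = np.maximum(dist[:, -1:], 1e-12)
    w = np.exp(-0.5 * (dist / bw) ** 2) * anchors.scores[idx]
    w_sum = np.maximum(w.sum(axis=1, keepdims=True), 1e-12)
    correction = np.einsum("ck,ckg->cg", w / w_sum, diffs[idx])
    return X_query + correction


def integrate(
    datasets: list[np.ndarray],
    params: IntegrationParams = IntegrationParams(),
) -> np.ndarray:
    """Sequentially merge scaled HVG matrices with anchor-based correction.

    The largest dataset is the initial reference; the others are merged in
    descending size order, each corrected toward the current reference.  The
    returned matrix stacks datasets in their input order and has the same
    shape as the input stack (cell count and gene set are never changed).
    """
    if len(datasets) == 0:
        raise ValueError("no datasets to integrate")
    if len(datasets) == 1:
        return np.asarray(datasets[0], float)

    order = sorted(range(len(datasets)), key=lambda i: -datasets[i].shape[0])
    corrected: dict[int, np.ndarray] = {order[0]: np.asarray(datasets[order[0]], float)}
    ref = corrected[order[0]]
    for i in order[1:]:
        q = np.asarray(datasets[i], float)
        emb_ref, emb_q = reduce_pair(ref, q, params.n_cc)
        anchors = find_anchors(emb_ref, emb_q, params.k_anchor, params.k_score)
        cq = _correct_query(ref, q, emb_q, anchors, params.k_weight)
        corrected[i] = cq
        ref = np.vstack([ref, cq])
    return np.vstack([corrected[i] for i in range(len(datasets))])


def pca(X: np.ndarray, n_pcs: int = 100) -> Embedding:
    """Centered PCA with a deterministic sign convention.

    Loadings are retained so query data can be projected; each component is
    flipped so its largest-magnitude gene loading is positive.
    """
    X = np.asarray(X, float)
    max_rank = min(X.shape)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank bound {max_rank}; truncated")
        n_pcs = max_rank
    mean = X.mean(axis=0)
    Xc = X - mean
    if max_rank > 300 and n_pcs <= max_rank // 5:
        # randomized solver for large problems; seeded, hence deterministic
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(Xc, n_components=n_pcs, random_state=0)
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = _fix_signs(Vt.T[:, :n_pcs], ref=Vt.T[:, :n_pcs])
    coords = Xc @ V
    ev = (s[:n_pcs] ** 2) / max(X.shape[0] - 1, 1)
    return Embedding(coords=coords, loadings=V, explained_variance=ev, mean=mean)


def lisi(
    embedding: np.ndarray,
    labels: np.ndarray,
    perplexity: float = 30.0,
) -> np.ndarray:
    """Per-cell Local Inverse Simpson Index of ``labels`` in ``embedding``.

    For each cell, Gaussian kernel weights over its neighbors are tuned by
    bisection so the weight distribution's entropy matches log(perplexity);
    LISI = 1 / sum_l p(l)^2 over the kernel-weighted label distribution.
    """
    X = np.asarray(embedding, float)
    labels = np.asarray(labels)
    n = len(X)
    if perplexity >= n - 1:
        raise ValueError("perplexity must be < n - 1")
    codes = np.unique(labels, return_inverse=True)[1]
    n_labels = codes.max() + 1
    k = min(int(3 * perplexity) + 1, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist**2
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * d2[i])
            sw = w.sum()
            if sw <= 0:
                beta = lo = lo / 2
                continue
            p = w / sw
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        w = np.exp(-beta * d2[i])
        p = w / max(w.sum(), 1e-300)
        probs = np.bincount(codes[idx[i]], weights=p, minlength=n_labels)
        out[i] = 1.0 / max((probs**2).sum(), 1e-300)
    return out
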