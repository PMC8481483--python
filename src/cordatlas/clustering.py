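"""Multiphase graph clustering with cluster-hygiene rules and robustness.

Cells are clustered on a shared-nearest-neighbor (SNN) graph: k-nearest
neighbors in PC space with Jaccard edge weights, partitioned by the Leiden
algorithm at a given resolution.  Clustering proceeds in phases (all cells,
then the neuronal compartment, then targeted sub-clustering), and after each
phase three hygiene rules run:

* low-quality rule — clusters with fewer than three significant enriched
  markers are flagged and excluded downstream;
* doublet rule — clusters whose markers span two unrelated coarse
  signatures AND whose individual cells co-express the top markers of both
  signatures ("barnyard" pattern) are flagged;
* merge rule — mutually-nearest cluster pairs with fewer than three genes
  enriched in each cluster (six total) are merged, unless a classic marker
  gene ranks among the top five differentially expressed genes of the pair.

Cluster robustness is scored by bootstrapped co-clustering: the fraction of
repeated subsampled clustering runs in which within-cluster cell pairs stay
together, plus per-cluster mean silhouette.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .qc import HVGParams, ScalingParams, select_hvgs, scale_regress

__all__ = [
    "PhaseParams",
    "ClusterLabeling",
    "RobustnessReport",
    "MergeRuleParams",
    "snn_graph",
    "cluster_graph",
    "resolution_sweep",
    "silhouette_scores",
    "coclustering_robustness",
    "make_standard_cluster_fn",
    "make_matrix_cluster_fn",
    "flag_low_quality",
    "flag_doublet_cluster",
    "merge_pass",
    "multiphase_cluster",
    "default_phase_params",
]


@dataclass
class PhaseParams:
    """Parameters for one clustering phase."""

    phase_id: str
    n_pcs: int
    resolution: float
    hvg: HVGParams = field(default_factory=HVGParams)
    k: int = 20
    parent_signature: list[str] | None = None  # genes selecting parent clusters
    min_cells: int = 50  # skip the phase if fewer cells are selected

    def __post_init__(self) -> None:
        if self.n_pcs < 1 or self.resolution <= 0:
            raise ValueError("n_pcs must be >= 1 and resolution > 0")


@dataclass
class MergeRuleParams:
    min_de_each: int = 3  # enriched genes required per side to stay separate
    classic_marker_rank: int = 5  # classic marker must rank in the top-N DE genes
    classic_marker_list: tuple[str, ...] = ()

    @property
    def min_de_total(self) -> int:
        return 2 * self.min_de_each


@dataclass
class ClusterLabeling:
    labels: np.ndarray  # final per-cell cluster id (str); excluded cells keep phase label
    status: dict[str, str]  # cluster id -> kept | low_quality | doublet | merged
    merge_provenance: dict[str, str]  # child id -> surviving id
    phase_labels: pd.DataFrame | None = None  # per-cell labels per phase

    def kept_clusters(self) -> list[str]:
        return sorted(c for c, s in self.status.items() if s == "kept")


@dataclass
class RobustnessReport:
    frequency: dict[str, float]  # per-cluster co-clustering frequency
    silhouette: dict[str, float]
    n_iterations: int
    flagged: list[str] = field(default_factory=list)  # clusters with undefined frequency


def snn_graph(
    embedding: np.ndarray,
    n_pcs: int | None = None,
    k: int = 20,
    prune: float = 1 / 15,
) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighborhood is its k nearest cells (self included, as is
    conventional for SNN graphs); the edge weight between two cells is the
    Jaccard overlap of their neighborhoods, pruned at ``prune``.
    """
    X = np.asarray(embedding, float)
    if n_pcs is not None:
        if n_pcs > X.shape[1]:
            raise ValueError("n_pcs exceeds embedding width")
        X = X[:, :n_pcs]
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()  # |N(i) & N(j)|
    i, j, inter = shared.row, shared.col, shared.data
    mask = i < j
    i, j, inter = i[mask], j[mask], inter[mask]
    jac = inter / (2 * k - inter)
    keep = jac > prune
    g = ig.Graph(n=n, edges=list(zip(i[keep].tolist(), j[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection (RB-configuration modularity) on an SNN graph."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def resolution_sweep(
    embedding: np.ndarray,
    resolutions: Sequence[float],
    seed: int = 0,
    k: int = 20,
) -> pd.DataFrame:
    """Cluster at a range of resolutions and tabulate stability diagnostics.

    For each resolution: the number of clusters, the mean silhouette, and
    the split-stability (fraction of clusters whose member set is unchanged
    from the previous, lower resolution).  The table is returned; choosing a
    resolution is left to the caller.
    """
    g = snn_graph(embedding, k=k)
    rows = []
    prev: np.ndarray | None = None
    for res in resolutions:
        labels = cluster_graph(g, resolution=res, seed=seed)
        n_clusters = len(np.unique(labels))
        if n_clusters > 1:
            sil = float(np.mean(silhouette_samples(embedding, labels)))
        else:
            sil = float("nan")
        if prev is None:
            stability = float("nan")
        else:
            prev_sets = {tuple(np.flatnonzero(prev == c)) for c in np.unique(prev)}
            cur_sets = {tuple(np.flatnonzero(labels == c)) for c in np.unique(labels)}
            stability = len(prev_sets & cur_sets) / max(len(cur_sets), 1)
        rows.append(
            {"resolution": res, "n_clusters": n_clusters, "mean_silhouette": sil,
             "split_stability": stability}
        )
        prev = labels
    return pd.DataFrame(rows)


def silhouette_scores(
    embedding: np.ndarray, labels: np.ndarray
) -> tuple[dict[str, float], list[str]]:
    """Per-cluster mean silhouette on Euclidean distances.

    Singleton clusters score 0 by convention and are returned in the flagged
    list.  A single global cluster is an error (silhouette undefined).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    flagged = [str(c) for c in uniq if (labels == c).sum() < 2]
    # silhouette_samples rejects nothing for singletons (scores them 0), so
    # compute directly and then overwrite singleton clusters explicitly.
    samp = silhouette_samples(np.asarray(embedding, float), labels)
    out = {}
    for c in uniq:
        m = labels == c
        out[str(c)] = 0.0 if m.sum() < 2 else float(samp[m].mean())
    return out, flagged


def make_standard_cluster_fn(
    hvg: HVGParams,
    n_pcs: int,
    resolution: float,
    k: int = 20,
    scaling: ScalingParams = ScalingParams(),
) -> Callable:
    """Factory for the HVG -> scale -> PCA -> SNN -> Leiden pipeline step.

    The returned callable maps (log-normalized AnnData, seed) to labels and
    is what the bootstrap robustness test re-runs on each subsample.
    """
    from .integration import pca as run_pca

    def _fn(adata, seed: int) -> np.ndarray:
        genes = select_hvgs(adata, hvg)
        if len(genes) < 2:
            genes = list(adata.var_names)
        X, _ = scale_regress(adata, genes, scaling)
        emb = run_pca(X, min(n_pcs, min(X.shape) - 1))
        g = snn_graph(emb.coords, k=min(k, adata.n_obs - 1))
        return cluster_graph(g, resolution=resolution, seed=seed)

    return _fn


def make_matrix_cluster_fn(n_pcs: int, resolution: float, k: int = 20) -> Callable:
    """PCA -> SNN -> Leiden on an already-corrected expression matrix.

    For robustness scoring of an integrated clustering: the batch correction
    is part of the clustering being scored, so subsamples are drawn from the
    corrected matrix and only the downstream steps are repeated.
    """
    from .integration import pca as run_pca

    def _fn(X: np.ndarray, seed: int) -> np.ndarray:
        emb = run_pca(X, min(n_pcs, min(X.shape) - 1))
        g = snn_graph(emb.coords, k=min(k, X.shape[0] - 1))
        return cluster_graph(g, resolution=resolution, seed=seed)

    return _fn


def coclustering_robustness(
    adata,
    reference_labels: np.ndarray,
    cluster_fn: Callable,
    n_iter: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    embedding: np.ndarray | None = None,
) -> RobustnessReport:
    """Bootstrapped co-clustering frequency per reference cluster.

    On each of ``n_iter`` iterations a fraction of cells is subsampled
    without replacement and the full clustering pipeline (``cluster_fn``) is
    re-run.  A cell pair co-clusters in an iteration when both are sampled
    and assigned to the same cluster.  The per-cluster frequency is the mean
    over within-cluster pairs of (co-clustered iterations) / (iterations in
    which both members were sampled).  If ``embedding`` is given, per-cluster
    mean silhouettes in that space are included.
    """
    reference_labels = np.asarray(reference_labels)
    is_array = isinstance(adata, np.ndarray)
    n = adata.shape[0] if is_array else adata.n_obs
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n), dtype=np.int32)
    both = np.zeros((n, n), dtype=np.int32)
    m = max(2, int(round(subsample_frac * n)))
    for _ in range(n_iter):
        samp = np.sort(rng.choice(n, size=min(m, n), replace=False))
        sub = adata[samp] if is_array else adata[samp].copy()
        labels = np.asarray(cluster_fn(sub, int(rng.integers(2**31 - 1))))
        same = labels[:, None] == labels[None, :]
        both[np.ix_(samp, samp)] += 1
        together[np.ix_(samp, samp)] += same.astype(np.int32)

    freq: dict[str, float] = {}
    flagged: list[str] = []
    for c in np.unique(reference_labels):
        members = np.flatnonzero(reference_labels == c)
        if len(members) < 2:
            flagged.append(str(c))
            freq[str(c)] = float("nan")
            continue
        B = both[np.ix_(members, members)]
        T = together[np.ix_(members, members)]
        iu = np.triu_indices(len(members), 1)
        b, t = B[iu], T[iu]
        ok = b > 0
        freq[str(c)] = float(np.mean(t[ok] / b[ok])) if ok.any() else float("nan")

    sil: dict[str, float] = {}
    if embedding is not None and len(np.unique(reference_labels)) > 1:
        sil, _ = silhouette_scores(embedding, reference_labels)
    return RobustnessReport(frequency=freq, silhouette=sil, n_iterations=n_iter, flagged=flagged)


def flag_low_quality(
    de_table: pd.DataFrame,
    median_n_genes: float | None = None,
    min_markers: int = 3,
    alpha: float = 0.05,
    min_logfc: float = 0.25,
    min_pct: float = 0.1,
) -> tuple[bool, dict]:
    """Low-quality rule: fewer than ``min_markers`` significant enriched markers.

    Returns the flag and an evidence dict (marker count, the markers, and the
    cluster's median detected-gene count when provided).
    """
    if de_table.empty:
        markers: list[str] = []
    else:
        sig = (
            (de_table["p_adj"] < alpha)
            & (de_table["log_fc"] > min_logfc)
            & (de_table["pct_group"] >= min_pct)
        )
        markers = list(de_table.index[sig])
    flagged = len(markers) < min_markers
    return flagged, {
        "n_significant_markers": len(markers),
        "markers": markers[:10],
        "median_n_genes": median_n_genes,
    }


def flag_doublet_cluster(
    X_norm,
    cluster_mask: np.ndarray,
    cluster_markers: Sequence[str],
    signature_sets: Mapping[str, pd.Index | Sequence[str]],
    gene_index: pd.Index,
    top_n: int = 10,
    dual_fraction_threshold: float = 0.5,
    background_quantile: float = 0.9,
    positive_fraction: float = 0.5,
) -> tuple[bool, dict]:
    """Doublet-cluster rule: markers of two unrelated types, co-expressed per cell.

    (a) the cluster's significant markers must intersect at least two of the
    provided (unrelated) coarse signature sets; (b) for the two best-hit
    signatures, a cluster cell counts as positive for a signature when its
    summed expression of the signature's top ``top_n`` genes exceeds
    ``positive_fraction`` of the signature's positive peak (the
    ``background_quantile`` of scores among cells outside the cluster); the
    cluster is a doublet cluster when the fraction of cells positive for
    BOTH signatures simultaneously reaches ``dual_fraction_threshold`` (the
    barnyard criterion).  A mixture of two pure subsets fails (b).
    """
    cluster_mask = np.asarray(cluster_mask, bool)
    marker_set = set(cluster_markers)
    hits = {
        name: len(marker_set & set(list(genes)))
        for name, genes in signature_sets.items()
    }
    hit_names = [k for k, v in sorted(hits.items(), key=lambda kv: -kv[1]) if v > 0]
    evidence: dict = {"signature_hits": hits}
    if len(hit_names) < 2:
        return False, evidence

    s1, s2 = hit_names[0], hit_names[1]
    dense = X_norm.toarray() if sp.issparse(X_norm) else np.asarray(X_norm, float)
    dual = np.ones(cluster_mask.sum(), dtype=bool)
    for s in (s1, s2):
        genes = [g for g in list(signature_sets[s])[:top_n] if g in gene_index]
        cols = gene_index.get_indexer(genes)
        score = dense[:, cols].sum(axis=1)
        thresh = positive_fraction * np.quantile(score[~cluster_mask], background_quantile)
        dual &= score[cluster_mask] > thresh
    frac = float(dual.mean()) if dual.size else 0.0
    evidence.update({"signatures": (s1, s2), "dual_fraction": frac})
    return frac >= dual_fraction_threshold, evidence


def _centroids(embedding: np.ndarray, labels: np.ndarray) -> tuple[list, np.ndarray]:
    uniq = sorted(set(labels.tolist()))
    cents = np.vstack([embedding[labels == c].mean(axis=0) for c in uniq])
    return uniq, cents


def merge_pass(
    labels: np.ndarray,
    embedding: np.ndarray,
    de_fn: Callable[[np.ndarray, np.ndarray], pd.DataFrame],
    params: MergeRuleParams = MergeRuleParams(),
    alpha: float = 0.05,
    min_logfc: float = 0.25,
    min_pct: float = 0.1,
) -> ClusterLabeling:
    """Iteratively merge under-separated mutually-nearest cluster pairs.

    Candidate pairs are mutually nearest cluster centroids in the embedding.
    For each pair, ``de_fn(mask_a, mask_b)`` yields genes enriched in a over
    b (called in both directions).  The pair merges when each side has fewer
    than ``min_de_each`` significantly enriched genes AND no classic marker
    gene ranks within the top ``classic_marker_rank`` DE genes of the pair
    (by adjusted p).  Iterates until no pair merges; provenance is recorded.
    """
    labels = np.asarray(labels).astype(str)
    provenance: dict[str, str] = {}
    while True:
        uniq, cents = _centroids(embedding, labels)
        if len(uniq) < 2:
            break
        D = np.linalg.norm(cents[:, None] - cents[None], axis=2)
        np.fill_diagonal(D, np.inf)
        nearest = D.argmin(axis=1)
        merged_any = False
        for i, j in enumerate(nearest):
            if nearest[j] != i or j <= i:
                continue
            a, b = uniq[i], uniq[j]
            mask_a, mask_b = labels == a, labels == b
            tab_a = de_fn(mask_a, mask_b)
            tab_b = de_fn(mask_b, mask_a)

            def _enriched(t: pd.DataFrame) -> pd.DataFrame:
                if t.empty:
                    return t
                sig = (
                    (t["p_adj"] < alpha)
                    & (t["log_fc"] > min_logfc)
                    & (t["pct_group"] >= min_pct)
                )
                return t[sig]

            enr_a, enr_b = _enriched(tab_a), _enriched(tab_b)
            if len(enr_a) >= params.min_de_each or len(enr_b) >= params.min_de_each:
                continue
            pooled = pd.concat([tab_a, tab_b]).sort_values("p_adj")
            pooled = pooled[~pooled.index.duplicated()]
            top = set(pooled.index[: params.classic_marker_rank])
            if top & set(params.classic_marker_list):
                continue
            # merge b into a (the lexicographically first id survives)
            survivor, child = sorted([a, b])
            labels[labels == child] = survivor
            provenance[child] = survivor
            for k, v in list(provenance.items()):
                if v == child:
                    provenance[k] = survivor
            merged_any = True
            break
        if not merged_any:
            break
    status = {c: "kept" for c in sorted(set(labels.tolist()))}
    for child in provenance:
        status[child] = "merged"
    return ClusterLabeling(labels=labels, status=status, merge_provenance=provenance)


def default_phase_params() -> list[PhaseParams]:
    """Atlas-scale defaults: 2000 HVGs/28 PCs/res 1.2 on all cells,
    4000 HVGs/40 PCs on neurons, then 40 PCs/res 4 and 7 PCs/res 0.6
    targeted sub-clustering."""
    return [
        PhaseParams("phase1", n_pcs=28, resolution=1.2, hvg=HVGParams(n_top=2000)),
        PhaseParams("phase2", n_pcs=40, resolution=2.0, hvg=HVGParams(n_top=4000)),
        PhaseParams("phase3a", n_pcs=40, resolution=4.0, hvg=HVGParams(n_top=4000)),
        PhaseParams("phase3b", n_pcs=7, resolution=0.6, hvg=HVGParams(n_top=2000)),
    ]


def multiphase_cluster(
    adata,
    phases: Sequence[PhaseParams],
    seed: int = 0,
    de_params=None,
    merge_params: MergeRuleParams = MergeRuleParams(),
    signature_sets: Mapping[str, Sequence[str]] | None = None,
    apply_flags: bool = True,
) -> tuple[ClusterLabeling, dict]:
    """Run phased clustering with hygiene rules between phases.

    ``adata`` must hold log-normalized expression in ``.X`` with QC covariates
    in ``.obs``.  Phase 1 clusters all cells.  Each later phase selects the
    clusters whose mean expression of its ``parent_signature`` genes is
    highest (above the midpoint of the per-cluster score range) and
    re-clusters only those cells, re-selecting HVGs and re-scaling.  After
    every phase, low-quality and doublet clusters are flagged and their cells
    excluded from later phases, and the merge rule is applied.

    Returns the final labeling (per-cell deepest kept label, with status per
    cluster) and a diagnostics dict with per-phase embeddings and reports.
    """
    from .markers import DEParams, wilcoxon_de

    de_params = de_params or DEParams()
    rng = np.random.default_rng(seed)
    n = adata.n_obs
    final = np.array(["unassigned"] * n, dtype=object)
    status: dict[str, str] = {}
    provenance: dict[str, str] = {}
    phase_cols: dict[str, np.ndarray] = {}
    diagnostics: dict = {"phases": {}}
    active = np.ones(n, dtype=bool)  # cells eligible for this phase
    current_parent_labels = None

    for p_idx, phase in enumerate(phases):
        if p_idx == 0:
            cells = np.flatnonzero(active)
        else:
            if current_parent_labels is None:
                warnings.warn(f"{phase.phase_id}: no upstream labels; skipped")
                continue
            if phase.parent_signature is None:
                warnings.warn(f"{phase.phase_id}: no parent signature; skipped")
                continue
            cells = _select_parent_cells(
                adata, current_parent_labels, phase.parent_signature, active
            )
            if len(cells) < phase.min_cells:
                warnings.warn(
                    f"{phase.phase_id}: only {len(cells)} cells selected; phase skipped"
                )
                continue

        sub = adata[cells].copy()
        cluster_fn = make_standard_cluster_fn(
            phase.hvg, phase.n_pcs, phase.resolution, k=min(phase.k, len(cells) - 1)
        )
        genes = select_hvgs(sub, phase.hvg)
        if len(genes) < 2:
            genes = list(sub.var_names)
        X, _ = scale_regress(sub, genes)
        from .integration import integrate as _integrate, pca as _pca, IntegrationParams

        if "study" in sub.obs and sub.obs["study"].nunique() > 1:
            studies = sub.obs["study"].astype(str).to_numpy()
            keys = pd.unique(studies)
            mats = [X[studies == s] for s in keys]
            Xi = _integrate(mats, IntegrationParams())
            # restore original cell order
            order = np.concatenate([np.flatnonzero(studies == s) for s in keys])
            X = np.empty_like(Xi)
            X[order] = Xi
        emb = _pca(X, min(phase.n_pcs, min(X.shape) - 1))
        g = snn_graph(emb.coords, k=min(phase.k, len(cells) - 1))
        raw = cluster_graph(g, resolution=phase.resolution, seed=int(rng.integers(2**31 - 1)))
        labels = np.array([f"{phase.phase_id}.{c}" for c in raw], dtype=object)

        def _de(mask_a, mask_b, _sub=sub):
            return wilcoxon_de(_sub.X, _sub.var_names, mask_a, mask_b, de_params)

        merged = merge_pass(
            labels, emb.coords, _de, merge_params,
            alpha=de_params.alpha, min_logfc=de_params.min_logfc, min_pct=de_params.min_pct,
        )
        labels = merged.labels
        provenance.update(merged.merge_provenance)

        excluded_here = np.zeros(len(cells), dtype=bool)
        phase_status: dict[str, str] = {}
        if apply_flags:
            for c in sorted(set(labels.tolist())):
                mask_c = labels == c
                if mask_c.sum() < 3 or mask_c.all():
                    phase_status[c] = "kept"
                    continue
                tab = wilcoxon_de(sub.X, sub.var_names, mask_c, ~mask_c, de_params)
                med_genes = float(np.median(sub.obs["n_genes"].to_numpy()[mask_c])) \
                    if "n_genes" in sub.obs else None
                lq, _ev = flag_low_quality(
                    tab, med_genes, alpha=de_params.alpha,
                    min_logfc=de_params.min_logfc, min_pct=de_params.min_pct,
                )
                if lq:
                    phase_status[c] = "low_quality"
                    excluded_here |= mask_c
                    continue
                if signature_sets:
                    from .markers import significant_markers

                    dbl, _ev2 = flag_doublet_cluster(
                        sub.X, mask_c, significant_markers(tab, de_params),
                        signature_sets, sub.var_names,
                    )
                    if dbl:
                        phase_status[c] = "doublet"
                        excluded_here |= mask_c
                        continue
                phase_status[c] = "kept"
        else:
            phase_status = {c: "kept" for c in sorted(set(labels.tolist()))}

        status.update(phase_status)
        for child, surv in merged.merge_provenance.items():
            status[child] = "merged"
        col = np.array([None] * n, dtype=object)
        col[cells] = labels
        phase_cols[phase.phase_id] = col
        # update the final label for cells whose cluster is kept
        for c, s in phase_status.items():
            mask_c = labels == c
            if s == "kept":
                final[cells[mask_c]] = c
            else:
                final[cells[mask_c]] = c
                active[cells[mask_c]] = False
        current_parent_labels = col
        diagnostics["phases"][phase.phase_id] = {
            "embedding": emb.coords,
            "cells": cells,
            "labels": labels.copy(),
            "status": phase_status,
        }

    phase_df = pd.DataFrame(phase_cols, index=adata.obs_names)
    labeling = ClusterLabeling(
        labels=final, status=status, merge_provenance=provenance, phase_labels=phase_df
    )
    return labeling, diagnostics


def _select_parent_cells(
    adata,
    parent_labels: np.ndarray,
    signature: Sequence[str],
    active: np.ndarray,
) -> np.ndarray:
    """Cells of the clusters scoring highest on a signature gene set.

    Per-cluster mean expression of the signature is computed; clusters above
    the midpoint between the lowest and highest score are selected.
    """
    genes = [g for g in signature if g in adata.var_names]
    if not genes:
        return np.zeros(0, dtype=int)
    cols = adata.var_names.get_indexer(genes)
    X = adata.X[:, cols]
    score = np.asarray(X.mean(axis=1)).ravel()
    valid = np.array([l is not None for l in parent_labels]) & active
    out = []
    cl_scores = {}
    for c in set(parent_labels[valid].tolist()):
        m = valid & (parent_labels == c)
        cl_scores[c] = score[m].mean()
    if not cl_scores:
        return np.zeros(0, dtype=int)
    lo, hi = min(cl_scores.values()), max(cl_scores.values())
    cut = (lo + hi) / 2
    for c, s in cl_scores.items():
        if s > cut:
            out.append(np.flatnonzero(valid & (parent_labels == c)))
    return np.sort(np.concatenate(out)) if out else np.zeros(0, dtype=int)
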