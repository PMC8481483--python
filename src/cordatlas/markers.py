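"""Marker detection and differential expression statistics.

Cluster markers are scored two ways, following common single-cell practice:
a two-sided Wilcoxon rank-sum test (normal approximation with tie
correction; exact enumeration for small groups) with Bonferroni adjustment,
and an AUROC analysis where each gene's expression is treated as a
classifier of group membership (power = 2*|AUC - 0.5|).  Genes are
pre-filtered by minimum fraction expressing and minimum log fold change
before testing.  Class-level signatures use the AUROC route with stricter
fraction filters; within-cluster covariate DE contrasts conditions inside
each cluster and pools the top genes.  A greedy combinatorial panel selector
builds a family-marker + given-marker code per cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "DEParams",
    "wilcoxon_de",
    "auroc_markers",
    "class_level_de",
    "within_cluster_covariate_de",
    "combinatorial_panel",
    "significant_markers",
]


@dataclass
class DEParams:
    min_pct: float = 0.1  # minimum fraction expressing in the enriched group
    min_logfc: float = 0.25
    alpha: float = 0.05  # adjusted-p significance threshold
    power_cut: float = 0.6  # AUROC power threshold for class signatures
    top_k: int = 30

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct <= 1) or self.min_logfc < 0:
            raise ValueError("invalid DE parameters")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def _group_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fraction of cells expressing, mean of back-transformed expression)."""
    pct = (X > 0).mean(axis=0)
    mean_lin = np.expm1(X).mean(axis=0)
    return pct, mean_lin


def _log_fc(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    return np.log((mean_a + pseudocount) / (mean_b + pseudocount))


def _auc_from_ranks(Xg: np.ndarray, Xr: np.ndarray) -> np.ndarray:
    """Vectorized per-gene AUC of expression as a group classifier.

    Uses the rank-sum identity AUC = (R_group - n_g(n_g+1)/2) / (n_g * n_r)
    with midranks, so ties count 1/2.
    """
    n_g, n_r = Xg.shape[0], Xr.shape[0]
    allx = np.vstack([Xg, Xr])
    ranks = stats.rankdata(allx, axis=0)
    r_group = ranks[:n_g].sum(axis=0)
    return (r_group - n_g * (n_g + 1) / 2) / (n_g * n_r)


def _rank_sum_p(Xg: np.ndarray, Xr: np.ndarray, exact_max: int = 10) -> np.ndarray:
    """Two-sided rank-sum p-values, vectorized over gene columns.

    Normal approximation with tie correction; when both groups have at most
    ``exact_max`` observations and a gene has no ties, the exact null
    enumeration is used instead.
    """
    n1, n2 = Xg.shape[0], Xr.shape[0]
    use_exact = n1 <= exact_max and n2 <= exact_max
    p = np.empty(Xg.shape[1])
    if use_exact:
        for j in range(Xg.shape[1]):
            method = "exact" if len(np.unique(np.r_[Xg[:, j], Xr[:, j]])) == n1 + n2 else "asymptotic"
            p[j] = stats.mannwhitneyu(
                Xg[:, j], Xr[:, j], alternative="two-sided", method=method
            ).pvalue
        return p

    allx = np.vstack([Xg, Xr])
    ranks = stats.rankdata(allx, axis=0)
    U = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    # tie correction per gene
    tie_term = np.zeros(Xg.shape[1])
    for j in range(Xg.shape[1]):
        _, counts = np.unique(allx[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (U - mu - np.sign(U - mu) * 0.5) / sigma  # continuity corrected
    p[:] = 2 * stats.norm.sf(np.abs(z))
    np.clip(p, 0.0, 1.0, out=p)
    p[sigma2 <= 0] = 1.0
    return p


def _build_table(
    genes: np.ndarray,
    Xg: np.ndarray,
    Xr: np.ndarray,
    params: DEParams,
    compute_p: bool,
    n_total_genes: int | None = None,
) -> pd.DataFrame:
    pct_g, mean_g = _group_stats(Xg)
    pct_r, mean_r = _group_stats(Xr)
    lfc = _log_fc(mean_g, mean_r)
    keep = (pct_g >= params.min_pct) & (lfc >= params.min_logfc)
    tbl = pd.DataFrame(
        {
            "log_fc": lfc[keep],
            "pct_group": pct_g[keep],
            "pct_rest": pct_r[keep],
        },
        index=np.asarray(genes)[keep],
    )
    if tbl.empty:
        for c in ("p", "p_adj", "auc", "power"):
            tbl[c] = pd.Series(dtype=float)
        return tbl
    auc = _auc_from_ranks(Xg[:, keep], Xr[:, keep])
    tbl["auc"] = auc
    tbl["power"] = 2 * np.abs(auc - 0.5)
    if compute_p:
        p = _rank_sum_p(Xg[:, keep], Xr[:, keep])
        n_tested = n_total_genes if n_total_genes is not None else int(keep.sum())
        tbl["p"] = p
        tbl["p_adj"] = np.minimum(1.0, p * n_tested)
    else:
        tbl["p"] = np.nan
        tbl["p_adj"] = np.nan
    return tbl.sort_values(["p_adj", "p"] if compute_p else "power",
                           ascending=[True, True] if compute_p else False)


def wilcoxon_de(
    X,
    genes,
    group_mask: np.ndarray,
    rest_mask: np.ndarray | None = None,
    params: DEParams = DEParams(min_pct=0.1, min_logfc=0.25),
) -> pd.DataFrame:
    """Rank-sum DE of ``group`` vs ``rest`` on log-normalized expression.

    Genes are pre-filtered by ``min_pct`` (fraction expressing in the group)
    and ``min_logfc`` (natural-log fold change of back-transformed means,
    pseudocount 1); p-values are Bonferroni-adjusted over the tested genes.
    Returns a table sorted by adjusted p.
    """
    group_mask = np.asarray(group_mask, bool)
    if rest_mask is None:
        rest_mask = ~group_mask
    rest_mask = np.asarray(rest_mask, bool)
    if (group_mask & rest_mask).any():
        raise ValueError("group and rest overlap")
    if group_mask.sum() == 0 or rest_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    Xg = _dense(X[group_mask])
    Xr = _dense(X[rest_mask])
    return _build_table(np.asarray(genes), Xg, Xr, params, compute_p=True)


def auroc_markers(
    X,
    genes,
    group_mask: np.ndarray,
    rest_mask: np.ndarray | None = None,
    params: DEParams = DEParams(min_pct=0.1, min_logfc=0.25),
) -> pd.DataFrame:
    """AUROC marker table: per-gene AUC of expression as a group classifier."""
    group_mask = np.asarray(group_mask, bool)
    if rest_mask is None:
        rest_mask = ~group_mask
    rest_mask = np.asarray(rest_mask, bool)
    if (group_mask & rest_mask).any():
        raise ValueError("group and rest overlap")
    if group_mask.sum() == 0 or rest_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")
    Xg = _dense(X[group_mask])
    Xr = _dense(X[rest_mask])
    tbl = _build_table(np.asarray(genes), Xg, Xr, params, compute_p=False)
    return tbl.sort_values("power", ascending=False)


def significant_markers(table: pd.DataFrame, params: DEParams = DEParams()) -> list[str]:
    """Genes passing the enrichment significance thresholds in a DE table."""
    if table.empty:
        return []
    sig = (
        (table["p_adj"] < params.alpha)
        & (table["log_fc"] > params.min_logfc)
        & (table["pct_group"] >= params.min_pct)
    )
    return list(table.index[sig])


def class_level_de(
    X,
    genes,
    class_a: np.ndarray,
    class_b: np.ndarray,
    params: DEParams = DEParams(min_pct=0.3, min_logfc=0.25, power_cut=0.6),
) -> tuple[list[str], list[str]]:
    """Class signature lists by AUROC power, both directions.

    Each direction requires the gene to be expressed in more than ``min_pct``
    of its class and have log FC above ``min_logfc``; genes with power above
    ``power_cut`` are returned ranked by power.  (The candidate-threshold
    reading of an AUROC cutoff: power is 2*|AUC-0.5|, bounded by 1.)
    """
    lists = []
    for g, r in ((class_a, class_b), (class_b, class_a)):
        tbl = auroc_markers(X, genes, g, r, params)
        tbl = tbl[tbl["pct_group"] > params.min_pct]
        tbl = tbl[tbl["power"] > params.power_cut]
        lists.append(list(tbl.sort_values("power", ascending=False).index))
    return lists[0], lists[1]


def within_cluster_covariate_de(
    X,
    genes,
    cluster_labels: np.ndarray,
    condition_labels: np.ndarray,
    params: DEParams = DEParams(min_pct=0.1, min_logfc=0.25, top_k=30),
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Condition-contrast DE inside each cluster, pooled and deduplicated.

    Within each cluster, cells of the first condition (sorted order) are
    contrasted against the rest with the rank-sum test in both directions;
    the ``top_k`` genes by adjusted p per cluster enter a union from which
    duplicates are removed (keeping each gene's best adjusted p).  Direction
    of enrichment is retained as the sign of ``log_fc``.
    """
    cluster_labels = np.asarray(cluster_labels)
    condition_labels = np.asarray(condition_labels)
    conds = np.unique(condition_labels)
    if len(conds) < 2:
        warnings.warn("single condition present; no covariate DE possible")
        return pd.DataFrame(columns=["log_fc", "p", "p_adj", "cluster"]), {}

    per_cluster: dict[str, pd.DataFrame] = {}
    rows = []
    for cl in np.unique(cluster_labels):
        in_cl = cluster_labels == cl
        ca = in_cl & (condition_labels == conds[0])
        cb = in_cl & (condition_labels != conds[0])
        if ca.sum() < 3 or cb.sum() < 3:
            continue
        up = wilcoxon_de(X, genes, ca, cb, params)
        down = wilcoxon_de(X, genes, cb, ca, params)
        down = down.assign(log_fc=-down["log_fc"])
        both = pd.concat([up, down]).sort_values("p_adj")
        both = both[~both.index.duplicated()]
        top = both.head(params.top_k).assign(cluster=str(cl))
        per_cluster[str(cl)] = top
        rows.append(top)

    if not rows:
        return pd.DataFrame(columns=["log_fc", "p", "p_adj", "cluster"]), per_cluster
    union = pd.concat(rows).sort_values("p_adj")
    union = union[~union.index.duplicated()]
    return union, per_cluster


def combinatorial_panel(
    X,
    genes,
    cluster_labels: np.ndarray,
    family_of: dict[str, str],
    panel_size: int = 2,
    params: DEParams = DEParams(),
) -> dict:
    """Greedy family-marker + given-marker panel.

    For each family, the gene maximizing family-vs-rest AUROC power is the
    family marker.  Within each family, clusters receive "given" markers
    greedily (highest within-family power first) until each cluster's
    (family, given) code is unique or candidates are exhausted; clusters that
    cannot be disambiguated are reported as ambiguous.
    """
    cluster_labels = np.asarray(cluster_labels, dtype=object).astype(str)
    clusters = sorted(set(cluster_labels))
    fams = sorted({family_of[c] for c in clusters})
    panel: dict = {"families": {}, "clusters": {}, "ambiguous": []}

    for fam in fams:
        fam_clusters = [c for c in clusters if family_of[c] == fam]
        fam_mask = np.isin(cluster_labels, fam_clusters)
        if fam_mask.all():
            family_marker = None
        else:
            tbl = auroc_markers(X, genes, fam_mask, ~fam_mask, params)
            family_marker = tbl.index[0] if len(tbl) else None
        panel["families"][fam] = family_marker

        codes: dict[str, tuple] = {}
        for c in fam_clusters:
            mask_c = cluster_labels == c
            within_rest = fam_mask & ~mask_c
            given: list[str] = []
            if within_rest.sum() > 0:
                tbl = auroc_markers(X, genes, mask_c, within_rest, params)
                given = list(tbl.index[:panel_size])
            codes[c] = (family_marker, tuple(given))
            panel["clusters"][c] = {"family_marker": family_marker, "given_markers": list(given)}
        seen: dict[tuple, list[str]] = {}
        for c, code in codes.items():
            seen.setdefault(code, []).append(c)
        for code, members in seen.items():
            if len(members) > 1:
                panel["ambiguous"].extend(members)
            elif code[1] == () and len(fam_clusters) > 1:
                panel["ambiguous"].extend(members)
    panel["ambiguous"] = sorted(set(panel["ambiguous"]))
    return panel
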