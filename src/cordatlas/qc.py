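"""Uniform QC filtering, log-normalization, HVG selection, and scaling.

The filters mirror a liberal, uniform multi-study QC: cells are kept when
they have more than 200 detected genes and less than 5% mitochondrial
transcripts.  Normalization is the standard library-size log transform
(counts scaled to 10,000 per cell, then ln(1+x)).  Highly variable genes are
selected by the mean/dispersion method with cutoffs (0.0125, 3) on the mean
and 0.5 on the bin-standardized dispersion, or alternatively by a top-N rank
on standardized dispersion.  Scaling regresses out per-cell covariates
(total counts, mitochondrial percentage) with ordinary least squares before
z-scoring and clipping each gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCParams",
    "HVGParams",
    "ScalingParams",
    "ScaleState",
    "qc_filter",
    "log_normalize",
    "select_hvgs",
    "scale_regress",
]


@dataclass
class QCParams:
    min_genes: int = 200  # keep cells with detected genes strictly above this
    max_mito: float = 0.05  # keep cells with mito fraction strictly below this
    inclusive_min_genes: bool = False  # True: ">= min_genes" instead of "> min_genes"
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes < 0 or not (0 <= self.max_mito <= 1):
            raise ValueError("invalid QC parameters")


@dataclass
class HVGParams:
    mean_low: float = 0.0125
    mean_high: float = 3.0
    dispersion_cut: float = 0.5
    n_top: int | None = None  # count-based alternative selection
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.mean_low >= self.mean_high:
            raise ValueError("mean_low must be < mean_high")
        if self.n_top is not None and self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class ScalingParams:
    covariates: tuple[str, ...] = ("n_counts", "pct_mito")
    clip_value: float = 10.0

    def __post_init__(self) -> None:
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")


def _mito_mask(adata: AnnData, prefix: str) -> np.ndarray:
    if "mito" in adata.var.columns:
        return adata.var["mito"].to_numpy(dtype=bool)
    return np.array([g.lower().startswith(prefix.lower()) for g in adata.var_names])


def _detected_genes(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (X > 0).sum(axis=1)


def qc_filter(adata: AnnData, params: QCParams = QCParams()) -> tuple[AnnData, dict]:
    """Filter cells by detected-gene count and mitochondrial fraction.

    Returns the filtered AnnData (a copy) and a report with removed-cell
    counts per reason and per study.  If no mitochondrial genes can be
    identified, the mito filter is skipped with a warning recorded in the
    report.
    """
    X = adata.X
    n_genes = _detected_genes(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = _mito_mask(adata, params.mito_prefix)

    if params.inclusive_min_genes:
        pass_genes = n_genes >= params.min_genes
    else:
        pass_genes = n_genes > params.min_genes

    report: dict = {"params": {"min_genes": params.min_genes, "max_mito": params.max_mito}}
    if mito.sum() == 0:
        warnings.warn("no mitochondrial genes identified; mito filter skipped")
        report["mito_filter_skipped"] = True
        pass_mito = np.ones(adata.n_obs, dtype=bool)
        mito_frac = np.zeros(adata.n_obs)
    else:
        report["mito_filter_skipped"] = False
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(
                totals > 0,
                np.asarray(X[:, mito].sum(axis=1)).ravel() / np.maximum(totals, 1),
                1.0,
            )
        pass_mito = mito_frac < params.max_mito

    keep = pass_genes & pass_mito
    studies = (
        adata.obs["study"].astype(str)
        if "study" in adata.obs
        else pd.Series(["all"] * adata.n_obs, index=adata.obs_names)
    )
    per_study: dict[str, dict[str, int]] = {}
    for s in studies.unique():
        m = (studies == s).to_numpy()
        per_study[s] = {
            "removed_low_genes": int((~pass_genes & m).sum()),
            "removed_high_mito": int((pass_genes & ~pass_mito & m).sum()),
            "kept": int((keep & m).sum()),
        }
    report["per_study"] = per_study
    report["n_removed"] = int((~keep).sum())
    report["n_kept"] = int(keep.sum())

    out = adata[keep].copy()
    out.obs["n_genes"] = n_genes[keep]
    out.obs["n_counts"] = totals[keep]
    out.obs["pct_mito"] = mito_frac[keep]
    return out, report


def log_normalize(adata: AnnData, scale: float = 10_000.0) -> AnnData:
    """Library-size normalize to ``scale`` counts per cell, then ln(1+x).

    value(i, j) = ln(1 + count(i, j) * scale / total(i)); sparse zeros are
    preserved.  Raw counts are kept in ``.layers["counts"]``.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = list(np.asarray(adata.obs_names)[totals <= 0][:5])
        raise ValueError(f"cells with zero total counts (should be removed by QC): {bad}")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    if sp.issparse(X):
        Xn = X.astype(np.float64).tocsr(copy=True)
        rep = np.repeat(totals, np.diff(Xn.indptr))
        Xn.data = np.log1p(Xn.data * scale / rep)
        out.X = Xn
    else:
        out.X = np.log1p(np.asarray(X, dtype=np.float64) * scale / totals[:, None])
    if "n_counts" not in out.obs:
        out.obs["n_counts"] = totals
    if "pct_mito" not in out.obs:
        mito = _mito_mask(adata, "mt-")
        out.obs["pct_mito"] = (
            np.asarray(X[:, mito].sum(axis=1)).ravel() / totals if mito.any() else 0.0
        )
    return out


def _dispersion_stats(adata: AnnData) -> pd.DataFrame:
    """Per-gene mean/dispersion statistics on back-transformed values.

    Mean and variance are computed on expm1 of the log-normalized values;
    dispersion = variance / mean; both are then log-transformed before the
    mean-bin standardization.
    """
    X = adata.X
    if sp.issparse(X):
        e = X.copy()
        e.data = np.expm1(e.data)
        mean = np.asarray(e.mean(axis=0)).ravel()
        sq = e.multiply(e).mean(axis=0)
        var = np.asarray(sq).ravel() - mean**2
        var *= X.shape[0] / max(X.shape[0] - 1, 1)
    else:
        e = np.expm1(X)
        mean = e.mean(axis=0)
        var = e.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"mean": mean, "dispersion": disp}, index=adata.var_names)
    df["log_mean"] = np.log1p(mean)
    with np.errstate(divide="ignore"):
        df["log_dispersion"] = np.where(disp > 0, np.log(disp), np.nan)
    return df


def select_hvgs(adata: AnnData, params: HVGParams = HVGParams()) -> list[str]:
    """Select highly variable genes on log-normalized data.

    Cutoff mode keeps genes whose log1p mean lies in (mean_low, mean_high)
    and whose dispersion, standardized within ``n_bins`` equal-frequency mean
    bins, exceeds ``dispersion_cut``.  Count mode (``n_top`` set) returns the
    top genes by standardized dispersion among genes with nonzero dispersion.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells for HVG selection")
    df = _dispersion_stats(adata)
    valid = df["dispersion"].notna() & (df["dispersion"] > 0)
    df["disp_std"] = np.nan
    if valid.sum() > 0:
        sub = df.loc[valid]
        n_bins = min(params.n_bins, max(valid.sum() // 2, 1))
        bins = pd.qcut(sub["log_mean"], q=n_bins, duplicates="drop")
        grouped = sub.groupby(bins, observed=True)["log_dispersion"]
        mu = grouped.transform("mean")
        sd = grouped.transform("std").replace(0, np.nan)
        z = (sub["log_dispersion"] - mu) / sd
        # singleton or zero-variance bins: fall back to the raw log dispersion
        z = z.fillna(sub["log_dispersion"])
        df.loc[valid, "disp_std"] = z

    if params.n_top is not None:
        ranked = df.loc[valid].sort_values("disp_std", ascending=False)
        if params.n_top > len(ranked):
            warnings.warn(
                f"requested {params.n_top} HVGs but only {len(ranked)} qualify; returning all"
            )
        return list(ranked.index[: params.n_top])

    sel = (
        valid
        & (df["log_mean"] > params.mean_low)
        & (df["log_mean"] < params.mean_high)
        & (df["disp_std"] > params.dispersion_cut)
    )
    return list(df.index[sel])


@dataclass
class ScaleState:
    """Fitted scaling state so query data can be transformed consistently."""

    genes: list[str]
    covariates: tuple[str, ...]
    beta: np.ndarray  # (n_covariates+1, n_genes) OLS coefficients
    mean: np.ndarray  # residual means (0 after fit, stored for projection)
    std: np.ndarray  # residual standard deviations
    clip_value: float
    cov_center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cov_scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def transform(self, adata: AnnData) -> np.ndarray:
        sub = adata[:, self.genes]
        X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, float)
        D = _design(adata, self.covariates, self.cov_center, self.cov_scale)
        resid = X - D @ self.beta
        Z = (resid - self.mean) / self.std
        return np.clip(Z, -self.clip_value, self.clip_value)


def _design(
    adata: AnnData,
    covariates: tuple[str, ...],
    center: np.ndarray,
    scale: np.ndarray,
) -> np.ndarray:
    cols = [np.ones(adata.n_obs)]
    for i, c in enumerate(covariates):
        v = adata.obs[c].to_numpy(dtype=float)
        cols.append((v - center[i]) / scale[i])
    return np.column_stack(cols)


def scale_regress(
    adata: AnnData,
    genes: list[str] | None = None,
    params: ScalingParams = ScalingParams(),
) -> tuple[np.ndarray, ScaleState]:
    """Regress covariates out of each gene, z-score, and clip.

    Per gene: OLS residuals of the log-normalized expression on the covariate
    table (plus intercept), then zero-mean/unit-variance scaling, then
    clipping to +/- clip_value.  Zero-variance residual genes scale to all
    zeros.  Returns the dense scaled matrix and the fitted state for
    projecting new data.
    """
    genes = list(genes) if genes is not None else list(adata.var_names)
    sub = adata[:, genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, float)

    covs = tuple(c for c in params.covariates if c in adata.obs.columns)
    if covs != tuple(params.covariates):
        missing = set(params.covariates) - set(covs)
        warnings.warn(f"covariates missing from obs and skipped: {sorted(missing)}")
    center = np.array([adata.obs[c].to_numpy(dtype=float).mean() for c in covs])
    scale = np.array([max(adata.obs[c].to_numpy(dtype=float).std(), 1e-12) for c in covs])
    D = _design(adata, covs, center, scale)
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    mean = resid.mean(axis=0)
    std = resid.std(axis=0)
    std_safe = np.where(std > 1e-12, std, 1.0)
    Z = (resid - mean) / std_safe
    Z[:, std <= 1e-12] = 0.0
    state = ScaleState(
        genes=genes,
        covariates=covs,
        beta=beta,
        mean=mean,
        std=std_safe,
        clip_value=params.clip_value,
        cov_center=center,
        cov_scale=scale,
    )
    return np.clip(Z, -params.clip_value, params.clip_value), state
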