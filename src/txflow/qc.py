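"""QC filtering, normalization, HVG selection and detection rate.

Filter order is fixed: gene blocklist first, then gene prevalence, then
observation thresholds computed on the gene-filtered matrix. Thresholds
come in two assay profiles (spatial and single-nucleus), exposed as
named presets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from txflow.data import ConfigError, EmptyDatasetError, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QC_PROFILES",
    "NormalizedMatrix",
    "filter_dataset",
    "qc_report",
    "normalize_log1p",
    "select_hvg",
    "compute_cdr",
]


@dataclass(frozen=True)
class QCThresholds:
    """Observation/gene filtering thresholds.

    Observations are kept iff ``min_genes <= detected genes <= max_genes``,
    total UMI ``<= max_umi`` and mitochondrial fraction ``<= max_mito_frac``
    (all bounds inclusive: "fewer than min" / "more than max" are removed).
    """

    min_genes: int = 100
    max_genes: int = 8000
    max_umi: int = 50_000
    max_mito_frac: float = 0.35
    min_cells_per_gene: int = 3
    gene_blocklist: frozenset[str] = frozenset({"Gm42418"})

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ConfigError("min_genes must be < max_genes")
        if not 0 <= self.max_mito_frac <= 1:
            raise ConfigError("max_mito_frac must be in [0, 1]")


#: Named threshold presets for the two assay profiles.
QC_PROFILES: dict[str, QCThresholds] = {
    "spatial": QCThresholds(min_genes=100, max_genes=8000, max_umi=50_000,
                            max_mito_frac=0.35),
    "snrna": QCThresholds(min_genes=200, max_genes=8000, max_umi=60_000,
                          max_mito_frac=0.20),
}


def _obs_metrics(ds: ExpressionDataset):
    counts = ds.counts
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    n_umi = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(ds.var["mito"], dtype=bool)
    mito_umi = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() \
        else np.zeros(ds.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    return n_genes, n_umi, mito_frac


def filter_dataset(ds: ExpressionDataset, t: QCThresholds) -> ExpressionDataset:
    """Apply QC: blocklist genes -> low-prevalence genes -> observations
    violating any threshold (metrics computed on the gene-filtered
    matrix). Raises :class:`EmptyDatasetError` if nothing survives."""
    keep_gene = ~ds.gene_ids.isin(t.gene_blocklist)
    ds = ds.subset_genes(np.asarray(keep_gene))

    prevalence = np.asarray((ds.counts > 0).sum(axis=0)).ravel()
    ds = ds.subset_genes(prevalence >= t.min_cells_per_gene)
    if ds.n_genes == 0:
        raise EmptyDatasetError("no genes left after gene filtering")

    n_genes, n_umi, mito_frac = _obs_metrics(ds)
    keep = (
        (n_genes >= t.min_genes)
        & (n_genes <= t.max_genes)
        & (n_umi <= t.max_umi)
        & (mito_frac <= t.max_mito_frac)
    )
    if not keep.any():
        raise EmptyDatasetError("no observations left after QC filtering")
    logger.info("QC kept %d/%d observations, %d genes", keep.sum(),
                len(keep), ds.n_genes)
    logger.info("doublet removal: not implemented (upstream tool out of "
                "scope); stage is a no-op")
    return ds.subset_obs(keep)


def qc_report(ds: ExpressionDataset, t: QCThresholds) -> pd.DataFrame:
    """Per-observation pass/fail table with reasons, computed after gene
    filtering (same metric basis as :func:`filter_dataset`)."""
    keep_gene = ~ds.gene_ids.isin(t.gene_blocklist)
    tmp = ds.subset_genes(np.asarray(keep_gene))
    prevalence = np.asarray((tmp.counts > 0).sum(axis=0)).ravel()
    tmp = tmp.subset_genes(prevalence >= t.min_cells_per_gene)
    n_genes, n_umi, mito_frac = _obs_metrics(tmp)
    rep = pd.DataFrame({
        "n_genes": n_genes,
        "n_umi": n_umi,
        "mito_frac": mito_frac,
        "fail_min_genes": n_genes < t.min_genes,
        "fail_max_genes": n_genes > t.max_genes,
        "fail_max_umi": n_umi > t.max_umi,
        "fail_mito": mito_frac > t.max_mito_frac,
    }, index=ds.obs_ids)
    rep["pass"] = ~rep[[c for c in rep.columns if c.startswith("fail_")]].any(axis=1)
    return rep


# ----------------------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """log1p of library-size-scaled counts, observations x genes."""

    values: sp.csr_matrix
    scale_target: float
    gene_ids: pd.Index
    obs_ids: pd.Index

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def normalize_log1p(ds: ExpressionDataset,
                    scale_target: float | None = None) -> NormalizedMatrix:
    """Scale each observation to ``scale_target`` total counts (default:
    median of per-observation totals) and apply log1p. Zero-total
    observations stay all-zero (with a warning)."""
    totals = np.asarray(ds.counts.sum(axis=1), dtype=float).ravel()
    if scale_target is None:
        nz = totals[totals > 0]
        scale_target = float(np.median(nz)) if nz.size else 1.0
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} observations have zero "
                      "total counts; their normalized rows are all zero")
    factors = np.where(totals > 0, scale_target / np.maximum(totals, 1e-300), 0.0)
    mat = sp.csr_matrix(ds.counts, dtype=float)
    mat = sp.diags(factors) @ mat
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(sp.csr_matrix(mat), scale_target,
                            ds.gene_ids.copy(), ds.obs_ids.copy())


# ----------------------------------------------------------------------
# Highly variable genes (variance-stabilized ranking on raw counts)


def _local_poly_trend(x: np.ndarray, y: np.ndarray, span: float = 0.3,
                      degree: int = 2, n_anchors: int = 200) -> np.ndarray:
    """Windowed polynomial trend fit: at each anchor along sorted x, fit a
    degree-``degree`` polynomial to the nearest ``span`` fraction of
    points; interpolate anchor fits back to every x."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    half = max(degree + 1, int(round(span * n / 2)))
    anchors = np.unique(np.linspace(0, n - 1, min(n_anchors, n)).astype(int))
    fitted_at_anchor = np.empty(len(anchors))
    for i, a in enumerate(anchors):
        lo = max(0, a - half)
        hi = min(n, a + half + 1)
        xw, yw = xs[lo:hi], ys[lo:hi]
        deg = min(degree, len(np.unique(xw)) - 1)
        if deg < 1:
            fitted_at_anchor[i] = yw.mean()
            continue
        coef = np.polyfit(xw, yw, deg)
        fitted_at_anchor[i] = np.polyval(coef, xs[a])
    fitted_sorted = np.interp(np.arange(n), anchors, fitted_at_anchor)
    out = np.empty(n)
    out[order] = fitted_sorted
    return out


def select_hvg(ds: ExpressionDataset, n_top: int = 2000) -> pd.DataFrame:
    """Rank genes by standardized variance of raw counts after a local
    polynomial mean-variance trend fit; clip standardized values at
    sqrt(n_observations). Returns the top ``n_top`` genes (ties broken by
    gene id; all-zero genes rank last).

    The returned frame is indexed by gene id with columns ``mean``,
    ``variance`` and ``variance_standardized``, sorted by rank.
    """
    if n_top > ds.n_genes:
        raise ConfigError(f"n_top={n_top} exceeds n_genes={ds.n_genes}")
    X = sp.csc_matrix(ds.counts, dtype=float)
    n = ds.n_obs
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean ** 2) * n / max(n - 1, 1)

    expressed = (mean > 0) & (var > 0)
    est_sd = np.zeros(ds.n_genes)
    if expressed.sum() >= 2:
        trend = _local_poly_trend(np.log10(mean[expressed]),
                                  np.log10(var[expressed]))
        est_sd[expressed] = np.sqrt(10.0 ** trend)

    clip = np.sqrt(n)
    std_var = np.zeros(ds.n_genes)
    idx = np.flatnonzero(expressed)
    for j in idx:
        col = X.getcol(j)
        nz = col.data
        sd = est_sd[j]
        z_nz = np.minimum((nz - mean[j]) / sd, clip)
        z_zero = -mean[j] / sd  # value of every zero count
        n_zero = n - nz.size
        zbar = (z_nz.sum() + n_zero * z_zero) / n
        std_var[j] = (((z_nz - zbar) ** 2).sum()
                      + n_zero * (z_zero - zbar) ** 2) / max(n - 1, 1)

    tbl = pd.DataFrame({
        "mean": mean,
        "variance": var,
        "variance_standardized": std_var,
    }, index=ds.gene_ids)
    # rank by standardized variance, ties broken by gene id
    order = np.lexsort((tbl.index.astype(str),
                        -tbl["variance_standardized"].to_numpy()))
    return tbl.iloc[order].head(n_top)


def compute_cdr(ds: ExpressionDataset) -> pd.Series:
    """Cellular detection rate: fraction of genes detected (count > 0)
    per observation."""
    det = np.asarray((ds.counts > 0).sum(axis=1)).ravel()
    return pd.Series(det / ds.n_genes, index=ds.obs_ids, name="cdr")
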