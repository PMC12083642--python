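"""Single-nucleus statistics.

* Hurdle-model differential expression with the cellular detection rate
  as a covariate: a logistic component on the detection indicator and a
  Gaussian component on log-normalized expression of detected nuclei;
  the condition factor is tested by summing the two component likelihood
  ratios (chi-square with the summed degrees of freedom).
* Regulon activity: per-cell AUC of the regulon recovery curve over the
  top fraction of the cell's expression ranking, with a one-sided
  rank-sum test between conditions (Bonferroni-corrected) after an
  average-activity filter.
* Over-representation analysis: hypergeometric upper tail with BH-FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, hypergeom

from txflow.data import ConfigError, ExpressionDataset, TxflowError
from txflow.qc import NormalizedMatrix
from txflow.stats_util import bh_adjust, bonferroni, rank_sum_one_sided

logger = logging.getLogger(__name__)

__all__ = [
    "expressed_gene_filter",
    "HurdleFit",
    "fit_hurdle",
    "hurdle_log2fc",
    "hurdle_deg",
    "aucell_score",
    "aucell_matrix",
    "differential_tf",
    "ora",
]


def expressed_gene_filter(ds: ExpressionDataset, labels: pd.Series,
                          min_frac: float = 0.05) -> dict[str, pd.Index]:
    """Per cell type, genes detected in strictly more than ``min_frac``
    of that type's nuclei."""
    labels = pd.Series(np.asarray(labels), index=ds.obs_ids)
    out: dict[str, pd.Index] = {}
    det = sp.csr_matrix((ds.counts > 0).astype(np.int64))
    for ct in pd.unique(labels):
        sel = (labels == ct).to_numpy()
        if not sel.any():
            raise TxflowError(f"cell type {ct!r} has no nuclei")
        frac = np.asarray(det[sel].sum(axis=0)).ravel() / sel.sum()
        out[str(ct)] = ds.gene_ids[frac > min_frac]
    return out


# ----------------------------------------------------------------------
# Hurdle model


def _logistic_fit(X: np.ndarray, y: np.ndarray, n_iter: int = 60,
                  ridge: float = 1e-8) -> tuple[np.ndarray, float, bool]:
    """Newton-IRLS logistic regression; returns (beta, loglik, ok)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    ok = False
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, -np.inf, False
        eta = np.clip(X @ beta, -30, 30)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < 1e-10:
            ok = True
            break
        ll_old = ll
    return beta, ll_old if not ok else ll, True


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """OLS with Gaussian (MLE-variance) log-likelihood."""
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return beta, -np.inf, False
    rss = float(np.sum((y - X @ beta) ** 2))
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return beta, ll, True


@dataclass
class HurdleFit:
    """Per-gene hurdle fit: component coefficients and the combined LRT."""

    levels: list[str]
    disc_coef: np.ndarray | None
    cont_coef: np.ndarray | None
    lr_disc: float
    df_disc: int
    lr_cont: float
    df_cont: int
    statistic: float = np.nan
    df: int = 0
    p: float = np.nan
    flag: str = ""

    def finalize(self) -> "HurdleFit":
        self.statistic = max(self.lr_disc + self.lr_cont, 0.0)
        self.df = self.df_disc + self.df_cont
        self.p = float(chi2.sf(self.statistic, self.df)) if self.df > 0 \
            else np.nan
        if self.df == 0 and not self.flag:
            self.flag = "degenerate"
        return self


def _design(cond_codes: np.ndarray, n_levels: int,
            cdr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full ([1, level dummies, cdr]) and reduced ([1, cdr]) designs."""
    n = len(cond_codes)
    dummies = np.zeros((n, n_levels - 1))
    for k in range(1, n_levels):
        dummies[:, k - 1] = cond_codes == k
    X_full = np.column_stack([np.ones(n), dummies, cdr])
    X_red = np.column_stack([np.ones(n), cdr])
    return X_full, X_red


def fit_hurdle(y: np.ndarray, conditions: pd.Series | np.ndarray,
               cdr: np.ndarray, levels: list[str] | None = None) -> HurdleFit:
    """Fit the two-part hurdle model for one gene and test the condition
    factor by the combined component LRT.

    ``y`` is log-normalized expression per nucleus (zeros mean
    undetected); ``conditions`` the per-nucleus condition labels; ``cdr``
    the detection-rate covariate. A degenerate component (all/none
    detected, or fewer than 2 detected nuclei in some condition for the
    continuous part) contributes 0 with 0 df.
    """
    cond = pd.Series(np.asarray(conditions, dtype=object))
    if levels is None:
        levels = [c for c in ["HC", "CD", "TN"] if c in set(cond)]
    if len(levels) < 2:
        raise ConfigError("need at least two conditions")
    codes = np.array([levels.index(c) for c in cond])
    y = np.asarray(y, dtype=float)
    cdr = np.asarray(cdr, dtype=float)
    detected = (y > 0).astype(float)
    n_det = int(detected.sum())

    fit = HurdleFit(levels=levels, disc_coef=None, cont_coef=None,
                    lr_disc=0.0, df_disc=0, lr_cont=0.0, df_cont=0)
    if n_det < 3:
        fit.flag = "undetected"
        return fit.finalize()

    X_full, X_red = _design(codes, len(levels), cdr)
    df_cond = len(levels) - 1

    # discrete component
    if 0 < n_det < len(y):
        bf, llf, okf = _logistic_fit(X_full, detected)
        br, llr, okr = _logistic_fit(X_red, detected)
        if okf and okr and np.isfinite(llf) and np.isfinite(llr):
            fit.disc_coef = bf
            fit.lr_disc = max(2.0 * (llf - llr), 0.0)
            fit.df_disc = df_cond

    # continuous component on detected nuclei
    pos = y > 0
    per_cond_pos = np.array([(pos & (codes == k)).sum()
                             for k in range(len(levels))])
    if (per_cond_pos >= 2).all() and n_det > X_full.shape[1]:
        bf, llf, okf = _ols_fit(X_full[pos], y[pos])
        br, llr, okr = _ols_fit(X_red[pos], y[pos])
        if okf and okr and np.isfinite(llf) and np.isfinite(llr):
            fit.cont_coef = bf
            fit.lr_cont = max(2.0 * (llf - llr), 0.0)
            fit.df_cont = df_cond
    return fit.finalize()


def hurdle_log2fc(fit: HurdleFit, cond_a: str, cond_b: str,
                  cdr_ref: float) -> float:
    """Model-expected log2FC of ``cond_b`` over ``cond_a`` at the
    reference detection rate: difference of
    ``P(detected) * E[expression | detected]`` between conditions (the
    continuous component must be fit on log2-scale expression)."""
    def expected(cond: str) -> float:
        k = fit.levels.index(cond)
        # design row: intercept, dummies, cdr
        row = np.zeros(len(fit.levels) + 1)
        row[0] = 1.0
        if k > 0:
            row[k] = 1.0
        row[-1] = cdr_ref
        if fit.disc_coef is not None:
            eta = float(row @ fit.disc_coef)
            p_det = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        else:
            p_det = 1.0
        mu = float(row @ fit.cont_coef) if fit.cont_coef is not None else 0.0
        return p_det * mu

    return expected(cond_b) - expected(cond_a)


@dataclass
class HurdleDEGResult:
    """Per-cell-type DEG output: LRT table and per-contrast tables."""

    cell_type: str
    lrt: pd.DataFrame
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)


DEFAULT_CONTRASTS = (("HC", "CD"), ("HC", "TN"), ("CD", "TN"))


def hurdle_deg(
    ds: ExpressionDataset,
    norm: NormalizedMatrix,
    labels: pd.Series,
    contrasts=DEFAULT_CONTRASTS,
    min_frac: float = 0.05,
    padj_max: float = 0.05,
    lfc_min: float = 0.1,
    cell_types: list[str] | None = None,
) -> dict[str, HurdleDEGResult]:
    """Two-stage hurdle DEG per cell type: combined LRT over all
    conditions, then pairwise contrasts; a gene is a significant pairwise
    DEG only if it is an LRT DEG (BH ``padj < padj_max``) and passes
    ``padj < padj_max`` and ``|log2fc| > lfc_min`` in the contrast."""
    from txflow.qc import compute_cdr

    labels = pd.Series(np.asarray(labels), index=ds.obs_ids)
    gene_lists = expressed_gene_filter(ds, labels, min_frac)
    cdr_all = compute_cdr(ds).to_numpy()
    cond_all = ds.obs["condition"].to_numpy()
    # log2-scale normalized expression
    Y2 = norm.values.multiply(1.0 / np.log(2.0)).tocsc()

    results: dict[str, HurdleDEGResult] = {}
    for ct in (cell_types or list(gene_lists)):
        sel = (labels == ct).to_numpy()
        genes = gene_lists[ct]
        cols = ds.gene_ids.get_indexer(genes)
        Ysub = np.asarray(Y2[np.ix_(np.flatnonzero(sel), cols)].todense())
        cond = cond_all[sel]
        cdr = cdr_all[sel]
        levels = [c for c in ["HC", "CD", "TN"] if c in set(cond)]

        lrt_rows = []
        for j, g in enumerate(genes):
            fit = fit_hurdle(Ysub[:, j], cond, cdr, levels)
            lrt_rows.append((g, fit.statistic, fit.df, fit.p, fit.flag))
        lrt = pd.DataFrame(lrt_rows, columns=["gene", "statistic", "df",
                                              "p", "flag"]).set_index("gene")
        lrt["padj"] = bh_adjust(lrt["p"].to_numpy())
        lrt["sig_lrt"] = np.isfinite(lrt["padj"]) & (lrt["padj"] < padj_max)

        res = HurdleDEGResult(cell_type=str(ct), lrt=lrt)
        for a, b in contrasts:
            if a not in levels or b not in levels:
                continue
            pair = np.isin(cond, [a, b])
            cdr_ref = float(cdr[pair].mean())
            rows = []
            for j, g in enumerate(genes):
                fit = fit_hurdle(Ysub[pair, j], cond[pair], cdr[pair],
                                 [a, b])
                lfc = hurdle_log2fc(fit, a, b, cdr_ref)
                rows.append((g, fit.statistic, fit.p, lfc))
            tbl = pd.DataFrame(rows, columns=["gene", "statistic", "p",
                                              "log2fc"]).set_index("gene")
            tbl["padj"] = bh_adjust(tbl["p"].to_numpy())
            tbl["sig"] = (lrt["sig_lrt"]
                          & np.isfinite(tbl["padj"])
                          & (tbl["padj"] < padj_max)
                          & (tbl["log2fc"].abs() > lfc_min))
            res.contrasts[f"{b}_vs_{a}"] = tbl
        results[str(ct)] = res
        logger.info("hurdle DEG %s: %d genes tested, %d LRT DEGs", ct,
                    len(genes), int(lrt["sig_lrt"].sum()))
    return results


# ----------------------------------------------------------------------
# Regulon activity (AUC of the recovery curve over the top ranks)


def aucell_score(values: np.ndarray, regulon_idx: np.ndarray,
                 top_fraction: float = 0.05) -> float:
    """AUC score of one cell: genes are ranked by decreasing expression
    (ties broken by gene order); with cutoff ``T = ceil(top_fraction*G)``
    the raw area ``sum_{k<=T} hits(k)`` is normalized by its maximum
    ``sum_{k<=T} min(k, |regulon|)``."""
    values = np.asarray(values, dtype=float).ravel()
    G = values.size
    regulon_idx = np.asarray(regulon_idx, dtype=int)
    if regulon_idx.size == 0:
        raise ConfigError("empty regulon")
    if regulon_idx.size > G:
        raise ConfigError("regulon larger than gene universe")
    T = int(np.ceil(top_fraction * G))
    order = np.lexsort((np.arange(G), -values))
    ranks = np.empty(G, dtype=int)
    ranks[order] = np.arange(1, G + 1)
    r = ranks[regulon_idx]
    raw = int(np.clip(T - r + 1, 0, None).sum())
    ks = np.arange(1, T + 1)
    max_raw = int(np.minimum(ks, regulon_idx.size).sum())
    return raw / max_raw


def aucell_matrix(norm: NormalizedMatrix, regulons: dict[str, list[str]],
                  top_fraction: float = 0.05) -> pd.DataFrame:
    """Cells x regulons activity-score matrix (vectorized over cells)."""
    G = len(norm.gene_ids)
    T = int(np.ceil(top_fraction * G))
    X = np.asarray(norm.values.todense())
    n = X.shape[0]
    # per-cell dense ranks, ties broken by gene order (stable argsort)
    order = np.argsort(-X, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, G + 1)[None, :]
    ks = np.arange(1, T + 1)
    out = {}
    for name, genes in regulons.items():
        idx = norm.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise ConfigError(f"regulon {name!r}: genes not in universe: "
                              f"{missing[:5]}")
        if len(idx) == 0:
            raise ConfigError(f"regulon {name!r} is empty")
        r = ranks[:, idx]
        raw = np.clip(T - r + 1, 0, None).sum(axis=1)
        max_raw = int(np.minimum(ks, len(idx)).sum())
        out[name] = raw / max_raw
    return pd.DataFrame(out, index=norm.obs_ids)


def differential_tf(
    ras: pd.DataFrame,
    cell_type_labels: pd.Series,
    conditions: pd.Series,
    cell_type: str,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided rank-sum test of regulon activity (``cond_b`` vs
    ``cond_a``) within a cell type.

    Regulons are tested only if their mean activity within the cell type
    exceeds the dataset-wide mean; Bonferroni correction is applied over
    the tested regulons and significance called at ``padj < alpha``.
    Regulons with fewer than 2 cells in either group are skipped.
    """
    labels = np.asarray(cell_type_labels)
    conds = np.asarray(conditions)
    in_type = labels == cell_type
    if not in_type.any():
        raise TxflowError(f"no cells of type {cell_type!r}")
    global_mean = ras.mean(axis=0)
    type_mean = ras[in_type].mean(axis=0)
    tested = [r for r in ras.columns if type_mean[r] > global_mean[r]]

    sel_b = in_type & (conds == cond_b)
    sel_a = in_type & (conds == cond_a)
    rows = []
    for reg in tested:
        xb = ras.loc[sel_b, reg].to_numpy()
        xa = ras.loc[sel_a, reg].to_numpy()
        if len(xb) < 2 or len(xa) < 2:
            continue
        stat, p = rank_sum_one_sided(xb, xa, alternative=alternative)
        rows.append((reg, stat, p))
    tbl = pd.DataFrame(rows, columns=["regulon", "statistic", "p"]) \
        .set_index("regulon")
    tbl["padj"] = bonferroni(tbl["p"].to_numpy()) if len(tbl) else []
    tbl["direction"] = "up" if alternative == "greater" else "down"
    tbl["sig"] = tbl["padj"] < alpha if len(tbl) else []
    return tbl.sort_values("padj") if len(tbl) else tbl


# ----------------------------------------------------------------------
# Over-representation analysis


def ora(query: list[str], universe: list[str],
        gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of ``query`` within
    each gene set (sets are intersected with the universe); BH-FDR
    across sets, sorted by FDR."""
    uni = set(universe)
    if not uni:
        raise TxflowError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ConfigError("query genes outside the universe: "
                          f"{sorted(q - uni)[:5]}")
    M = len(uni)
    n = len(q)
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        k = len(s & q)
        p = float(hypergeom.sf(k - 1, M, len(s), n)) if s else 1.0
        rows.append((name, k, len(s), M, p))
    tbl = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                      "universe_size", "p"]) \
        .set_index("gene_set")
    tbl["fdr"] = bh_adjust(tbl["p"].to_numpy())
    return tbl.sort_values("fdr")
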