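"""Signature-based abundance estimation and enrichment region annotation.

Per-spot cell-type abundances come from non-negative least squares
against a mean-expression signature matrix. Abundances are binarized at
the 99th quantile per cell type, each (cluster, cell type) pair is tested
with Fisher's exact test on the binary labels, and every cluster is
assigned the region of its maximum-odds-ratio significant region-specific
cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from scipy.stats import fisher_exact

from txflow.data import ConfigError, ExpressionDataset, TxflowError
from txflow.stats_util import bh_adjust

__all__ = [
    "filter_reference",
    "estimate_abundance",
    "binarize_abundance",
    "annotate_clusters",
    "AbundanceMatrix",
    "ClusterEnrichment",
]


def filter_reference(
    ref: ExpressionDataset,
    label_col: str = "cell_type",
    min_cells: int = 5,
    min_cell_frac: float = 0.03,
    min_nonzero_mean: float = 1.12,
) -> pd.DataFrame:
    """Build a (cell type x gene) mean-expression signature from reference
    single-cell counts.

    Genes are retained only if detected in strictly more than
    ``min_cells`` cells, strictly more than ``min_cell_frac`` of cells,
    and their mean over non-zero cells is strictly greater than
    ``min_nonzero_mean``. A cell type whose signature row becomes
    all-zero raises an error naming the type.
    """
    if label_col not in ref.obs.columns:
        raise ConfigError(f"reference lacks obs column {label_col!r}")
    X = sp.csc_matrix(ref.counts, dtype=float)
    n = ref.n_obs
    n_det = np.asarray((X > 0).sum(axis=0)).ravel()
    total = np.asarray(X.sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        nz_mean = np.where(n_det > 0, total / np.maximum(n_det, 1), 0.0)
    keep = (
        (n_det > min_cells)
        & (n_det > min_cell_frac * n)
        & (nz_mean > min_nonzero_mean)
    )
    if not keep.any():
        raise TxflowError("no genes pass the reference filter")
    kept = ref.subset_genes(keep)
    labels = kept.obs[label_col]
    rows = {}
    for ct in pd.unique(labels):
        sub = kept.counts[np.asarray(labels == ct)]
        rows[ct] = np.asarray(sub.mean(axis=0)).ravel()
    sig = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=kept.gene_ids)
    zero_rows = sig.index[(sig.sum(axis=1) == 0)]
    if len(zero_rows):
        raise TxflowError(
            f"cell type(s) with all-zero signature after filtering: "
            f"{list(zero_rows)}"
        )
    sig.index.name = "cell_type"
    return sig


@dataclass
class AbundanceMatrix:
    """Spots x cell types abundance estimates with NNLS residual norms."""

    values: pd.DataFrame
    residuals: pd.Series
    binarized: pd.DataFrame | None = None
    quantile: float | None = None


def estimate_abundance(ds: ExpressionDataset,
                       signatures: pd.DataFrame) -> AbundanceMatrix:
    """Per-spot non-negative least squares of counts on signature rows
    over the shared gene set."""
    shared = ds.gene_ids.intersection(signatures.columns)
    if len(shared) == 0:
        raise TxflowError("no genes shared between dataset and signatures")
    S = signatures[shared].to_numpy(dtype=float).T  # genes x types
    cols = ds.gene_ids.get_indexer(shared)
    X = np.asarray(ds.counts[:, cols].todense(), dtype=float)
    vals = np.empty((ds.n_obs, S.shape[1]))
    res = np.empty(ds.n_obs)
    for i in range(ds.n_obs):
        vals[i], res[i] = nnls(S, X[i])
    return AbundanceMatrix(
        pd.DataFrame(vals, index=ds.obs_ids, columns=signatures.index),
        pd.Series(res, index=ds.obs_ids, name="residual"),
    )


def binarize_abundance(ab: AbundanceMatrix, q: float = 0.99) -> pd.DataFrame:
    """Per cell type, mark spots strictly above that type's q-quantile
    (linear interpolation) of abundance. Stored on the input and returned."""
    if not 0 < q < 1:
        raise ConfigError("quantile must be in (0, 1)")
    thresh = ab.values.quantile(q, axis=0, interpolation="linear")
    binary = ab.values.gt(thresh, axis=1)
    ab.binarized = binary
    ab.quantile = q
    return binary


@dataclass
class ClusterEnrichment:
    """Per-(cluster, cell type) Fisher results and region assignments."""

    table: pd.DataFrame
    assignments: dict[int, str] = field(default_factory=dict)


def annotate_clusters(
    binary: pd.DataFrame,
    labels: np.ndarray,
    region_map: dict[str, str],
    fdr_max: float = 0.05,
) -> ClusterEnrichment:
    """Fisher's exact test of binary cell-type labels against cluster
    membership; assign each cluster the region of the max-odds-ratio
    region-specific cell type among those with FDR < ``fdr_max``.

    The odds ratio is the sample ``ad/bc`` with a Haldane-Anscombe 0.5
    correction applied to all cells when any cell is zero; p-values are
    two-sided and BH-adjusted over all (cluster, cell type) pairs.
    """
    labels = np.asarray(labels)
    if len(labels) != len(binary):
        raise ConfigError("labels length does not match binary matrix")
    clusters = np.unique(labels)
    rows = []
    for c in clusters:
        in_c = labels == c
        for ct in binary.columns:
            pos = binary[ct].to_numpy()
            a = int((in_c & pos).sum())
            b = int((in_c & ~pos).sum())
            cc = int((~in_c & pos).sum())
            d = int((~in_c & ~pos).sum())
            if min(a, b, cc, d) == 0:
                orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (cc + 0.5))
            else:
                orr = a * d / (b * cc)
            p = fisher_exact([[a, b], [cc, d]], alternative="two-sided")[1]
            rows.append((int(c), ct, a, b, cc, d, orr, p))
    tbl = pd.DataFrame(rows, columns=[
        "cluster", "cell_type", "a", "b", "c", "d", "odds_ratio", "p",
    ])
    tbl["fdr"] = bh_adjust(tbl["p"].to_numpy())

    assignments: dict[int, str] = {}
    region_types = set(region_map)
    for c in clusters:
        sub = tbl[(tbl["cluster"] == int(c))
                  & tbl["cell_type"].isin(region_types)
                  & (tbl["fdr"] < fdr_max)]
        if len(sub) == 0:
            assignments[int(c)] = "unassigned"
        else:
            best = sub.loc[sub["odds_ratio"].idxmax(), "cell_type"]
            assignments[int(c)] = region_map[best]
    return ClusterEnrichment(tbl, assignments)
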