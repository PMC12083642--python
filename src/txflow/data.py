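"""Core data model and on-disk formats.

Counts live in a sparse observations x genes matrix of non-negative
integers; observation and gene metadata are pandas data frames aligned by
position. On disk a dataset is an MTX file plus ``obs.tsv`` / ``var.tsv``
(or a 10x-style directory with ``matrix.mtx``, ``barcodes.tsv``,
``features.tsv``, optionally gzipped).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

#: Ordered experimental conditions; contrast orientation is always
#: second-listed over first in this order (e.g. CD vs HC = log2(CD/HC)).
CONDITIONS = ["HC", "CD", "TN"]

#: Gene-id prefix marking mitochondrial genes (mouse nomenclature).
MITO_PREFIX = "mt-"


class TxflowError(Exception):
    """Base class for all package errors."""


class ConfigError(TxflowError):
    """Invalid configuration."""


class EmptyDatasetError(TxflowError):
    """An operation produced or received an empty dataset."""


class FormatError(TxflowError):
    """Malformed input file."""


@dataclass
class ExpressionDataset:
    """Sparse count matrix with aligned observation/gene metadata.

    Parameters
    ----------
    counts
        ``(n_obs, n_genes)`` sparse matrix of non-negative integers.
    obs
        Per-observation metadata indexed by observation id. Recognized
        columns: ``sample``, ``condition``, ``x``, ``y`` and arbitrary
        label columns.
    var
        Per-gene metadata indexed by gene id. Column ``mito`` (bool) flags
        mitochondrial genes; it is derived from :data:`MITO_PREFIX` when
        absent.
    """

    counts: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.var is None:
            self.var = pd.DataFrame(
                index=[f"g{i}" for i in range(self.counts.shape[1])]
            )
        if self.counts.shape[0] != len(self.obs):
            raise FormatError(
                f"counts has {self.counts.shape[0]} rows but obs has "
                f"{len(self.obs)} entries"
            )
        if self.counts.shape[1] != len(self.var):
            raise FormatError(
                f"counts has {self.counts.shape[1]} columns but var has "
                f"{len(self.var)} entries"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts contain negative values")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise FormatError("counts contain non-integer values")
        if "mito" not in self.var.columns:
            self.var["mito"] = [
                str(g).startswith(MITO_PREFIX) for g in self.var.index
            ]
        if "condition" in self.obs.columns:
            bad = set(self.obs["condition"].dropna().unique()) - set(CONDITIONS)
            if bad:
                raise FormatError(f"unknown condition values: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.var.index

    @property
    def obs_ids(self) -> pd.Index:
        return self.obs.index

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.counts.copy(), self.obs.copy(), self.var.copy()
        )

    def subset_obs(self, mask) -> "ExpressionDataset":
        """Row-subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        return ExpressionDataset(
            sp.csr_matrix(self.counts[mask]),
            self.obs.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
            self.var.copy(),
        )

    def subset_genes(self, mask) -> "ExpressionDataset":
        """Column-subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionDataset(
            sp.csr_matrix(self.counts[:, idx]),
            self.obs.copy(),
            self.var.iloc[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and self.obs.equals(other.obs)
            and self.var.equals(other.var)
        )


# ----------------------------------------------------------------------
# Readers / writers


def write_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    """Write ``matrix.mtx`` + ``obs.tsv`` + ``var.tsv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", ds.counts.astype(np.int64).T)
    ds.obs.to_csv(path / "obs.tsv", sep="\t", index_label="obs_id")
    ds.var.to_csv(path / "var.tsv", sep="\t", index_label="gene_id")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(path: Path, stem: str) -> Path | None:
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    return None


def read_dataset(path: str | Path) -> ExpressionDataset:
    """Read a dataset directory written by :func:`write_dataset` or a
    10x-style directory (``matrix.mtx`` + ``barcodes.tsv`` +
    ``features.tsv``/``genes.tsv``, possibly gzipped)."""
    path = Path(path)
    mtx = _find(path, "matrix.mtx")
    if mtx is None:
        raise FormatError(f"no matrix.mtx(.gz) under {path}")
    with _open_maybe_gz(mtx) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat).T  # stored genes x obs (MTX/10x convention)
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{mtx}: non-integer counts")
    mat = mat.astype(np.int64)

    obs_path = _find(path, "obs.tsv")
    if obs_path is not None:
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        var = pd.read_csv(_find(path, "var.tsv"), sep="\t", index_col=0)
    else:
        bc = _find(path, "barcodes.tsv")
        ft = _find(path, "features.tsv") or _find(path, "genes.tsv")
        if bc is None or ft is None:
            raise FormatError(
                f"{path}: need obs.tsv/var.tsv or barcodes.tsv/features.tsv"
            )
        with _open_maybe_gz(bc) as fh:
            obs = pd.DataFrame(index=[line.strip().split("\t")[0] for line in fh])
        with _open_maybe_gz(ft) as fh:
            ids = [line.rstrip("\n").split("\t") for line in fh]
        var = pd.DataFrame(index=[row[0] for row in ids])
        if ids and len(ids[0]) > 1:
            var["name"] = [row[1] for row in ids]
    if mat.shape[0] != len(obs):
        raise FormatError(
            f"{mtx} has {mat.shape[0]} observations but metadata "
            f"({obs_path or 'barcodes'}) has {len(obs)} rows"
        )
    if mat.shape[1] != len(var):
        raise FormatError(
            f"{mtx} has {mat.shape[1]} genes but gene metadata has "
            f"{len(var)} rows"
        )
    if "mito" in var.columns:
        var["mito"] = var["mito"].astype(bool)
    return ExpressionDataset(mat, obs, var)


# ----------------------------------------------------------------------
# Gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: ``name TAB description TAB gene...`` per line.

    Duplicate genes within a set are dropped (first occurrence kept);
    empty sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, "
                                  "description and at least one gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
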