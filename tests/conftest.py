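"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from txflow import simulate
from txflow.data import ExpressionDataset
from txflow.simulate import (CellTypeSpec, EffectProgram, RegionSpec,
                             SnSimConfig, SpatialSimConfig, SubtypeSpec)


@pytest.fixture(scope="session")
def small_spatial_cfg() -> SpatialSimConfig:
    return simulate.default_spatial_config(
        n_spots_per_sample=400, n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_spatial_ds(small_spatial_cfg):
    return simulate.generate_spatial(small_spatial_cfg)


@pytest.fixture(scope="session")
def small_sn_cfg() -> SnSimConfig:
    return simulate.default_snrna_config(
        n_nuclei=600, n_genes=300, seed=12)


@pytest.fixture(scope="session")
def small_sn_ds(small_sn_cfg):
    return simulate.generate_snrna(small_sn_cfg)


def four_region_cfg(seed: int, n_spots: int = 900, n_genes: int = 300,
                    dispersion: float = 0.6,
                    n_markers: int = 15) -> SpatialSimConfig:
    """Four planted contiguous regions with clear marker programs, used by
    the clustering recovery checks."""
    regions = tuple(
        RegionSpec(f"R{i}", 0.25,
                   tuple(f"m{i}_{j}" for j in range(n_markers)), 2.0)
        for i in range(4)
    )
    return SpatialSimConfig(
        n_spots_per_sample=n_spots, regions=regions, n_genes=n_genes,
        baseline_mean=1.0, nb_dispersion=dispersion, seed=seed,
        conditions=("HC",), n_samples_per_condition=1,
    )


def tiny_dataset(counts, obs=None, genes=None) -> ExpressionDataset:
    """Hand-built dataset from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = obs if obs is not None else pd.DataFrame(
        {"sample": "s0", "condition": "HC"},
        index=[f"c{i}" for i in range(n)])
    var = pd.DataFrame(index=genes if genes is not None
                       else [f"g{j}" for j in range(g)])
    return ExpressionDataset(sp.csr_matrix(counts), obs, var)
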