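"""Pseudo-replication, NB GLM tests, consensus rule."""

import numpy as np
import pandas as pd
import pytest

from txflow import simulate
from txflow.consensus import (ConsensusDEGTable, PseudobulkDesign,
                              PseudobulkMatrix, gene_prevalence_filter,
                              make_pseudoreplicates, nb_lrt, pairwise_test,
                              run_consensus, size_factors)
from txflow.data import ConfigError, TxflowError
from txflow.stats_util import bh_adjust

from conftest import tiny_dataset


def _pb(counts, conditions, genes=None, mito=None):
    counts = np.asarray(counts)
    meta = pd.DataFrame({"group": "g", "sample": "s",
                         "condition": conditions,
                         "split": range(len(conditions))})
    gene_ids = pd.Index(genes if genes is not None
                        else [f"g{j}" for j in range(counts.shape[1])])
    return PseudobulkMatrix(
        counts.astype(np.int64), meta, gene_ids,
        np.zeros(counts.shape[1], bool) if mito is None else np.asarray(mito))


def _spot_ds(n_spots, n_genes=20, seed=0, group="G", sample="s0",
             condition="HC"):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(5, size=(n_spots, n_genes))
    ds = tiny_dataset(counts)
    ds.obs["sample"] = sample
    ds.obs["condition"] = condition
    ds.obs["region"] = group
    return ds


class TestMakePseudoreplicates:
    def test_small_group_excluded(self):
        ds = _spot_ds(9)
        with pytest.raises(TxflowError):
            make_pseudoreplicates(ds, PseudobulkDesign(min_spots=10))

    def test_near_equal_split(self):
        # subset sizes recovered via totals of an all-ones gene
        ones = tiny_dataset(np.ones((11, 1), dtype=int))
        ones.obs["sample"] = "s0"
        ones.obs["condition"] = "HC"
        ones.obs["region"] = "G"
        pb1 = make_pseudoreplicates(ones, PseudobulkDesign(min_spots=10,
                                                           n_splits=2))
        assert sorted(pb1.counts[:, 0].tolist()) == [5, 6]

    def test_count_conservation(self):
        ds = _spot_ds(37, seed=5)
        pb = make_pseudoreplicates(ds, PseudobulkDesign(min_spots=10,
                                                        n_splits=3))
        total = np.asarray(ds.counts.sum(axis=0)).ravel()
        assert np.array_equal(pb.counts.sum(axis=0), total)

    def test_deterministic(self):
        ds = _spot_ds(30)
        d = PseudobulkDesign(seed=42)
        a = make_pseudoreplicates(ds, d)
        b = make_pseudoreplicates(ds, d)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_design(self):
        with pytest.raises(ConfigError):
            PseudobulkDesign(n_splits=1)


class TestPrevalenceFilter:
    def test_min_reps(self):
        pb = _pb([[1, 0, 2], [0, 0, 3], [1, 0, 0]], ["HC", "CD", "TN"])
        out = gene_prevalence_filter(pb, min_reps=3, drop_mito=False)
        assert list(out.gene_ids) == []
        out2 = gene_prevalence_filter(pb, min_reps=2, drop_mito=False)
        assert list(out2.gene_ids) == ["g0", "g2"]

    def test_identity_at_zero(self):
        pb = _pb([[1, 0], [0, 1]], ["HC", "CD"])
        out = gene_prevalence_filter(pb, min_reps=0, drop_mito=False)
        assert list(out.gene_ids) == ["g0", "g1"]

    def test_mito_dropped(self):
        pb = _pb([[5, 5], [5, 5]], ["HC", "CD"], genes=["mt-1", "g"],
                 mito=[True, False])
        out = gene_prevalence_filter(pb, min_reps=0, drop_mito=True)
        assert list(out.gene_ids) == ["g"]


class TestSizeFactors:
    def test_doubled_replicate(self):
        a = np.array([10, 20, 40, 5])
        pb = _pb(np.vstack([a, 2 * a]), ["HC", "CD"])
        sf = size_factors(pb)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_identical_replicates(self):
        a = np.array([10, 20, 40, 5])
        pb = _pb(np.vstack([a, a, a]), ["HC", "CD", "TN"])
        assert np.allclose(size_factors(pb), 1.0)

    def test_hand_computed(self):
        # geomeans per gene: 2, 4, 8, 16; ratios rows: 1, 2, 0.5
        counts = np.array([[2, 4, 8, 16],
                           [4, 8, 16, 32],
                           [1, 2, 4, 8]])
        pb = _pb(counts, ["HC", "CD", "TN"])
        assert np.allclose(size_factors(pb), [1.0, 2.0, 0.5])

    def test_no_common_gene_errors(self):
        pb = _pb([[1, 0], [0, 1]], ["HC", "CD"])
        with pytest.raises(TxflowError):
            size_factors(pb)


class TestNbTests:
    def test_constant_gene_stat_zero(self):
        counts = np.tile([[7, 13]], (6, 1))
        pb = _pb(counts, ["HC"] * 2 + ["CD"] * 2 + ["TN"] * 2)
        res = nb_lrt(pb, sf=np.ones(6))
        assert res["statistic"].max() < 1e-6
        assert (res["p"] > 0.999).all()

    def test_lrt_statistic_nonnegative_p_monotone(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(9, 300))
        pb = _pb(counts, ["HC"] * 3 + ["CD"] * 3 + ["TN"] * 3)
        res = nb_lrt(pb)
        assert (res["statistic"] >= 0).all()
        order = res.sort_values("statistic")
        assert (np.diff(order["p"]) <= 1e-12).all()

    def test_planted_fourfold_log2fc(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(2000, size=(3, 200))
        pb = _pb(np.vstack([base, 4 * base]), ["HC"] * 3 + ["CD"] * 3)
        res = pairwise_test(pb, "HC", "CD", sf=np.ones(6))
        assert np.allclose(res["log2fc"], 2.0, atol=0.05)

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(6, 50))
        pb = _pb(counts, ["HC"] * 3 + ["CD"] * 3)
        sf = size_factors(pb)
        fwd = pairwise_test(pb, "HC", "CD", sf=sf)
        alpha = None
        rev = pairwise_test(pb, "CD", "HC", sf=sf)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)

    def test_bh_hand_oracle(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_power_planted_twofold(self):
        # 2-fold effect, mean 100, dispersion 0.05, 3v3; the closed-form
        # normal-approximation power bound at these settings is ~0.94
        rng = np.random.default_rng(3)
        G = 500
        mu = np.where(np.arange(6)[:, None] < 3, 100.0, 200.0) * np.ones((6, G))
        counts = rng.poisson(rng.gamma(1 / 0.05, 0.05 * mu))
        pb = _pb(counts, ["HC"] * 3 + ["CD"] * 3)
        res = nb_lrt(pb, sf=np.ones(6))
        assert (res["p"] < 0.05).mean() >= 0.90


@pytest.fixture(scope="module")
def planted_ds():
    cfg = simulate.default_spatial_config(
        n_spots_per_sample=1500, n_genes=300, seed=21)
    return simulate.generate_spatial(cfg)


class TestRunConsensus:

    def test_recovery_and_specificity(self, planted_ds):
        design = PseudobulkDesign(group_col="region", seed=50)
        res = run_consensus(planted_ds, design, R=10, groups=["DCN"])
        t = res["DCN"].table
        for g in ("Fos", "Junb", "Egr1", "Npas4"):
            assert t.loc[g, "CD_vs_HC_sig"]
        assert not t.loc["Npas4", "TN_vs_HC_sig"]

    def test_r1_degenerate_fractions(self, planted_ds):
        design = PseudobulkDesign(group_col="region", seed=50)
        res = run_consensus(planted_ds, design, R=1, groups=["DCN"])
        t = res["DCN"].table
        fracs = t[[c for c in t.columns if c.endswith("fraction")]]
        assert set(np.unique(fracs.to_numpy())) <= {0.0, 1.0}

    def test_run_order_invariance(self, planted_ds):
        # fractions do not depend on the order runs are executed in;
        # rerunning with the same base seed reproduces them exactly
        design = PseudobulkDesign(group_col="region", seed=7)
        a = run_consensus(planted_ds, design, R=5, groups=["DCN"])
        b = run_consensus(planted_ds, design, R=5, groups=["DCN"])
        pd.testing.assert_frame_equal(a["DCN"].table, b["DCN"].table)

    def test_monte_carlo_spread_shrinks_with_R(self):
        # weak planted effect => intermediate per-run significance rates;
        # variance of the consensus fraction shrinks as R grows
        genes = ["e1", "e2", "e3", "e4", "e5"]
        cfg = simulate.default_spatial_config(
            n_spots_per_sample=300, n_genes=120, seed=9,
            effect_programs=tuple(
                simulate.EffectProgram("DCN", (g,), ("CD", "TN"),
                                       0.9 + 0.15 * i)
                for i, g in enumerate(genes)))
        ds = simulate.generate_spatial(cfg)

        def fractions(R, base):
            design = PseudobulkDesign(group_col="region", seed=base)
            res = run_consensus(ds, design, R=R, groups=["DCN"])
            t = res["DCN"].table
            return np.r_[t.loc[genes, "lrt_fraction"].to_numpy(),
                         t.loc[genes, "CD_vs_HC_fraction"].to_numpy()]

        small = np.stack([fractions(6, 1000 * i) for i in range(4)])
        large = np.stack([fractions(24, 1000 * i) for i in range(4)])
        assert small.var(axis=0).mean() > large.var(axis=0).mean()

    def test_bad_params(self, planted_ds):
        design = PseudobulkDesign(group_col="region")
        with pytest.raises(ConfigError):
            run_consensus(planted_ds, design, R=0)
        with pytest.raises(ConfigError):
            run_consensus(planted_ds, design, consensus=1.5)
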