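"""Hurdle model, AUCell scoring, differential TF, ORA — with oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from txflow import qc, simulate
from txflow.data import ConfigError, TxflowError
from txflow.scstats import (aucell_matrix, aucell_score, differential_tf,
                            expressed_gene_filter, fit_hurdle, hurdle_deg,
                            hurdle_log2fc, ora)
from txflow.stats_util import rank_sum_one_sided

from conftest import tiny_dataset


# ----------------------------------------------------------------------
# Oracles


def aucell_oracle(values, regulon_idx, top_fraction=0.05):
    """Recovery-curve enumeration: walk the ranking, accumulate hits."""
    values = np.asarray(values, float)
    G = len(values)
    T = int(np.ceil(top_fraction * G))
    order = sorted(range(G), key=lambda j: (-values[j], j))
    member = set(int(i) for i in regulon_idx)
    raw, hits = 0, 0
    for k in range(T):
        if order[k] in member:
            hits += 1
        raw += hits
    max_raw = sum(min(k, len(member)) for k in range(1, T + 1))
    return raw / max_raw


def wilcoxon_oracle_greater(x, y):
    """Exact one-sided p (x greater) by enumerating all rank splits."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    total = 0
    ge = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if sum(i + 1 for i in idx) >= obs:
            ge += 1
    return ge / total


# ----------------------------------------------------------------------


class TestExpressedGeneFilter:
    def test_strict_five_percent(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:5, 0] = 1     # exactly 5% -> removed
        counts[:6, 1] = 1     # 6% -> kept
        ds = tiny_dataset(counts)
        out = expressed_gene_filter(ds, pd.Series(["T"] * 100), 0.05)
        assert list(out["T"]) == ["g1"]

    def test_zero_threshold_keeps_detected(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 1
        ds = tiny_dataset(counts)
        out = expressed_gene_filter(ds, pd.Series(["T"] * 10), 0.0)
        assert list(out["T"]) == ["g0"]

    def test_ubiquitous_kept_everywhere(self):
        counts = np.ones((30, 1), dtype=int)
        ds = tiny_dataset(counts)
        labels = pd.Series(["A"] * 15 + ["B"] * 15)
        out = expressed_gene_filter(ds, labels)
        assert list(out["A"]) == ["g0"] and list(out["B"]) == ["g0"]


class TestHurdle:
    def test_undetected_gene_flagged(self):
        f = fit_hurdle(np.zeros(30), ["HC"] * 15 + ["CD"] * 15,
                       np.full(30, 0.3))
        assert np.isnan(f.p) and f.flag == "undetected"

    def test_combined_df(self):
        rng = np.random.default_rng(0)
        n = 300
        cond = ["HC", "CD", "TN"] * 100
        cdr = rng.uniform(0.2, 0.5, n)
        y = np.where(rng.random(n) < 0.6, rng.normal(3, 1, n), 0.0)
        y = np.abs(y)
        f = fit_hurdle(y, cond, cdr)
        assert f.df == f.df_disc + f.df_cont == 4
        assert f.statistic >= 0

    def test_detection_only_effect_power(self):
        # equal continuous means, detection differs by 0.2
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 600
            cond = np.array(["HC"] * 300 + ["CD"] * 300)
            cdr = rng.uniform(0.3, 0.5, n)
            pdet = np.where(cond == "HC", 0.4, 0.6)
            det = rng.random(n) < pdet
            y = np.zeros(n)
            y[det] = np.abs(rng.normal(2, 0.5, det.sum())) + 0.01
            f = fit_hurdle(y, cond, cdr)
            if f.p < 0.05:
                hits += 1
        assert hits / n_sim >= 0.8

    def test_log2fc_identical_conditions_zero(self):
        f = fit_hurdle(
            np.tile([0, 1.0, 2.0, 0], 25),
            ["HC", "HC", "CD", "CD"] * 25,
            np.full(100, 0.4))
        # same detection/means across conditions (paired pattern)
        assert abs(hurdle_log2fc(f, "HC", "CD", 0.4)) < 0.2

    def test_log2fc_pure_continuous_shift(self):
        # everything detected, continuous means differ by exactly 1
        n = 200
        cond = np.array(["HC"] * 100 + ["CD"] * 100)
        y = np.where(cond == "HC", 3.0, 4.0)
        rng = np.random.default_rng(2)
        cdr = rng.uniform(0.3, 0.7, n)  # varying, independent of y
        f = fit_hurdle(y, cond, cdr)
        assert hurdle_log2fc(f, "HC", "CD", 0.5) == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_log2fc_antisymmetry(self):
        rng = np.random.default_rng(3)
        n = 200
        cond = np.array(["HC", "CD"] * 100)
        cdr = rng.uniform(0.2, 0.6, n)
        y = np.where(rng.random(n) < 0.7,
                     np.abs(rng.normal(2 + (cond == "CD"), 1)), 0)
        f = fit_hurdle(y, cond, cdr)
        ref = float(cdr.mean())
        assert hurdle_log2fc(f, "HC", "CD", ref) == pytest.approx(
            -hurdle_log2fc(f, "CD", "HC", ref))

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(4)
        n = 300
        cond = np.array(["HC", "CD", "TN"] * 100)
        ps = []
        for _ in range(300):
            cdr = rng.uniform(0.2, 0.6, n)
            pdet = 1 / (1 + np.exp(-(-1 + 4 * cdr)))
            det = rng.random(n) < pdet
            y = np.zeros(n)
            y[det] = np.abs(rng.normal(2 + cdr[det], 0.5)) + 0.01
            ps.append(fit_hurdle(y, cond, cdr).p)
        ps = np.asarray(ps)
        assert 0.01 <= (ps < 0.05).mean() <= 0.11


class TestAUCell:
    def test_maximal_score(self):
        values = np.arange(100, 0, -1, dtype=float)
        assert aucell_score(values, [0, 1, 2], 0.05) == 1.0

    def test_zero_score(self):
        values = np.arange(100, 0, -1, dtype=float)
        assert aucell_score(values, [50, 60], 0.05) == 0.0

    def test_worked_example(self):
        # G=100, T=5, regulon at ranks 2 and 4 -> 6/9
        values = np.arange(100, 0, -1, dtype=float)
        assert aucell_score(values, [1, 3], 0.05) == pytest.approx(2 / 3)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            G = int(rng.integers(20, 120))
            values = rng.normal(size=G)
            size = int(rng.integers(1, max(2, G // 5)))
            idx = rng.choice(G, size=size, replace=False)
            tf = float(rng.uniform(0.03, 0.3))
            assert aucell_score(values, idx, tf) == pytest.approx(
                aucell_oracle(values, idx, tf))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(6)
        values = rng.random(80)
        idx = [3, 17, 40]
        a = aucell_score(values, idx, 0.1)
        b = aucell_score(np.exp(5 * values), idx, 0.1)
        assert a == b

    def test_errors(self):
        with pytest.raises(ConfigError):
            aucell_score(np.arange(10.0), [], 0.1)
        with pytest.raises(ConfigError):
            aucell_score(np.arange(4.0), [0, 1, 2, 3, 4], 0.5)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(3, size=(15, 60))
        ds = tiny_dataset(counts)
        norm = qc.normalize_log1p(ds)
        regs = {"r1": ["g3", "g10", "g20"], "r2": ["g1", "g50"]}
        mat = aucell_matrix(norm, regs, 0.1)
        dense = norm.to_dense()
        for i in (0, 7, 14):
            for name, genes in regs.items():
                idx = [int(g[1:]) for g in genes]
                assert mat.iloc[i][name] == pytest.approx(
                    aucell_score(dense[i], idx, 0.1))


class TestWilcoxon:
    def test_exact_example(self):
        # (4,5,6) greater than (1,2,3): p = 1/C(6,3) = 0.05
        _, p = rank_sum_one_sided([4, 5, 6], [1, 2, 3], "greater")
        assert p == pytest.approx(0.05)

    def test_matches_enumeration_small(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            pooled = rng.permutation(100)[:n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            _, p = rank_sum_one_sided(x, y, "greater")
            assert p == pytest.approx(wilcoxon_oracle_greater(x, y))

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        _, p = rank_sum_one_sided(x, y, "greater")
        assert p > 0.01


class TestDifferentialTF:
    def test_planted_regulon_top_ranked(self, small_sn_cfg, small_sn_ds):
        regs = simulate.generate_gene_sets(
            "regulon", small_sn_cfg, n_sets=6, set_size=5, seed=2,
            active_program=small_sn_cfg.effect_programs[0])
        inh = small_sn_ds.subset_obs(
            (small_sn_ds.obs["cell_type"] == "Inh").to_numpy())
        norm = qc.normalize_log1p(inh)
        ras = aucell_matrix(norm, regs, 0.05)
        tbl = differential_tf(ras, inh.obs["subtype"],
                              inh.obs["condition"], "Inh-Kit", "HC", "CD")
        assert tbl.index[0] == "regulon_active"

    def test_mean_ras_filter(self):
        rng = np.random.default_rng(10)
        ras = pd.DataFrame({
            "low": np.r_[np.zeros(50), np.ones(50)],
            "high": np.r_[np.ones(50), np.zeros(50)],
        })
        labels = pd.Series(["A"] * 50 + ["B"] * 50)
        conds = pd.Series((["HC", "CD"] * 25) * 2)
        tbl = differential_tf(ras, labels, conds, "A", "HC", "CD")
        assert "low" not in tbl.index  # below-average activity in type A

    def test_missing_type(self):
        ras = pd.DataFrame({"r": [0.1, 0.2]})
        with pytest.raises(TxflowError):
            differential_tf(ras, pd.Series(["A", "A"]),
                            pd.Series(["HC", "CD"]), "B", "HC", "CD")


class TestORA:
    def test_query_equals_universe(self):
        uni = [f"g{i}" for i in range(20)]
        res = ora(uni, uni, {"s": uni[:5]})
        assert res.loc["s", "p"] == pytest.approx(1.0)

    def test_closed_form(self):
        uni = [f"g{i}" for i in range(20)]
        res = ora(uni[:5], uni, {"s": uni[:5]})
        assert res.loc["s", "p"] == pytest.approx(1 / comb(20, 5))

    def test_empty_query(self):
        uni = [f"g{i}" for i in range(10)]
        res = ora([], uni, {"s": uni[:3]})
        assert (res["p"] == 1.0).all()

    def test_exhaustive_small_universes(self):
        # closed-form hypergeometric tail for every configuration, M<=12
        rng = np.random.default_rng(11)
        for _ in range(50):
            M = int(rng.integers(3, 13))
            uni = [f"g{i}" for i in range(M)]
            n = int(rng.integers(1, M + 1))
            s = int(rng.integers(1, M + 1))
            query = list(rng.choice(uni, n, replace=False))
            gset = list(rng.choice(uni, s, replace=False))
            res = ora(query, uni, {"s": gset})
            k = len(set(query) & set(gset))
            expected = sum(
                comb(s, x) * comb(M - s, n - x) / comb(M, n)
                for x in range(k, min(s, n) + 1))
            assert res.loc["s", "p"] == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(TxflowError):
            ora(["a"], [], {})
        with pytest.raises(ConfigError):
            ora(["zz"], ["a"], {})


class TestHurdleDEGEndToEnd:
    def test_grm5_in_kit_only(self):
        cfg = simulate.default_snrna_config(n_nuclei=1200, n_genes=300,
                                            seed=31)
        ds = simulate.generate_snrna(cfg)
        inh = ds.subset_obs((ds.obs["cell_type"] == "Inh").to_numpy())
        norm = qc.normalize_log1p(inh)
        res = hurdle_deg(inh, norm, inh.obs["subtype"])
        kit = res["Inh-Kit"]
        assert kit.contrasts["CD_vs_HC"].loc["Grm5", "sig"]
        assert kit.contrasts["TN_vs_HC"].loc["Grm5", "sig"]
        for st in ("Inh-Zfhx4", "Inh-Piezo2"):
            for cname in ("CD_vs_HC", "TN_vs_HC"):
                tbl = res[st].contrasts[cname]
                if "Grm5" in tbl.index:
                    assert not tbl.loc["Grm5", "sig"]
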