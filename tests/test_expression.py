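"""Stabilization, batch adjustment, delta expression, GSEA and GO clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mexphen.expression import (DeltaExpressionSet, batch_adjust,
                                cluster_go_terms, correct_degradation,
                                delta_expression, enrichment_score,
                                gsea_preranked, host_paralog_report,
                                joint_ranking, per_line_union_nes, read_gmt,
                                stabilize, write_gmt)
from mexphen.synthetic import SimConfig, gen_expression_counts


def small_counts(seed=0, n_genes=300, n_samples=8):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(4, 1, n_genes))
    c = rng.poisson(mu[:, None], size=(n_genes, n_samples))
    return pd.DataFrame(c, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestStabilize:
    def test_scaling_equivariance(self):
        counts = small_counts()
        stab0, sf0 = stabilize(counts)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 2
        stab1, sf1 = stabilize(scaled)
        assert sf1["s0"] == pytest.approx(2 * sf0["s0"], rel=1e-9)
        pd.testing.assert_frame_equal(stab1, stab0, atol=1e-9, rtol=0)

    def test_identical_samples_identical_columns(self):
        counts = small_counts()
        counts["s1"] = counts["s0"]
        stab, _ = stabilize(counts)
        assert np.allclose(stab["s0"], stab["s1"])

    def test_monotone_within_sample(self):
        counts = small_counts(seed=1)
        stab, _ = stabilize(counts)
        order = counts["s0"].argsort().to_numpy()
        assert np.all(np.diff(stab["s0"].to_numpy()[order]) >= 0)

    def test_gene_order_invariance(self):
        counts = small_counts(seed=2)
        stab0, _ = stabilize(counts)
        perm = counts.sample(frac=1, random_state=0)
        stab1, _ = stabilize(perm)
        pd.testing.assert_frame_equal(stab1.sort_index(), stab0.sort_index())

    def test_zero_total_sample_rejected(self):
        counts = small_counts()
        counts["s0"] = 0
        with pytest.raises(ValueError):
            stabilize(counts)


class TestBatchAdjust:
    def setup_frames(self, offset=0.0, seed=0, del_only_shift=0.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(400)]
        cols, batch, wt = [], {}, {}
        data = {}
        for b in ("b0", "b1"):
            for genotype in ("WT", "Del"):
                for r in range(3):
                    name = f"{b}_{genotype}_{r}"
                    x = rng.normal(8, 1, len(genes)) + (offset if b == "b1" else 0)
                    if genotype == "Del" and b == "b1":
                        x = x + del_only_shift
                    data[name] = x
                    batch[name] = b
                    wt[name] = genotype == "WT"
        df = pd.DataFrame(data, index=genes)
        return df, pd.Series(batch), pd.Series(wt)

    def test_no_batch_structure_near_identity(self):
        df, batch, wt = self.setup_frames(offset=0.0)
        adj = batch_adjust(df, batch, wt)
        assert np.abs(adj.to_numpy() - df.to_numpy()).max() < 0.2

    def test_planted_offset_recovered(self):
        df, batch, wt = self.setup_frames(offset=2.0, seed=1)
        adj = batch_adjust(df, batch, wt)
        sep = (adj.loc[:, (batch == "b1").to_numpy()].mean().mean()
               - adj.loc[:, (batch == "b0").to_numpy()].mean().mean())
        assert abs(sep) < 0.3  # 2.0 offset removed up to shrinkage tolerance

    def test_del_only_shift_untouched(self):
        df, batch, wt = self.setup_frames(offset=0.0, seed=2, del_only_shift=1.5)
        adj = batch_adjust(df, batch, wt)
        del_b1 = [c for c in df.columns if c.startswith("b1_Del")]
        # the genotype signal must survive the WT-fitted adjustment
        assert (adj[del_b1].mean().mean()
                - adj[[c for c in df.columns if c.startswith("b1_WT")]]
                .mean().mean()) == pytest.approx(1.5, abs=0.3)

    def test_single_batch_rejected(self):
        df, batch, wt = self.setup_frames()
        with pytest.raises(ValueError):
            batch_adjust(df, pd.Series("b0", index=df.columns), wt)

    def test_batch_without_wt_rejected(self):
        df, batch, wt = self.setup_frames()
        wt[batch == "b1"] = False
        with pytest.raises(ValueError):
            batch_adjust(df, batch, wt)


class TestDeltaExpression:
    def sheet(self):
        idx = [f"{g}_{r}" for g in ("WT", "Del") for r in range(2)]
        return pd.DataFrame({"line": "l1", "genotype": ["WT", "WT", "Del", "Del"]},
                            index=idx)

    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 1))
        df = pd.DataFrame(np.tile(x, (1, 4)), columns=self.sheet().index)
        d = delta_expression(df, self.sheet())
        assert np.allclose(d.delta["l1"], 0.0)

    def test_planted_shift_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=self.sheet().index)
        df.iloc[0, 2:] += 2.0
        d = delta_expression(df, self.sheet())
        assert d.delta.iloc[0, 0] == pytest.approx(
            2.0 + df.iloc[0, :2].mean() - df.iloc[0, :2].mean(), abs=2.0)
        flipped = self.sheet()
        flipped["genotype"] = ["Del", "Del", "WT", "WT"]
        d2 = delta_expression(df, flipped)
        assert np.allclose(d2.delta["l1"], -d.delta["l1"])

    def test_missing_genotype_errors(self):
        sheet = self.sheet()
        sheet["genotype"] = "WT"
        with pytest.raises(ValueError):
            delta_expression(pd.DataFrame(np.zeros((5, 4)),
                                          columns=sheet.index), sheet)


class TestHostParalogReport:
    def deltas(self, host_rank):
        vals = np.arange(100, dtype=float)
        genes = [f"g{i}" for i in range(100)]
        host = genes[host_rank - 1]  # value host_rank-1, rank host_rank of 100
        delta = pd.DataFrame({"l1": vals}, index=genes)
        return DeltaExpressionSet(delta=delta, host_gene={"l1": host})

    def test_extreme_host_flagged(self):
        rep = host_paralog_report(self.deltas(100))
        assert rep.iloc[0]["percentile"] == pytest.approx(99.5)
        assert rep.iloc[0]["flagged"]

    def test_median_host_not_flagged(self):
        rep = host_paralog_report(self.deltas(50))
        assert rep.iloc[0]["percentile"] == pytest.approx(49.5)
        assert not rep.iloc[0]["flagged"]

    def test_rank_91_flagged(self):
        rep = host_paralog_report(self.deltas(91))
        assert rep.iloc[0]["flagged"]

    def test_absent_host_errors(self):
        ds = self.deltas(50)
        ds.host_gene["l1"] = "missing_gene"
        with pytest.raises(KeyError):
            host_paralog_report(ds)


class TestJointRanking:
    def test_absolute_sum_and_order(self):
        delta = pd.DataFrame({"l1": [1.0, 0.0, 0.5], "l2": [-1.0, 0.0, 0.5],
                              "l3": [1.0, 0.0, -0.5]},
                             index=["a", "b", "c"])
        score = joint_ranking(delta)
        assert score["a"] == pytest.approx(3.0)
        assert score["b"] == pytest.approx(0.0)
        assert list(score.index) == ["a", "c", "b"]

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            joint_ranking(pd.DataFrame({"l1": [1.0]}))


def brute_force_es(scores, hits, weight):
    """Maximum-deviation ES by explicit evaluation at every prefix.

    At each prefix the bridge-normalized deviation (N-k)/N * (weighted
    hit CDF - miss CDF) is evaluated directly.
    """
    s = np.abs(scores) ** weight
    hit_sum = (s * hits).sum()
    n, k = len(scores), hits.sum()
    best = 0.0
    for i in range(n):
        hit_cdf = (s[:i + 1] * hits[:i + 1]).sum() / hit_sum
        miss_cdf = (~hits[:i + 1]).sum() / (n - k)
        dev = (hit_cdf - miss_cdf) * (n - k) / n
        if abs(dev) > abs(best):
            best = dev
    return best


class TestGsea:
    def ranking(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(np.sort(rng.normal(size=n))[::-1],
                         index=[f"g{i}" for i in range(n)])

    def test_unweighted_top_k_closed_form(self):
        n, k = 200, 10
        scores = pd.Series(np.linspace(10, 1, n), index=[f"g{i}" for i in range(n)])
        hit = np.zeros(n, dtype=bool)
        hit[:k] = True
        es, pos = enrichment_score(scores.to_numpy(), hit, weight=0.0)
        assert es == pytest.approx(1 - k / n)
        assert pos == k - 1

    def test_running_sum_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(10, 50)
            scores = np.sort(rng.normal(size=n))[::-1]
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, size=rng.integers(2, n - 1), replace=False)] = True
            es, _ = enrichment_score(scores, hits, weight=1.0)
            assert es == pytest.approx(brute_force_es(scores, hits, 1.0), abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        ranking = self.ranking(n=150, seed=5)
        ps = []
        for i in range(120):
            members = rng.choice(ranking.index, size=15, replace=False)
            res = gsea_preranked(ranking, {"s": members}, n_perm=100, seed=i)
            ps.append(res.iloc[0]["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_set_recovered(self):
        counts, sheet, truth = gen_expression_counts(
            SimConfig(seed=6, n_genes=600, n_lines=4, pathway_shift=1.5))
        stab, _ = stabilize(counts)
        d = delta_expression(stab, sheet)
        score = joint_ranking(d.delta)
        rng = np.random.default_rng(7)
        decoys = {f"rand{i}": rng.choice(score.index, 50, replace=False)
                  for i in range(5)}
        res = gsea_preranked(score, {"planted": truth["pathway_genes"], **decoys},
                             n_perm=1500, seed=0, positive_only=True)
        assert res.iloc[0]["set_name"] == "planted"
        assert res.iloc[0]["padj"] < 0.01

    def test_whole_universe_set_rejected(self):
        ranking = self.ranking(n=50)
        with pytest.raises(ValueError):
            gsea_preranked(ranking, {"all": list(ranking.index)}, n_perm=100)

    def test_tiny_overlap_rejected(self):
        ranking = self.ranking(n=50)
        with pytest.raises(ValueError):
            gsea_preranked(ranking, {"one": [ranking.index[0]]}, n_perm=100)


class TestGoClustering:
    def results(self, names, ps):
        return pd.DataFrame({"set_name": names, "p": ps,
                             "padj": ps, "es": 0.5, "nes": 1.5})

    def test_identical_sets_merge(self):
        sets = {"a": ["g1", "g2", "g3"], "b": ["g1", "g2", "g3"]}
        cl = cluster_go_terms(self.results(["a", "b"], [1e-5, 1e-4]), sets)
        assert len(cl) == 1
        assert cl[0].representative == "a"
        assert cl[0].union_genes == frozenset({"g1", "g2", "g3"})

    def test_disjoint_sets_split(self):
        sets = {"a": ["g1", "g2"], "b": ["g3", "g4"]}
        cl = cluster_go_terms(self.results(["a", "b"], [1e-5, 1e-4]), sets)
        assert len(cl) == 2

    def test_similarity_15pct_merges_at_09_cut(self):
        # Jaccard similarity 3/20 = 0.15 -> distance 0.85 < 0.9
        common = [f"c{i}" for i in range(3)]
        a = common + [f"a{i}" for i in range(10)]
        b = common + [f"b{i}" for i in range(7)]
        cl = cluster_go_terms(self.results(["a", "b"], [1e-5, 1e-4]),
                              {"a": a, "b": b})
        assert len(cl) == 1

    def test_weak_cluster_dropped(self):
        sets = {"a": ["g1", "g2"], "b": ["g3", "g4"]}
        cl = cluster_go_terms(self.results(["a", "b"], [1e-5, 0.005]), sets)
        assert [c.representative for c in cl] == ["a"]

    def test_single_term_singleton(self):
        cl = cluster_go_terms(self.results(["a"], [1e-5]), {"a": ["g1", "g2"]})
        assert len(cl) == 1 and cl[0].members == ["a"]


class TestPerLineNes:
    def test_planted_line_starred(self):
        counts, sheet, truth = gen_expression_counts(
            SimConfig(seed=8, n_genes=500, n_lines=4, pathway_shift=2.0))
        stab, _ = stabilize(counts)
        d = delta_expression(stab, sheet)
        from mexphen.expression import GoCluster
        cl = [GoCluster(members=["planted"], representative="planted",
                        union_genes=frozenset(truth["pathway_genes"]))]
        nes = per_line_union_nes(cl, d.delta, n_perm=300, seed=0)
        nes = nes.set_index("line")
        up = [l for l, s in truth["shifted_lines"].items() if s > 0]
        down = [l for l, s in truth["shifted_lines"].items() if s < 0]
        assert all(nes.loc[l, "star"] for l in up + down)
        assert all(nes.loc[l, "nes"] > 0 for l in up)
        assert all(nes.loc[l, "nes"] < 0 for l in down)
        unshifted = [l for l in d.delta.columns if l not in truth["shifted_lines"]]
        assert not nes.loc[unshifted, "star"].any()


def test_degradation_hook_passthrough():
    counts = small_counts(seed=3)
    assert correct_degradation(counts) is counts
    other = counts * 2
    assert correct_degradation(counts, other) is other


def test_gmt_roundtrip(tmp_path):
    sets = {"setA": ["g1", "g2", "g3"], "setB": ["g4", "g5"]}
    write_gmt(sets, tmp_path / "x.gmt")
    back = read_gmt(tmp_path / "x.gmt")
    assert {k: sorted(v) for k, v in back.items()} == {
        k: sorted(v) for k, v in sets.items()}
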