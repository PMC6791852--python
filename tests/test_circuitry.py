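"""TF filtering, Markov clustering, connectivity and BRD4 degrees."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from crckit.circuitry import (
    CircuitEdge,
    MclConvergenceError,
    brd4_degree,
    compare_connectivity,
    enumerate_edges,
    mcl_cluster,
    nucleosome_free_regions,
    prioritize_tfs,
    rank_delta_out,
    regulatory_connectivity,
)
from crckit.intervals import GenomicInterval, RegionSet, merge_union
from crckit.motifs import MotifHit
from crckit.simulate import simulate_ppi
from conftest import iv, tx


def hit(tf, start, width=10):
    return MotifHit(tf, GenomicInterval("chr1", start, start + width), "+",
                    10.0, 1e-9, 1e-7)


class TestPrioritizeTfs:
    def _setup(self, landscape_ivs, ppi_rows):
        landscape = merge_union([RegionSet(landscape_ivs)])
        t = tx(100_000, gene="TFA", tid="tTFA")
        ppi = pd.DataFrame(ppi_rows,
                           columns=["protein1", "protein2", "combined_score"])
        ppi["evidence"] = "experimental"
        return t, landscape, ppi

    def test_promoter_only_not_enhancer_regulated(self):
        t, landscape, ppi = self._setup(
            [iv(99_500, 100_500)],  # inside the promoter window only
            [("TFA", "TFB", 0.9)])
        out = prioritize_tfs([t], [t], ["TFA", "TFB"], {"TFA", "TFB"},
                             landscape, ppi)
        assert not out.loc["TFA", "enhancer_regulated"]
        assert not out.loc["TFA", "retained"]

    def test_no_ppi_edge_excluded(self):
        t, landscape, ppi = self._setup(
            [iv(99_500, 100_500), iv(120_000, 121_000)],  # distal element
            [("TFX", "TFY", 0.9)])
        out = prioritize_tfs([t], [t], ["TFA"], {"TFA"}, landscape, ppi)
        assert out.loc["TFA", "enhancer_regulated"]
        assert not out.loc["TFA", "has_ppi"]
        assert not out.loc["TFA", "retained"]

    def test_low_score_ppi_not_counted(self):
        t, landscape, ppi = self._setup(
            [iv(120_000, 121_000)], [("TFA", "TFB", 0.35)])
        out = prioritize_tfs([t], [t], ["TFA", "TFB"], {"TFA", "TFB"},
                             landscape, ppi)
        assert not out.loc["TFA", "has_ppi"]

    def test_all_filters_pass(self):
        t, landscape, ppi = self._setup(
            [iv(99_500, 100_500), iv(120_000, 121_000)], [("TFA", "TFB", 0.9)])
        out = prioritize_tfs([t], [t], ["TFA", "TFB"], {"TFA", "TFB"},
                             landscape, ppi)
        assert out.loc["TFA", "retained"]


class TestMclCluster:
    def test_two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        clusters = mcl_cluster(g)
        assert len(set(clusters.values())) == 2
        assert clusters["a"] == clusters["b"] == clusters["c"]
        assert clusters["x"] == clusters["y"] == clusters["z"]
        assert clusters["a"] != clusters["x"]

    def test_isolated_node_singleton(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b")])
        g.add_node("lone")
        clusters = mcl_cluster(g)
        assert sum(1 for n, c in clusters.items()
                   if c == clusters["lone"]) == 1

    def test_partition_covers_every_node(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        clusters = mcl_cluster(g)
        assert set(clusters) == set(g.nodes)

    def test_planted_cliques_recovered(self):
        ppi, truth = simulate_ppi([f"TF{i:02d}" for i in range(30)], seed=11)
        g = nx.Graph()
        g.add_nodes_from(truth)
        for r in ppi.itertuples(index=False):
            g.add_edge(r.protein1, r.protein2, weight=r.combined_score)
        clusters = mcl_cluster(g)
        names = sorted(truth)
        ari = adjusted_rand_score([truth[n] for n in names],
                                  [clusters[n] for n in names])
        assert ari >= 0.9

    def test_deterministic(self):
        g = nx.gnp_random_graph(15, 0.3, seed=5)
        assert mcl_cluster(g) == mcl_cluster(g)

    def test_nonconvergence_reported(self):
        g = nx.path_graph(6)
        with pytest.raises(MclConvergenceError):
            mcl_cluster(g, max_iter=1)


def make_circuit(tf_positions, peak_width=50):
    """Landscape of one element per TF TSS-adjacent peak."""
    peaks = [iv(p, p + peak_width) for p in tf_positions]
    atac = RegionSet(peaks, merged=True)
    landscape = merge_union([RegionSet([iv(p - 100, p + peak_width + 100)
                                        for p in tf_positions])])
    return atac, landscape


class TestRegulatoryConnectivity:
    def test_self_binding_counts_in_and_out(self):
        # one TF whose motif hit lies in the ATAC peak near its own TSS
        atac, landscape = make_circuit([10_000])
        tfs = {"TFA": [tx(10_500, gene="TFA", tid="t1")]}
        hits = {"TFA": [hit("TFA", 10_010)]}
        nfr = nucleosome_free_regions(atac, landscape)
        conn = regulatory_connectivity(tfs, hits, landscape, nfr)
        assert conn.loc["TFA", "in_count"] == 1
        assert conn.loc["TFA", "out_count"] == 1

    def test_no_hits_zero_out(self):
        atac, landscape = make_circuit([10_000])
        tfs = {"TFA": [tx(10_500, gene="TFA", tid="t1")]}
        conn = regulatory_connectivity(tfs, {}, landscape,
                                       nucleosome_free_regions(atac, landscape))
        assert conn.loc["TFA", "out_count"] == 0

    def test_degree_sums_balance_and_bounded(self):
        rng = np.random.default_rng(4)
        positions = [20_000 * (i + 1) for i in range(6)]
        atac, landscape = make_circuit(positions)
        tfs = {f"TF{i}": [tx(positions[i] + 500, gene=f"TF{i}", tid=f"t{i}")]
               for i in range(6)}
        hits = {}
        for i in range(6):
            targets = rng.choice(6, size=rng.integers(0, 4), replace=False)
            hits[f"TF{i}"] = [hit(f"TF{i}", positions[j] + 5) for j in targets]
        conn = regulatory_connectivity(
            tfs, hits, landscape, nucleosome_free_regions(atac, landscape))
        assert conn["in_count"].sum() == conn["out_count"].sum()
        assert conn["in_count"].max() <= 6
        assert conn["out_count"].max() <= 6


def edge(tf, i, auc_a, auc_b):
    region = iv(1000 * i, 1000 * i + 500)
    return CircuitEdge(tf, i, region, iv(1000 * i, 1000 * i + 100),
                       {"A": auc_a, "B": auc_b})


class TestBrd4Degree:
    def test_identical_conditions_zero_fc(self):
        edges = [edge("T", i, 5.0, 5.0) for i in range(10)]
        rec = brd4_degree("T", edges, "A", "B", seed=0)
        assert rec.mean_edge_log2fc == pytest.approx(0.0)
        assert rec.ci_low <= 0.0 <= rec.ci_high

    def test_doubled_counts_approach_unit_fc(self):
        edges = [edge("T", i, 2.0 * (i + 5), float(i + 5)) for i in range(10)]
        rec = brd4_degree("T", edges, "A", "B", pseudo=1e-9, seed=0)
        assert rec.mean_edge_log2fc == pytest.approx(1.0, abs=1e-6)

    def test_out_degree_additive_over_partition(self):
        edges = [edge("T", i, float(i), 2.0 * i) for i in range(12)]
        full = brd4_degree("T", edges, "A", "B", seed=0)
        part1 = brd4_degree("T", edges[:5], "A", "B", seed=0)
        part2 = brd4_degree("T", edges[5:], "A", "B", seed=0)
        for cond in ("A", "B"):
            assert full.out_degree_rpm[cond] == pytest.approx(
                part1.out_degree_rpm[cond] + part2.out_degree_rpm[cond])

    def test_fold_change_antisymmetric_under_swap(self):
        rng = np.random.default_rng(9)
        edges = [edge("T", i, float(rng.uniform(1, 9)), float(rng.uniform(1, 9)))
                 for i in range(8)]
        fwd = brd4_degree("T", edges, "A", "B", seed=0)
        rev = brd4_degree("T", edges, "B", "A", seed=0)
        assert fwd.mean_edge_log2fc == pytest.approx(-rev.mean_edge_log2fc)

    def test_zero_edges_flagged(self):
        rec = brd4_degree("T", [], "A", "B")
        assert rec.n_edges == 0 and not rec.has_edges
        assert np.isnan(rec.mean_edge_log2fc)


class TestRankDeltaOut:
    def test_sign_ordering_and_edgeless_excluded(self):
        pos = brd4_degree("P", [edge("P", 0, 4.0, 1.0)] * 3, "A", "B", seed=0)
        neg = brd4_degree("N", [edge("N", 0, 1.0, 4.0)] * 3, "A", "B", seed=0)
        none = brd4_degree("Z", [], "A", "B")
        ranked = rank_delta_out([neg, none, pos])
        assert [r.tf for r in ranked] == ["P", "N"]

    def test_all_zero_sorted_by_name(self):
        recs = [brd4_degree(name, [edge(name, 0, 3.0, 3.0)], "A", "B", seed=0)
                for name in ("c", "a", "b")]
        ranked = rank_delta_out(recs)
        assert [r.tf for r in ranked] == ["a", "b", "c"]


class TestCompareConnectivity:
    def test_worked_example_exact(self):
        w, p = compare_connectivity([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_not_significant(self):
        _, p = compare_connectivity([1, 2, 3], [1, 2, 3], alternative="greater")
        assert p >= 0.5

    @pytest.mark.parametrize("n,m", [(2, 3), (4, 4), (5, 3), (8, 8), (7, 6)])
    def test_exact_matches_scipy_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(3):
            perm = rng.permutation(1000).astype(float)  # tie-free
            a, b = perm[:n], perm[n:n + m]
            for alt in ("greater", "less"):
                _, p = compare_connectivity(a, b, alternative=alt)
                ref = stats.mannwhitneyu(a, b, alternative=alt,
                                         method="exact").pvalue
                assert p == pytest.approx(float(ref), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        _, p_exact = compare_connectivity(a, b, alternative="greater")
        _, p_norm = compare_connectivity(a, b, alternative="greater",
                                         exact_max_n=0)
        assert p_exact == pytest.approx(p_norm, abs=0.02)
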