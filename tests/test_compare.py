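import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from statsmodels.stats.multitest import multipletests

from dielnet import compare as cp
from dielnet.io import EdgeList, OrthogroupMap, ValidationError
from dielnet.network import GeneNetwork


def _net(triples):
    edges = EdgeList(pd.DataFrame(
        [(a, b, w) for a, b, w in triples],
        columns=["node_a", "node_b", "weight"]))
    return GeneNetwork(pd.DataFrame(index=edges.nodes()), edges)


def _omap(mapping):
    tr = pd.DataFrame(
        {"orthogroup": list(mapping.values()), "length": 1000.0},
        index=pd.Index(list(mapping.keys()), name="transcript"))
    return OrthogroupMap(tr)


class TestOrthogroupConnectivity:
    def test_triangle_two_groups(self):
        net = _net([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        conn = cp.orthogroup_connectivity(net, _omap({"a": "OG1", "b": "OG1", "c": "OG2"}))
        assert conn["OG1"] == 2.0 and conn["OG2"] == 2.0

    def test_mean_over_nodes(self):
        net = _net([("a", "b", 1), ("a", "c", 1), ("a", "d", 1), ("b", "c", 1)])
        conn = cp.orthogroup_connectivity(
            net, _omap({"a": "OG1", "b": "OG1", "c": "OG2", "d": "OG2"}))
        assert conn["OG1"] == pytest.approx(2.5)  # degrees 3 and 2

    def test_unmapped_node_strict_error(self):
        net = _net([("a", "b", 1)])
        with pytest.raises(ValidationError):
            cp.orthogroup_connectivity(net, _omap({"a": "OG1"}))
        with pytest.warns(UserWarning):
            conn = cp.orthogroup_connectivity(net, _omap({"a": "OG1"}),
                                              ignore_unmapped=True)
        assert list(conn.index) == ["OG1"]


class TestZDiff:
    def test_identical_tables_zero(self):
        t = pd.Series([1.0, 2.0, 3.0], index=["OG1", "OG2", "OG3"])
        comp = cp.connectivity_zdiff(t, t.copy())
        np.testing.assert_allclose(comp.table["z_diff"], 0.0, atol=1e-12)

    def test_reversed_tables_hand_computed(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["OG1", "OG2", "OG3"])
        b = pd.Series([3.0, 2.0, 1.0], index=["OG1", "OG2", "OG3"])
        comp = cp.connectivity_zdiff(a, b)
        np.testing.assert_allclose(comp.table["z_diff"].to_numpy(), [2.0, 0.0, -2.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        idx = [f"OG{i}" for i in range(8)]
        a = pd.Series(rng.uniform(0, 10, 8), index=idx)
        b = pd.Series(rng.uniform(0, 10, 8), index=idx)
        fwd = cp.connectivity_zdiff(a, b).table["z_diff"]
        rev = cp.connectivity_zdiff(b, a).table["z_diff"]
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_union_includes_one_sided_orthogroups(self):
        a = pd.Series([5.0, 1.0, 2.0, 1.0], index=["OGa", "OG1", "OG2", "OG3"])
        b = pd.Series([1.0, 2.0, 1.0], index=["OG1", "OG2", "OG3"])
        comp = cp.connectivity_zdiff(a, b, include="union")
        assert "OGa" in comp.table.index
        assert comp.table.loc["OGa", "mean_degree_b"] == 0.0
        shared = cp.connectivity_zdiff(a, b, include="shared")
        assert "OGa" not in shared.table.index

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        idx = [f"OG{i}" for i in range(6)]
        a = pd.Series(rng.uniform(0, 5, 6), index=idx)
        b = pd.Series(rng.uniform(0, 5, 6), index=idx)
        base = cp.connectivity_zdiff(a, b).table["z_diff"]
        perm = rng.permutation(6)
        shuf = cp.connectivity_zdiff(a.iloc[perm], b.iloc[perm]).table["z_diff"]
        pd.testing.assert_series_equal(base.sort_index(), shuf.sort_index())


class TestIQROutliers:
    def test_single_extreme_value(self):
        z = pd.Series([1.0, 2.0, 3.0, 4.0, 100.0], index=list("abcde"))
        assert cp.iqr_outliers(z) == {"e"}

    def test_symmetric_values_large_multiplier(self):
        z = pd.Series([-5.0, -1.0, 0.0, 1.0, 5.0])
        assert cp.iqr_outliers(z, multiplier=10.0) == set()

    def test_zero_iqr_flags_non_median(self):
        z = pd.Series([0.0, 0.0, 0.0, 0.0, 10.0], index=list("abcde"))
        with pytest.warns(UserWarning):
            assert cp.iqr_outliers(z) == {"e"}

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        z = pd.Series(rng.normal(size=30))
        assert cp.iqr_outliers(z) == cp.iqr_outliers(z + 42.0)

    def test_absolute_rule(self):
        z = pd.Series([-3.0, -0.1, 0.0, 0.1, 3.0], index=list("abcde"))
        out = cp.iqr_outliers(z, multiplier=1.5, rule="absolute")
        assert out == {"a", "e"}


class TestDiffusion:
    def test_two_node_closed_form(self):
        net = _net([("a", "b", 1.0)])
        heat = cp.diffuse(net, "a", time=0.1)
        np.testing.assert_allclose(
            heat.loc[["a", "b"]].to_numpy(),
            [(1 + math.exp(-0.2)) / 2, (1 - math.exp(-0.2)) / 2],
            atol=1e-10,
        )


    def test_zero_time_identity(self):
        net = _net([("a", "b", 1.0), ("b", "c", 1.0)])
        heat = cp.diffuse(net, "b", time=0.0)
        assert heat.loc["b"] == pytest.approx(1.0)

    def test_heat_conserved(self):
        rng = np.random.default_rng(3)
        triples = [(f"n{i}", f"n{j}", 1.0)
                   for i in range(15) for j in range(i + 1, 15) if rng.uniform() < 0.3]
        net = _net(triples)
        heat = cp.diffuse(net, net.nodes.index[0], time=0.7)
        assert heat.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_matrix_exponential(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(10, 30))
            triples = [(f"n{i}", f"n{j}", 1.0)
                       for i in range(n) for j in range(i + 1, n)
                       if rng.uniform() < 0.2]
            if not triples:
                continue
            net = _net(triples)
            nodes = net.nodes.index
            A = np.zeros((len(nodes), len(nodes)))
            pos = {g: i for i, g in enumerate(nodes)}
            for _, r in net.edges.edges.iterrows():
                i, j = pos[r["node_a"]], pos[r["node_b"]]
                A[i, j] = A[j, i] = 1.0
            L = np.diag(A.sum(1)) - A
            h0 = np.zeros(len(nodes))
            h0[0] = 1.0
            oracle = expm(-L * 0.1) @ h0
            heat = cp.diffuse(net, nodes[0], time=0.1)
            np.testing.assert_allclose(heat.to_numpy(), oracle, atol=1e-8)


class TestDiffusionSubnetwork:
    def test_star_ceiling(self):
        triples = [("hub", f"leaf{i}", 1.0) for i in range(9)]
        net = _net(triples)
        res = cp.diffusion_subnetwork(net, "hub", fraction=0.1)
        assert res.subnetwork_nodes == {"hub"}
        assert len(res.subnetwork_edges) == 0

    def test_two_cliques_heat_stays_local(self):
        triples = [(f"a{i}", f"a{j}", 1.0) for i in range(10) for j in range(i + 1, 10)]
        triples += [(f"b{i}", f"b{j}", 1.0) for i in range(10) for j in range(i + 1, 10)]
        triples.append(("a0", "b0", 1.0))
        net = _net(triples)
        res = cp.diffusion_subnetwork(net, "a5", fraction=0.5, time=0.1)
        assert all(node.startswith("a") for node in res.subnetwork_nodes)

    def test_fraction_one_returns_everything(self):
        net = _net([("a", "b", 1.0), ("c", "d", 1.0)])
        res = cp.diffusion_subnetwork(net, "a", fraction=1.0)
        assert res.subnetwork_nodes == {"a", "b", "c", "d"}
        assert len(res.subnetwork_edges) == 2

    def test_invalid_fraction(self):
        net = _net([("a", "b", 1.0)])
        with pytest.raises(ValidationError):
            cp.diffusion_subnetwork(net, "a", fraction=0.0)


class TestHypergeom:
    def test_full_overlap_small_universe(self):
        assert cp.hypergeom_test(2, 2, 2, 4, "over") == pytest.approx(1 / 6)

    def test_zero_overlap_under(self):
        assert cp.hypergeom_test(0, 2, 2, 4, "under") == pytest.approx(1 / 6)

    def test_forced_overlap_p_one(self):
        assert cp.hypergeom_test(3, 3, 3, 3, "over") == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            cp.hypergeom_test(5, 2, 2, 4)

    def test_matches_exhaustive_enumeration(self):
        # enumerate all C(N, n) draws for a small case
        N, K, n = 8, 3, 4
        universe = range(N)
        marked = set(range(K))
        overlaps = [len(marked & set(draw))
                    for draw in itertools.combinations(universe, n)]
        total = len(overlaps)
        for k in range(0, min(K, n) + 1):
            over = sum(1 for o in overlaps if o >= k) / total
            under = sum(1 for o in overlaps if o <= k) / total
            assert cp.hypergeom_test(k, K, n, N, "over") == pytest.approx(over)
            assert cp.hypergeom_test(k, K, n, N, "under") == pytest.approx(under)


class TestEnrichment:
    def test_target_equals_universe_all_p_one(self):
        gm = {"OG1": {"T1"}, "OG2": {"T1", "T2"}, "OG3": {"T2"}}
        table = cp.go_enrichment(set(gm), gm, set(gm))
        assert (table["p"] == 1.0).all()

    def test_perfectly_concentrated_term(self):
        universe = {f"OG{i}" for i in range(20)}
        members = {f"OG{i}" for i in range(10)}
        gm = {og: ({"T"} if og in members else set()) for og in universe}
        table = cp.go_enrichment(members, gm, universe)
        assert table.loc["T", "p"] == pytest.approx(1 / math.comb(20, 10))

    def test_bh_step_up_example(self):
        _, padj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(padj, [0.03, 0.03, 0.03])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=25))
    def test_bh_matches_brute_force(self, pvals):
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        m = len(pvals)
        order = np.argsort(pvals)
        brute = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(reversed(order)):
            rank = m - rank_from_end
            running = min(running, pvals[idx] * m / rank)
            brute[idx] = running
        np.testing.assert_allclose(padj, brute, rtol=1e-12)

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            cp.go_enrichment({"OGx"}, {}, {"OG1"})


class TestSubnetworkOverlap:
    def test_identical_subnetworks(self):
        omap = _omap({"a": "OG1", "b": "OG2"})
        res = cp.subnetwork_overlap({"a", "b"}, {"a", "b"}, omap, {"OG1", "OG2"})
        assert res["shared"] == {"OG1", "OG2"}
        assert res["p"] == pytest.approx(1.0)

    def test_disjoint_subnetworks_exact_p(self):
        omap = _omap({"a": "OG1", "b": "OG2", "c": "OG3", "d": "OG4"})
        res = cp.subnetwork_overlap({"a", "b"}, {"c", "d"}, omap,
                                    {"OG1", "OG2", "OG3", "OG4"})
        assert res["shared"] == set()
        # P(X <= 0) for Hypergeometric(N=4, K=2, n=2)
        assert res["p"] == pytest.approx(1 / 6)

    def test_planted_overlap_recovered(self, small_dataset):
        matrices, omap, _, _ = small_dataset
        genes_a = list(matrices["speciesA"].gene_ids)
        rng = np.random.default_rng(5)
        sub_a = set(rng.choice(genes_a, size=40, replace=False))
        sub_b = set(rng.choice(genes_a, size=40, replace=False))
        universe = set(omap.transcripts["orthogroup"])
        res = cp.subnetwork_overlap(sub_a, sub_b, omap, universe)
        assert res["shared"] == res["orthogroups_a"] & res["orthogroups_b"]
        assert 0.0 <= res["p"] <= 1.0
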