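import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import (
    bh_oracle,
    betweenness_oracle,
    closeness_oracle,
    clustering_oracle,
    eigenvector_oracle,
    graph_to_adj,
    ranksum_exact_oracle,
    spearman_oracle,
)
from raretaxa.io import OtuTable, SampleMetadata
from raretaxa.network import (
    build_network,
    build_network_from_table,
    compare_health_networks,
    compare_topology,
    fdr_adjust,
    link_decomposition,
    pairwise_spearman,
    positive_percentage,
    topology_metrics,
)
from raretaxa.partition import GspPartition
from raretaxa.simulate import generate_dataset


def _table(counts):
    counts = np.asarray(counts)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(counts.shape[0])],
            columns=[f"O{i}" for i in range(counts.shape[1])],
        )
    )


def _partition_for(otus, classes):
    return GspPartition(
        pd.DataFrame(
            {
                "gsp_class": classes,
                "mean_relative_abundance": [1.0 / len(otus)] * len(otus),
                "occupancy": [1.0] * len(otus),
            },
            index=list(otus),
        )
    )


class TestPairwiseSpearman:
    def test_identical_and_reversed_profiles(self):
        base = np.arange(1, 7)
        t = _table(np.column_stack([base, base, base[::-1]]))
        r, _ = pairwise_spearman(t)
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert r.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_midrank_oracle(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 40, size=(10, 12))
        t = _table(counts)
        r, p = pairwise_spearman(t)
        for i in range(12):
            for j in range(i + 1, 12):
                ro, po = spearman_oracle(counts[:, i], counts[:, j])
                assert r.iloc[i, j] == pytest.approx(ro, abs=1e-12)
                assert p.iloc[i, j] == pytest.approx(po, abs=1e-12)

    def test_constant_otu_yields_nan_not_error(self):
        t = _table(np.column_stack([np.arange(5), np.full(5, 3)]))
        r, p = pairwise_spearman(t)
        assert np.isnan(r.iloc[0, 1]) and np.isnan(p.iloc[0, 1])

    def test_rank_invariance_of_edge_set(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 100, size=(12, 8))
        part = _partition_for([f"O{i}" for i in range(8)], ["AT"] * 8)
        g1 = build_network_from_table(_table(counts), part, r_threshold=0.3)
        g2 = build_network_from_table(_table(counts * 7 + 1), part, r_threshold=0.3)
        assert set(g1.edges) == set(g2.edges)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pairwise_spearman(_table(np.ones((3, 4), dtype=int)))


class TestFdrAdjust:
    def test_equal_p_values_unchanged(self):
        p = np.full(6, 0.04)
        assert fdr_adjust(p) == pytest.approx(p)

    def test_hand_computed_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_step_up_oracle_and_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        adj = fdr_adjust(p)
        assert adj == pytest.approx(bh_oracle(p), abs=1e-12)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestBuildNetwork:
    def _rp(self, r_vals):
        ids = [f"O{i}" for i in range(len(r_vals) + 1)]
        n = len(ids)
        r = np.eye(n)
        p = np.zeros((n, n))
        for k, v in enumerate(r_vals):
            r[0, k + 1] = r[k + 1, 0] = v
        return (
            pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids),
            _partition_for(ids, ["AT"] * n),
        )

    def test_threshold_is_strict(self):
        r, p, part = self._rp([0.65])
        g = build_network(r, p, part)
        assert g.number_of_edges() == 0
        r, p, part = self._rp([0.651])
        assert build_network(r, p, part).number_of_edges() == 1

    def test_subthreshold_keeps_isolated_nodes(self):
        r, p, part = self._rp([0.1, -0.2, 0.3])
        g = build_network(r, p, part)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 4

    def test_planted_modules_have_elevated_edge_density(self):
        table, _, _, truth = generate_dataset(
            n_samples=20, n_otus=200, depth=20_000, seed=5,
            frac_module_members=0.2, module_strength=1.5,
        )
        from raretaxa.partition import classify_gsp

        part = classify_gsp(table)
        net = build_network_from_table(table, part, r_threshold=0.65)
        mod = set(truth.modules[0].otu_ids)
        within = sum(1 for u, v in net.edges if u in mod and v in mod)
        n_mod = len(mod)
        density_within = within / (n_mod * (n_mod - 1) / 2)
        n = net.number_of_nodes()
        density_all = net.number_of_edges() / (n * (n - 1) / 2)
        assert density_within > 2 * density_all


class TestLinkDecomposition:
    def _net_with(self, edges):
        g = nx.Graph()
        for u, v, cu, cv, sign in edges:
            g.add_node(u, gsp_class=cu)
            g.add_node(v, gsp_class=cv)
            g.add_edge(u, v, r=0.9 if sign == "+" else -0.9, sign=sign,
                       adjusted_p=0.01, weight=0.9)
        return g

    def test_single_cross_class_edge(self):
        g = self._net_with([("a", "b", "AT", "RT", "+")])
        d = link_decomposition(g)
        assert d.loc["AT-RT"].tolist() == [1, 1, 0, 100.00]
        assert d.drop("AT-RT")["total_links"].sum() == 0

    def test_totals_reconcile_with_edge_count(self):
        rng = np.random.default_rng(6)
        g = nx.Graph()
        classes = ["AT", "IT", "RT"]
        for i in range(30):
            g.add_node(i, gsp_class=classes[i % 3])
        for _ in range(60):
            u, v = rng.choice(30, 2, replace=False)
            sign = "+" if rng.random() < 0.8 else "-"
            g.add_edge(int(u), int(v), sign=sign, r=0.9, adjusted_p=0.01)
        d = link_decomposition(g)
        assert d["total_links"].sum() == g.number_of_edges()
        assert (d["positive_links"] + d["negative_links"]).equals(d["total_links"])

    def test_unlabeled_node_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+", r=0.9, adjusted_p=0.01)
        with pytest.raises(ValueError):
            link_decomposition(g)

    @pytest.mark.parametrize(
        "pos,total,expected",
        [(3935, 4132, 95.23), (356, 435, 81.84), (1, 1, 100.00), (1, 3, 33.33)],
    )
    def test_positive_percentage_rounding(self, pos, total, expected):
        assert positive_percentage(pos, total) == expected


class TestTopologyMetrics:
    def test_complete_graph(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        per_node, gstats = topology_metrics(g)
        assert gstats["graph_density"] == pytest.approx(1.0)
        assert (per_node["clustering"] == 1.0).all()

    def test_path_graph_betweenness(self):
        g = nx.path_graph(["a", "b", "c"])
        nx.set_edge_attributes(g, 1.0, "weight")
        per_node, _ = topology_metrics(g)
        assert per_node.loc["b", "betweenness"] == 1.0
        assert per_node.loc["a", "betweenness"] == 0.0

    def test_random_graph_matches_brute_force_oracles(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(25, 0.15, seed=12)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.65, 1.0))
        per_node, gstats = topology_metrics(g)
        adj, weights = graph_to_adj(g)
        bc = betweenness_oracle(adj)
        cc = closeness_oracle(adj)
        cl = clustering_oracle(adj)
        ev = eigenvector_oracle(adj, weights)
        for n in g.nodes:
            assert per_node.loc[n, "betweenness"] == pytest.approx(bc[n], abs=1e-10)
            assert per_node.loc[n, "closeness"] == pytest.approx(cc[n], abs=1e-10)
            assert per_node.loc[n, "clustering"] == pytest.approx(cl[n], abs=1e-10)
            assert per_node.loc[n, "eigenvector"] == pytest.approx(ev[n], abs=1e-8)
        assert gstats["graph_density"] == pytest.approx(
            2 * g.number_of_edges() / (25 * 24), abs=1e-12
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology_metrics(nx.Graph())


class TestCompareTopology:
    def _metrics(self, values_by_class):
        rows = {}
        classes = []
        otus = []
        vals = []
        for cls, values in values_by_class.items():
            for i, v in enumerate(values):
                otus.append(f"{cls}{i}")
                classes.append(cls)
                vals.append(v)
        metrics = pd.DataFrame({"degree": vals}, index=otus)
        part = _partition_for(otus, classes)
        return metrics, part

    def test_identical_distributions_not_significant(self):
        m, part = self._metrics({"AT": [1, 2, 3, 4], "IT": [1, 2, 3, 4], "RT": [9] * 3})
        res = compare_topology(m, part, "degree")
        assert res.loc["AT-IT", "p"] > 0.9

    def test_complete_separation_extreme_u(self):
        m, part = self._metrics(
            {"AT": list(range(10)), "IT": list(range(100, 110)), "RT": [1, 2, 3]}
        )
        res = compare_topology(m, part, "degree")
        assert res.loc["AT-IT", "W"] in (0.0, 100.0)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=7)
        b = rng.normal(size=8)
        m, part = self._metrics({"AT": a, "IT": b, "RT": [0.0] * 3})
        res = compare_topology(m, part, "degree")
        u_obs, p_exact = ranksum_exact_oracle(a, b)
        assert res.loc["AT-IT", "W"] in (
            pytest.approx(u_obs), pytest.approx(len(a) * len(b) - u_obs)
        )
        assert res.loc["AT-IT", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_small_class_undefined(self):
        m, part = self._metrics({"AT": [1, 2], "IT": [1, 2, 3], "RT": [1, 2, 3]})
        res = compare_topology(m, part, "degree")
        assert not res.loc["AT-IT", "defined"]


class TestHealthComparison:
    def _meta(self, n):
        half = n // 2
        return SampleMetadata(
            pd.DataFrame(
                {"site": ["QS"] * n, "health": ["H"] * half + ["M"] * half},
                index=[f"S{i}" for i in range(n)],
            )
        )

    def test_identical_groups_identical_stats(self):
        rng = np.random.default_rng(10)
        block = rng.integers(0, 60, size=(5, 10))
        counts = np.vstack([block, block])  # M samples mirror H samples
        t = _table(counts)
        part = _partition_for(t.otu_ids, ["AT"] * 10)
        cmp_ = compare_health_networks(t, part, self._meta(10), r_threshold=0.3)
        pd.testing.assert_series_equal(
            cmp_.stats.loc["H"], cmp_.stats.loc["M"], check_names=False
        )

    def test_decorrelated_module_reduces_positive_links(self):
        table, meta, _, truth = generate_dataset(
            n_samples=20, n_otus=150, depth=20_000, seed=6,
            frac_module_members=0.4, module_strength=2.0,
            decorrelate_modules_in_m=True,
        )
        from raretaxa.partition import classify_gsp

        part = classify_gsp(table)
        cmp_ = compare_health_networks(table, part, meta, r_threshold=0.65)
        pos = {
            h: cmp_.decompositions[h]["positive_links"].sum() for h in ("H", "M")
        }
        assert pos["M"] < pos["H"]

    def test_output_schema(self, processed):
        table, part, meta, _, _ = processed
        cmp_ = compare_health_networks(table, part, meta)
        for col in ("graph_density", "links"):
            assert col in cmp_.stats.columns
        assert set(cmp_.decompositions) == {"H", "M"}

    def test_small_group_rejected(self):
        t = _table(np.arange(24).reshape(6, 4))
        part = _partition_for(t.otu_ids, ["AT"] * 4)
        with pytest.raises(ValueError, match="fewer than 4"):
            compare_health_networks(t, part, self._meta(6))
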