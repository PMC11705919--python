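"""Spearman/FDR co-occurrence networks and their GSP decomposition.

An edge connects two OTUs whose abundance profiles are strongly
(|Spearman r| > 0.65) and significantly (Benjamini-Hochberg adjusted
p < 0.05) correlated across samples; the edge sign is the sign of r.
Edges are then tabulated by the abundance classes of their endpoints
(AT-AT, AT-IT, ... RT-RT) and by sign, and standard topology metrics are
computed per node and per graph.
"""

from __future__ import annotations

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import round_half_away
from .io import OtuTable, SampleMetadata
from .partition import GspPartition, GSP_CLASSES, classify_gsp

CLASS_PAIRS = ("AT-AT", "AT-IT", "AT-RT", "IT-IT", "IT-RT", "RT-RT")


def pairwise_spearman(
    table: OtuTable, otu_subset: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlation across samples.

    Returns symmetric (r, p) DataFrames indexed by OTU ID. Ties get
    midranks; p-values use the large-sample t approximation. Pairs
    involving a constant OTU come back NaN and are treated as no-link
    downstream.
    """
    sub = table if otu_subset is None else table.subset_otus(otu_subset)
    if sub.shape[0] < 4:
        raise ValueError("pairwise correlation requires at least 4 samples")
    x = sub.counts.to_numpy(dtype=float)
    ids = sub.otu_ids
    n = x.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    z = ranks - ranks.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, z / sd, np.nan)
        r = (z.T @ z) / n
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    partition: GspPartition,
    r_threshold: float = 0.65,
    alpha: float = 0.05,
    pre_adjusted: bool = False,
) -> nx.Graph:
    """Threshold correlation matrices into an undirected signed graph.

    BH adjustment is applied over the upper-triangle p-values of the
    tested subset (one family per network build) unless ``pre_adjusted``.
    Edge rule: |r| strictly above ``r_threshold`` and adjusted p strictly
    below ``alpha``. Isolated nodes are kept.
    """
    ids = list(r.index)
    if list(p.index) != ids or list(p.columns) != ids or list(r.columns) != ids:
        raise ValueError("r and p matrices must share identical OTU index")
    missing = [o for o in ids if o not in partition.table.index]
    if missing:
        raise ValueError(f"OTUs missing from partition: {missing[:5]}")

    m = len(ids)
    iu = np.triu_indices(m, k=1)
    raw_p = p.to_numpy()[iu]
    adj_p = raw_p if pre_adjusted else fdr_adjust(raw_p)
    rv = r.to_numpy()[iu]

    g = nx.Graph()
    for o in ids:
        g.add_node(
            o,
            gsp_class=str(partition.table.at[o, "gsp_class"]),
        )
    keep = np.isfinite(rv) & np.isfinite(adj_p) & (np.abs(rv) > r_threshold) & (adj_p < alpha)
    for k in np.flatnonzero(keep):
        i, j = iu[0][k], iu[1][k]
        g.add_edge(
            ids[i],
            ids[j],
            r=float(rv[k]),
            weight=float(abs(rv[k])),
            sign="+" if rv[k] > 0 else "-",
            adjusted_p=float(adj_p[k]),
        )
    return g


def build_network_from_table(
    table: OtuTable,
    partition: GspPartition,
    otu_subset: list[str] | None = None,
    r_threshold: float = 0.65,
    alpha: float = 0.05,
) -> nx.Graph:
    """Convenience wrapper: correlations + FDR + thresholding in one call."""
    r, p = pairwise_spearman(table, otu_subset)
    return build_network(r, p, partition, r_threshold=r_threshold, alpha=alpha)


def link_decomposition(network: nx.Graph) -> pd.DataFrame:
    """Edge counts by endpoint-class pair and sign.

    Rows follow the class-pair order AT-AT ... RT-RT; columns: total,
    positive and negative link counts plus the positive percentage
    (two decimals, ties away from zero).
    """
    counts = {pair: {"total": 0, "positive": 0, "negative": 0} for pair in CLASS_PAIRS}
    for u, v, d in network.edges(data=True):
        cu = network.nodes[u].get("gsp_class")
        cv = network.nodes[v].get("gsp_class")
        if cu not in GSP_CLASSES or cv not in GSP_CLASSES:
            raise ValueError(f"node without GSP class label on edge ({u}, {v})")
        pair = "-".join(sorted((cu, cv), key=GSP_CLASSES.index))
        counts[pair]["total"] += 1
        counts[pair]["positive" if d["sign"] == "+" else "negative"] += 1
    rows = []
    for pair in CLASS_PAIRS:
        c = counts[pair]
        pct = (
            round_half_away(100.0 * c["positive"] / c["total"], 2)
            if c["total"]
            else np.nan
        )
        rows.append(
            {
                "pair": pair,
                "total_links": c["total"],
                "positive_links": c["positive"],
                "negative_links": c["negative"],
                "positive_pct": pct,
            }
        )
    return pd.DataFrame(rows).set_index("pair")


def positive_percentage(positive: int, total: int) -> float:
    """Positive-link share as a percent, two decimals, ties away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * positive / total, 2)


def topology_metrics(network: nx.Graph) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-node and graph-level topology summaries.

    Betweenness (unnormalized pair counts), closeness and clustering are
    computed on the unweighted skeleton; closeness uses within-component
    distances only. Eigenvector centrality uses the |r|-weighted adjacency
    of the largest connected component, scaled to max 1, and is 0 for
    nodes outside it. Graph stats: average weighted degree (sum of |r|
    over incident edges, averaged over nodes), density 2L/(N(N-1)) and the
    average unweighted clustering coefficient.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("topology metrics undefined for an empty graph")
    nodes = list(network.nodes)
    degree = dict(network.degree())
    wdegree = dict(network.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(network, normalized=False)
    closeness = nx.closeness_centrality(network, wf_improved=False)
    clustering = nx.clustering(network)

    eig = {n: 0.0 for n in nodes}
    components = sorted(
        nx.connected_components(network), key=lambda c: (len(c), sorted(c)[0]),
        reverse=True,
    )
    if components and len(components[0]) > 1:
        giant_nodes = sorted(components[0])
        adj = nx.to_numpy_array(network.subgraph(giant_nodes), nodelist=giant_nodes,
                                weight="weight")
        vals, vecs = np.linalg.eigh(adj)  # deterministic symmetric solver
        vec = np.abs(vecs[:, int(np.argmax(vals))])
        top = vec.max()
        for n, v in zip(giant_nodes, vec):
            eig[n] = float(v / top) if top > 0 else 0.0

    per_node = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "weighted_degree": pd.Series(wdegree),
            "betweenness": pd.Series(betweenness),
            "eigenvector": pd.Series(eig),
            "closeness": pd.Series(closeness),
            "clustering": pd.Series(clustering),
        }
    ).loc[nodes]
    n = network.number_of_nodes()
    graph_stats = {
        "nodes": float(n),
        "links": float(network.number_of_edges()),
        "average_weighted_degree": float(per_node["weighted_degree"].mean()),
        "graph_density": (
            2.0 * network.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        ),
        "average_clustering": float(per_node["clustering"].mean()),
    }
    return per_node, graph_stats


def compare_topology(
    metrics: pd.DataFrame, partition: GspPartition, metric_name: str
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of a node metric between classes."""
    if metric_name not in metrics.columns:
        raise ValueError(f"unknown metric {metric_name!r}")
    cls = partition.classes.reindex(metrics.index)
    rows = []
    for a, b in itertools.combinations(GSP_CLASSES, 2):
        xa = metrics.loc[cls == a, metric_name].to_numpy()
        xb = metrics.loc[cls == b, metric_name].to_numpy()
        if len(xa) < 3 or len(xb) < 3:
            rows.append({"pair": f"{a}-{b}", "W": np.nan, "p": np.nan, "defined": False})
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {"pair": f"{a}-{b}", "W": float(res.statistic), "p": float(res.pvalue), "defined": True}
        )
    return pd.DataFrame(rows).set_index("pair")


@dataclasses.dataclass
class HealthComparison:
    stats: pd.DataFrame  # graph-level stats, one row per health group
    decompositions: dict[str, pd.DataFrame]  # health -> link decomposition
    networks: dict[str, nx.Graph]


def compare_health_networks(
    table: OtuTable,
    partition: GspPartition,
    metadata: SampleMetadata,
    r_threshold: float = 0.65,
    alpha: float = 0.05,
) -> HealthComparison:
    """Build one network per health group with identical thresholds.

    The partition labels come from the pooled classification so the same
    OTU carries the same class in both groups.
    """
    stats_rows = {}
    decomps = {}
    nets = {}
    for health in ("H", "M"):
        samples = [s for s in table.sample_ids if s in metadata.samples_with_health(health)]
        if len(samples) < 4:
            raise ValueError(f"health group {health!r} has fewer than 4 samples")
        sub = table.subset_samples(samples)
        net = build_network_from_table(sub, partition, r_threshold=r_threshold, alpha=alpha)
        _, gstats = topology_metrics(net)
        stats_rows[health] = gstats
        decomps[health] = link_decomposition(net)
        nets[health] = net
    return HealthComparison(pd.DataFrame(stats_rows).T, decomps, nets)
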