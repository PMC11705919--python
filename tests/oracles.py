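"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit rank
computation, path enumeration, power iteration, normal equations) and
deliberately shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import t as t_dist


def midranks(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    order = np.argsort(x)
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> tuple[float, float]:
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * t_dist.sf(abs(t), n - 2))


def bh_oracle(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        idx = order[rank_i]
        running = min(running, p[idx] * m / (rank_i + 1))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# graph oracles (edges: dict-of-sets adjacency; weights: dict pair -> w)
# ---------------------------------------------------------------------------


def _bfs(adj: dict, source) -> tuple[dict, dict]:
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalized betweenness: for each unordered pair (s, t), the
    fraction of shortest s-t paths through v, summed over pairs."""
    nodes = list(adj)
    bc = {v: 0.0 for v in nodes}
    info = {s: _bfs(adj, s) for s in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sig_s = info[s]
        if t not in dist_s:
            continue
        dst = dist_s[t]
        dist_t, sig_t = info[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == dst:
                bc[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return bc


def closeness_oracle(adj: dict) -> dict:
    """(reachable - 1) / sum of within-component distances; isolated -> 0."""
    out = {}
    for u in adj:
        dist, _ = _bfs(adj, u)
        tot = sum(dist.values())
        out[u] = (len(dist) - 1) / tot if tot > 0 else 0.0
    return out


def clustering_oracle(adj: dict) -> dict:
    out = {}
    for u in adj:
        nbrs = list(adj[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        out[u] = 2.0 * links / (k * (k - 1))
    return out


def eigenvector_oracle(adj: dict, weights: dict) -> dict:
    """Power iteration on the weighted adjacency of the largest component,
    |.|, scaled to max 1; nodes outside the component get 0."""
    # find components
    seen = set()
    comps = []
    for u in adj:
        if u in seen:
            continue
        dist, _ = _bfs(adj, u)
        comps.append(sorted(dist))
        seen |= set(dist)
    comps.sort(key=lambda c: (len(c), c[0]), reverse=True)
    out = {u: 0.0 for u in adj}
    giant = comps[0]
    if len(giant) < 2:
        return out
    index = {u: i for i, u in enumerate(giant)}
    A = np.zeros((len(giant), len(giant)))
    for (a, b), w in weights.items():
        if a in index and b in index:
            A[index[a], index[b]] = w
            A[index[b], index[a]] = w
    # spectral shift keeps eigenvectors but speeds convergence and pins
    # the dominant eigenvalue to the largest algebraic one
    A = A + (1.0 + A.sum(axis=1).max()) * np.eye(len(giant))
    v = np.ones(len(giant))
    for _ in range(100000):
        nv = A @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            break
        nv /= norm
        if np.allclose(nv, v, rtol=0, atol=1e-13):
            v = nv
            break
        v = nv
    v = np.abs(v)
    v /= v.max()
    for u, i in index.items():
        out[u] = float(v[i])
    return out


def graph_to_adj(graph) -> tuple[dict, dict]:
    """networkx graph -> (adjacency dict, weight dict) for the oracles."""
    adj = {u: set(graph.neighbors(u)) for u in graph.nodes}
    weights = {
        (u, v): d.get("weight", 1.0) for u, v, d in graph.edges(data=True)
    }
    return adj, weights


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def indval_oracle(abundance, grouping) -> tuple[float, float]:
    a = np.asarray(abundance, dtype=float)
    g = np.asarray(grouping, dtype=bool)
    means = [a[~g].mean(), a[g].mean()]
    tot = sum(means)
    if tot == 0:
        return 0.0, 0.0
    freq = [(a[~g] > 0).mean(), (a[g] > 0).mean()]
    return (
        100.0 * (means[0] / tot) * freq[0],
        100.0 * (means[1] / tot) * freq[1],
    )


def ols_oracle(x, y) -> dict:
    """Simple linear regression by the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / float(((x - x.mean()) ** 2).sum()))
    t = beta[1] / se
    p = float(2 * t_dist.sf(abs(t), n - 2))
    return {"slope": float(beta[1]), "intercept": float(beta[0]), "r2": r2, "p": p}


def chao1_oracle(counts) -> float:
    c = np.asarray(counts)
    c = c[c > 0]
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def bray_curtis_oracle(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.abs(a - b).sum() / (a + b).sum())


def ranksum_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (tie-free data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = midranks(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mean_u = n1 * len(y) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            hits += 1
    return u_obs, hits / total
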