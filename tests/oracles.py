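"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and self-contained (BFS path counting,
exhaustive enumeration, hand-rolled neighbor search) so the package
implementations are checked against code that shares none of their machinery.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_path_counts(adj: dict, source):
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_betweenness(nodes, edges) -> dict:
    """Unnormalized betweenness: sum over unordered pairs j<k (both != i) of
    n_jk(i)/n_jk, from all-pairs BFS path counting."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_path_counts(adj, s)
    out = {n: 0.0 for n in nodes}
    for j, k in itertools.combinations(nodes, 2):
        if k not in dist[j]:
            continue
        d = dist[j][k]
        n_jk = sigma[j][k]
        for i in nodes:
            if i in (j, k) or i not in dist[j] or k not in dist[i]:
                continue
            if dist[j][i] + dist[i][k] == d:
                out[i] += sigma[j][i] * sigma[i][k] / n_jk
    return out


def brute_motifs(nodes, edges, genders):
    """Dyad and triad counts by exhaustive enumeration of pairs/triples."""
    eset = {frozenset(e) for e in edges}
    dyads = {"FF": 0, "MM": 0, "FM": 0}
    for e in eset:
        u, v = tuple(e)
        key = "FM" if genders[u] != genders[v] else ("FF" if genders[u] == "F" else "MM")
        dyads[key] += 1
    triads = {"FFF": 0, "MMM": 0, "mixed": 0}
    for a, b, c in itertools.combinations(nodes, 3):
        if {frozenset((a, b)), frozenset((b, c)), frozenset((a, c))} <= eset:
            nf = sum(genders[x] == "F" for x in (a, b, c))
            triads["FFF" if nf == 3 else ("MMM" if nf == 0 else "mixed")] += 1
    return dyads, triads


def exact_homophily_null(nodes, edges, n_female):
    """Exact permutation-null distribution of motif counts on a small graph:
    enumerate every distinct placement of the female labels."""
    results = []
    for female_set in itertools.combinations(nodes, n_female):
        genders = {n: ("F" if n in female_set else "M") for n in nodes}
        dyads, triads = brute_motifs(nodes, edges, genders)
        results.append({**{f"dyads_{k}": v for k, v in dyads.items()},
                        **{f"triads_{k}": v for k, v in triads.items()}})
    return results


def brute_knn_impute(table, k=7, standardize=True):
    """Exhaustive-search overlap-distance KNN imputation on a small table.

    All-pairs distances with explicit python loops, neighbors ranked by
    (distance, id), per-feature neighbor averaging with single-neighbor copy
    and cohort-mean fallback.  Returns a dict (id, feature) -> value for the
    cells that were filled.
    """
    ids = sorted(table.index.astype(str))
    cols = list(table.columns)
    x = {i: table.loc[i].to_numpy(dtype=float) for i in ids}
    col_vals = {c: table[c].dropna() for c in cols}
    if standardize:
        mu = {c: col_vals[c].mean() for c in cols}
        sd = {c: (col_vals[c].std(ddof=1) if col_vals[c].std(ddof=1) > 0 else 1.0)
              for c in cols}
        z = {
            i: np.array(
                [(x[i][j] - mu[c]) / sd[c] for j, c in enumerate(cols)]
            )
            for i in ids
        }
    else:
        z = x
    filled = {}
    for i in ids:
        miss = [j for j in range(len(cols)) if np.isnan(x[i][j])]
        if not miss:
            continue
        dists = []
        for other in ids:
            if other == i:
                continue
            both = [j for j in range(len(cols))
                    if not np.isnan(z[i][j]) and not np.isnan(z[other][j])]
            if both:
                d = float(np.mean([abs(z[i][j] - z[other][j]) for j in both]))
                dists.append((d, other))
        dists.sort()
        neighbors = [o for _, o in dists[:k]]
        for j in miss:
            vals = [x[o][j] for o in neighbors if not np.isnan(x[o][j])]
            if len(vals) == 0:
                filled[(i, cols[j])] = float(col_vals[cols[j]].mean())
            else:
                filled[(i, cols[j])] = float(np.mean(vals))
    return filled
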