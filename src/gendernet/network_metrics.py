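"""Structural and interaction indicators on the weekly channel networks.

Covers degree, same-gender neighbor fraction, unnormalized betweenness
centrality, base-2 interaction entropy over the ego network, gender-labeled
dyad/triad motif counts, active-dyad fraction, weekly text-message counts,
and call-duration statistics by ordered gender pair.

Betweenness is delegated to igraph's C core (exact Brandes algorithm on
unweighted shortest paths, summed over unordered pairs, no normalization);
the rest is computed directly on the networkx containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .cohort_data import Cohort, ChannelNetworkSeries

_METRIC_NAMES = ("degree", "same_gender_fraction", "betweenness", "interaction_entropy")


def degree(graph: nx.Graph, node) -> int:
    if node not in graph:
        raise KeyError(node)
    return graph.degree(node)


def same_gender_fraction(graph: nx.Graph, node) -> float:
    """Fraction of gender-labeled neighbors sharing the node's gender.

    Neighbors of unknown gender (alters outside the cohort) are excluded.
    NaN for isolates or nodes with no labeled neighbors.
    """
    if node not in graph:
        raise KeyError(node)
    own = graph.nodes[node].get("gender")
    if own is None:
        return float("nan")
    labeled = same = 0
    for nb in graph.neighbors(node):
        g = graph.nodes[nb].get("gender")
        if g is None:
            continue
        labeled += 1
        same += g == own
    if labeled == 0:
        return float("nan")
    return same / labeled


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, dict]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    return ig.Graph(n=len(nodes), edges=edges, directed=False), index


def betweenness_all(graph: nx.Graph) -> dict:
    """Unnormalized betweenness C_B(i) = sum_{j<k} n_jk(i)/n_jk for all nodes."""
    if graph.number_of_nodes() == 0:
        return {}
    h, index = _to_igraph(graph)
    vals = h.betweenness(directed=False)
    return {n: float(vals[i]) for n, i in index.items()}


def betweenness(graph: nx.Graph, node) -> float:
    """Unnormalized betweenness of one node (0 for leaves and isolates)."""
    if node not in graph:
        raise KeyError(node)
    return betweenness_all(graph)[node]


@dataclass
class EgoInteractionDistribution:
    """Share of a participant's interactions going to each contact."""

    participant: str
    channel: str
    p: dict  # contact -> share, positive, sums to 1

    def __post_init__(self) -> None:
        if self.p:
            if any(v <= 0 for v in self.p.values()):
                raise ValueError("shares must be positive")
            if abs(sum(self.p.values()) - 1.0) > 1e-9:
                raise ValueError("shares must sum to 1")


def interaction_entropy(dist: EgoInteractionDistribution | dict) -> float:
    """Base-2 Shannon entropy of the ego interaction distribution (bits).

    Bounded by log2(ego-network size); NaN for an empty ego network.
    Accepts raw (unnormalized) weights and normalizes them.
    """
    p = dist.p if isinstance(dist, EgoInteractionDistribution) else dist
    if not p:
        return float("nan")
    w = np.asarray(list(p.values()), dtype=float)
    w = w / w.sum()
    return float(-(w * np.log2(w)).sum())


@dataclass
class MotifCounts:
    channel: str | None
    dyads: dict = field(default_factory=lambda: {"FF": 0, "MM": 0, "FM": 0})
    triads: dict = field(default_factory=lambda: {"FFF": 0, "MMM": 0, "mixed": 0})


def enumerate_triangles(graph: nx.Graph) -> list[tuple]:
    """All closed triangles, each listed once (node-order canonicalized)."""
    order = {n: i for i, n in enumerate(graph.nodes)}
    adj = {n: {nb for nb in graph.neighbors(n) if order[nb] > order[n]} for n in graph.nodes}
    triangles = []
    for u in graph.nodes:
        for v in adj[u]:
            common = adj[u] & adj[v]
            triangles.extend((u, v, w) for w in common)
    return triangles


def count_motifs(graph: nx.Graph, channel: str | None = None) -> MotifCounts:
    """Dyad (edge) and triad (closed triangle) counts by gender composition.

    Every node incident to a counted motif must carry a gender label.
    """
    mc = MotifCounts(channel=channel)
    genders = {}
    for n, d in graph.nodes(data=True):
        g = d.get("gender")
        if g is None:
            raise ValueError(f"node {n!r} has no gender label")
        genders[n] = g
    for u, v in graph.edges:
        gu, gv = genders[u], genders[v]
        key = "FM" if gu != gv else ("FF" if gu == "F" else "MM")
        mc.dyads[key] += 1
    for u, v, w in enumerate_triangles(graph):
        nf = (genders[u] == "F") + (genders[v] == "F") + (genders[w] == "F")
        key = "FFF" if nf == 3 else ("MMM" if nf == 0 else "mixed")
        mc.triads[key] += 1
    return mc


def active_dyad_fraction(graph: nx.Graph, n_participants: int) -> float:
    """Ratio of existing to potential links among ``n_participants``."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    return graph.number_of_edges() / (n_participants * (n_participants - 1) / 2)


def call_duration_stats(events: pd.DataFrame, genders: dict) -> dict[str, float]:
    """Mean call duration per ordered (initiator, receiver) gender pair.

    Keys: 'MF', 'FM', 'FF', 'MM' (initiator gender first).  Same-gender pairs
    are direction-symmetric by construction and reported once.  Empty strata
    are NaN.  Events whose endpoints lack a gender label are skipped.
    """
    out = {k: float("nan") for k in ("MF", "FM", "FF", "MM")}
    if events is None or len(events) == 0:
        return out
    gi = events["initiator"].map(genders)
    gr = events["receiver"].map(genders)
    ok = gi.notna() & gr.notna() & events["duration_s"].notna()
    key = gi[ok] + gr[ok]
    means = events.loc[ok, "duration_s"].groupby(key).mean()
    for k in out:
        if k in means.index:
            out[k] = float(means[k])
    return out


def n_texts_weekly(series: ChannelNetworkSeries) -> dict[str, dict[int, float]]:
    """Per participant, weekly total text-message count (sum of incident edge
    weights in the text channel)."""
    out: dict[str, dict[int, float]] = {}
    for week, g in series.weekly_graphs.items():
        for u, v, d in g.edges(data=True):
            w = d.get("weight", 1)
            out.setdefault(u, {})[week] = out.setdefault(u, {}).get(week, 0) + w
            out.setdefault(v, {})[week] = out.setdefault(v, {}).get(week, 0) + w
    return out


def network_indicator_table(
    cohort: Cohort, networks: dict[str, ChannelNetworkSeries]
) -> pd.DataFrame:
    """Per-participant network indicators, weekly values averaged.

    For each channel: degree, same_gender_fraction, betweenness, and
    interaction_entropy, averaged over the weeks in which the participant has
    at least one contact in that channel; plus ``n_texts`` from the text
    channel.  A participant with no activity at all in a channel gets NaN in
    that channel's columns — this is how channel-level missing data surfaces
    in the feature table.
    """
    ids = cohort.ids
    cols: dict[str, pd.Series] = {}
    for channel, series in networks.items():
        acc = {
            n: {m: 0.0 for m in _METRIC_NAMES} | {"weeks": 0} for n in ids
        }
        sgf_weeks = {n: 0 for n in ids}
        for week, g in sorted(series.weekly_graphs.items()):
            if g.number_of_edges() == 0:
                continue
            bet = betweenness_all(g)
            for node in ids:
                if node not in g or g.degree(node) == 0:
                    continue
                a = acc[node]
                a["weeks"] += 1
                a["degree"] += g.degree(node)
                sgf = same_gender_fraction(g, node)
                if not np.isnan(sgf):
                    a["same_gender_fraction"] += sgf
                    sgf_weeks[node] += 1
                a["betweenness"] += bet[node]
                weights = {nb: g[node][nb].get("weight", 1) for nb in g.neighbors(node)}
                a["interaction_entropy"] += interaction_entropy(weights)
        for metric in _METRIC_NAMES:
            denom = sgf_weeks if metric == "same_gender_fraction" else None
            vals = []
            for n in ids:
                d = denom[n] if denom is not None else acc[n]["weeks"]
                vals.append(acc[n][metric] / d if d > 0 else float("nan"))
            cols[f"{channel}_{metric}"] = pd.Series(vals, index=ids)
    if "text" in networks:
        from .cohort_data import weekly_average

        weekly = n_texts_weekly(networks["text"])
        cols["n_texts"] = pd.Series(
            [weekly_average(weekly.get(n, {})) for n in ids], index=ids
        )
    out = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    return out
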