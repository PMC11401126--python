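"""Eleven topological hub measures and per-measure node rankings.

The measure set mirrors the classic Cytoscape hub-ranking panel: MCC, DMNC,
MNC, Degree, EPC, BottleNeck, EcCentricity, Closeness, Radiality, Betweenness
and Stress.  All measures treat the graph as unweighted and simple; the only
stochastic one is EPC (edge-percolated component), which is seeded and
reproducible.  Closeness is the harmonic variant so disconnected graphs score
sensibly (an unreachable node contributes 0 rather than breaking the sum).

Scores are oriented so that larger is better; ranks run 1..|V| with ties
broken by score descending, then gene symbol ascending.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MEASURES = (
    "mcc", "dmnc", "mnc", "degree", "epc", "bottleneck",
    "eccentricity", "closeness", "radiality", "betweenness", "stress",
)


@dataclass
class CentralityParams:
    """Tunables for the measure panel.

    dmnc_epsilon
        Exponent in DMNC = E'/V'^ε over the largest connected component of a
        node's open neighbourhood (default 1.7).
    epc_realizations, epc_retention
        Number of seeded edge percolations and the per-edge keep probability;
        ``retention="edge-weight"`` keeps each edge with its confidence score.
    bottleneck_fraction
        A node scores a point from root s when its BFS-tree subtree holds
        strictly more than this fraction of the tree (default 1/4).
    """

    dmnc_epsilon: float = 1.7
    epc_realizations: int = 100
    epc_retention: float | str = 0.5
    rng_seed: int = 0
    bottleneck_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.dmnc_epsilon <= 0:
            raise ValueError("dmnc_epsilon must be > 0")
        if self.epc_realizations < 1:
            raise ValueError("epc_realizations must be ≥ 1")
        if self.epc_retention != "edge-weight" and not 0 < float(self.epc_retention) <= 1:
            raise ValueError("epc_retention must be in (0, 1] or 'edge-weight'")


@dataclass
class RankTable:
    """Per-measure scores and 1-based ranks, genes × measures."""

    scores: pd.DataFrame
    ranks: pd.DataFrame
    params: CentralityParams = field(default_factory=CentralityParams)

    @property
    def measures(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    def to_tsv(self) -> str:
        rows = ["measure\trank\tgene\tscore"]
        for m in self.measures:
            order = self.ranks[m].sort_values().index
            rows += [f"{m}\t{int(self.ranks.at[g, m])}\t{g}\t{self.scores.at[g, m]:.6g}"
                     for g in order]
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# shortest-path machinery shared by betweenness / stress / bottleneck

def _bfs_counts(net: nx.Graph, source):
    """Distances and shortest-path counts from ``source`` (unweighted BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in net.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _all_pairs(net: nx.Graph):
    return {v: _bfs_counts(net, v) for v in net.nodes}


def _betweenness_and_stress(net: nx.Graph):
    nodes = sorted(net.nodes)
    ap = _all_pairs(net)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sig_s = ap[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            d_st, sig_st = dist_s[t], sig_s[t]
            dist_t, sig_t = ap[t]
            for v in nodes:
                if v is s or v is t or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    through = sig_s[v] * sig_t[v]
                    stress[v] += through
                    bet[v] += through / sig_st
    return bet, stress


# ---------------------------------------------------------------------------
# neighbourhood measures

def _neighborhood_component(net: nx.Graph, v):
    """Largest connected component of the subgraph induced on N(v)."""
    nbrs = list(net.neighbors(v))
    if not nbrs:
        return None
    sub = net.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
    return sub.subgraph(comp)


def _mnc(net, v):
    comp = _neighborhood_component(net, v)
    return 0 if comp is None else comp.number_of_nodes()


def _dmnc(net, v, epsilon):
    comp = _neighborhood_component(net, v)
    if comp is None or comp.number_of_nodes() < 2:
        return 0.0
    return comp.number_of_edges() / comp.number_of_nodes() ** epsilon


def _mcc_all(net: nx.Graph):
    """MCC(v) = Σ over maximal cliques C ∋ v of (|C|−1)!.

    For a node whose neighbourhood is edgeless every incident edge is its own
    maximal 2-clique, so the sum collapses to the degree — the documented
    special case falls out of the definition.
    """
    score = {v: 0.0 for v in net.nodes}
    for clique in nx.find_cliques(net):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            score[v] += contrib
    return score


# ---------------------------------------------------------------------------
# eccentricity / radiality / closeness

def _component_info(net: nx.Graph):
    info = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        ecc = nx.eccentricity(sub) if len(comp) > 1 else {next(iter(comp)): 0}
        diam = max(ecc.values()) if len(comp) > 1 else 0
        for v in comp:
            info[v] = (ecc[v], diam, len(comp))
    return info


# ---------------------------------------------------------------------------
# BottleNeck

def _bfs_tree_lex(net: nx.Graph, root):
    """Deterministic BFS shortest-path tree: parent = lexicographically
    smallest neighbour on the previous level."""
    dist, _ = _bfs_counts(net, root)
    parent = {}
    for v in dist:
        if v == root:
            continue
        parent[v] = min(w for w in net.neighbors(v) if dist[w] == dist[v] - 1)
    return dist, parent


def _bottleneck(net: nx.Graph, fraction: float):
    score = {v: 0.0 for v in net.nodes}
    for root in net.nodes:
        dist, parent = _bfs_tree_lex(net, root)
        tree_size = len(dist)
        if tree_size < 2:
            continue
        # subtree sizes by processing nodes deepest-first
        sub = {v: 1 for v in dist}
        for v in sorted(parent, key=lambda x: -dist[x]):
            sub[parent[v]] += sub[v]
        for v in dist:
            if v is not root and sub[v] > fraction * tree_size:
                score[v] += 1
    return score


# ---------------------------------------------------------------------------
# EPC

def _epc(net: nx.Graph, params: CentralityParams):
    nodes = sorted(net.nodes)
    edges = sorted((min(u, v), max(u, v)) for u, v in net.edges)
    rng = np.random.default_rng(params.rng_seed)
    if params.epc_retention == "edge-weight":
        keep_p = np.array([net[u][v].get("weight", 1.0) for u, v in edges])
    else:
        keep_p = np.full(len(edges), float(params.epc_retention))
    total = {v: 0.0 for v in nodes}
    for _ in range(params.epc_realizations):
        draws = rng.random(len(edges))
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        for (u, v), r, p in zip(edges, draws, keep_p):
            if r < p:
                sub.add_edge(u, v)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                total[v] += size
    return {v: total[v] / params.epc_realizations for v in nodes}


# ---------------------------------------------------------------------------
# public API

def compute_measure(net: nx.Graph, measure: str,
                    params: CentralityParams | None = None) -> dict[str, float]:
    """Score every node of ``net`` under one measure (larger = more central)."""
    params = params or CentralityParams()
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    nodes = sorted(net.nodes)
    if measure == "degree":
        return {v: float(net.degree(v)) for v in nodes}
    if measure == "mnc":
        return {v: float(_mnc(net, v)) for v in nodes}
    if measure == "dmnc":
        return {v: _dmnc(net, v, params.dmnc_epsilon) for v in nodes}
    if measure == "mcc":
        return _mcc_all(net)
    if measure == "closeness":
        dist = {v: _bfs_counts(net, v)[0] for v in nodes}
        return {v: sum(1.0 / d for u, d in dist[v].items() if u != v) for v in nodes}
    if measure in ("betweenness", "stress"):
        bet, stress = _betweenness_and_stress(net)
        return bet if measure == "betweenness" else stress
    if measure == "eccentricity":
        info = _component_info(net)
        return {v: (1.0 / info[v][0] if info[v][0] > 0 else 0.0) for v in nodes}
    if measure == "radiality":
        info = _component_info(net)
        n = net.number_of_nodes()
        out = {}
        for v in nodes:
            if n < 2 or info[v][2] < 2:
                out[v] = 0.0
                continue
            dist, _ = _bfs_counts(net, v)
            diam = info[v][1]
            out[v] = sum(diam + 1 - d for u, d in dist.items() if u != v) / (n - 1)
        return out
    if measure == "bottleneck":
        return _bottleneck(net, params.bottleneck_fraction)
    return _epc(net, params)


def rank_scores(scores: dict[str, float]) -> dict[str, int]:
    """1-based ranks: score descending, symbol ascending on ties."""
    order = sorted(scores, key=lambda g: (-scores[g], g))
    return {g: i + 1 for i, g in enumerate(order)}


def compute_all(net: nx.Graph, params: CentralityParams | None = None) -> RankTable:
    """All eleven measures with ranks; deterministic given ``params.rng_seed``."""
    params = params or CentralityParams()
    nodes = sorted(net.nodes)
    scores = pd.DataFrame(index=nodes, columns=list(MEASURES), dtype=float)
    ranks = pd.DataFrame(index=nodes, columns=list(MEASURES), dtype=int)
    for m in MEASURES:
        s = compute_measure(net, m, params)
        scores[m] = [s[v] for v in nodes]
        r = rank_scores(s)
        ranks[m] = [r[v] for v in nodes]
    return RankTable(scores=scores, ranks=ranks, params=params)


def top_k(table: RankTable, measure: str, k: int = 10) -> list[str]:
    """First ``k`` genes by rank under ``measure`` (all genes if |V| < k)."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if measure not in table.measures:
        raise ValueError(f"measure {measure!r} not in table")
    order = table.ranks[measure].sort_values().index
    return list(order[:k])
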