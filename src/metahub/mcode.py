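"""Density-based molecular-complex detection (MCODE-style).

Stage 1 weights every vertex by the core density of its open neighbourhood:
weight(v) = k · density(highest k-core of the subgraph induced on N(v)),
with vertices below the degree cutoff weighted 0.  Stage 2 grows complexes
outward from the highest-weight unvisited seed, admitting neighbours whose
weight is within the node-score cutoff (VWP) of the seed's.  Post-processing
optionally shaves singly-connected members (haircut) and annexes dense
halo neighbours (fluff).  Cluster score = density × size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class MCODEParams:
    """Plugin-style defaults: degree cutoff 2, node score cutoff (VWP) 0.2,
    k-core filter 2, haircut on, fluff off, max growth depth 100."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    k_core_filter: int = 2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff < 1:
            raise ValueError("node_score_cutoff (VWP) must be in [0, 1)")
        if self.degree_cutoff < 0 or self.k_core_filter < 0:
            raise ValueError("cutoffs must be ≥ 0")


@dataclass
class ClusterResult:
    members: set[str]
    seed: str
    density: float
    score: float
    member_weights: dict[str, float] = field(default_factory=dict)
    fluffed: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "score": self.score,
            "density": self.density,
            "members": sorted(self.members),
            "weights": {g: self.member_weights.get(g, 0.0) for g in sorted(self.members)},
            "fluffed": sorted(self.fluffed),
        }, indent=2)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(net: nx.Graph, params: MCODEParams | None = None) -> dict[str, float]:
    """k × density of the highest k-core of each open neighbourhood."""
    params = params or MCODEParams()
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph(net.neighbors(v))
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(nbhd)
        k = max(core_num.values())
        kcore = nbhd.subgraph([u for u, c in core_num.items() if c >= k])
        weights[v] = k * _density(kcore)
    return weights


def find_clusters(net: nx.Graph, params: MCODEParams | None = None) -> list[ClusterResult]:
    """Grow complexes from high-weight seeds; return them scored and sorted."""
    params = params or MCODEParams()
    weights = vertex_weights(net, params)
    visited: set[str] = set()
    clusters: list[ClusterResult] = []
    # seeds in weight-descending, symbol-ascending order for determinism
    for seed in sorted(weights, key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in net.neighbors(u):
                    if w in members or w in visited:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        visited |= members
        cluster = _postprocess(net, members, seed, weights, params)
        if cluster is not None:
            clusters.append(cluster)
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return clusters


def _postprocess(net: nx.Graph, members: set[str], seed: str,
                 weights: dict[str, float], params: MCODEParams) -> ClusterResult | None:
    sub = net.subgraph(members)
    if params.haircut:
        keep = set(members)
        while True:
            shaved = {v for v in keep if sum(1 for w in net.neighbors(v) if w in keep) <= 1 and len(keep) > 1}
            if not shaved:
                break
            keep -= shaved
        if seed not in keep:
            return None  # no dense core around the seed survives
        members = keep
        sub = net.subgraph(members)
    # discard clusters with no k-core at the filter level
    if members and params.k_core_filter > 0:
        core = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core or max(core.values()) < params.k_core_filter:
            return None
    fluffed: set[str] = set()
    if params.fluff:
        halo = {w for v in members for w in net.neighbors(v)} - members
        for w in sorted(halo):
            nbhd = net.subgraph(list(net.neighbors(w)) + [w])
            if _density(nbhd) > params.fluff_density:
                fluffed.add(w)
    final = set(members) | fluffed
    sub = net.subgraph(final)
    dens = _density(sub)
    return ClusterResult(
        members=final, seed=seed, density=dens, score=dens * len(final),
        member_weights={v: weights[v] for v in final}, fluffed=fluffed,
    )


def top_cluster_genes(cluster: ClusterResult, k: int = 10) -> list[str]:
    """Members by vertex weight descending, symbol ascending; first ``k``."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    order = sorted(cluster.members,
                   key=lambda g: (-cluster.member_weights.get(g, 0.0), g))
    return order[:k]
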