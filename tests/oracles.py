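"""Independent brute-force reference implementations used only by tests.

Everything here is written against first principles — subset enumeration for
maximal cliques, explicit BFS for distances and path counts, iterative
deletion for k-cores — and deliberately shares no code with the package's
centrality or MCODE modules.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def adjacency(net) -> dict:
    return {v: set(net.neighbors(v)) for v in net.nodes}


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def components(adj: dict) -> list[set]:
    seen, comps = set(), []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def induced(adj: dict, nodes) -> dict:
    nodes = set(nodes)
    return {v: adj[v] & nodes for v in nodes}


def edge_count(adj: dict) -> int:
    return sum(len(nbrs) for nbrs in adj.values()) // 2


def maximal_cliques(adj: dict) -> list[set]:
    nodes = sorted(adj)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(b in adj[a] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques if not any(c < d for d in cliques)]


def all_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """Every shortest s→t path, by BFS-layered backtracking."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, tail):
        if v == s:
            paths.append((s, *reversed(tail)))
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, tail + [v])

    back(t, [])
    return paths


# --- the eleven measures ---------------------------------------------------

def degree(net):
    adj = adjacency(net)
    return {v: float(len(adj[v])) for v in adj}


def mnc(net):
    adj = adjacency(net)
    out = {}
    for v in adj:
        sub = induced(adj, adj[v])
        out[v] = float(max((len(c) for c in components(sub)), default=0))
    return out


def dmnc(net, epsilon=1.7):
    adj = adjacency(net)
    out = {}
    for v in adj:
        sub = induced(adj, adj[v])
        comps = components(sub)
        if not comps:
            out[v] = 0.0
            continue
        comp = max(comps, key=lambda c: (len(c), sorted(c)))
        if len(comp) < 2:
            out[v] = 0.0
            continue
        csub = induced(sub, comp)
        out[v] = edge_count(csub) / len(comp) ** epsilon
    return out


def mcc(net):
    adj = adjacency(net)
    cliques = maximal_cliques(adj)
    return {v: float(sum(math.factorial(len(c) - 1) for c in cliques if v in c))
            for v in adj}


def closeness(net):
    adj = adjacency(net)
    return {v: sum(1.0 / d for u, d in bfs_distances(adj, v).items() if u != v)
            for v in adj}


def betweenness(net):
    adj = adjacency(net)
    nodes = sorted(adj)
    out = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                out[v] += sum(v in p for p in paths) / len(paths)
    return out


def stress(net):
    adj = adjacency(net)
    nodes = sorted(adj)
    out = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            for p in all_shortest_paths(adj, s, t):
                for v in p[1:-1]:
                    out[v] += 1
    return out


def eccentricity(net):
    adj = adjacency(net)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        ecc = max(dist.values())
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def radiality(net):
    adj = adjacency(net)
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        if len(dist) < 2 or n < 2:
            out[v] = 0.0
            continue
        diam = max(max(bfs_distances(adj, u).values()) for u in dist)
        out[v] = sum(diam + 1 - d for u, d in dist.items() if u != v) / (n - 1)
    return out


def bottleneck(net, fraction=0.25):
    adj = adjacency(net)
    out = {v: 0.0 for v in adj}
    for root in adj:
        dist = bfs_distances(adj, root)
        if len(dist) < 2:
            continue
        parent = {v: min(u for u in adj[v] if dist[u] == dist[v] - 1)
                  for v in dist if v != root}
        for v in dist:
            if v == root:
                continue
            subtree = sum(1 for w in dist if _has_ancestor(w, v, parent))
            if subtree > fraction * len(dist):
                out[v] += 1
    return out


def _has_ancestor(w, v, parent):
    while True:
        if w == v:
            return True
        if w not in parent:
            return False
        w = parent[w]


def mcode_vertex_weights(net, degree_cutoff=2):
    """k-core by iterative deletion over each open neighbourhood."""
    adj = adjacency(net)
    out = {}
    for v in adj:
        if len(adj[v]) < degree_cutoff:
            out[v] = 0.0
            continue
        sub = induced(adj, adj[v])
        best_k = 0
        best = None
        k = 1
        while True:
            cur = {u: set(n) for u, n in sub.items()}
            changed = True
            while changed:
                changed = False
                for u in list(cur):
                    if len(cur[u]) < k:
                        for w in cur[u]:
                            cur[w].discard(u)
                        del cur[u]
                        changed = True
            if not cur:
                break
            best_k, best = k, cur
            k += 1
        if best is None or edge_count(best) == 0:
            out[v] = 0.0
        else:
            n = len(best)
            dens = 2 * edge_count(best) / (n * (n - 1)) if n > 1 else 0.0
            out[v] = best_k * dens
    return out


DETERMINISTIC = {
    "degree": degree, "mnc": mnc, "dmnc": dmnc, "mcc": mcc,
    "closeness": closeness, "betweenness": betweenness, "stress": stress,
    "eccentricity": eccentricity, "radiality": radiality,
    "bottleneck": bottleneck,
}
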