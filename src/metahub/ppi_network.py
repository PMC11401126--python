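"""Weighted undirected protein–protein interaction networks.

Edge lists follow the STRING export convention: three tab-separated columns
(node1, node2, combined score).  Scores may be printed on the 0–1 scale or as
0–1000 integers; the latter are divided by 1000 at load.  A confidence
threshold (``min_score``, default 0.4) is applied while reading, duplicate
pairs collapse to the maximum score, and self-loops are dropped with a warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx

from .genesets import normalize_symbol

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.4


def read_network(path: str | Path, min_score: float = DEFAULT_MIN_SCORE,
                 keep_isolated: bool = False,
                 query_nodes: set[str] | None = None) -> nx.Graph:
    """Load a TSV edge list into a simple undirected ``networkx.Graph``.

    Graph attributes record ``min_score``.  With ``keep_isolated`` and
    ``query_nodes``, query genes missing from every retained edge are added as
    isolated nodes (STRING keeps queried proteins visible even when all their
    interactions fall below the cutoff).
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    path = Path(path)
    g = nx.Graph(min_score=min_score)
    integer_scale = None  # decided from the first score > 1
    rows: list[tuple[str, str, float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#node\t"):
                g.add_node(normalize_symbol(line.split("\t")[1]))
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected ≥3 columns, got {len(parts)}")
            if lineno == 1 and _looks_like_header(parts):
                continue
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score {parts[2]!r}") from exc
            u, v = normalize_symbol(parts[0]), normalize_symbol(parts[1])
            if score > 1.0:
                if integer_scale is False:
                    raise ValueError(f"{path}:{lineno}: mixed 0–1 and 0–1000 score scales")
                integer_scale = True
            elif integer_scale is None and "." in parts[2]:
                integer_scale = False
            rows.append((u, v, score))
    if integer_scale:
        rows = [(u, v, s / 1000.0) for u, v, s in rows]
    for u, v, score in rows:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"{path}: score {score} outside [0, 1]")
        if u == v:
            log.warning("%s: dropping self-loop on %s", path, u)
            continue
        if score < min_score:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], score)
        else:
            g.add_edge(u, v, weight=score)
    if keep_isolated and query_nodes:
        for q in query_nodes:
            g.add_node(normalize_symbol(q))
    return g


def _looks_like_header(parts: list[str]) -> bool:
    try:
        float(parts[2])
        return False
    except ValueError:
        return True


def network_summary(net: nx.Graph) -> dict:
    """Node count, edge count, average degree 2E/V and density 2E/(V(V−1))."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    avg_degree = 2.0 * e / n if n else 0.0
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    return {
        "nodes": n,
        "edges": e,
        "average_degree": avg_degree,
        "density": density,
    }


def summary_text(net: nx.Graph) -> str:
    s = network_summary(net)
    return (f"{s['nodes']} nodes, {s['edges']} edges, "
            f"average node degree {s['average_degree']:.1f}, "
            f"density {s['density']:.3f}")


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Serialize as node1/node2/weight TSV (sorted, reload-stable)."""
    lines = ["node1\tnode2\tcombined_score"]
    for u, v, d in sorted(net.edges(data=True), key=lambda t: (min(t[0], t[1]), max(t[0], t[1]))):
        a, b = sorted((u, v))
        lines.append(f"{a}\t{b}\t{d['weight']:.3f}")
    for n in sorted(net.nodes):
        if net.degree(n) == 0:
            lines.append(f"#node\t{n}")  # isolated query nodes survive a round trip
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def summary_json(net: nx.Graph) -> str:
    return json.dumps(network_summary(net), indent=2)
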