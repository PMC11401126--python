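"""Directed, effect-labelled disease signalling maps and their superimposition.

Each disease carries a map of (source, target, effect) interactions curated
per disease.  Superimposing the maps keeps the (source, target) pairs present
in at least ``min_support`` diseases — with full support this is the shared
signalling core common to every disease.  On the superimposed map the
"hub of hubs" is the gene touching the most other genes through directed
reachability (ancestors plus descendants), and its core equation is the
one-step picture: direct upstream inputs ⇒ hub ⇒ direct downstream outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .genesets import normalize_symbol

log = logging.getLogger(__name__)

EFFECTS = ("activate", "inhibit", "regulate")


@dataclass
class DiseaseMap:
    disease: str
    edges: dict[tuple[str, str], str]  # (source, target) → effect
    isolated: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        out = {n for pair in self.edges for n in pair}
        return out | self.isolated


@dataclass
class SuperimposedMap:
    edges: dict[tuple[str, str], str]
    support: dict[tuple[str, str], int]
    nodes: set[str]

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), eff in self.edges.items():
            g.add_edge(u, v, effect=eff, support=self.support[(u, v)])
        return g

    def to_sif(self) -> str:
        rows = [f"{u}\t{eff}\t{v}" for (u, v), eff in sorted(self.edges.items())]
        return "\n".join(rows) + ("\n" if rows else "")


@dataclass
class CoreEquation:
    hub: str
    inputs: set[str]
    outputs: set[str]

    @property
    def node_count(self) -> int:
        return len(self.inputs) + 1 + len(self.outputs)

    def __str__(self) -> str:
        lhs = ",".join(sorted(self.inputs)) or "∅"
        rhs = "+".join(sorted(self.outputs)) or "∅"
        return f"{lhs}=>{self.hub}=>{rhs}"


def read_map(path: str | Path, disease: str | None = None) -> DiseaseMap:
    """TSV columns: source, target, effect, disease.  ``#node<TAB>SYM`` rows
    declare isolated nodes.  Duplicate (source, target) rows collapse."""
    path = Path(path)
    edges: dict[tuple[str, str], str] = {}
    isolated: set[str] = set()
    label = disease
    lines = path.read_text(encoding="utf-8").splitlines()
    for lineno, line in enumerate(lines, 1):
        if line.startswith("#node\t"):
            isolated.add(normalize_symbol(line.split("\t")[1]))
            continue
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0].lower() == "source":
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: need source, target, effect[, disease]")
        u, v = normalize_symbol(parts[0]), normalize_symbol(parts[1])
        eff = parts[2].strip().lower()
        if eff not in EFFECTS:
            raise ValueError(f"{path}:{lineno}: unknown effect {eff!r} "
                             f"(expected one of {EFFECTS})")
        if u == v:
            raise ValueError(f"{path}:{lineno}: self-edge on {u}")
        if label is None and len(parts) > 3:
            label = parts[3].strip()
        if (u, v) in edges and edges[(u, v)] != eff:
            edges[(u, v)] = "regulate"  # conflicting duplicates downgrade
        else:
            edges[(u, v)] = eff
    if not edges and not isolated:
        log.warning("%s: empty disease map", path)
    return DiseaseMap(disease=label or path.stem, edges=edges, isolated=isolated)


def write_map(dmap: DiseaseMap, path: str | Path) -> None:
    rows = ["source\ttarget\teffect\tdisease"]
    rows += [f"{u}\t{v}\t{eff}\t{dmap.disease}"
             for (u, v), eff in sorted(dmap.edges.items())]
    rows += [f"#node\t{n}" for n in sorted(dmap.isolated - {x for p in dmap.edges for x in p})]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def superimpose(maps: list[DiseaseMap], min_support: int | None = None) -> SuperimposedMap:
    """Retain (source, target) pairs present in ≥ min_support diseases
    (default: all of them).  Conflicting effects collapse to 'regulate'."""
    if len(maps) < 2:
        raise ValueError("need at least 2 disease maps to superimpose")
    if min_support is None:
        min_support = len(maps)
    if min_support > len(maps):
        raise ValueError(f"min_support {min_support} exceeds number of maps {len(maps)}")
    support: dict[tuple[str, str], int] = {}
    effects: dict[tuple[str, str], set[str]] = {}
    for m in maps:
        for pair, eff in m.edges.items():
            support[pair] = support.get(pair, 0) + 1
            effects.setdefault(pair, set()).add(eff)
    kept: dict[tuple[str, str], str] = {}
    for pair, cnt in support.items():
        if cnt < min_support:
            continue
        effs = effects[pair]
        if len(effs) > 1:
            log.warning("edge %s→%s has conflicting effects %s; collapsing to 'regulate'",
                        pair[0], pair[1], sorted(effs))
            kept[pair] = "regulate"
        else:
            kept[pair] = next(iter(effs))
    shared_isolated = set.intersection(*(m.nodes for m in maps)) if maps else set()
    nodes = {n for pair in kept for n in pair} | shared_isolated
    return SuperimposedMap(edges=kept, support={p: support[p] for p in kept}, nodes=nodes)


def hub_of_hubs(smap: SuperimposedMap) -> tuple[str, int]:
    """Gene maximizing |ancestors ∪ descendants| by directed reachability."""
    if not smap.edges:
        raise ValueError("superimposed map has no edges")
    g = smap.digraph()
    best: tuple[str, int] | None = None
    for v in sorted(g.nodes):
        conn = len(nx.ancestors(g, v) | nx.descendants(g, v))
        if best is None or conn > best[1]:
            best = (v, conn)
    return best


def core_equation(smap: SuperimposedMap, hub: str) -> CoreEquation:
    """Direct in-neighbours ⇒ hub ⇒ direct out-neighbours."""
    hub = normalize_symbol(hub)
    if hub not in smap.nodes:
        raise ValueError(f"hub {hub!r} absent from superimposed map")
    g = smap.digraph()
    return CoreEquation(hub=hub,
                        inputs=set(g.predecessors(hub)),
                        outputs=set(g.successors(hub)))


def participating_genes(smap: SuperimposedMap, candidates: set[str]) -> set[str]:
    """Candidates incident to at least one superimposed interaction."""
    if not candidates:
        raise ValueError("empty candidate set")
    incident = {n for pair in smap.edges for n in pair}
    return {normalize_symbol(c) for c in candidates} & incident
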