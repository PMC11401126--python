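"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure — a common core across disease gene
lists, a dense module (and optionally a universal hub) inside a sparse
interaction background, enriched terms in a gene-set collection, concordant
expression directions, a shared directed core across disease maps — and
returns the planted ground truth alongside the emitted files, so every
pipeline stage can be tested for exact recovery without any download.

Defaults emulate the study conditions: three disease lists of 376/567/360
mined genes with a 31-gene common core, interaction confidences uniform on
[0.4, 1.0] so the default 0.4 threshold is non-trivial but lossless, and a
planted clique module against a sparse random background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genesets import GeneListCollection


@dataclass
class SyntheticSpec:
    rng_seed: int = 0
    universe_size: int = 500
    list_sizes: dict[str, int] = field(default_factory=lambda: {
        "T2DM": 376, "OA": 567, "TNBC": 360})
    core_size: int = 31
    duplicate_rate: float = 0.1          # occurrence duplicates injected per list
    module_size: int = 8                 # planted dense module m
    p_in: float = 1.0
    p_out: float = 0.05
    background_size: int = 40            # total network nodes n (module included)
    planted_hub: bool = False            # wire one node to every other node
    n_terms: int = 20
    n_planted_terms: int = 3
    planted_term_fraction: float = 0.8   # f: fraction of the query inside a planted term
    term_size: int = 40
    diseases: tuple[str, ...] = ("T2DM", "OA", "TNBC")
    map_core_edges: int = 6
    map_noise_edges: int = 4

    def __post_init__(self) -> None:
        if self.core_size > min(self.list_sizes.values(), default=0):
            raise ValueError("core_size exceeds the smallest list size")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 ≤ p_out < p_in ≤ 1")
        if not 0 < self.planted_term_fraction <= 1:
            raise ValueError("planted_term_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    core_genes: list[str] = field(default_factory=list)
    module_members: list[str] = field(default_factory=list)
    hub: str | None = None
    node_count: int = 0
    edge_count: int = 0
    planted_terms: list[str] = field(default_factory=list)
    concordant_genes: list[str] = field(default_factory=list)
    map_core_edges: list[list[str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _gene_universe(size: int) -> list[str]:
    return [f"G{i:04d}" for i in range(size)]


def gen_gene_lists(spec: SyntheticSpec, out_dir: str | Path | None = None
                   ) -> tuple[GeneListCollection, GroundTruth]:
    """Disease lists sharing a planted core, disjoint otherwise-specific tails.

    Each list = core ∪ a disease-specific draw without replacement from the
    part of the universe reserved for that disease (so with core_size 0 the
    triple intersection is empty by construction, not by chance).  Occurrence
    duplicates are appended at ``duplicate_rate`` for redundancy testing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    universe = _gene_universe(spec.universe_size)
    if spec.core_size > spec.universe_size:
        raise ValueError("core_size exceeds universe")
    perm = rng.permutation(spec.universe_size)
    core = [universe[i] for i in perm[:spec.core_size]]
    rest = [universe[i] for i in perm[spec.core_size:]]
    # carve disjoint disease-specific pools so no accidental full overlap
    labels = list(spec.list_sizes)
    pool_size = len(rest) // max(len(labels), 1)
    lists: dict[str, list[str]] = {}
    for idx, label in enumerate(labels):
        want = min(spec.list_sizes[label], spec.core_size + pool_size)
        pool = rest[idx * pool_size:(idx + 1) * pool_size]
        extra = min(want - spec.core_size, len(pool))
        specific = [pool[i] for i in rng.permutation(len(pool))[:extra]]
        seq = core + specific
        n_dup = int(round(spec.duplicate_rate * len(seq)))
        dups = [seq[i] for i in rng.integers(0, len(seq), size=n_dup)] if n_dup else []
        lists[label] = seq + dups
    coll = GeneListCollection(lists, name="synthetic", universe=set(universe))
    truth = GroundTruth(core_genes=sorted(core))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, seq in coll.lists.items():
            (out_dir / f"genes_{label}.txt").write_text("\n".join(seq) + "\n")
    return coll, truth


def gen_planted_network(spec: SyntheticSpec, out_path: str | Path | None = None,
                        node_names: list[str] | None = None
                        ) -> tuple[list[tuple[str, str, float]], GroundTruth]:
    """Edge list with a dense planted module inside a sparse background.

    Module pairs appear with probability ``p_in``, all other pairs with
    ``p_out``; confidences are uniform on [0.4, 1.0].  With ``planted_hub``
    one background node is wired to every other node, giving it strict maxima
    on degree-driven measures.  ``node_names`` lets callers build the network
    over real gene symbols (e.g. a planted core) instead of synthetic ids.
    """
    if spec.module_size < 3 or spec.background_size < spec.module_size:
        raise ValueError("need module_size ≥ 3 and background_size ≥ module_size")
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.background_size
    if node_names is not None:
        if len(node_names) < n:
            raise ValueError("node_names shorter than background_size")
        names = list(node_names[:n])
    else:
        names = [f"N{i:03d}" for i in range(n)]
    module = set(names[:spec.module_size])
    hub = None
    if spec.planted_hub:
        names[-1] = "HUB"  # distinguished symbol for the designated hub
        hub = names[-1]
    edges: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = names[i], names[j]
            if hub is not None and hub in (u, v):
                p = 1.0
            elif u in module and v in module:
                p = spec.p_in
            else:
                p = spec.p_out
            if rng.random() < p:
                edges.append((u, v, float(0.4 + 0.6 * rng.random())))
    truth = GroundTruth(module_members=sorted(module), hub=hub,
                        node_count=n, edge_count=len(edges))
    if out_path is not None:
        lines = ["node1\tnode2\tcombined_score"]
        lines += [f"{u}\t{v}\t{s:.6f}" for u, v, s in edges]
        Path(out_path).write_text("\n".join(lines) + "\n")
    return edges, truth


def gen_gene_set_collection(spec: SyntheticSpec, query: set[str],
                            out_path: str | Path | None = None
                            ) -> tuple[dict[str, list[str]], GroundTruth]:
    """GMT terms: planted ones hold ⌈f·|query|⌉ query genes plus background
    filler; decoys are uniform draws from the universe."""
    rng = np.random.default_rng(spec.rng_seed)
    universe = _gene_universe(spec.universe_size)
    query_sorted = sorted(query)
    n_hit = int(np.ceil(spec.planted_term_fraction * len(query_sorted)))
    if n_hit > spec.term_size:
        raise ValueError("planted query share exceeds term capacity")
    background = [g for g in universe if g not in query]
    terms: dict[str, list[str]] = {}
    planted = []
    for t in range(spec.n_planted_terms):
        hits = [query_sorted[i] for i in rng.permutation(len(query_sorted))[:n_hit]]
        fill = [background[i] for i in
                rng.permutation(len(background))[:spec.term_size - n_hit]]
        name = f"PLANTED_{t:02d}"
        terms[name] = sorted(hits + fill)
        planted.append(name)
    for t in range(spec.n_terms - spec.n_planted_terms):
        members = [universe[i] for i in rng.permutation(len(universe))[:spec.term_size]]
        terms[f"DECOY_{t:02d}"] = sorted(members)
    truth = GroundTruth(planted_terms=planted)
    if out_path is not None:
        lines = [f"{name}\tsynthetic\t" + "\t".join(members)
                 for name, members in terms.items()]
        Path(out_path).write_text("\n".join(lines) + "\n")
    return terms, truth


def gen_expression_annotations(spec: SyntheticSpec, genes: list[str],
                               out_path: str | Path | None = None,
                               source: str = "database"
                               ) -> tuple[dict[tuple[str, str], str], GroundTruth]:
    """Direction table over ``genes`` × diseases: a designated leading subset
    is concordant (same known direction everywhere), the rest mixed/unknown."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = list(genes)
    n_conc = max(1, len(genes) // 4) if genes else 0
    concordant = genes[:n_conc]
    direction: dict[tuple[str, str], str] = {}
    for g in concordant:
        d = "up" if rng.random() < 0.5 else "down"
        for dis in spec.diseases:
            direction[(g, dis)] = d
    for g in genes[n_conc:]:
        dirs = ["up", "down", "unknown"]
        # force discordance: at least two distinct values across diseases
        picks = [dirs[int(rng.integers(0, 3))] for _ in spec.diseases]
        if len(set(picks)) == 1 and len(spec.diseases) > 1:
            picks[0] = "unknown" if picks[0] != "unknown" else "up"
        for dis, d in zip(spec.diseases, picks):
            direction[(g, dis)] = d
    truth = GroundTruth(concordant_genes=sorted(concordant))
    if out_path is not None:
        lines = ["gene\tdisease\tdirection\tsource"]
        lines += [f"{g}\t{dis}\t{d}\t{source}"
                  for (g, dis), d in sorted(direction.items())]
        Path(out_path).write_text("\n".join(lines) + "\n")
    return direction, truth


def gen_disease_maps(spec: SyntheticSpec, out_dir: str | Path | None = None
                     ) -> tuple[dict[str, dict[tuple[str, str], str]], GroundTruth]:
    """Per-disease directed maps sharing a planted core; noise edges never
    reuse a core (source, target) pair and never appear in every disease."""
    rng = np.random.default_rng(spec.rng_seed)
    pool = [f"M{i:03d}" for i in range(30)]
    effects = ["activate", "inhibit", "regulate"]

    def draw_edge(used: set[tuple[str, str]]) -> tuple[str, str]:
        while True:
            i, j = rng.integers(0, len(pool), size=2)
            if i != j and (pool[i], pool[j]) not in used:
                return pool[i], pool[j]

    core: dict[tuple[str, str], str] = {}
    while len(core) < spec.map_core_edges:
        pair = draw_edge(set(core))
        core[pair] = effects[int(rng.integers(0, 3))]
    maps: dict[str, dict[tuple[str, str], str]] = {}
    noise_used: set[tuple[str, str]] = set(core)
    for dis in spec.diseases:
        edges = dict(core)
        for _ in range(spec.map_noise_edges):
            pair = draw_edge(noise_used)
            noise_used.add(pair)  # noise pairs globally unique → never full support
            edges[pair] = effects[int(rng.integers(0, 3))]
        maps[dis] = edges
    truth = GroundTruth(map_core_edges=sorted([u, v] for u, v in core))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for dis, edges in maps.items():
            lines = ["source\ttarget\teffect\tdisease"]
            lines += [f"{u}\t{v}\t{eff}\t{dis}" for (u, v), eff in sorted(edges.items())]
            (out_dir / f"map_{dis}.tsv").write_text("\n".join(lines) + "\n")
    return maps, truth


def generate_all(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write every pipeline input plus ``ground_truth.json``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coll, gt_lists = gen_gene_lists(spec, out_dir)
    from .genesets import intersect_all
    core = intersect_all(coll).core
    # the interaction network lives over the planted core (plus filler genes),
    # as in a real run where the common hub genes seed the PPI query
    universe_sorted = sorted(coll.universe or [])
    names = sorted(core) + [g for g in universe_sorted if g not in core]
    net_path = out_dir / "network.tsv"
    _, gt_net = gen_planted_network(spec, net_path, node_names=names)
    gmt_path = out_dir / "collection.gmt"
    _, gt_terms = gen_gene_set_collection(spec, core, gmt_path)
    genes = sorted(core)
    expr_db = out_dir / "expression_database.tsv"
    expr_lit = out_dir / "expression_literature.tsv"
    _, gt_expr = gen_expression_annotations(spec, genes, expr_db, source="database")
    gen_expression_annotations(spec, genes, expr_lit, source="literature")
    maps_dir = out_dir / "maps"
    _, gt_maps = gen_disease_maps(spec, maps_dir)
    truth = GroundTruth(
        core_genes=gt_lists.core_genes,
        module_members=gt_net.module_members, hub=gt_net.hub,
        node_count=gt_net.node_count, edge_count=gt_net.edge_count,
        planted_terms=gt_terms.planted_terms,
        concordant_genes=gt_expr.concordant_genes,
        map_core_edges=gt_maps.map_core_edges,
    )
    (out_dir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return {
        "gene_lists": [out_dir / f"genes_{lab}.txt" for lab in coll.labels],
        "network": net_path,
        "gmt": gmt_path,
        "expression_database": expr_db,
        "expression_literature": expr_lit,
        "maps": sorted(maps_dir.glob("map_*.tsv")),
        "ground_truth": out_dir / "ground_truth.json",
    }
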