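"""End-to-end orchestration: gene lists → network analysis → consensus →
enrichment → prioritization → map superimposition, from one config.

Every stage writes its TSV/JSON artifacts into the output directory and the
run closes with a manifest recording parameters, input digests and stage
status.  Stages whose inputs are absent are skipped explicitly and the
downstream stages degrade (e.g. no disease maps → no core equation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (centrality, consensus, disease_map, enrichment, genesets,
               mcode, ppi_network, prioritize)

log = logging.getLogger(__name__)

STAGES = ("venn", "network_summary", "ranking", "mcode", "consensus",
          "enrichment", "prioritization", "disease_maps")


@dataclass
class PipelineConfig:
    gene_lists: dict[str, str] = field(default_factory=dict)  # label → path
    gene_list_dialect: str = "one-per-line"
    network: str | None = None
    min_score: float = 0.4
    gmt: str | None = None
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    consensus_k: int = 10
    expression_database: str | None = None
    expression_literature: str | None = None
    disease_maps: list[str] = field(default_factory=list)
    min_support: int | None = None
    rng_seed: int = 0
    centrality: centrality.CentralityParams = field(default_factory=centrality.CentralityParams)
    mcode: mcode.MCODEParams = field(default_factory=mcode.MCODEParams)
    out_dir: str = "metahub_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cent = centrality.CentralityParams(**raw.pop("centrality", {}))
        mc = mcode.MCODEParams(**raw.pop("mcode", {}))
        cfg = cls(**raw, centrality=cent, mcode=mc)
        cfg.centrality.rng_seed = cfg.rng_seed
        return cfg

    def validate(self) -> None:
        for label, p in self.gene_lists.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"gene list {label!r}: {p}")
        for p in [self.network, self.gmt, self.expression_database,
                  self.expression_literature, *self.disease_maps]:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "min_score": config.min_score, "alpha": config.alpha,
            "kappa_threshold": config.kappa_threshold,
            "consensus_k": config.consensus_k,
            "min_support": config.min_support, "rng_seed": config.rng_seed,
            "centrality": vars(config.centrality),
            "mcode": vars(config.mcode),
        },
        "inputs": {},
        "stages": {},
    }
    for label, p in config.gene_lists.items():
        manifest["inputs"][f"gene_list:{label}"] = _digest(p)
    for key in ("network", "gmt", "expression_database", "expression_literature"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = _digest(p)
    for p in config.disease_maps:
        manifest["inputs"][f"map:{Path(p).stem}"] = _digest(p)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
                manifest["stages"][name] = {
                    "status": "completed",
                    "seconds": round(time.perf_counter() - t0, 3)}
                log.info("stage %s completed in %.2fs", name,
                         time.perf_counter() - t0)
                return result
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(manifest, out)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    def skip(name, reason):
        manifest["stages"][name] = {"status": "skipped", "reason": reason}
        log.info("stage %s skipped: %s", name, reason)

    # --- Venn -------------------------------------------------------------
    core: set[str] = set()
    coll = None
    if len(config.gene_lists) >= 2:
        def _venn():
            nonlocal coll
            coll = genesets.combine(
                genesets.read_gene_lists(p, config.gene_list_dialect, label=lab)
                for lab, p in config.gene_lists.items())
            venn = genesets.intersect_all(coll)
            (out / "venn.json").write_text(venn.to_json() + "\n")
            genesets.write_region_tsv(venn, out / "venn_regions.tsv")
            return venn
        core = set(stage("venn")(_venn).core)
    else:
        skip("venn", "fewer than 2 gene lists configured")

    # --- network, ranking, MCODE, consensus -------------------------------
    merged = None
    hub_rank: dict[str, int] = {}
    cluster_rank: dict[str, int] = {}
    net = None
    if config.network:
        def _summary():
            nonlocal net
            net = ppi_network.read_network(config.network, config.min_score,
                                           keep_isolated=bool(core), query_nodes=core or None)
            (out / "network_summary.json").write_text(ppi_network.summary_json(net) + "\n")
            return net
        stage("network_summary")(_summary)

        def _ranking():
            table = centrality.compute_all(net, config.centrality)
            (out / "rank_table.tsv").write_text(table.to_tsv())
            return table
        table = stage("ranking")(_ranking)

        def _mcode():
            clusters = mcode.find_clusters(net, config.mcode)
            (out / "clusters.json").write_text(json.dumps(
                [json.loads(c.to_json()) for c in clusters], indent=2) + "\n")
            return clusters
        clusters = stage("mcode")(_mcode)

        def _consensus():
            cons = consensus.consensus_rank(table, config.consensus_k)
            (out / "consensus.tsv").write_text(cons.to_tsv())
            if clusters:
                cl_top = mcode.top_cluster_genes(clusters[0], config.consensus_k)
            else:
                cl_top = cons.meta_hubs  # degenerate: no module found
            merged_ = consensus.merge_hub_cluster(cons.meta_hubs, cl_top)
            (out / "merged.json").write_text(json.dumps({
                "union": merged_.union_list, "overlap": sorted(merged_.overlap),
                "counts": merged_.counts}, indent=2) + "\n")
            return cons, cl_top, merged_
        cons, cl_top, merged = stage("consensus")(_consensus)
        hub_rank = {g: i + 1 for i, g in enumerate(cons.meta_hubs)}
        cluster_rank = {g: i + 1 for i, g in enumerate(cl_top)}
    else:
        for name in ("network_summary", "ranking", "mcode", "consensus"):
            skip(name, "no network configured")

    # --- enrichment -------------------------------------------------------
    enr_freq: dict[str, int] = {}
    query = set(merged.union_list) if merged else core
    if config.gmt and query:
        def _enrich():
            coll_gs = enrichment.read_gmt(config.gmt)
            recs = enrichment.fisher_enrich(query, coll_gs, config.alpha)
            (out / "enrichment.tsv").write_text(enrichment.records_to_tsv(recs))
            if any(r.significant for r in recs):
                groups = enrichment.kappa_group(recs, coll_gs, query,
                                                config.kappa_threshold)
                (out / "term_groups.json").write_text(json.dumps(
                    [{"representative": g.representative,
                      "members": sorted(g.members)} for g in groups],
                    indent=2) + "\n")
            return recs
        recs = stage("enrichment")(_enrich)
        enr_freq = enrichment.enrichment_frequency(recs, query)
    else:
        skip("enrichment", "no GMT collection configured" if not config.gmt
             else "no query genes available")

    # --- prioritization ---------------------------------------------------
    shortlisted = None
    if merged and coll:
        def _prior():
            redundancy = genesets.redundancy_counts(coll, set(merged.union_list))
            db = (prioritize.read_expression_tsv(config.expression_database, "database")
                  if config.expression_database
                  else prioritize.ExpressionAnnotation({}, "database"))
            lit = (prioritize.read_expression_tsv(config.expression_literature, "literature")
                   if config.expression_literature
                   else prioritize.ExpressionAnnotation({}, "literature"))
            ledger = prioritize.build_ledger(
                merged, redundancy=redundancy, hub_rank=hub_rank,
                cluster_rank=cluster_rank, enrichment_frequency=enr_freq,
                database_expression=db, literature_expression=lit)
            result = prioritize.shortlist(ledger)
            (out / "shortlist.json").write_text(result.to_json() + "\n")
            return result
        shortlisted = stage("prioritization")(_prior)
    else:
        skip("prioritization", "requires both the merged list and gene lists")

    # --- disease maps -----------------------------------------------------
    if len(config.disease_maps) >= 2:
        def _maps():
            maps = [disease_map.read_map(p) for p in config.disease_maps]
            smap = disease_map.superimpose(maps, config.min_support)
            (out / "superimposed.sif").write_text(smap.to_sif())
            payload: dict = {"edges": len(smap.edges), "nodes": sorted(smap.nodes)}
            if smap.edges:
                hub, conn = disease_map.hub_of_hubs(smap)
                eq = disease_map.core_equation(smap, hub)
                payload.update(hub=hub, connectivity=conn, equation=str(eq),
                               equation_nodes=eq.node_count)
                if shortlisted:
                    part = disease_map.participating_genes(smap, shortlisted.shortlist)
                    payload["participating_candidates"] = sorted(part)
            (out / "map_analysis.json").write_text(json.dumps(payload, indent=2) + "\n")
            return smap
        stage("disease_maps")(_maps)
    else:
        skip("disease_maps", "fewer than 2 disease maps configured")

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["completed_stages"] = sum(
        1 for s in manifest["stages"].values() if s["status"] == "completed")
    def _clean(o):
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        return o
    (out / "manifest.json").write_text(json.dumps(_clean(manifest), indent=2,
                                                  default=str) + "\n")
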