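# metahub

Consensus meta-hub gene discovery across related diseases, built around
protein–protein interaction (PPI) network topology.

When several complex diseases — for example type 2 diabetes, osteoarthritis
and triple-negative breast cancer — share risk relationships, the genes they
hold in common may mark a shared molecular origin. `metahub` implements the
full discovery pipeline for such a signature: intersect disease-specific hub
gene lists, rank the nodes of the common-gene interaction network by eleven
topological measures, detect dense molecular complexes, aggregate everything
into consensus meta-hub genes, test them for gene-set over-representation,
prioritize them through a seven-parameter ledger, and finally superimpose
directed disease signalling maps to extract the core "hub of hubs" equation.
It is aimed at systems-biology researchers who have per-disease gene lists
(text-mined or database-derived), a STRING-style weighted edge list, GMT
gene-set collections and curated signalling interactions, and who want the
whole chain reproducible from files on disk — no web services involved.

## The methods in brief

**Venn core.** Disease gene lists are normalized (uppercased symbols,
duplicates kept as occurrence counts) and intersected with distinct-symbol
semantics; the core is the set present in every list.

**Eleven hub measures.** For a simple undirected graph G = (V, E): Degree;
MNC (size of the largest connected component of the open neighbourhood
N(v)); DMNC = E′/V′^ε over that component (ε = 1.7); MCC = Σ_C (|C|−1)! over
maximal cliques C ∋ v; harmonic Closeness Σ_u 1/d(v,u); Betweenness
Σ σ_st(v)/σ_st; Stress (count of shortest paths through v); EcCentricity
1/ecc(v); Radiality Σ_u (Δ+1−d(v,u))/(|V|−1); BottleNeck (number of BFS
shortest-path trees in which v's subtree holds more than a quarter of the
tree); and EPC, the mean component size of v under seeded edge percolation.
Ranks are 1..|V| per measure, ties broken by symbol.

**Molecular complexes.** MCODE-style: weight each vertex by k·density of the
highest k-core of its neighbourhood, grow complexes from high-weight seeds
within a node-score cutoff, haircut singly-connected members; cluster score
= density × size.

**Consensus and merge.** Meta-hubs are ranked by how many measures place
them in their top-10 (mean rank, then symbol, break ties); the consensus
top-10 is merged with the top-10 module genes, recording the overlap.

**Enrichment.** One-sided hypergeometric (Fisher) tests against GMT terms
with Benjamini–Hochberg correction, plus kappa-statistic grouping of
redundant significant terms.

**Prioritization.** Seven parameters (mining redundancy, hub rank, module
rank, hub∩module overlap, enrichment frequency, database and literature
expression concordance) each nominate genes; the shortlist is the union with
per-gene provenance.

**Disease maps.** Directed, effect-labelled interactions per disease are
superimposed (edge kept if present in ≥ min_support diseases); the hub of
hubs maximizes |ancestors ∪ descendants|, and its core equation is
inputs ⇒ hub ⇒ outputs.

## Worked example

Generate a fully synthetic study (three disease lists with a planted 31-gene
core, a planted dense module in the interaction network, planted enriched
terms, expression tables and three disease maps sharing a directed core),
then run the whole pipeline:

```sh
metahub simulate --seed 7 --out demo/inputs
metahub run --config demo/config.yaml
```

with `demo/config.yaml` pointing at the generated files (see
`metahub.pipeline.PipelineConfig` for the fields). The run prints

```json
{
  "completed_stages": 8,
  "out_dir": "demo/out"
}
```

and the artifacts show the planted structure recovered end to end:

- `venn.json` — a 31-gene core, exactly the generator's planted core;
- `network_summary.json` — `{"nodes": 38, "edges": 62, "average_degree": 3.26, ...}`;
- `merged.json` — counts `[10, 8, 8, 10]`: the 10 consensus hubs, 8 module
  genes, 8 shared, 10 merged meta-hub genes;
- `shortlist.json` — 9 prioritized candidates with the parameters that
  nominated each;
- `map_analysis.json` — the superimposed map's hub and its core equation.

The shipped curated fixture reproduces the published three-disease core: the
superimposed map's hub is AKT1 and its equation

```
CD44,EGFR => AKT1 => MMP9+NFKB1+STAT3
```

covers 6 genes, with 8 of the 9 prioritized candidates participating in the
map (IFNG carries no shared interaction):

```python
from metahub import disease_map, fixtures

smap = disease_map.superimpose(fixtures.per_disease_core_maps())
hub, _ = disease_map.hub_of_hubs(smap)          # ('AKT1', 6)
eq = disease_map.core_equation(smap, hub)       # 6 nodes
part = disease_map.participating_genes(smap, set(fixtures.PRIORITIZED_CANDIDATES))
```

## Layout

- `src/metahub/` — library modules (`genesets`, `ppi_network`, `centrality`,
  `mcode`, `enrichment`, `consensus`, `prioritize`, `disease_map`,
  `synthetic_data`, `pipeline`, `cli`, `fixtures`)
- `tests/` — pytest suite, including brute-force oracle cross-checks
- `docs/methods.md` — modelling and design notes
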