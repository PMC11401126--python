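# Methods notes

## Scope and model

`metahub` operationalizes a consensus hub-gene discovery procedure for a set
of related diseases. The pipeline's object of study is the *common-gene
interactome*: the PPI network induced by the genes shared by every disease
list. All downstream machinery — topological ranking, complex detection,
consensus, enrichment, prioritization, map superimposition — operates on
plain files (gene lists, TSV edge lists, GMT collections, annotation tables,
directed interaction tables), so a run is fully reproducible offline.

## Gene lists and the Venn core

Symbols are uppercased and whitespace-stripped; no alias or HGNC resolution
is attempted — identifier harmonization is the caller's responsibility,
since any mapping policy would silently change every downstream count.
Lists keep duplicates (a gene mined from several articles appears several
times); all intersections use distinct-symbol semantics, and the raw
multiplicities feed only the redundancy parameter of prioritization. Venn
regions are exclusive (keyed by the exact label subset), so they partition
the union — asserted as a property test.

## Interaction networks

Edge lists follow the STRING export convention; scores on a 0–1000 integer
scale are detected (any score > 1) and divided by 1000. The default
confidence threshold is 0.4 (medium confidence). Duplicate pairs keep the
maximum score — the least destructive collapse, since an interaction's
support can only accumulate across rows. Self-loops are dropped with a
warning. Summary statistics use average degree 2E/V and density
2E/(V(V−1)); a 31-node, 379-edge network therefore prints an average node
degree of 24.5 at one decimal.

## The eleven hub measures

The measures are the classic Cytoscape hub-ranking panel. The package
defines them normatively (graph unweighted and simple throughout):

- **Degree** |N(v)|.
- **MNC** size of the largest connected component of the subgraph induced on
  the open neighbourhood N(v).
- **DMNC** E′/V′^ε over that component, ε = 1.7 by default; 0 when V′ < 2.
  Ties between equal-sized neighbourhood components break by sorted node
  list, making the measure deterministic.
- **MCC** Σ over maximal cliques C ∋ v of (|C|−1)!. When the neighbourhood
  is edgeless every incident edge is a maximal 2-clique and the sum equals
  the degree, so the documented special case needs no branch.
- **Closeness** harmonic: Σ_{u≠v} 1/d(v,u); an unreachable vertex
  contributes 0, so disconnected inputs score sensibly.
- **Betweenness** Σ_{s<t} σ_st(v)/σ_st over unordered pairs, endpoints
  excluded; **Stress** the unnormalized path count. Both come from one
  all-pairs BFS path-counting pass.
- **EcCentricity** 1/ecc(v) within v's component; isolated vertices score 0.
- **Radiality** Σ_{u reachable} (Δ+1−d(v,u))/(|V|−1) with Δ the diameter of
  v's component.
- **BottleNeck** counts BFS shortest-path trees (one per root) in which v's
  subtree holds strictly more than a quarter of the tree. Parent ties in the
  BFS tree break to the lexicographically smallest parent — the only way to
  make the measure reproducible across runs and platforms.
- **EPC** mean size of v's component over seeded edge percolations (default
  100 realizations, retention 0.5; retention may also be each edge's
  confidence). Retention 1.0 reduces exactly to component size, which the
  tests exploit as a deterministic anchor for the stochastic measure.

Ranks are score-descending with symbol-ascending tie-break. Every
deterministic measure is cross-checked against an independent brute-force
implementation (subset-enumerated cliques, explicit BFS, literal path
enumeration) on all connected graphs of the networkx atlas (≤ 7 nodes, 853
graphs) plus 50 seeded 8-node random graphs.

## Molecular complex detection

Vertex weight = k · density of the highest k-core of the subgraph induced on
N(v) (vertex excluded), 0 below the degree cutoff. Complexes grow breadth-
first from the highest-weight unvisited seed, admitting neighbours with
weight ≥ (1 − VWP) · seed weight; defaults are the plugin-style settings
(degree cutoff 2, VWP 0.2, k-core filter 2, haircut on, fluff off, depth
100). Haircut iterates degree-1 removal to a fixed point rather than one
pass, so no emitted cluster can contain a singly-connected member; if the
seed itself is shaved away the candidate had no dense core around its seed
and is discarded. Clusters whose induced subgraph has no 2-core are dropped.
Cluster score = density × size, recomputed independently in tests. On the
planted-module benchmark (an 8-clique inside a 40-node background with
p_out = 0.05) the top cluster recovers the module at Jaccard ≥ 0.8 in at
least 18 of 20 seeds.

## Enrichment

Over-representation p-values are exact hypergeometric tails
P(X ≥ k | N, m, n), verified against full enumeration for every
configuration with N ≤ 15. BH adjustment is the standard step-up, order-
preserving, cross-checked against statsmodels. When no universe accompanies
a collection it defaults to the union of all term members; this is logged
prominently because the choice moves every p-value. Kappa grouping is
ClueGO-style: binary term-membership vectors over the query genes only,
Cohen's κ from the 2×2 table, single-linkage joining of pairs with
κ ≥ 0.4 (configurable), lowest-p member as representative.

## Consensus, merge, prioritization

Consensus counts top-10 membership per measure; frequency, then mean rank
over contributing measures, then symbol. The merge keeps hub-list order and
appends novel module genes. Prioritization parameters 1, 2, 3 and 5 nominate
single best performers; 4 nominates the whole overlap; 6 and 7 nominate
every gene whose expression direction is identical and known across all
configured diseases — the strictest reading, with "unknown" disqualifying,
since a weaker rule would let missing data masquerade as concordance.

## Disease maps

Maps are directed and effect-labelled (activate / inhibit / regulate), no
self-edges, one edge per (source, target, disease). Superimposition keeps
pairs supported by ≥ min_support diseases (default: all); conflicting
effects collapse to "regulate" with a warning. The hub of hubs maximizes
|ancestors ∪ descendants| — reachability rather than direct adjacency,
because the interesting claim is which gene sits in the signalling stream of
the most others; on the shipped three-disease core this yields AKT1 touching
6 of the 8 wired genes. The shipped fixture pins one reading of the
ambiguous downstream wiring (NFKB1→MMP9, STAT3→MMP1); the hub identity, the
6-node core equation and the 8-gene participation count are invariant across
the alternative consistent wirings, which the tests exercise explicitly.

## Synthetic data

The generators are pure functions of their spec (byte-identical files per
seed). Defaults mirror the study conditions: three disease lists of
376/567/360 genes over a 500-gene universe with a 31-gene planted core
(lists truncate to the universe partition), interaction confidences uniform
on [0.4, 1.0] so default thresholding is exercised but lossless, a planted
module of 8 at p_in = 1 inside a 40-node background at p_out = 0.05, 3
planted terms holding 80 % of the query among 20 terms of size 40, and
three disease maps sharing a 6-edge directed core with 4 per-disease noise
edges. Disease-specific list tails are drawn from disjoint universe
partitions, so a zero-size core yields an empty triple intersection by
construction, not by luck. In `generate_all` the network is built over the
planted core genes plus filler from the universe, as in a real run where the
common genes seed the PPI query.

Two deliberate departures from naive planting: (i) the clean-background
planted-hub network (p_in = 1, p_out = 0) is the configuration under which
the full frequency-11 consensus claim is tested, because DMNC structurally
penalizes a hub wired into a noisy background — its neighbourhood is large
and sparse — so no noisy construction can make the hub maximal on all
eleven measures; and (ii) the designated hub carries a distinguished symbol
so that the documented symbol tie-break resolves its exact DMNC/MNC ties
with module members in its favour.

What the generators do **not** emulate: scale-free degree structure,
evidence-channel score correlations, realistic GO term nesting, or
literature-curation noise in maps. Passing recovery tests therefore
demonstrates correctness of the algorithms under controlled separation, not
performance on real interactomes.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit parameters; two runs with the same seed produce identical outputs
  including EPC and all generated files.
- All tie-breaks in the package are lexicographic on gene symbol after the
  primary key; this is stated per operation and asserted in tests.
- Problem sizes in the test suite (40-node networks, 20 seeds per recovery
  experiment, the ≤ 7-node exhaustive atlas plus 50 8-node graphs, N ≤ 15
  enumeration for the hypergeometric oracle) were chosen so each experiment
  is statistically meaningful while the whole suite stays interactive-fast.

## Known limitations

- MCC uses maximal-clique enumeration; dense graphs beyond a few hundred
  nodes will be slow.
- The kappa threshold default (0.4) follows common practice; group counts
  are sensitive to it and should be reported with it.
- The hub-of-hubs reachability criterion ignores effect signs; an inhibitory
  chain counts the same as an activating one.
- Expression concordance treats each (gene, disease) annotation as a single
  label; magnitudes and per-study disagreement are out of scope.
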