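"""Consensus aggregation of per-measure rankings into meta-hub genes.

A gene's consensus standing is the number of measures that place it inside
their top-k list ("frequency of occurrence within the top rankings"); ties
break by mean rank over the contributing measures, then by symbol.  The
consensus top-k is then merged with the top module genes from complex
detection, keeping hub-list order first and recording the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .centrality import RankTable, top_k


@dataclass
class ConsensusResult:
    frequency: dict[str, int]
    mean_rank: dict[str, float]
    meta_hubs: list[str]

    def to_tsv(self) -> str:
        rows = ["gene\tfrequency\tmean_rank\tselected"]
        chosen = set(self.meta_hubs)
        order = sorted(self.frequency,
                       key=lambda g: (-self.frequency[g], self.mean_rank[g], g))
        for g in order:
            rows.append(f"{g}\t{self.frequency[g]}\t{self.mean_rank[g]:.3f}"
                        f"\t{int(g in chosen)}")
        return "\n".join(rows) + "\n"


@dataclass
class MergeResult:
    union_list: list[str]
    overlap: set[str]
    counts: tuple[int, int, int, int]  # (|hub|, |cluster|, |overlap|, |union|)


def consensus_rank(table: RankTable, k: int = 10) -> ConsensusResult:
    """Frequency-in-top-k consensus over every measure in the table."""
    if not table.measures:
        raise ValueError("rank table covers no measures")
    freq: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for m in table.measures:
        for g in top_k(table, m, k):
            freq[g] = freq.get(g, 0) + 1
            rank_sums[g] = rank_sums.get(g, 0.0) + int(table.ranks.at[g, m])
    mean_rank = {g: rank_sums[g] / freq[g] for g in freq}
    order = sorted(freq, key=lambda g: (-freq[g], mean_rank[g], g))
    return ConsensusResult(frequency=freq, mean_rank=mean_rank, meta_hubs=order[:k])


def merge_hub_cluster(hub_top: list[str], cluster_top: list[str]) -> MergeResult:
    """Union of consensus hubs and top module genes, hub-list order first."""
    for name, lst in (("hub", hub_top), ("cluster", cluster_top)):
        if not lst:
            raise ValueError(f"{name} list is empty")
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicates within the {name} list")
    hub_set = set(hub_top)
    overlap = hub_set & set(cluster_top)
    union = list(hub_top) + [g for g in cluster_top if g not in hub_set]
    counts = (len(hub_top), len(cluster_top), len(overlap), len(union))
    assert counts[3] == counts[0] + counts[1] - counts[2]
    return MergeResult(union_list=union, overlap=overlap, counts=counts)
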