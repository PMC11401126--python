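"""Seven-parameter prioritization of merged meta-hub genes.

The ledger collects, for every merged gene: (1) occurrence redundancy in the
parent mined lists, (2) consensus hub rank, (3) module (cluster-weight) rank,
(4) membership in the hub∩cluster overlap, (5) number of significant enriched
terms containing the gene, and expression-direction concordance across the
configured diseases from (6) database and (7) literature annotation.

Selection policy: parameters 1, 2, 3 and 5 each contribute their single best
performer (ties break by symbol); parameter 4 contributes every overlap
member; parameters 6 and 7 contribute every gene whose direction is identical
— and known — across all diseases.  The shortlist is the union, with
per-gene provenance recording which parameters selected it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import MergeResult
from .genesets import normalize_symbol

log = logging.getLogger(__name__)

PARAMETERS = (
    "redundancy", "hub_rank", "cluster_rank", "overlap",
    "enrichment_frequency", "database_expression", "literature_expression",
)

DIRECTIONS = ("up", "down", "unknown")


@dataclass
class ExpressionAnnotation:
    """(gene, disease) → up/down/unknown, from one source class."""

    direction: dict[tuple[str, str], str]
    source: str = "database"
    diseases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for (g, d), v in self.direction.items():
            if v not in DIRECTIONS:
                raise ValueError(f"bad direction {v!r} for ({g}, {d})")
        if not self.diseases:
            self.diseases = tuple(sorted({d for _, d in self.direction}))

    def concordant(self, genes: set[str]) -> set[str]:
        """Genes with one identical, known direction across every disease."""
        out = set()
        for g in genes:
            dirs = {self.direction.get((g, d), "unknown") for d in self.diseases}
            if len(dirs) == 1 and dirs != {"unknown"} and self.diseases:
                out.add(g)
        return out


def read_expression_tsv(path: str | Path, source: str | None = None) -> ExpressionAnnotation:
    """TSV columns: gene, disease, direction, source (header optional)."""
    direction: dict[tuple[str, str], str] = {}
    src = source
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0].lower() == "gene":
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: need gene, disease, direction")
        g = normalize_symbol(parts[0])
        d = parts[1].strip()
        v = parts[2].strip().lower()
        if v not in DIRECTIONS:
            raise ValueError(f"{path}:{lineno}: unknown direction {v!r}")
        direction[(g, d)] = v
        if src is None and len(parts) > 3:
            src = parts[3].strip()
    return ExpressionAnnotation(direction=direction, source=src or "database")


@dataclass
class PrioritizationLedger:
    genes: list[str]
    redundancy: dict[str, int]
    hub_rank: dict[str, int]
    cluster_rank: dict[str, int]
    overlap: set[str]
    enrichment_frequency: dict[str, int]
    database_expression: ExpressionAnnotation
    literature_expression: ExpressionAnnotation


@dataclass
class PrioritizedSet:
    shortlist: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "shortlist": sorted(self.shortlist),
            "provenance": {g: sorted(ps) for g, ps in sorted(self.provenance.items())},
        }, indent=2)


def build_ledger(merged: MergeResult,
                 redundancy: dict[str, int],
                 hub_rank: dict[str, int],
                 cluster_rank: dict[str, int],
                 enrichment_frequency: dict[str, int],
                 database_expression: ExpressionAnnotation,
                 literature_expression: ExpressionAnnotation) -> PrioritizationLedger:
    """Assemble and restrict all seven parameter inputs to the merged genes."""
    genes = list(merged.union_list)
    gene_set = set(genes)
    if set(database_expression.diseases) and set(literature_expression.diseases) and \
            set(database_expression.diseases) != set(literature_expression.diseases):
        raise ValueError("disease labels differ between database and literature annotations")

    def restrict(mapping: dict[str, int], name: str) -> dict[str, int]:
        missing = gene_set - set(mapping)
        if missing:
            log.warning("%s missing for %d merged genes (default 0): %s",
                        name, len(missing), ", ".join(sorted(missing)[:8]))
        return {g: mapping.get(g, 0) for g in genes}

    return PrioritizationLedger(
        genes=genes,
        redundancy=restrict(redundancy, "redundancy"),
        hub_rank={g: hub_rank[g] for g in genes if g in hub_rank},
        cluster_rank={g: cluster_rank[g] for g in genes if g in cluster_rank},
        overlap=set(merged.overlap),
        enrichment_frequency=restrict(enrichment_frequency, "enrichment_frequency"),
        database_expression=database_expression,
        literature_expression=literature_expression,
    )


def shortlist(ledger: PrioritizationLedger) -> PrioritizedSet:
    """Apply the selection policy; returns the union with provenance."""
    if not ledger.genes:
        raise ValueError("empty ledger")
    gene_set = set(ledger.genes)
    selected: dict[str, set[str]] = {}

    def pick(gene: str, param: str) -> None:
        selected.setdefault(gene, set()).add(param)

    def best(mapping: dict[str, int | float], maximize: bool) -> str | None:
        if not mapping:
            return None
        sign = -1 if maximize else 1
        return min(mapping, key=lambda g: (sign * mapping[g], g))

    if (g := best(ledger.redundancy, maximize=True)) is not None:
        pick(g, "redundancy")
    if (g := best(ledger.hub_rank, maximize=False)) is not None:
        pick(g, "hub_rank")
    if (g := best(ledger.cluster_rank, maximize=False)) is not None:
        pick(g, "cluster_rank")
    for g in ledger.overlap & gene_set:
        pick(g, "overlap")
    if (g := best(ledger.enrichment_frequency, maximize=True)) is not None:
        pick(g, "enrichment_frequency")
    for g in ledger.database_expression.concordant(gene_set):
        pick(g, "database_expression")
    for g in ledger.literature_expression.concordant(gene_set):
        pick(g, "literature_expression")
    return PrioritizedSet(shortlist=set(selected), provenance=selected)
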