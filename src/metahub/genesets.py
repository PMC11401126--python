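"""Disease gene lists: parsing, normalization, Venn intersection and redundancy.

Gene symbols are plain uppercase tokens (e.g. ``AKT1``).  Lists keep their raw
order and multiplicity — a symbol mined from several articles appears several
times — but all set operations (Venn regions, annotation overlap) work on the
distinct-symbol view of each list.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DIALECTS = ("one-per-line", "semicolon", "tsv-column")


def normalize_symbol(raw: str) -> str:
    """Uppercase and strip a gene token; reject empty or separator-bearing input."""
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in sym) or ";" in sym:
        raise ValueError(f"gene symbol contains whitespace or semicolon: {raw!r}")
    return sym


@dataclass
class GeneListCollection:
    """Named, ordered gene lists (duplicates permitted) plus an optional universe."""

    lists: dict[str, list[str]]
    name: str = "collection"
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        self.lists = {label: [normalize_symbol(g) for g in genes]
                      for label, genes in self.lists.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.lists)

    def distinct(self, label: str) -> set[str]:
        return set(self.lists[label])


@dataclass
class VennResult:
    """Exclusive Venn regions (keyed by frozenset of labels) and the all-list core."""

    region_counts: dict[frozenset, int]
    core: set[str]
    regions: dict[frozenset, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"|".join(sorted(k)): v for k, v in sorted(
            self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))}
        payload["core"] = sorted(self.core)
        return json.dumps(payload, indent=2)


def read_gene_lists(path: str | Path, dialect: str = "one-per-line",
                    label: str | None = None) -> GeneListCollection:
    """Parse one gene-list file into a single-label collection.

    Dialects: ``one-per-line`` (one symbol per line), ``semicolon``
    (``LCK; STAT1; IFNG; ...`` possibly spanning lines), ``tsv-column``
    (first tab-separated column of each line).
    Duplicates are preserved in sequence and reported in a log line.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = path.read_text(encoding="utf-8")
    genes: list[str] = []
    if dialect == "semicolon":
        tokens = [t for chunk in text.split(";") for t in [chunk.strip()] if t]
        genes = [normalize_symbol(t) for t in tokens]
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split("\t")[0] if dialect == "tsv-column" else line
            genes.append(normalize_symbol(token))
    if not genes:
        raise ValueError(f"no genes parsed from {path}")
    n_dup = len(genes) - len(set(genes))
    if n_dup:
        log.info("%s: %d duplicate occurrences across %d entries", path, n_dup, len(genes))
    return GeneListCollection({label or path.stem: genes})


def combine(collections: Iterable[GeneListCollection],
            name: str = "combined") -> GeneListCollection:
    """Merge single-label collections into one; labels must be unique."""
    lists: dict[str, list[str]] = {}
    for coll in collections:
        for lab, genes in coll.lists.items():
            if lab in lists:
                raise ValueError(f"duplicate disease label {lab!r}")
            lists[lab] = list(genes)
    return GeneListCollection(lists, name=name)


def intersect_all(collection: GeneListCollection) -> VennResult:
    """Exclusive Venn regions over all lists; the core is the all-list intersection.

    Distinct-symbol semantics: multiplicities within a list are ignored here.
    """
    labels = collection.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 gene lists to intersect")
    distinct = {lab: collection.distinct(lab) for lab in labels}
    union = set().union(*distinct.values())
    regions: dict[frozenset, set[str]] = {
        frozenset(sub): set()
        for r in range(1, len(labels) + 1)
        for sub in combinations(labels, r)
    }
    for gene in union:
        member = frozenset(lab for lab in labels if gene in distinct[lab])
        regions[member].add(gene)
    core = set(regions[frozenset(labels)])
    counts = {k: len(v) for k, v in regions.items()}
    return VennResult(region_counts=counts, core=core, regions=regions)


def overlap_with_annotation(core: set[str], annotation: set[str]) -> tuple[int, list[str]]:
    """Size and sorted members of ``core ∩ annotation``."""
    if not core:
        raise ValueError("empty core gene set")
    if not annotation:
        raise ValueError("empty annotation gene set")
    hit = sorted(core & annotation)
    return len(hit), hit


def redundancy_counts(collection: GeneListCollection,
                      genes: Iterable[str]) -> dict[str, int]:
    """Total occurrences of each gene across all raw list sequences."""
    genes = [normalize_symbol(g) for g in genes]
    if not genes:
        raise ValueError("no genes supplied")
    tally: Counter = Counter()
    for seq in collection.lists.values():
        tally.update(seq)
    return {g: tally.get(g, 0) for g in genes}


def write_region_tsv(venn: VennResult, path: str | Path) -> None:
    """One (gene, region) row per union member, region as sorted |-joined labels."""
    rows = []
    for labels, members in sorted(venn.regions.items(),
                                  key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        tag = "|".join(sorted(labels))
        rows += [f"{g}\t{tag}" for g in sorted(members)]
    Path(path).write_text("gene\tregion\n" + "\n".join(rows) + "\n", encoding="utf-8")
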