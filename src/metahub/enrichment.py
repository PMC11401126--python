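"""Over-representation analysis against GMT gene-set collections.

P-values are one-sided hypergeometric tail probabilities (the Fisher exact
test for enrichment), corrected with the Benjamini–Hochberg step-up.
Significant terms can then be grouped by kappa-statistic agreement of their
query-gene memberships, ClueGO-style, so redundant terms collapse into one
functional group with the most significant member as representative.

The universe defaults to the union of all collection members when none is
supplied — this choice changes every p-value and is logged prominently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .genesets import normalize_symbol

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Term → (description, member set) plus the background universe."""

    terms: dict[str, tuple[str, set[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*(m for _, m in self.terms.values())) if self.terms else set()
            log.warning("no universe supplied; defaulting to union of all %d terms "
                        "(%d genes) — p-values depend on this choice",
                        len(self.terms), len(self.universe))
        for name, (_, members) in self.terms.items():
            extra = members - self.universe
            if extra:
                raise ValueError(f"term {name!r} has {len(extra)} genes outside the universe")


@dataclass
class EnrichmentRecord:
    term: str
    description: str
    overlap_k: int
    term_m: int
    query_n: int
    universe_N: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    overlap_genes: tuple[str, ...] = ()


@dataclass
class TermGroup:
    members: set[str]
    representative: str


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Standard GMT: term <tab> description <tab> member genes, one term per line."""
    terms: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs ≥3 fields")
        name, desc = parts[0], parts[1]
        if name in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term {name!r}")
        terms[name] = (desc, {normalize_symbol(g) for g in parts[2:] if g.strip()})
    return GeneSetCollection(terms, universe=set(universe) if universe else set())


def hypergeom_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X ≥ k) for X ~ Hypergeom(N population, m marked, n drawn)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def fisher_enrich(query: set[str], collection: GeneSetCollection,
                  alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Test every term; q < alpha flags significance. Sorted by (p, term)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    universe = collection.universe
    dropped = query - universe
    if dropped:
        log.warning("%d query genes outside universe dropped: %s",
                    len(dropped), ", ".join(sorted(dropped)[:10]))
    query_in = query & universe
    if not query_in:
        raise ValueError("no query genes remain after universe restriction")
    N, n = len(universe), len(query_in)
    records = []
    for name, (desc, members) in collection.terms.items():
        m = len(members & universe)
        if m > N:
            raise ValueError(f"term {name!r} larger than universe")
        hit = query_in & members
        k = len(hit)
        records.append(EnrichmentRecord(
            term=name, description=desc, overlap_k=k, term_m=m,
            query_n=n, universe_N=N, p_value=hypergeom_tail(k, N, m, n),
            overlap_genes=tuple(sorted(hit)),
        ))
    qs = bh_adjust([r.p_value for r in records])
    for r, q in zip(records, qs):
        r.q_value = q
        r.significant = q < alpha
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


def cohen_kappa(a: set[str], b: set[str], query: set[str]) -> float:
    """Chance-corrected agreement of two terms' memberships over the query."""
    n = len(query)
    if n == 0:
        return 0.0
    both = len(a & b & query)
    only_a = len((a - b) & query)
    only_b = len((b - a) & query)
    neither = n - both - only_a - only_b
    po = (both + neither) / n
    pa_yes, pb_yes = (both + only_a) / n, (both + only_b) / n
    pe = pa_yes * pb_yes + (1 - pa_yes) * (1 - pb_yes)
    if pe == 1.0:
        return 1.0  # identical constant memberships agree perfectly
    return (po - pe) / (1 - pe)


def kappa_group(records: list[EnrichmentRecord], collection: GeneSetCollection,
                query: set[str], kappa_threshold: float = 0.4) -> list[TermGroup]:
    """Single-linkage grouping of significant terms with κ ≥ threshold."""
    sig = [r for r in records if r.significant]
    if not sig:
        raise ValueError("no significant records to group")
    query_in = query & collection.universe
    names = [r.term for r in sig]
    p_of = {r.term: r.p_value for r in sig}
    # union-find over threshold pairs = single linkage
    parent = {t: t for t in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            k = cohen_kappa(collection.terms[a][1], collection.terms[b][1], query_in)
            if k >= kappa_threshold:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for t in names:
        groups.setdefault(find(t), set()).add(t)
    out = [TermGroup(members=members,
                     representative=min(members, key=lambda t: (p_of[t], t)))
           for members in groups.values()]
    out.sort(key=lambda g: (p_of[g.representative], g.representative))
    return out


def enrichment_frequency(records: list[EnrichmentRecord],
                         genes: set[str]) -> dict[str, int]:
    """Per gene: number of significant terms whose overlap contains it."""
    freq = {g: 0 for g in genes}
    for r in records:
        if r.significant:
            for g in r.overlap_genes:
                if g in freq:
                    freq[g] += 1
    return freq


def records_to_tsv(records: list[EnrichmentRecord]) -> str:
    rows = ["term\tdescription\toverlap\tterm_size\tquery_size\tuniverse\tp_value\tq_value\tsignificant\tgenes"]
    for r in records:
        rows.append(f"{r.term}\t{r.description}\t{r.overlap_k}\t{r.term_m}\t{r.query_n}"
                    f"\t{r.universe_N}\t{r.p_value:.6g}\t{r.q_value:.6g}"
                    f"\t{int(r.significant)}\t{';'.join(r.overlap_genes)}")
    return "\n".join(rows) + "\n"
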