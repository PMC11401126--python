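"""Shipped fixtures: the 31-gene common-hub signature and the shared
three-disease (3-D) signalling core.

The signature is the published semicolon-separated list of hub genes common
to type 2 diabetes, osteoarthritis and triple-negative breast cancer.  The
3-D map encodes the shared signalling wiring those diseases have in common —
EGFR and CD44 feeding into AKT1, AKT1 driving NFKB1/STAT3/MMP9, downstream
MMP1/MMP9 targets also recruited by CTNNB1 — with IFNG present but isolated.
The NFKB1/STAT3 → MMP1/MMP9 assignment below pins one concrete reading of an
ambiguous prose description; the hub, equation size and participant count are
invariant to the alternative wirings (exercised in tests).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .disease_map import DiseaseMap, read_map
from .genesets import GeneListCollection, read_gene_lists

#: The nine prioritized candidate meta-hub genes (IFNG included; it sits on
#: the map without touching any shared interaction).
PRIORITIZED_CANDIDATES = (
    "AKT1", "NFKB1", "CTNNB1", "EGFR", "MMP1", "MMP9", "CD44", "STAT3", "IFNG",
)


def _data(name: str) -> Path:
    return Path(resources.files("metahub") / "data" / name)


def signature_path() -> Path:
    return _data("signature_common_hubs.txt")


def load_signature() -> GeneListCollection:
    """The 31-gene signature, parsed through the semicolon dialect."""
    return read_gene_lists(signature_path(), dialect="semicolon", label="signature")


def three_disease_map_path() -> Path:
    return _data("three_disease_map.tsv")


def load_three_disease_map() -> DiseaseMap:
    return read_map(three_disease_map_path())


def per_disease_core_maps(diseases: tuple[str, ...] = ("T2DM", "OA", "TNBC")) -> list[DiseaseMap]:
    """The shared core replicated per disease, ready for superimposition."""
    core = load_three_disease_map()
    return [DiseaseMap(disease=d, edges=dict(core.edges), isolated=set(core.isolated))
            for d in diseases]
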