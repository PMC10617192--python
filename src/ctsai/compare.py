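"""Set algebra over gene sets: merging candidate sets from two annotation
sources and the cross-species alternative-splicing conservation overlap."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .models import OrthologMap

# normalization: strip an all-digit trailing version/transcript suffix
# (".1", ".2", but not locus segments like ".0004s0224") and the legacy
# "m.g" gene-model suffix, so v2.0- and v2.1-style ids compare equal
_VERSION_SUFFIX = re.compile(r"\.(t?\d+)$")
_LEGACY_SUFFIX = re.compile(r"m\.g$")


def normalize_gene_id(gene_id: str) -> str:
    gene_id = _LEGACY_SUFFIX.sub("", gene_id)
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass(frozen=True)
class GeneSet:
    label: str
    ids: frozenset[str]

    @staticmethod
    def from_ids(label: str, ids: Iterable[str], normalize: bool = False) -> "GeneSet":
        if normalize:
            ids = (normalize_gene_id(i) for i in ids)
        return GeneSet(label, frozenset(ids))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class OverlapReport:
    """Inclusion–exclusion bookkeeping for two gene sets."""

    size_a: int
    size_b: int
    intersection: int
    union: int
    unique_a: int
    unique_b: int


def merge_candidate_sets(
    a: GeneSet, b: GeneSet
) -> tuple[OverlapReport, GeneSet, dict[str, str]]:
    """Union two candidate sets, tagging each id with its provenance.

    Returns the overlap report, the merged set, and a per-id provenance
    map with values 'a-only', 'b-only' or 'both'.
    """
    inter = a.ids & b.ids
    union = a.ids | b.ids
    provenance = {}
    for g in union:
        if g in inter:
            provenance[g] = "both"
        elif g in a.ids:
            provenance[g] = "a-only"
        else:
            provenance[g] = "b-only"
    report = OverlapReport(
        size_a=len(a.ids),
        size_b=len(b.ids),
        intersection=len(inter),
        union=len(union),
        unique_a=len(a.ids) - len(inter),
        unique_b=len(b.ids) - len(inter),
    )
    merged = GeneSet(label=f"{a.label}+{b.label}", ids=frozenset(union))
    return report, merged, provenance


def as_conservation_overlap(
    orthologs: OrthologMap, as_genes_a: GeneSet, as_genes_b: GeneSet
) -> tuple[int, int, int]:
    """Conservation of alternative splicing across 1:1 ortholog pairs.

    Returns (pairs whose species-A member is alternatively spliced,
    pairs whose species-B member is, pairs where both members are).
    """
    in_a = sum(1 for a, _ in orthologs.pairs if a in as_genes_a.ids)
    in_b = sum(1 for _, b in orthologs.pairs if b in as_genes_b.ids)
    both = sum(
        1
        for a, b in orthologs.pairs
        if a in as_genes_a.ids and b in as_genes_b.ids
    )
    return in_a, in_b, both
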