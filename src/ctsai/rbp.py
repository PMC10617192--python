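"""RNA-binding-protein screen: identify predicted RBP genes by PFAM
domain content and classify their cell-type expression bias.

The default domain list covers the four named RBP families — RNA
recognition motif (PF00076), KH (PF00013), G-patch (PF01585) and the
DEAD/helicase-C pair (PF00270/PF00271) — and is extensible, since real
annotations include further RNA-binding families.

Bias tiers on the gene-level soma/gonidia expression ratio ER (fold
change f = max(ER, 1/ER)): ``similar`` f < 2, ``modest`` 2 <= f <= 5,
``specific`` f > 5.  Boundary values 2 and 5 fall in ``modest``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compare import GeneSet
from .models import DomainTable, ExpressionTable

DEFAULT_RBP_PFAMS = frozenset(
    {"PF00076", "PF00013", "PF01585", "PF00270", "PF00271"}
)


@dataclass(frozen=True)
class RbpRecord:
    gene_id: str
    domains: frozenset[str]
    ER: float
    category: str  # similar | modest | specific
    direction: str  # soma | gonidia | none


def identify_rbp_genes(
    domains: DomainTable, rbp_pfams: frozenset[str] = DEFAULT_RBP_PFAMS
) -> GeneSet:
    """Genes carrying at least one listed RNA-binding PFAM domain."""
    return GeneSet("rbp", frozenset(domains.genes_with_any(rbp_pfams)))


def _tier(er: float) -> tuple[str, str]:
    fold = max(er, 1.0 / er)
    if fold < 2.0:
        return "similar", "none"
    category = "modest" if fold <= 5.0 else "specific"
    return category, ("soma" if er > 1.0 else "gonidia")


def classify_rbp_bias(
    table: ExpressionTable,
    rbps: GeneSet,
    pseudocount: float = 0.01,
    domains: DomainTable | None = None,
) -> tuple[list[RbpRecord], dict[tuple[str, str], int]]:
    """Classify each expressed RBP gene into a bias tier.

    Gene-level FPKM is the per-sample sum of transcript FPKM; ER is the
    ratio of cell-type means with ``pseudocount`` added to both.  Returns
    records (gene_id order) and counts per (category, direction).
    """
    gene_fpkm = table.gene_sums()
    soma_cols = list(table.design.samples_of("soma"))
    gon_cols = list(table.design.samples_of("gonidia"))
    records: list[RbpRecord] = []
    counts: dict[tuple[str, str], int] = {}
    domain_lookup = dict(domains.records) if domains is not None else {}
    for gene_id in sorted(rbps.ids):
        if gene_id not in gene_fpkm.index:
            continue
        m_soma = float(gene_fpkm.loc[gene_id, soma_cols].mean())
        m_gon = float(gene_fpkm.loc[gene_id, gon_cols].mean())
        er = (m_soma + pseudocount) / (m_gon + pseudocount)
        category, direction = _tier(er)
        records.append(
            RbpRecord(
                gene_id=gene_id,
                domains=domain_lookup.get(gene_id, frozenset()),
                ER=er,
                category=category,
                direction=direction,
            )
        )
        counts[(category, direction)] = counts.get((category, direction), 0) + 1
    return records, counts
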