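"""Expression floor and isoform census.

A gene counts as expressed when the mean over all samples of its summed
per-transcript FPKM is strictly greater than the floor (default 1 FPKM).
Expressed genes are then binned by isoform count; only the two-isoform
genes move on to switch detection — single-isoform genes cannot show
isoform bias, and genes with three or more isoforms are counted but not
analyzed.

An optional per-transcript floor (``filter_expressed_transcripts``) drops
individual low-abundance transcripts before the census; it is off by
default — the gene-level floor is the primary contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .models import ConsistencyError, ExpressionTable, GeneModel


@dataclass(frozen=True)
class CensusResult:
    expressed_genes: frozenset[str]
    histogram: Mapping[int, int]  # isoform count -> number of genes
    two_isoform_genes: frozenset[str]
    excluded_single: int
    excluded_many: int


def filter_expressed_genes(
    table: ExpressionTable, min_mean_fpkm: float = 1.0
) -> set[str]:
    """Genes whose mean (over samples) summed-transcript FPKM exceeds the floor.

    The inequality is strict: a gene at exactly the floor is excluded.
    """
    gene_means = table.gene_sums().mean(axis=1)
    return set(gene_means.index[gene_means > min_mean_fpkm])


def filter_expressed_transcripts(
    table: ExpressionTable, min_mean_fpkm: float = 1.0
) -> set[str]:
    """Transcripts whose mean FPKM over all samples exceeds the floor."""
    tx_means = table.values.mean(axis=1)
    return set(tx_means.index[tx_means > min_mean_fpkm])


def census(
    models: Sequence[GeneModel], expressed: set[str] | frozenset[str]
) -> CensusResult:
    """Histogram of isoform counts over expressed genes; select the 2-isoform set."""
    by_gene = {g.gene_id: g for g in models}
    missing = set(expressed) - set(by_gene)
    if missing:
        raise ConsistencyError(
            f"expressed gene(s) without a model: {sorted(missing)[:5]}"
        )
    histogram: dict[int, int] = {}
    two: set[str] = set()
    single = many = 0
    for gene_id in expressed:
        k = by_gene[gene_id].n_isoforms
        histogram[k] = histogram.get(k, 0) + 1
        if k == 1:
            single += 1
        elif k == 2:
            two.add(gene_id)
        else:
            many += 1
    return CensusResult(
        expressed_genes=frozenset(expressed),
        histogram=dict(sorted(histogram.items())),
        two_isoform_genes=frozenset(two),
        excluded_single=single,
        excluded_many=many,
    )


def two_isoform_percentage(histogram: Mapping[int, int]) -> int | None:
    """Percentage of multi-isoform genes that have exactly two isoforms.

    Reported as an integer percentage truncated toward zero (974 of 1235
    multi-isoform genes -> 78).  None when there are no multi-isoform
    genes.
    """
    multi = sum(n for k, n in histogram.items() if k >= 2)
    if multi == 0:
        return None
    return math.floor(100.0 * histogram.get(2, 0) / multi)


def report_funnel(result: CensusResult) -> dict[str, object]:
    """Funnel counts of the census as a flat report dict."""
    pct = two_isoform_percentage(result.histogram)
    return {
        "expressed_genes": len(result.expressed_genes),
        "single_isoform": result.excluded_single,
        "multi_isoform": len(result.two_isoform_genes) + result.excluded_many,
        "two_isoform": len(result.two_isoform_genes),
        "three_plus_isoform": result.excluded_many,
        "two_isoform_percent": "NA" if pct is None else f"{pct}%",
    }


def format_funnel(result: CensusResult) -> str:
    lines = [f"{k}\t{v}" for k, v in report_funnel(result).items()]
    return "\n".join(lines) + "\n"
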