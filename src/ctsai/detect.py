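"""Isoform-switch detection: per-isoform cell-type statistics and the
three-stage filter cascade.

The statistic of interest for a transcript is its expression ratio
ER = (mean soma FPKM + eps) / (mean gonidia FPKM + eps).  A gene with two
isoforms is a candidate for cell-type-specific alternative isoforms when

  stage 1  one isoform is soma-biased (ER > tau_bias) and the other is
           gonidia-biased (ER < 1/tau_bias);
  stage 2  the combined bias B = ER_high / ER_low exceeds tau_B;
  stage 3  each isoform's two-group differential-expression p-value is
           below tau_p, equivalently the aggregate p = p1 * p2 is below
           tau_p**2 (independent tests multiply).

All threshold comparisons are strict; ties fail.  Stage 1 is equivalent to
requiring |log2 ER| > log2(tau_bias) with opposite signs for the two
isoforms (unit-tested equivalence).

The differential test is a two-group pooled-variance t-test on
log2(FPKM + 1) — for two groups this equals the F-test of the group term
in a one-way linear model.  No multiple-testing correction is applied
beyond the per-gene aggregate product; results are per-gene nominal, not
FDR-controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .census import CensusResult
from .models import ConsistencyError, ExpressionTable, GeneModel


@dataclass(frozen=True)
class Thresholds:
    """Filter-cascade cutoffs.

    tau_bias: per-isoform soma/gonidia ratio defining "biased" (>2 soma,
    <1/2 gonidia).  tau_B: combined bias of the isoform pair.  tau_p:
    per-isoform p cutoff; tau_aggregate defaults to tau_p**2 because the
    two per-isoform p-values multiply.  pseudocount (FPKM) guards the
    ratio against zero denominators and is far below the 1-FPKM
    expression floor, so ratios of expressed transcripts are barely
    perturbed.
    """

    tau_bias: float = 2.0
    tau_B: float = 8.0
    tau_p: float = 0.1
    tau_aggregate: float | None = None
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in ("tau_bias", "tau_B", "tau_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.tau_aggregate is None:
            object.__setattr__(self, "tau_aggregate", self.tau_p ** 2)

    def replace(self, **kw) -> "Thresholds":
        return replace(self, **kw)


@dataclass(frozen=True)
class IsoformStats:
    transcript_id: str
    mean_soma: float
    mean_gonidia: float
    ER: float
    log2ER: float
    p_value: float | None


@dataclass(frozen=True)
class CandidateRecord:
    """Per-gene outcome of the cascade; iso1 is the higher-ER isoform."""

    gene_id: str
    source: str
    iso1: IsoformStats
    iso2: IsoformStats
    B: float
    aggregate_p: float | None
    passed_stage1: bool
    passed_stage2: bool
    passed_stage3: bool
    verdict: str  # candidate | rejected


def two_group_isoform_test(
    soma_values: Sequence[float], gonidia_values: Sequence[float]
) -> float:
    """Two-sided p-value for a cell-type difference in one transcript.

    Pooled-variance t-test on log2(FPKM + 1).  Degenerate contract for
    noise-free data: if the within-group variance is zero in both groups,
    p = 1.0 when the group means are equal and p = 0.0 otherwise.
    """
    s = np.asarray(soma_values, dtype=float)
    g = np.asarray(gonidia_values, dtype=float)
    if (s < 0).any() or (g < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if len(s) < 2 or len(g) < 2:
        raise ValueError("need >=2 replicates per cell type for the test")
    ls = np.log2(s + 1.0)
    lg = np.log2(g + 1.0)
    n1, n2 = len(ls), len(lg)
    ss1 = float(((ls - ls.mean()) ** 2).sum())
    ss2 = float(((lg - lg.mean()) ** 2).sum())
    if ss1 == 0.0 and ss2 == 0.0:
        return 1.0 if ls.mean() == lg.mean() else 0.0
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    t = (ls.mean() - lg.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), df))


def isoform_cell_type_stats(
    table: ExpressionTable,
    transcript_id: str,
    thresholds: Thresholds = Thresholds(),
    run_test: bool = True,
) -> IsoformStats:
    """Cell-type means, expression ratio and p-value for one transcript."""
    soma = table.transcript_values(transcript_id, "soma")
    gonidia = table.transcript_values(transcript_id, "gonidia")
    eps = thresholds.pseudocount
    mean_s = float(soma.mean())
    mean_g = float(gonidia.mean())
    er = (mean_s + eps) / (mean_g + eps)
    p = two_group_isoform_test(soma, gonidia) if run_test else None
    return IsoformStats(
        transcript_id=transcript_id,
        mean_soma=mean_s,
        mean_gonidia=mean_g,
        ER=er,
        log2ER=math.log2(er),
        p_value=p,
    )


def apply_filter_cascade(
    gene_id: str,
    stats_pair: Sequence[IsoformStats],
    thresholds: Thresholds = Thresholds(),
    source: str = "ballgown",
) -> CandidateRecord:
    """Apply the three sequential filters to a gene's two isoforms."""
    if len(stats_pair) != 2:
        raise ValueError(
            f"gene {gene_id}: cascade requires exactly 2 isoforms, "
            f"got {len(stats_pair)}"
        )
    iso1, iso2 = sorted(
        stats_pair, key=lambda s: (-s.ER, s.transcript_id)
    )  # iso1 = higher ER, so B >= 1 regardless of orientation
    th = thresholds
    stage1 = iso1.ER > th.tau_bias and iso2.ER < 1.0 / th.tau_bias
    b = iso1.ER / iso2.ER
    stage2 = stage1 and b > th.tau_B
    if iso1.p_value is None or iso2.p_value is None:
        agg = None
        stage3 = False
    else:
        agg = iso1.p_value * iso2.p_value
        stage3 = stage2 and iso1.p_value < th.tau_p and iso2.p_value < th.tau_p
    return CandidateRecord(
        gene_id=gene_id,
        source=source,
        iso1=iso1,
        iso2=iso2,
        B=b,
        aggregate_p=agg,
        passed_stage1=stage1,
        passed_stage2=stage2,
        passed_stage3=stage3,
        verdict="candidate" if stage3 else "rejected",
    )


def run_detection(
    table: ExpressionTable,
    models: Sequence[GeneModel],
    census: CensusResult,
    thresholds: Thresholds = Thresholds(),
    source: str = "ballgown",
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Run the cascade over every expressed two-isoform gene.

    Returns the per-gene records (gene_id order) and the funnel counts
    for each stage.
    """
    by_gene = {g.gene_id: g for g in models}
    records: list[CandidateRecord] = []
    for gene_id in sorted(census.two_isoform_genes):
        gene = by_gene.get(gene_id)
        if gene is None:
            raise ConsistencyError(f"two-isoform gene {gene_id} has no model")
        pair = [
            isoform_cell_type_stats(table, t.transcript_id, thresholds)
            for t in gene.transcripts
        ]
        records.append(apply_filter_cascade(gene_id, pair, thresholds, source))
    funnel = {
        "two_isoform_genes": len(records),
        "stage1_opposite_bias": sum(r.passed_stage1 for r in records),
        "stage2_combined_bias": sum(r.passed_stage2 for r in records),
        "stage3_significant": sum(r.passed_stage3 for r in records),
        "candidates": sum(r.verdict == "candidate" for r in records),
    }
    return records, funnel
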