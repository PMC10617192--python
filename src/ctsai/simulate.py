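"""Synthetic two-cell-type expression datasets with planted ground truth.

The generator emulates the statistical structure of a germ/soma bulk
RNA-seq comparison: two cell types with a small number of replicates,
log-normally distributed baseline FPKM, multiplicative log-normal
replicate noise, genes carrying one to a few isoforms, a planted subset
of genes whose two isoforms have opposite cell-type biases, and planted
adjacent gene pairs transcribed convergently with overlapping 3' ends.
It does not simulate reads, positional coverage bias, or library-size
artifacts — coverage tracks are idealized piecewise-constant depth
proportional to FPKM.

Planted switch genes get exactly two isoforms that differ by at least one
exon, cycling through three architectures observed for validated switch
loci: an extra 3'-terminal exon, an alternative first exon, and an
internal start with a unique alternative 5' exon.

All three generators are deterministic given ``SimulationParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    ConsistencyError,
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    SampleDesign,
    TranscriptModel,
)

CTSAI = "ctsai"
CONV_SOMA = "convergent_partner_soma"
CONV_GONIDIA = "convergent_partner_gonidia"
NULL_SINGLE = "null_single_isoform"
NULL_MULTI = "null_multi_isoform"

_CHROM = "chrS1"
_EXON = 200          # exon length, bp
_INTRON = 100        # intron length, bp
_SPACING = 1000      # intergenic spacing, bp
_CONV_LOCUS = 1200   # per-partner locus width in a convergent pair, bp


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the simulator.

    Defaults mirror the structure of the germ/soma comparison the
    pipeline was designed for: duplicate samples per cell type, a
    baseline FPKM distribution with median ~20 FPKM (log-normal, natural
    log mean 3, sd 1), 20% replicate noise, ~89% of genes single-isoform,
    a four-fold-per-isoform planted switch effect (|log2 ER| = 2 per
    isoform, 16-fold between isoforms), and a 50-bp 3' overlap for
    planted convergent pairs.
    """

    n_genes: int = 200
    isoform_count_distribution: tuple[float, ...] = (0.89, 0.087, 0.023)
    n_ctsai: int = 20
    n_convergent_pairs: int = 2
    effect_log2: float = 2.0
    baseline_fpkm_log_mean: float = 3.0
    baseline_fpkm_log_sd: float = 1.0
    replicate_cv: float = 0.2
    replicates_per_cell_type: int = 2
    convergent_overlap: int = 50
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.isoform_count_distribution, dtype=float)
        if p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError(
                "isoform_count_distribution must be a probability vector"
            )
        if self.n_ctsai + 2 * self.n_convergent_pairs > self.n_genes:
            raise ParameterError(
                "planted genes exceed n_genes: "
                f"{self.n_ctsai} + 2*{self.n_convergent_pairs} > {self.n_genes}"
            )
        if self.effect_log2 < 0:
            raise ParameterError("effect_log2 must be >= 0")
        if self.replicate_cv < 0:
            raise ParameterError("replicate_cv must be >= 0")
        if self.replicates_per_cell_type < 2:
            raise ParameterError("need >=2 replicates per cell type")
        if not (0 < self.convergent_overlap <= _EXON):
            raise ParameterError(
                f"convergent_overlap must be in (0, {_EXON}]"
            )


@dataclass(frozen=True)
class TruthTable:
    """Planted label per generated gene."""

    labels: Mapping[str, str]

    def genes_with(self, label: str) -> set[str]:
        return {g for g, lab in self.labels.items() if lab == label}

    @property
    def ctsai_genes(self) -> set[str]:
        return self.genes_with(CTSAI)


def _null_gene(gene_id: str, x: int, k: int) -> tuple[GeneModel, int]:
    """Gene with k isoforms built from a chain of exons; isoform i>0 drops
    exon i so every pair of isoforms differs."""
    n_exons = 2 if k == 1 else k + 1
    chain = [
        (x + j * (_EXON + _INTRON), x + j * (_EXON + _INTRON) + _EXON)
        for j in range(n_exons)
    ]
    transcripts = []
    for i in range(k):
        exons = chain if i == 0 else chain[:i] + chain[i + 1:]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{i + 1}", gene_id=gene_id,
                chrom=_CHROM, strand="+", exons=tuple(exons),
            )
        )
    gene = GeneModel(gene_id, _CHROM, "+", tuple(transcripts))
    return gene, chain[-1][1]


def _ctsai_gene(gene_id: str, x: int, architecture: int) -> tuple[GeneModel, int]:
    """Two isoforms differing by >=1 exon; architecture cycles through
    extra 3' exon / alternative first exon / internal alternative start."""
    step = _EXON + _INTRON
    e = lambda j: (x + j * step, x + j * step + _EXON)
    if architecture % 3 == 0:
        # extra 3'-terminal exon on isoform 1, spliced from an internal
        # site that truncates the shared last exon (so both isoforms keep
        # a unique differential region)
        iso1 = (e(0), e(1), (e(2)[0], e(2)[0] + 120), e(3))
        iso2 = (e(0), e(1), e(2))
        end = e(3)[1]
    elif architecture % 3 == 1:  # alternative first exons
        a1 = (x, x + 120)
        b1 = (x + 150, x + 270)
        shared = (e(2), e(3))
        iso1 = (a1,) + shared
        iso2 = (b1,) + shared
        end = e(3)[1]
    else:  # internal start: unique alternative 5' exon inside intron 1
        u = (x + _EXON + 20, x + _EXON + 80)
        iso1 = (e(0), e(1), e(2))
        iso2 = (u, e(1), e(2))
        end = e(2)[1]
    transcripts = tuple(
        TranscriptModel(
            transcript_id=f"{gene_id}.t{i + 1}", gene_id=gene_id,
            chrom=_CHROM, strand="+", exons=exons,
        )
        for i, exons in enumerate((iso1, iso2))
    )
    return GeneModel(gene_id, _CHROM, "+", transcripts), end


def _convergent_pair(
    id_a: str, id_b: str, x: int, overlap: int
) -> tuple[GeneModel, GeneModel, int]:
    """Adjacent genes on opposite strands whose 3'-most exons overlap."""
    L = _CONV_LOCUS
    a_exons = ((x, x + _EXON), (x + L - 250, x + L))
    b_start = x + L - overlap
    b_exons = ((b_start, b_start + 250), (x + 2 * L - overlap - _EXON,
                                          x + 2 * L - overlap))
    gene_a = GeneModel(
        id_a, _CHROM, "+",
        (TranscriptModel(f"{id_a}.t1", id_a, _CHROM, "+", a_exons),),
    )
    gene_b = GeneModel(
        id_b, _CHROM, "-",
        (TranscriptModel(f"{id_b}.t1", id_b, _CHROM, "-", b_exons),),
    )
    return gene_a, gene_b, x + 2 * L - overlap


def generate_annotation(
    params: SimulationParams,
) -> tuple[list[GeneModel], TruthTable]:
    """Lay genes on one synthetic chromosome and emit the truth labels."""
    rng = np.random.default_rng(params.seed)
    # units: convergent pairs occupy two adjacent slots, everything else one
    units: list[str] = (
        ["conv"] * params.n_convergent_pairs
        + [CTSAI] * params.n_ctsai
        + ["null"] * (params.n_genes - params.n_ctsai
                      - 2 * params.n_convergent_pairs)
    )
    rng.shuffle(units)
    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    x = _SPACING
    idx = 0
    ctsai_arch = 0
    for unit in units:
        if unit == "conv":
            id_a = f"g{idx + 1:04d}"
            id_b = f"g{idx + 2:04d}"
            ga, gb, end = _convergent_pair(
                id_a, id_b, x, params.convergent_overlap
            )
            genes += [ga, gb]
            labels[id_a] = CONV_SOMA
            labels[id_b] = CONV_GONIDIA
            idx += 2
        else:
            gene_id = f"g{idx + 1:04d}"
            if unit == CTSAI:
                gene, end = _ctsai_gene(gene_id, x, ctsai_arch)
                ctsai_arch += 1
                labels[gene_id] = CTSAI
            else:
                k = 1 + int(
                    rng.choice(
                        len(params.isoform_count_distribution),
                        p=params.isoform_count_distribution,
                    )
                )
                gene, end = _null_gene(gene_id, x, k)
                labels[gene_id] = NULL_SINGLE if k == 1 else NULL_MULTI
            genes.append(gene)
            idx += 1
        x = end + _SPACING
    if params.chrom_length is not None and x > params.chrom_length:
        raise ParameterError(
            f"layout needs {x} bp but chrom_length is {params.chrom_length}"
        )
    return genes, TruthTable(labels)


def generate_expression(
    models: Sequence[GeneModel],
    truth: TruthTable,
    params: SimulationParams,
) -> ExpressionTable:
    """Per-transcript FPKM with planted cell-type effects and noise.

    Each transcript draws a log-normal baseline mean; planted switch
    genes put isoform 1 at mean*2**effect in soma and mean*2**(-effect)
    in gonidia with isoform 2 reversed; convergent partners carry a
    whole-transcript bias with opposite signs within the pair; null genes
    share one mean.  Replicate values multiply the mean by log-normal
    noise with the configured coefficient of variation (mean-corrected,
    so CV=0 reproduces the means exactly).
    """
    model_genes = {g.gene_id for g in models}
    if model_genes != set(truth.labels):
        raise ConsistencyError("models and truth table cover different genes")
    rng = np.random.default_rng((params.seed, 1))
    design = SampleDesign.paired(params.replicates_per_cell_type)
    n_rep = params.replicates_per_cell_type
    sigma = float(np.sqrt(np.log1p(params.replicate_cv ** 2)))
    eff = 2.0 ** params.effect_log2

    rows: dict[str, np.ndarray] = {}
    gene_map: dict[str, str] = {}
    for gene in sorted(models, key=lambda g: g.gene_id):
        label = truth.labels[gene.gene_id]
        for i, t in enumerate(gene.transcripts):
            mu = float(rng.lognormal(
                params.baseline_fpkm_log_mean, params.baseline_fpkm_log_sd
            ))
            if label == CTSAI:
                if i == 0:
                    m_soma, m_gon = mu * eff, mu / eff
                else:
                    m_soma, m_gon = mu / eff, mu * eff
            elif label == CONV_SOMA:
                m_soma, m_gon = mu * eff, mu / eff
            elif label == CONV_GONIDIA:
                m_soma, m_gon = mu / eff, mu * eff
            else:
                m_soma = m_gon = mu
            if sigma == 0.0:
                noise = np.ones(2 * n_rep)
            else:
                noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, 2 * n_rep)
            vals = np.concatenate(
                [m_soma * noise[:n_rep], m_gon * noise[n_rep:]]
            )
            rows[t.transcript_id] = vals
            gene_map[t.transcript_id] = gene.gene_id
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(design.sample_ids)
    )
    return ExpressionTable(values, gene_map, design)


def generate_coverage(
    models: Sequence[GeneModel],
    expression: ExpressionTable,
    depth_per_fpkm: float = 2.0,
) -> CoverageTrack:
    """Idealized per-base depth: each transcript deposits
    round(cell-type mean FPKM * depth_per_fpkm) over its exons,
    strand-agnostic; overlapping transcripts add."""
    if depth_per_fpkm <= 0:
        raise ValueError("depth_per_fpkm must be positive")
    table_tx = set(expression.transcript_ids)
    model_tx = {t.transcript_id for g in models for t in g.transcripts}
    if not table_tx <= model_tx:
        raise ConsistencyError(
            "expression table contains transcripts absent from models"
        )
    lengths: dict[str, int] = {}
    for g in models:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.span[1] + _SPACING)
    depths = {
        ct: {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
        for ct in ("soma", "gonidia")
    }
    for gene in models:
        for t in gene.transcripts:
            if t.transcript_id not in table_tx:
                continue
            for ct in ("soma", "gonidia"):
                mean_fpkm = float(
                    expression.transcript_values(t.transcript_id, ct).mean()
                )
                d = float(np.rint(mean_fpkm * depth_per_fpkm))
                if d == 0:
                    continue
                arr = depths[ct][t.chrom]
                for s, e in t.exons:
                    arr[s:e] += d
    return CoverageTrack(depths)


def simulate_dataset(
    params: SimulationParams, depth_per_fpkm: float = 2.0
) -> tuple[list[GeneModel], TruthTable, ExpressionTable, CoverageTrack]:
    """Convenience: annotation + expression + coverage in one call."""
    models, truth = generate_annotation(params)
    table = generate_expression(models, truth, params)
    coverage = generate_coverage(models, table, depth_per_fpkm)
    return models, truth, table, coverage
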