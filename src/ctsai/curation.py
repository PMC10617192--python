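"""Quantitative curation of isoform-switch candidates.

The original screen was applied by eye on genome-browser coverage tracks;
this module formalizes it as three ordered checks:

RD (read density)
    each isoform's unique (differential) regions must be sufficiently
    covered in the cell type where that isoform is claimed expressed:
    mean depth >= ``min_mean_depth`` (inclusive — the cutoff is
    artifact-defined) and fraction of covered bases >= ``min_covered_fraction``.

REL (relative expression level)
    the isoform-specific signal, normalized by the shared-region signal,
    must switch direction between cell types; a pure whole-gene
    expression difference cancels under the normalization and scores 0.

CT (convergent transcription)
    candidates sitting in a convergent overlapping gene pair — adjacent
    loci on opposite strands whose 3'-most exons overlap — are artifacts
    of unstranded assembly, not alternative isoforms, and are excluded.

A candidate is retained iff RD and REL pass and it is not CT-flagged;
the exclusion reason is the first failing check in RD, REL, CT order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .detect import CandidateRecord
from .models import ConsistencyError, CoverageTrack, GeneModel, TranscriptModel

Interval = tuple[int, int]


def _union(intervals: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    b = list(b)
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass(frozen=True)
class DifferentialRegions:
    """Exonic bases unique to each isoform and shared by both."""

    gene_id: str
    chrom: str
    unique_to_iso1: tuple[Interval, ...]
    unique_to_iso2: tuple[Interval, ...]
    shared: tuple[Interval, ...]


@dataclass(frozen=True)
class CurationResult:
    gene_id: str
    rd_pass: bool
    rel_pass: bool
    rel_score: float | None
    convergent_flag: bool
    final: str  # retained | excluded_RD | excluded_REL | excluded_CT


def differential_regions(
    iso1: TranscriptModel, iso2: TranscriptModel
) -> DifferentialRegions:
    """Exact set differences and intersection of two isoforms' exonic unions."""
    if iso1.chrom != iso2.chrom:
        raise ConsistencyError(
            f"{iso1.transcript_id} on {iso1.chrom} but "
            f"{iso2.transcript_id} on {iso2.chrom}"
        )
    if iso1.gene_id != iso2.gene_id:
        raise ConsistencyError(
            f"{iso1.transcript_id} and {iso2.transcript_id} belong to "
            "different genes"
        )
    u1 = _union(iso1.exons)
    u2 = _union(iso2.exons)
    return DifferentialRegions(
        gene_id=iso1.gene_id,
        chrom=iso1.chrom,
        unique_to_iso1=tuple(_subtract(u1, u2)),
        unique_to_iso2=tuple(_subtract(u2, u1)),
        shared=tuple(_intersect(u1, u2)),
    )


@dataclass(frozen=True)
class ReadDensityResult:
    iso1_pass: bool
    iso2_pass: bool
    rd_pass: bool


def read_density_check(
    coverage: CoverageTrack,
    regions: DifferentialRegions,
    claimed: Mapping[str, str],
    min_mean_depth: float = 5.0,
    min_covered_fraction: float = 0.8,
) -> ReadDensityResult:
    """Check coverage support for each isoform's unique regions.

    ``claimed`` maps 'iso1'/'iso2' to the cell type where that isoform is
    claimed expressed (from the sign of its expression ratio).  An
    isoform with no unique region cannot be density-checked and fails:
    there is no independent evidence for a distinct structure.
    """
    passes = {}
    for key, unique in (
        ("iso1", regions.unique_to_iso1), ("iso2", regions.unique_to_iso2)
    ):
        cell_type = claimed[key]
        if not unique:
            passes[key] = False
            continue
        mean = coverage.mean_depth(cell_type, regions.chrom, unique)
        frac = coverage.covered_fraction(cell_type, regions.chrom, unique)
        passes[key] = mean >= min_mean_depth and frac >= min_covered_fraction
    return ReadDensityResult(
        iso1_pass=passes["iso1"],
        iso2_pass=passes["iso2"],
        rd_pass=passes["iso1"] and passes["iso2"],
    )


def relative_support_score(
    coverage: CoverageTrack,
    regions: DifferentialRegions,
    min_rel: float = 2.0,
    pseudodepth: float = 0.5,
) -> tuple[float | None, bool]:
    """Shared-normalized isoform-specific depth switch between cell types.

    For cell type c let u1(c), u2(c), s(c) be mean depths over the
    regions unique to isoform 1, unique to isoform 2, and shared
    (``pseudodepth`` added to every mean).  The score is

        log2[(u1(soma)/s(soma)) / (u1(gonidia)/s(gonidia))]
      - log2[(u2(soma)/s(soma)) / (u2(gonidia)/s(gonidia))]

    and passes iff |score| >= min_rel and the two bracketed log terms
    have strictly opposite signs.  Scaling one cell type's whole track by
    a constant cancels (up to pseudodepth), so a pure overall expression
    difference between cell types scores 0.
    """
    if not regions.shared:
        return None, False
    eps = pseudodepth

    def mean(cell_type: str, ivs: Sequence[Interval]) -> float:
        return coverage.mean_depth(cell_type, regions.chrom, ivs) + eps

    terms = []
    for unique in (regions.unique_to_iso1, regions.unique_to_iso2):
        ratio_s = mean("soma", unique) / mean("soma", regions.shared)
        ratio_g = mean("gonidia", unique) / mean("gonidia", regions.shared)
        terms.append(math.log2(ratio_s / ratio_g))
    score = terms[0] - terms[1]
    opposite = (terms[0] > 0 > terms[1]) or (terms[0] < 0 < terms[1])
    return score, abs(score) >= min_rel and opposite


def detect_convergent_pairs(
    models: Sequence[GeneModel],
    gene_er: Mapping[str, float] | None = None,
    min_overlap: int = 1,
    tau_bias: float = 2.0,
) -> list[tuple[str, str, int, bool]]:
    """Find adjacent opposite-strand genes whose 3' ends overlap.

    A pair qualifies when the exonic spans of two distinct genes on
    opposite strands overlap by at least ``min_overlap`` bases and the
    overlap interval intersects the 3'-most exon of each partner (so
    divergent 5' overlaps are excluded).  ``opposite_bias`` is True when
    one gene's soma/gonidia expression ratio exceeds ``tau_bias`` and the
    other's is below 1/``tau_bias`` (requires ``gene_er``).

    Output is sorted by position and symmetric in gene order.
    """
    pairs: list[tuple[str, str, int, bool]] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in sorted(by_chrom.items()):
        genes = sorted(genes, key=lambda g: (g.span[0], g.gene_id))
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:]:
                if gb.span[0] >= ga.span[1]:
                    break
                if ga.strand == gb.strand:
                    continue
                ov_start = max(ga.span[0], gb.span[0])
                ov_end = min(ga.span[1], gb.span[1])
                overlap = ov_end - ov_start
                if overlap < min_overlap:
                    continue
                if not _pair_overlap_is_3prime(ga, gb, (ov_start, ov_end)):
                    continue
                opposite = False
                if gene_er is not None:
                    ers = (gene_er.get(ga.gene_id), gene_er.get(gb.gene_id))
                    if None not in ers:
                        hi, lo = max(ers), min(ers)
                        opposite = hi > tau_bias and lo < 1.0 / tau_bias
                a_id, b_id = sorted((ga.gene_id, gb.gene_id))
                pairs.append((a_id, b_id, overlap, opposite))
    return pairs


def _pair_overlap_is_3prime(
    ga: GeneModel, gb: GeneModel, ov: Interval
) -> bool:
    for gene in (ga, gb):
        hit = False
        for t in gene.transcripts:
            ts, te = t.three_prime_exon
            if max(ts, ov[0]) < min(te, ov[1]):
                hit = True
                break
        if not hit:
            return False
    return True


def curate(
    records: Sequence[CandidateRecord],
    models: Sequence[GeneModel],
    coverage: CoverageTrack,
    min_mean_depth: float = 5.0,
    min_covered_fraction: float = 0.8,
    min_rel: float = 2.0,
    pseudodepth: float = 0.5,
    min_overlap: int = 1,
    tau_bias: float = 2.0,
    reference_models: Sequence[GeneModel] | None = None,
) -> tuple[list[CurationResult], dict[str, int]]:
    """Apply RD, REL and CT to every candidate; report the funnel.

    ``models`` are the gene models the candidates were called on (which
    for a mis-assembled convergent locus is a fused two-"isoform" model);
    ``reference_models`` is a strand-aware reference annotation in which
    convergent pairs are detected (defaults to ``models``).  A candidate
    is CT-flagged when its span overlaps both members of a detected
    convergent pair — the geometry alone marks the "isoform" call as a
    mis-assembled convergent locus, whether or not the pair also shows
    opposite bias.
    """
    by_gene = {g.gene_id: g for g in models}
    reference = list(reference_models) if reference_models is not None else list(models)
    ref_by_gene = {g.gene_id: g for g in reference}
    pairs = detect_convergent_pairs(reference, None, min_overlap=min_overlap,
                                    tau_bias=tau_bias)

    def _ct_flagged(gene: GeneModel) -> bool:
        gs, ge = gene.span
        for a, b, _, _ in pairs:
            ga, gb = ref_by_gene[a], ref_by_gene[b]
            if ga.chrom != gene.chrom:
                continue
            if (max(gs, ga.span[0]) < min(ge, ga.span[1])
                    and max(gs, gb.span[0]) < min(ge, gb.span[1])):
                return True
        return False

    results: list[CurationResult] = []
    counts = {"retained": 0, "excluded_RD": 0, "excluded_REL": 0,
              "excluded_CT": 0}
    for rec in records:
        gene = by_gene.get(rec.gene_id)
        if gene is None:
            raise ConsistencyError(f"candidate {rec.gene_id} has no model")
        ct_flag = _ct_flagged(gene)
        if gene.n_isoforms == 2:
            iso_models = {
                t.transcript_id: t for t in gene.transcripts
            }
            t1 = iso_models.get(rec.iso1.transcript_id)
            t2 = iso_models.get(rec.iso2.transcript_id)
            if t1 is None or t2 is None:
                raise ConsistencyError(
                    f"candidate {rec.gene_id}: record transcripts not in model"
                )
            regions = differential_regions(t1, t2)
            claimed = {
                "iso1": "soma" if rec.iso1.ER >= 1.0 else "gonidia",
                "iso2": "soma" if rec.iso2.ER >= 1.0 else "gonidia",
            }
            rd = read_density_check(
                coverage, regions, claimed, min_mean_depth,
                min_covered_fraction,
            ).rd_pass
            rel_score, rel = relative_support_score(
                coverage, regions, min_rel, pseudodepth
            )
        else:
            # single-transcript "gene" (e.g. a convergent partner): no
            # isoform pair to support
            rd, rel, rel_score = False, False, None
        if not rd:
            final = "excluded_RD"
        elif not rel:
            final = "excluded_REL"
        elif ct_flag:
            final = "excluded_CT"
        else:
            final = "retained"
        counts[final] += 1
        results.append(
            CurationResult(
                gene_id=rec.gene_id, rd_pass=rd, rel_pass=rel,
                rel_score=rel_score, convergent_flag=ct_flag, final=final,
            )
        )
    counts["input"] = len(records)
    return results, counts
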