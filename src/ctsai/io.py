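"""Readers and writers for the external formats the pipeline consumes.

GFF3 comes in 1-based inclusive and is converted to internal 0-based
half-open intervals at this boundary; bedGraph is already half-open.
The expression TSV dialect is canonical: ``transcript_id``, ``gene_id``,
then one FPKM column per sample in the design.  This is a deliberate
simplification of Ballgown's ``t_data.ctab`` (whose ``t_name``/``gene_id``
and ``FPKM.<sample>`` columns map 1:1 onto it) — the analysis needs only
the transcript-to-gene mapping and the FPKM matrix.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .models import (
    ConsistencyError,
    CoverageTrack,
    DomainTable,
    ExpressionTable,
    GeneModel,
    OrthologMap,
    SampleDesign,
    TranscriptModel,
)

if TYPE_CHECKING:  # pragma: no cover
    from .detect import CandidateRecord


class GFF3ParseError(ValueError):
    pass


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into GeneModels.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons are grouped under their parent transcript and transcripts under
    their parent gene via ID/Parent attributes.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    transcript_ids = {
        f.id for t in _TRANSCRIPT_TYPES for f in db.features_of_type(t)
    }
    gene_ids = {f.id for f in db.features_of_type("gene")}

    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise GFF3ParseError(
                f"exon {exon.start}-{exon.end} on {exon.seqid} has no Parent"
            )
        for parent in parents:
            if parent not in transcript_ids:
                raise GFF3ParseError(
                    f"exon {exon.start}-{exon.end} on {exon.seqid}: Parent "
                    f"{parent!r} is not an mRNA/transcript feature"
                )
            exons_by_tx.setdefault(parent, []).append(
                (exon.start - 1, exon.end)  # 1-based inclusive -> half-open
            )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for ttype in _TRANSCRIPT_TYPES:
            for mrna in db.children(gene, featuretype=ttype):
                parents = mrna.attributes.get("Parent", [])
                if gene.id not in parents:
                    raise GFF3ParseError(
                        f"transcript {mrna.id}: Parent does not name gene "
                        f"{gene.id}"
                    )
                exons = sorted(exons_by_tx.get(mrna.id, []))
                if not exons:
                    raise GFF3ParseError(f"transcript {mrna.id} has no exons")
                source = mrna.attributes.get("source_tag", [mrna.source])[0]
                try:
                    transcripts.append(
                        TranscriptModel(
                            transcript_id=mrna.id,
                            gene_id=gene.id,
                            chrom=mrna.seqid,
                            strand=mrna.strand,
                            exons=tuple(exons),
                            source=source,
                        )
                    )
                except ValueError as exc:
                    raise GFF3ParseError(str(exc)) from exc
        if not transcripts:
            raise GFF3ParseError(f"gene {gene.id} has no transcripts")
        genes.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                transcripts=tuple(transcripts),
            )
        )
    # orphan transcripts (Parent gene missing from file)
    for tid in transcript_ids:
        parent = db[tid].attributes.get("Parent", [None])[0]
        if parent not in gene_ids:
            raise GFF3ParseError(
                f"transcript {tid}: Parent {parent!r} is not a gene feature"
            )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels back out as gene/mRNA/exon GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\tctsai\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}"
                f"\t.\tID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                ts, te = t.span
                fh.write(
                    f"{t.chrom}\t{t.source}\tmRNA\t{ts + 1}\t{te}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, (es, ee) in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.chrom}\t{t.source}\texon\t{es + 1}\t{ee}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


def read_expression_tsv(
    path: str | os.PathLike, design: SampleDesign
) -> ExpressionTable:
    """Read the canonical transcript-level FPKM table.

    Columns: transcript_id, gene_id, then one column per sample in
    ``design`` (any order; reordered to design order).  Missing values and
    negative FPKM are hard errors — the upstream tables are complete and
    silent imputation would corrupt expression ratios.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    for col in ("transcript_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"expression TSV lacks required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("transcript_id", "gene_id")]
    if set(sample_cols) != set(design.sample_ids):
        raise ConsistencyError(
            f"expression columns {sorted(sample_cols)} do not match design "
            f"samples {sorted(design.sample_ids)}"
        )
    values = df.set_index("transcript_id")[list(design.sample_ids)]
    if values.isna().any().any():
        raise ValueError("expression TSV contains missing FPKM values")
    gene_map = dict(zip(df["transcript_id"], df["gene_id"]))
    return ExpressionTable(values, gene_map, design)


def write_expression_tsv(
    table: ExpressionTable, path: str | os.PathLike
) -> None:
    df = table.values.copy()
    df.insert(0, "gene_id", [table.gene_map[t] for t in df.index])
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_bedgraph(
    paths: Mapping[str, str | os.PathLike],
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Read one bedGraph per cell type into per-base depth arrays.

    bedGraph intervals are 0-based half-open already.  Arrays are sized to
    ``chrom_lengths`` when given, otherwise to the largest end seen.
    """
    depths: dict[str, dict[str, np.ndarray]] = {}
    for cell_type, path in paths.items():
        rows = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "depth"],
        )
        by_chrom: dict[str, np.ndarray] = {}
        for chrom, grp in rows.groupby("chrom"):
            length = (
                chrom_lengths[chrom] if chrom_lengths else int(grp["end"].max())
            )
            arr = np.zeros(length, dtype=float)
            for _, r in grp.iterrows():
                arr[int(r["start"]):int(r["end"])] += r["depth"]
            by_chrom[str(chrom)] = arr
        depths[cell_type] = by_chrom
    return CoverageTrack(depths)


def write_bedgraph(
    track: CoverageTrack, cell_type: str, path: str | os.PathLike
) -> None:
    """Write one cell type's depth arrays as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths[cell_type]):
            arr = track.depths[cell_type][chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                d = arr[s]
                if d != 0:
                    dstr = f"{int(d)}" if float(d).is_integer() else f"{d:g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{dstr}\n")


def read_pairs_tsv(
    path: str | os.PathLike, kind: str = "ortholog"
) -> OrthologMap | DomainTable:
    """Read a two-column TSV as an OrthologMap or a DomainTable.

    ``kind='ortholog'``: rows are (gene_A, gene_B); duplicates violating
    the 1:1 property are an error.  ``kind='domain'``: rows are
    (gene_id, PFAM accession); duplicate rows collapse into a set.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"expected two columns, got: {line!r}")
            pairs.append((fields[0], fields[1]))
    if kind == "ortholog":
        return OrthologMap(tuple(pairs))
    if kind == "domain":
        records: dict[str, set[str]] = {}
        for gene, acc in pairs:
            records.setdefault(gene, set()).add(acc)
        return DomainTable({g: frozenset(a) for g, a in records.items()})
    raise ValueError(f"unknown kind {kind!r}")


_REPORT_COLUMNS = [
    "gene_id", "source",
    "iso1_id", "iso1_mean_soma", "iso1_mean_gonidia", "iso1_ER",
    "iso1_log2ER", "iso1_p",
    "iso2_id", "iso2_mean_soma", "iso2_mean_gonidia", "iso2_ER",
    "iso2_log2ER", "iso2_p",
    "B", "aggregate_p",
    "passed_stage1", "passed_stage2", "passed_stage3", "verdict",
]


def write_candidate_report(
    records: Iterable["CandidateRecord"], path: str | os.PathLike
) -> None:
    """Write per-gene candidate records as a deterministic TSV.

    Rows sorted by gene_id; "." marks not-applicable fields; writing the
    same records twice yields byte-identical files.
    """
    rows = []
    for rec in sorted(records, key=lambda r: r.gene_id):
        row = {
            "gene_id": rec.gene_id,
            "source": rec.source,
            "B": _fmt(rec.B),
            "aggregate_p": _fmt(rec.aggregate_p),
            "passed_stage1": str(rec.passed_stage1),
            "passed_stage2": str(rec.passed_stage2),
            "passed_stage3": str(rec.passed_stage3),
            "verdict": rec.verdict,
        }
        for label, iso in (("iso1", rec.iso1), ("iso2", rec.iso2)):
            row[f"{label}_id"] = iso.transcript_id
            row[f"{label}_mean_soma"] = _fmt(iso.mean_soma)
            row[f"{label}_mean_gonidia"] = _fmt(iso.mean_gonidia)
            row[f"{label}_ER"] = _fmt(iso.ER)
            row[f"{label}_log2ER"] = _fmt(iso.log2ER)
            row[f"{label}_p"] = _fmt(iso.p_value)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _fmt(x: float | None) -> str:
    return "." if x is None else f"{x:.6g}"
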