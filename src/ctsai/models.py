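"""Canonical in-memory data model shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from 1-based inclusive GFF3 happens only at format boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CELL_TYPES = ("soma", "gonidia")

_PFAM_RE = re.compile(r"^PF\d{5}$")


class ConsistencyError(ValueError):
    """Raised when linked objects (models, tables, tracks) disagree."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exon intervals on one strand.

    Exons are 0-based half-open, sorted, non-overlapping, all on one
    chromosome.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty or inverted exon "
                    f"[{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    f"unsorted at [{start}, {end})"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def three_prime_exon(self) -> tuple[int, int]:
        """The 3'-most exon: last exon on '+', first on '-'."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ConsistencyError(
                    f"transcript {t.transcript_id} has gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )
            if t.chrom != self.chrom:
                raise ConsistencyError(
                    f"transcript {t.transcript_id} on {t.chrom}, gene on "
                    f"{self.chrom}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet: which replicate of which cell type each column is."""

    samples: tuple[tuple[str, str, int], ...]  # (sample_id, cell_type, replicate)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for _, ct, rep in self.samples:
            if ct not in CELL_TYPES:
                raise ValueError(f"unknown cell type {ct!r}")
            if rep < 1:
                raise ValueError("replicate index must be positive")
        for ct in CELL_TYPES:
            if not any(s[1] == ct for s in self.samples):
                raise ValueError(f"design has no {ct} samples")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.samples)

    def samples_of(self, cell_type: str) -> tuple[str, ...]:
        return tuple(s[0] for s in self.samples if s[1] == cell_type)

    def swapped(self) -> "SampleDesign":
        """Relabel soma <-> gonidia (used by symmetry checks)."""
        flip = {"soma": "gonidia", "gonidia": "soma"}
        return SampleDesign(
            tuple((sid, flip[ct], rep) for sid, ct, rep in self.samples)
        )

    @staticmethod
    def paired(replicates_per_cell_type: int = 2) -> "SampleDesign":
        """A standard design: n replicates of each cell type."""
        samples = []
        for ct in CELL_TYPES:
            for r in range(1, replicates_per_cell_type + 1):
                samples.append((f"{ct}_{r}", ct, r))
        return SampleDesign(tuple(samples))


class ExpressionTable:
    """Transcript x sample FPKM matrix with a transcript -> gene mapping."""

    def __init__(
        self,
        values: pd.DataFrame,
        gene_map: Mapping[str, str],
        design: SampleDesign,
    ) -> None:
        if list(values.columns) != list(design.sample_ids):
            raise ConsistencyError(
                "expression columns do not match design sample ids"
            )
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValueError("FPKM values must be finite")
        if (values.to_numpy(dtype=float) < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(values.index) - set(gene_map)
        if missing:
            raise ConsistencyError(
                f"transcripts without gene mapping: {sorted(missing)[:5]}"
            )
        self.values = values.astype(float)
        self.gene_map = dict(gene_map)
        self.design = design

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.values.index:
            seen.setdefault(self.gene_map[t], None)
        return list(seen)

    def transcripts_of(self, gene_id: str) -> list[str]:
        return [t for t in self.values.index if self.gene_map[t] == gene_id]

    def transcript_values(self, transcript_id: str, cell_type: str) -> np.ndarray:
        cols = self.design.samples_of(cell_type)
        return self.values.loc[transcript_id, list(cols)].to_numpy(dtype=float)

    def gene_sums(self) -> pd.DataFrame:
        """Per-gene FPKM: sum of transcript FPKM per sample."""
        genes = self.values.index.map(self.gene_map)
        return self.values.groupby(genes).sum()

    def with_design(self, design: SampleDesign) -> "ExpressionTable":
        return ExpressionTable(self.values, self.gene_map, design)


class CoverageTrack:
    """Per-base read depth per cell type: cell_type -> chrom -> int array."""

    def __init__(self, depths: Mapping[str, Mapping[str, np.ndarray]]) -> None:
        self.depths = {
            ct: {c: np.asarray(a) for c, a in by_chrom.items()}
            for ct, by_chrom in depths.items()
        }
        for ct, by_chrom in self.depths.items():
            for chrom, arr in by_chrom.items():
                if (arr < 0).any():
                    raise ValueError(f"negative depth on {chrom} ({ct})")

    def mean_depth(
        self, cell_type: str, chrom: str, intervals: Sequence[tuple[int, int]]
    ) -> float:
        """Mean depth over the union of intervals; 0.0 if intervals empty."""
        arr = self._array(cell_type, chrom, intervals)
        if arr.size == 0:
            return 0.0
        return float(arr.mean())

    def covered_fraction(
        self, cell_type: str, chrom: str, intervals: Sequence[tuple[int, int]]
    ) -> float:
        arr = self._array(cell_type, chrom, intervals)
        if arr.size == 0:
            return 0.0
        return float((arr > 0).mean())

    def scaled(self, cell_type: str, factor: float) -> "CoverageTrack":
        """Multiply one cell type's whole track by a constant."""
        new = {
            ct: {c: (a * factor if ct == cell_type else a.copy())
                 for c, a in by_chrom.items()}
            for ct, by_chrom in self.depths.items()
        }
        return CoverageTrack(new)

    def _array(
        self, cell_type: str, chrom: str, intervals: Sequence[tuple[int, int]]
    ) -> np.ndarray:
        try:
            track = self.depths[cell_type][chrom]
        except KeyError as exc:
            raise ConsistencyError(
                f"no coverage for {chrom} in cell type {cell_type}"
            ) from exc
        pieces = []
        for start, end in intervals:
            if start < 0 or end > len(track):
                raise ConsistencyError(
                    f"interval [{start}, {end}) outside coverage of {chrom} "
                    f"(length {len(track)})"
                )
            pieces.append(track[start:end])
        if not pieces:
            return np.empty(0)
        return np.concatenate(pieces)


@dataclass(frozen=True)
class OrthologMap:
    """1:1 ortholog pairs between two species; no gene appears twice."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a_ids = [p[0] for p in self.pairs]
        b_ids = [p[1] for p in self.pairs]
        for ids, side in ((a_ids, "A"), (b_ids, "B")):
            dup = {g for g in ids if ids.count(g) > 1}
            if dup:
                raise ValueError(
                    f"gene(s) {sorted(dup)} appear in more than one ortholog "
                    f"pair (species {side}); map must be 1:1"
                )


@dataclass(frozen=True)
class DomainTable:
    """gene_id -> set of PFAM accessions ('PFxxxxx')."""

    records: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, accs in self.records.items():
            for acc in accs:
                if not _PFAM_RE.match(acc):
                    raise ValueError(
                        f"{gene}: {acc!r} is not a PFAM accession (PFxxxxx)"
                    )

    def genes_with_any(self, accessions: Iterable[str]) -> set[str]:
        wanted = set(accessions)
        return {g for g, accs in self.records.items() if accs & wanted}
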