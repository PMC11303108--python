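"""Genomic file formats and the shared coordinate model.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GTF (1-based, closed) is converted on read and write; BED and narrowPeak are
native.  Transcription start sites are strand-aware: the TSS of a ``+`` gene
is ``start``, of a ``-`` gene ``end - 1``.

Formats handled: GTF gene features, BED3 / ENCODE narrowPeak, MatrixMarket
MTX triplets with barcode/gene TSVs, and plain FASTA.  Every reader has a
matching writer and the pair round-trips bit-exactly on valid input.
"""

from __future__ import annotations

import io
import os
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MARKS = ("TF", "H3K27ac", "H3K4me3", "H3K27me3", "IgG")
GROUPS = ("normal", "OIR")
TIMEPOINTS = ("P14", "P17")

_VALID_STRANDS = frozenset({"+", "-", "."})
_FASTA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file (carries the offending line number if known)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: str
    interval: GenomicInterval
    tss: int

    def __post_init__(self) -> None:
        iv = self.interval
        if iv.strand == "+":
            expected = iv.start
        elif iv.strand == "-":
            expected = iv.end - 1
        else:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"strand {iv.strand} interval [{iv.start},{iv.end})"
            )


class GeneTable:
    """Immutable collection of genes with strand-aware TSS coordinates.

    ``gene_id`` is the unique join key used by every downstream stage;
    duplicate IDs are fatal while duplicate human-readable names are allowed.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        recs = list(records)
        seen: set[str] = set()
        for r in recs:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene_id {r.gene_id!r}")
            seen.add(r.gene_id)
        self._records = tuple(recs)
        self._by_id = {r.gene_id: r for r in recs}

    @classmethod
    def from_fields(
        cls,
        gene_ids: Sequence[str],
        gene_names: Sequence[str],
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Sequence[str],
    ) -> "GeneTable":
        records = []
        for gid, name, chrom, start, end, strand in zip(
            gene_ids, gene_names, chroms, starts, ends, strands, strict=True
        ):
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            tss = iv.start if strand == "+" else iv.end - 1
            records.append(GeneRecord(gid, name, iv, tss))
        return cls(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return self._records == other._records

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(r.gene_id for r in self._records)

    @property
    def chroms(self) -> frozenset[str]:
        return frozenset(r.interval.chrom for r in self._records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self._records],
                "gene_name": [r.gene_name for r in self._records],
                "chrom": [r.interval.chrom for r in self._records],
                "start": [r.interval.start for r in self._records],
                "end": [r.interval.end for r in self._records],
                "strand": [r.interval.strand for r in self._records],
                "tss": [r.tss for r in self._records],
            }
        )


@dataclass(frozen=True)
class Condition:
    """Experimental condition: mouse group and postnatal timepoint."""

    group: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )

    @property
    def label(self) -> str:
        return f"{self.group}_{self.timepoint}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        group, _, timepoint = label.partition("_")
        return cls(group, timepoint)


@dataclass(frozen=True)
class PeakSet:
    """Unstranded peak intervals for one antibody (mark) in one condition."""

    mark: str
    condition: Condition
    peaks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class CellMatrix:
    """Sparse cell-by-gene count matrix with per-cell metadata.

    ``cell_meta`` is aligned positionally with ``cell_ids`` and carries at
    least ``group`` and ``timepoint`` columns, plus an optional ``true_type``
    column when the matrix came from the synthetic generator.
    """

    counts: sp.csr_matrix
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = tuple(self.cell_ids)
        self.gene_ids = tuple(self.gene_ids)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_meta is not None and len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def cell_indices(self, cell_ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cell_ids], dtype=int)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(source) -> GeneTable:
    """Read gene-level features from a GTF file into a :class:`GeneTable`.

    GTF coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention; the TSS is placed strand-aware.  Non-gene feature
    lines are skipped.  Malformed lines raise :class:`FormatError` with the
    line number; duplicate gene IDs are fatal.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise FormatError(f"GTF line {lineno}: gene strand must be + or -")
            attr_map = dict(_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if not gene_id:
                raise FormatError(f"GTF line {lineno}: missing gene_id attribute")
            if gene_id in seen:
                raise FormatError(f"GTF line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            gene_name = attr_map.get("gene_name", gene_id)
            try:
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except ValueError as exc:
                raise FormatError(f"GTF line {lineno}: {exc}") from None
            tss = iv.start if strand == "+" else iv.end - 1
            records.append(GeneRecord(gene_id, gene_name, iv, tss))
    return GeneTable(records)


def write_gtf(genes: GeneTable, dest) -> None:
    """Write gene features in GTF (1-based, closed) with gene_id/gene_name."""
    with _open_text(dest, "w") as fh:
        for r in genes:
            iv = r.interval
            attrs = f'gene_id "{r.gene_id}"; gene_name "{r.gene_name}";'
            fh.write(
                f"{iv.chrom}\ttfgate\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_peaks(source, mark: str, condition: Condition) -> PeakSet:
    """Read BED3+ or ENCODE narrowPeak intervals as a :class:`PeakSet`.

    Coordinates are already 0-based half-open and are preserved bit-exact;
    any columns beyond the first three are tolerated and ignored.  Peaks are
    unstranded by construction.
    """
    peaks: list[GenomicInterval] = []
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise FormatError(f"BED line {lineno}: non-integer coordinates") from None
            try:
                peaks.append(GenomicInterval(fields[0], start, end, "."))
            except ValueError as exc:
                raise FormatError(f"BED line {lineno}: {exc}") from None
    return PeakSet(mark=mark, condition=condition, peaks=tuple(peaks))


def write_peaks(peakset: PeakSet, dest, narrowpeak: bool = False) -> None:
    """Write peaks as BED3, or 10-column narrowPeak with placeholder stats."""
    with _open_text(dest, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            if narrowpeak:
                name = f"{peakset.mark}_{peakset.condition.label}_peak{i}"
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t.\t0\t-1\t-1\t-1\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# MTX triplet
# ---------------------------------------------------------------------------


def read_cell_matrix(
    mtx_source, cells_source, genes_source, meta_source=None
) -> CellMatrix:
    """Read an MTX triplet (matrix + barcodes TSV + genes TSV) and metadata.

    The MTX is stored genes-as-rows/cells-as-columns (the common single-cell
    layout); it is transposed into the internal cells x genes orientation.
    """
    mat = scipy.io.mmread(mtx_source)
    counts = sp.csr_matrix(mat.T).astype(np.int64)
    cell_ids = _read_single_column(cells_source)
    genes_df = pd.read_csv(genes_source, sep="\t", header=None, dtype=str)
    gene_ids = genes_df[0].tolist()
    n_cells, n_genes = counts.shape
    if n_cells != len(cell_ids):
        raise FormatError(
            f"matrix has {n_cells} cells but barcode file lists {len(cell_ids)}"
        )
    if n_genes != len(gene_ids):
        raise FormatError(
            f"matrix has {n_genes} genes but gene file lists {len(gene_ids)}"
        )
    meta = None
    if meta_source is not None:
        meta = pd.read_csv(meta_source, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise FormatError("metadata TSV must have a cell_id column")
        if len(meta) != n_cells:
            raise FormatError(
                f"metadata lists {len(meta)} cells but matrix has {n_cells}"
            )
        meta = meta.set_index("cell_id").loc[list(cell_ids)].reset_index()
    return CellMatrix(counts, tuple(cell_ids), tuple(gene_ids), meta)


def write_cell_matrix(
    matrix: CellMatrix, mtx_dest, cells_dest, genes_dest, meta_dest=None
) -> None:
    """Write the MTX triplet (genes x cells orientation) and metadata TSV."""
    scipy.io.mmwrite(mtx_dest, sp.coo_matrix(matrix.counts.T), field="integer")
    with _open_text(cells_dest, "w") as fh:
        for c in matrix.cell_ids:
            fh.write(c + "\n")
    with _open_text(genes_dest, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(g + "\n")
    if meta_dest is not None:
        if matrix.cell_meta is None:
            raise ValueError("matrix carries no cell metadata to write")
        meta = matrix.cell_meta.copy()
        if "cell_id" not in meta.columns:
            meta.insert(0, "cell_id", list(matrix.cell_ids))
        meta.to_csv(meta_dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(source) -> dict[str, str]:
    """Read plain FASTA into ``{name: sequence}``; names cut at whitespace.

    Sequences are upper-cased and must be over the ACGTN alphabet.  Empty
    records and non-IUPAC characters are errors.
    """
    sequences: dict[str, str] = {}
    with _open_text(source) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            name = record.id
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"FASTA record {name!r} is empty")
            bad = set(seq) - _FASTA_ALPHABET
            if bad:
                raise FormatError(
                    f"FASTA record {name!r} has non-ACGTN characters: {sorted(bad)}"
                )
            if name in sequences:
                raise FormatError(f"duplicate FASTA record name {name!r}")
            sequences[name] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], dest, width: int = 60) -> None:
    with _open_text(dest, "w") as fh:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sequences.items()
        ]
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_single_column(source) -> list[str]:
    with _open_text(source) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


class _open_text:
    """Context manager accepting a path or an already-open text handle."""

    def __init__(self, source, mode: str = "r"):
        self._source = source
        self._mode = mode
        self._own = isinstance(source, (str, os.PathLike))
        self._fh = None

    def __enter__(self):
        if self._own:
            self._fh = open(self._source, self._mode)
            return self._fh
        if isinstance(self._source, io.IOBase) or hasattr(self._source, "read") or hasattr(self._source, "write"):
            return self._source
        raise TypeError(f"cannot open {type(self._source)!r} as text")

    def __exit__(self, *exc):
        if self._own and self._fh is not None:
            self._fh.close()
        return False
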