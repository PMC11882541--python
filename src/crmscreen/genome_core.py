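"""Shared genomic data types and text-format readers/writers.

All coordinates are 0-based half-open (BED-native) throughout the package.
GFF3 (1-based closed) is converted at the parsing boundary and converted back
on write, so no other module ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "ContactMatrix",
    "FormatError",
    "parse_intervals",
    "write_bed",
    "parse_fasta",
    "write_fasta",
    "parse_contact_matrix",
    "write_contact_matrix",
]

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``value`` carries
    a per-interval number where the source format has one (bedGraph score).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_len(other) >= min_bp


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}, plus '-' if aligned."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("sequence must be non-empty")
        bad = set(self.seq) - set("ACGTN-")
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class ContactMatrix:
    """A dense symmetric chromatin contact matrix over uniform-width bins."""

    bins: list[GenomicInterval]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square, got shape {m.shape}")
        if m.shape[0] != len(self.bins):
            raise ValueError(
                f"{len(self.bins)} bins but matrix has {m.shape[0]} rows"
            )
        if np.any(m < 0):
            raise ValueError("matrix entries must be non-negative")
        if np.max(np.abs(m - m.T)) > 1e-9 * max(1.0, float(np.max(m))):
            raise ValueError("matrix not symmetric within tolerance")
        widths = {len(b) for b in self.bins}
        if len(widths) > 1:
            raise ValueError(f"bins must have uniform width, got {sorted(widths)}")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_width(self) -> int:
        return len(self.bins[0])

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.bins[0].chrom, self.bins[0].start, self.bins[-1].end)

    def bin_index_of(self, position: float) -> int:
        """Bin index containing a genomic position (bins are half-open)."""
        s = self.span
        if not (s.start <= position < s.end):
            raise ValueError(f"position {position} outside covered span [{s.start}, {s.end})")
        return int((position - s.start) // self.bin_width)


# ---------------------------------------------------------------------------
# interval I/O


def _parse_bed_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: BED line has {len(fields)} fields, need >=3")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    value = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            value = float(fields[4])
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-numeric score") from e
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom, start, end, strand=strand, name=name, value=value)
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: {e}") from e


def _parse_gff3_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) != 9:
        raise FormatError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields, need 9")
    chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
    # 1-based closed -> 0-based half-open
    start, end = start1 - 1, end1
    name = ftype
    for kv in attrs.split(";"):
        if kv.startswith("ID="):
            name = kv[3:]
            break
    if strand not in VALID_STRANDS:
        strand = "."
    try:
        iv = GenomicInterval(chrom, start, end, strand=strand, name=name)
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: {e}") from e
    object.__setattr__(iv, "feature_type", ftype)  # annotation, not a dataclass field
    return iv


def _parse_bedgraph_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) != 4:
        raise FormatError(f"{path}:{lineno}: bedGraph line has {len(fields)} fields, need 4")
    try:
        start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: malformed bedGraph fields") from e
    try:
        return GenomicInterval(fields[0], start, end, value=value)
    except ValueError as e:
        raise FormatError(f"{path}:{lineno}: {e}") from e


_PARSERS = {"BED": _parse_bed_line, "GFF3": _parse_gff3_line, "bedGraph": _parse_bedgraph_line}


def parse_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval]:
    """Parse BED / GFF3 / bedGraph into 0-based half-open intervals.

    Input ordering is preserved. GFF3 feature type is retained: the interval
    ``name`` is the ID attribute when present (feature type otherwise) and a
    ``feature_type`` attribute is attached for filtering by type.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_PARSERS)}")
    parse_line = _PARSERS[format]
    out: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            out.append(parse_line(line.split("\t"), lineno, str(path)))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name/score columns '.' when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.value is None else format(iv.value, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# sequence I/O


def parse_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read (optionally aligned) FASTA; sequences are upper-cased.

    With ``aligned=True`` all records must be the same length (gap char '-').
    Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if aligned and len({len(r) for r in records}) > 1:
        raise FormatError(f"{path}: aligned records have unequal lengths")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# contact-matrix I/O (dense TSV + companion bin BED)


def parse_contact_matrix(matrix_path: str | Path, bins_path: str | Path) -> ContactMatrix:
    """Load a dense TSV contact matrix with its companion bin BED file.

    Mild asymmetry (numeric round-trip noise, below 1e-6 of the matrix
    maximum) is repaired by averaging with the transpose; anything larger is
    an error.
    """
    m = np.loadtxt(matrix_path, dtype=float, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{matrix_path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    if np.any(m < 0):
        raise FormatError(f"{matrix_path}: negative contact values")
    bins = parse_intervals(bins_path, "BED")
    if len(bins) != m.shape[0]:
        raise FormatError(
            f"{bins_path}: {len(bins)} bins for a {m.shape[0]}x{m.shape[1]} matrix"
        )
    asym = float(np.max(np.abs(m - m.T))) if m.size else 0.0
    if asym > 1e-6 * max(1.0, float(np.max(m))):
        raise FormatError(f"{matrix_path}: matrix asymmetry {asym:g} exceeds tolerance")
    m = (m + m.T) / 2.0
    return ContactMatrix(bins=bins, matrix=m)


def write_contact_matrix(cm: ContactMatrix, matrix_path: str | Path, bins_path: str | Path) -> None:
    np.savetxt(matrix_path, cm.matrix, delimiter="\t", fmt="%.10g")
    write_bed(cm.bins, bins_path)
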