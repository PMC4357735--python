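"""Readers and writers for the external file formats the pipeline touches.

Conventions
-----------
All internal coordinates are 0-based, half-open ``[start, end)``.  BED input
already uses that convention; fixedStep WIG is 1-based on disk and converted
on read.  Per-cytosine methylation count tables are tab-delimited with columns
``chrom  pos  context  meth_count  total_count`` and 0-based positions (pass
``one_based=True`` for dialects counted from 1).  A missing strand is recorded
as ``"."``.

All readers raise :class:`FormatError` (a ``ValueError``) on malformed input,
with the offending line number where one exists; they never silently truncate.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs


class FormatError(ValueError):
    """A file did not conform to its declared format."""


PFM_ALPHABET = "ACGT"

#: contexts accepted in methylation count tables
METH_CONTEXTS = ("CG", "CH", "hmC")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one shared base under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class CpGRecord:
    """Methylation evidence at one cytosine position.

    ``meth_count`` is the number of reads supporting methylation and
    ``total_count`` the total read coverage; the unmethylated read count is
    their difference.
    """

    chrom: str
    pos: int
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not (0 <= self.meth_count <= self.total_count):
            raise ValueError(
                f"require 0 <= meth_count <= total_count, "
                f"got {self.meth_count}/{self.total_count}"
            )


@dataclass
class PFM:
    """A position frequency matrix: 4 x L non-negative counts over A, C, G, T."""

    counts: np.ndarray
    name: str = "motif"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"PFM counts must be 4 x L, got {self.counts.shape}")
        if self.counts.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if np.any(self.counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValueError(f"PFM {self.name!r} has an all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


class ConservationTrack:
    """Sparse per-base conservation scores keyed by (chrom, position).

    Missing positions are permitted and treated as score 0 by consumers.
    """

    def __init__(self, scores: Mapping[str, Mapping[int, float]] | None = None):
        self._scores: dict[str, dict[int, float]] = {
            chrom: dict(vals) for chrom, vals in (scores or {}).items()
        }

    def set(self, chrom: str, pos: int, score: float) -> None:
        self._scores.setdefault(chrom, {})[pos] = float(score)

    def get(self, chrom: str, pos: int, default: float = 0.0) -> float:
        return self._scores.get(chrom, {}).get(pos, default)

    def positions(self, chrom: str) -> dict[int, float]:
        return self._scores.get(chrom, {})

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConservationTrack) and self._scores == other._scores

    def __len__(self) -> int:
        return sum(len(v) for v in self._scores.values())


class CpGTable:
    """Column-oriented methylation counts, sorted by position within chromosome.

    Wraps the per-cytosine records of one context as numpy arrays so window
    aggregation can use binary search instead of per-record scans.
    """

    def __init__(self, records: Iterable[CpGRecord] = ()):
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(
                (rec.pos, rec.meth_count, rec.total_count)
            )
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64)
            self._arrays[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    @classmethod
    def from_arrays(
        cls, per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> "CpGTable":
        table = cls()
        for chrom, (pos, meth, total) in per_chrom.items():
            order = np.argsort(pos, kind="stable")
            table._arrays[chrom] = (
                np.asarray(pos, dtype=np.int64)[order],
                np.asarray(meth, dtype=np.int64)[order],
                np.asarray(total, dtype=np.int64)[order],
            )
        return table

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, meth_counts, total_counts), sorted by position."""
        if chrom not in self._arrays:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        return self._arrays[chrom]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._arrays)

    def __len__(self) -> int:
        return sum(len(a[0]) for a in self._arrays.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a mapping ``chrom -> sequence``.

    Sequences are uppercased; IUPAC ambiguity codes are preserved as-is.
    Duplicate record names and empty files are format errors.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise FormatError(f"duplicate FASTA record name {record.id!r} in {path}")
            genome[record.id] = str(record.seq).upper()
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as handle:
        for chrom in genome:
            handle.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Per-cytosine methylation count tables
# ---------------------------------------------------------------------------

def read_cpg_table(
    path: str | Path,
    context_filter: str | Sequence[str] | None = None,
    one_based: bool = False,
) -> list[CpGRecord]:
    """Read a tab-delimited per-cytosine count table.

    Columns: ``chrom  pos  context  meth_count  total_count``.  Positions are
    0-based unless ``one_based`` is set, in which case 1 is subtracted on read.
    ``context_filter`` keeps only the given context(s) (e.g. ``"CG"``).
    Records with zero total coverage are retained; they simply contribute no
    coverage downstream.  Rows where ``meth_count > total_count`` raise a
    :class:`FormatError` naming the line.
    """
    if isinstance(context_filter, str):
        context_filter = (context_filter,)
    records: list[CpGRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-delimited columns, got {len(fields)}"
                )
            chrom, pos_s, context, meth_s, total_s = fields[:5]
            try:
                pos = int(pos_s) - (1 if one_based else 0)
                meth = int(meth_s)
                total = int(total_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if context_filter is not None and context not in context_filter:
                continue
            try:
                records.append(CpGRecord(chrom, pos, context, meth, total))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_cpg_table(path: str | Path, records: Iterable[CpGRecord]) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.context}\t{rec.meth_count}\t{rec.total_count}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals, returned sorted by (chrom, start, end).

    The optional 6th column supplies the strand; name and score columns are
    ignored.  A line with ``start >= end`` or non-integer coordinates raises a
    :class:`FormatError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path) -> PFM:
    """Read a single motif in JASPAR text dialect (4 labeled count rows).

    Accepts the 2016-style block::

        >MA0139.1 CTCF
        A  [ 87 167 ... ]
        C  [291 145 ... ]
        G  [ 76 414 ... ]
        T  [459 187 ... ]

    The header line is optional; exactly one motif per file.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty PFM file")
    if not text.lstrip().startswith(">"):
        text = ">motif\n" + text
    try:
        parsed = bio_motifs.parse(_stdio.StringIO(text), "jaspar")
        parsed = list(parsed)
    except Exception as exc:
        raise FormatError(f"{path}: unrecognized PFM dialect ({exc})") from None
    if len(parsed) != 1:
        raise FormatError(f"{path}: expected exactly one motif, found {len(parsed)}")
    motif = parsed[0]
    counts = np.array([motif.counts[base] for base in PFM_ALPHABET], dtype=float)
    name = motif.name or motif.matrix_id or "motif"
    try:
        return PFM(counts=counts, name=name)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_pfm(path: str | Path, pfm: PFM) -> None:
    with open(path, "w") as handle:
        handle.write(f">{pfm.name}\n")
        for i, base in enumerate(PFM_ALPHABET):
            row = " ".join(f"{v:g}" for v in pfm.counts[i])
            handle.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Conservation: fixedStep WIG and 4-column bedGraph
# ---------------------------------------------------------------------------

def read_wig(path: str | Path) -> ConservationTrack:
    """Read a per-base conservation track.

    Supports fixedStep WIG (1-based on disk; converted to 0-based) and
    4-column bedGraph (already 0-based half-open).  ``variableStep`` and any
    other dialect raise a :class:`FormatError`.
    """
    track = ConservationTrack()
    chrom: str | None = None
    pos = 0
    step = 1
    span = 1
    mode: str | None = None  # "fixed" | "bedgraph"
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(
                    item.split("=", 1) for item in line.split()[1:] if "=" in item
                )
                try:
                    chrom = params["chrom"]
                    pos = int(params["start"]) - 1  # WIG is 1-based
                    step = int(params.get("step", 1))
                    span = int(params.get("span", 1))
                except (KeyError, ValueError):
                    raise FormatError(
                        f"{path}:{lineno}: malformed fixedStep declaration"
                    ) from None
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep WIG is not supported")
            fields = line.split()
            if len(fields) == 1 and mode == "fixed":
                try:
                    value = float(fields[0])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric WIG value") from None
                assert chrom is not None
                for offset in range(span):
                    track.set(chrom, pos + offset, value)
                pos += step
            elif len(fields) == 4:
                mode = mode or "bedgraph"
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from None
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: bedGraph start >= end")
                for p in range(start, end):
                    track.set(fields[0], p, value)
            else:
                raise FormatError(
                    f"{path}:{lineno}: unrecognized conservation track line {line!r}"
                )
    return track


def write_bedgraph(path: str | Path, track: ConservationTrack) -> None:
    """Write a track as 4-column bedGraph, merging runs of equal adjacent values."""
    with open(path, "w") as handle:
        for chrom in sorted(track._scores):
            scores = track.positions(chrom)
            run_start = None
            prev_pos = None
            prev_val = None
            for pos in sorted(scores):
                val = scores[pos]
                if run_start is not None and pos == prev_pos + 1 and val == prev_val:
                    prev_pos = pos
                    continue
                if run_start is not None:
                    handle.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")
                run_start, prev_pos, prev_val = pos, pos, val
            if run_start is not None:
                handle.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")


# ---------------------------------------------------------------------------
# Predictions (BED6 + methylation scores + class probability)
# ---------------------------------------------------------------------------

#: leading columns of the prediction table, in BED6 order
PREDICTION_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_predictions(path: str | Path, predictions: pd.DataFrame) -> None:
    """Write a prediction table as BED6 plus extra columns.

    The frame must contain the BED6 columns (``name`` is the site id and
    ``score`` the motif log-odds); every remaining column (per-context
    methylation scores, class probability, label) is appended after them.
    The header line is prefixed with ``#`` so the file stays BED-toolable.
    """
    missing = [c for c in PREDICTION_BED_COLUMNS if c not in predictions.columns]
    if missing:
        raise ValueError(f"prediction table missing required columns: {missing}")
    extra = [c for c in predictions.columns if c not in PREDICTION_BED_COLUMNS]
    ordered = predictions[PREDICTION_BED_COLUMNS + extra]
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(ordered.columns) + "\n")
        ordered.to_csv(handle, sep="\t", header=False, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '#'-prefixed prediction header")
        columns = header[1:].rstrip("\n").split("\t")
        frame = pd.read_csv(handle, sep="\t", names=columns)
    return frame
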