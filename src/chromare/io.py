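"""Readers, writers and the shared genomic data model.

All coordinates are 0-based half-open throughout the package.  BED and
bedGraph are consumed and emitted natively in that convention; any 1-based
dialect must be converted at the boundary.  Tracks are held dense at 1-bp
resolution: the genomes this package targets are desk-scale simulations,
and the contract that matters is random access by (chrom, position) with
non-negative values, not the storage layout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "GenomicInterval",
    "IntervalSet",
    "CoverageTrack",
    "TssRecord",
    "Pwm",
    "DegTable",
    "DEG_STATUSES",
    "parse_bed",
    "write_bed",
    "parse_bedgraph",
    "write_bedgraph",
    "parse_chrom_sizes",
    "write_chrom_sizes",
    "parse_jaspar",
    "write_jaspar",
    "parse_tss_table",
    "write_tss_table",
    "parse_deg_table",
    "write_deg_table",
    "read_fasta",
    "write_fasta",
    "genome_background",
]

BASES = "ACGT"
DEG_STATUSES = ("up", "down", "unchanged")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``summit`` is an optional offset from ``start`` marking the single-bp
    position of maximal signal inside the interval (MACS-style).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise ValueError(
                f"summit {self.summit} outside interval of length "
                f"{self.end - self.start}"
            )

    @property
    def summit_pos(self) -> int:
        """Absolute summit position; interval midpoint when no summit is set."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`."""

    intervals: tuple[GenomicInterval, ...] = ()

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        key = lambda iv: (iv.chrom, iv.start, iv.end, iv.name or "")
        return IntervalSet(tuple(sorted(self.intervals, key=key)))

    def ids(self) -> list[str]:
        return [
            iv.name if iv.name is not None else f"iv{i}"
            for i, iv in enumerate(self.intervals)
        ]

    def summit_positions(self) -> dict[str, np.ndarray]:
        """Per-chromosome sorted arrays of absolute summit positions."""
        out: dict[str, list[int]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv.summit_pos)
        return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in out.items()}


@dataclass
class CoverageTrack:
    """Dense per-base, non-negative signal over a genome."""

    data: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, vec in self.data.items():
            size = self.chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"track chromosome {chrom!r} has no declared size")
            if len(vec) != size:
                raise ValueError(
                    f"{chrom}: vector length {len(vec)} != declared size {size}"
                )
            if np.any(vec < 0):
                raise ValueError(f"{chrom}: negative coverage values")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{chrom}: non-finite coverage values")

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over [start, end); bases outside the chromosome are 0."""
        size = self.chrom_sizes[chrom]
        out = np.zeros(end - start, dtype=float)
        lo, hi = max(start, 0), min(end, size)
        if lo < hi:
            out[lo - start : hi - start] = self.data[chrom][lo:hi]
        return out

    def total(self) -> float:
        return float(sum(vec.sum() for vec in self.data.values()))

    def mean(self) -> float:
        n = sum(self.chrom_sizes[c] for c in self.data)
        return self.total() / n if n else 0.0

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "CoverageTrack":
        return cls(
            {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()},
            dict(chrom_sizes),
        )


@dataclass(frozen=True)
class TssRecord:
    """A stranded transcription start site."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be +/-, got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("TSS position must be non-negative")


@dataclass(frozen=True, eq=False)
class Pwm:
    """Position probability matrix with an explicit background model.

    ``probs`` is an L x 4 array over A, C, G, T; every row sums to 1.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM must be an L x 4 matrix")
        if np.any(probs < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9) or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pwm):
            return NotImplemented
        return (
            self.motif_id == other.motif_id
            and self.pseudocount == other.pseudocount
            and np.array_equal(self.probs, other.probs)
            and np.array_equal(self.background, other.background)
        )

    def __hash__(self) -> int:
        return hash((self.motif_id, self.probs.tobytes()))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def with_background(self, background: np.ndarray) -> "Pwm":
        return dataclasses.replace(self, background=np.asarray(background, float))


@dataclass(frozen=True)
class DegTable:
    """Gene id -> regulation status (up / down / unchanged)."""

    status: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.status.values() if s not in DEG_STATUSES}
        if bad:
            raise ValueError(f"unknown regulation status(es): {sorted(bad)}")

    def genes(self, status: str) -> set[str]:
        if status not in DEG_STATUSES:
            raise ValueError(f"unknown regulation status {status!r}")
        return {g for g, s in self.status.items() if s == status}

    def __len__(self) -> int:
        return len(self.status)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _fmt_score(x: float) -> str:
    return f"{x:.6g}"


def parse_bed(path, summit_col: int | None = None) -> IntervalSet:
    """Parse a 3-7 column BED file.

    Columns beyond the first three are optional: 4 name, 5 score, 6 strand.
    ``summit_col`` (0-based column index) selects a column holding the summit
    offset from ``start``; MACS-style files differ in where they put it, so
    the position is configurable rather than fixed.
    """
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"fewer than 3 columns, line {lineno}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates, line {lineno}") from exc
            if start == end:
                raise ParseError(f"zero-length interval, line {lineno}")
            name = None
            if len(fields) > 3 and fields[3] != ".":
                name = fields[3]
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"non-numeric score, line {lineno}") from exc
            strand = fields[5] if len(fields) > 5 else "."
            summit = None
            if summit_col is not None:
                if summit_col >= len(fields):
                    raise ParseError(f"missing summit column, line {lineno}")
                try:
                    summit = int(fields[summit_col])
                except ValueError as exc:
                    raise ParseError(f"non-integer summit, line {lineno}") from exc
            try:
                ivs.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValueError as exc:
                raise ParseError(f"{exc}, line {lineno}") from exc
    return IntervalSet(tuple(ivs))


def write_bed(intervals: IntervalSet, path, summit: bool | None = None) -> None:
    """Write a deterministic, coordinate-sorted BED file.

    The summit offset, when any interval carries one, is written as a 7th
    column (readable back with ``summit_col=6``).
    """
    ivs = intervals.sorted()
    if summit is None:
        summit = any(iv.summit is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name if iv.name is not None else ".",
                _fmt_score(iv.score) if iv.score is not None else ".",
                iv.strand,
            ]
            if summit:
                fields.append(str(iv.summit) if iv.summit is not None else ".")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph / chrom sizes
# ---------------------------------------------------------------------------


def parse_bedgraph(path, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Expand a bedGraph into a dense track; overlapping records sum."""
    track = CoverageTrack.zeros(chrom_sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"fewer than 4 columns, line {lineno}")
            chrom = fields[0]
            if chrom not in chrom_sizes:
                raise ParseError(f"unknown chromosome {chrom!r}, line {lineno}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"malformed record, line {lineno}") from exc
            if start < 0 or start >= end or end > chrom_sizes[chrom]:
                raise ParseError(
                    f"record outside chromosome bounds, line {lineno}"
                )
            if value < 0:
                raise ParseError(f"negative value, line {lineno}")
            track.data[chrom][start:end] += value
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode a dense track; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def parse_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"expected 2 columns, line {lineno}")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"non-integer size, line {lineno}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# JASPAR count matrices
# ---------------------------------------------------------------------------


def parse_jaspar(
    path,
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
) -> list[Pwm]:
    """Parse JASPAR-format count matrices into probability PWMs.

    Counts are regularised as ``(count + pseudocount * bg_b) /
    (column_total + pseudocount)`` so each column sums to one and, for a
    positive pseudocount, every probability is strictly positive.
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, float)
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms: list[Pwm] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T  # L x 4
        if np.any(counts < 0):
            raise ParseError(f"negative counts in motif {m.matrix_id or m.name}")
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals + pseudocount <= 0):
            raise ParseError(f"empty count column in motif {m.matrix_id or m.name}")
        probs = (counts + pseudocount * bg) / (totals + pseudocount)
        ident = m.matrix_id or m.name or f"motif{len(pwms)}"
        pwms.append(Pwm(ident, probs, background=bg, pseudocount=pseudocount))
    return pwms


def write_jaspar(pwms: Iterable[Pwm], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR-style integer count matrices (probs * scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            counts = np.rint(pwm.probs * scale).astype(int)
            for j, base in enumerate(BASES):
                row = " ".join(f"{c:6d}" for c in counts[:, j])
                fh.write(f"{base}  [{row} ]\n")


# ---------------------------------------------------------------------------
# TSS / DEG tables
# ---------------------------------------------------------------------------


def parse_tss_table(path) -> list[TssRecord]:
    """Parse a 4-column TSV: gene id, chrom, TSS position, strand."""
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"expected 4 columns, line {lineno}")
            try:
                records.append(
                    TssRecord(fields[0], fields[1], int(fields[2]), fields[3])
                )
            except ValueError as exc:
                raise ParseError(f"{exc}, line {lineno}") from exc
    return records


def write_tss_table(records: Iterable[TssRecord], path) -> None:
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.gene_id))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.pos}\t{r.strand}\n")


def parse_deg_table(path) -> DegTable:
    """Parse a 2-column TSV: gene id, status in {up, down, unchanged}."""
    status: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"expected 2 columns, line {lineno}")
            gene, st = fields[0], fields[1]
            if st not in DEG_STATUSES:
                raise ParseError(
                    f"unknown regulation status {st!r}, line {lineno}"
                )
            if gene in status:
                raise ParseError(f"duplicate gene id {gene!r}, line {lineno}")
            status[gene] = st
    return DegTable(status)


def write_deg_table(deg: DegTable, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(deg.status):
            fh.write(f"{gene}\t{deg.status[gene]}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in sorted(genome)
    ]
    SeqIO.write(records, str(path), "fasta")


def genome_background(genome: Mapping[str, str]) -> np.ndarray:
    """0-order A/C/G/T frequencies of a genome; N bases are excluded."""
    counts = np.zeros(4, dtype=float)
    for seq in genome.values():
        for i, base in enumerate(BASES):
            counts[i] += seq.count(base)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return counts / total
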