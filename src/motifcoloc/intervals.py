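"""Genomic interval data model and file I/O.

All coordinates are 0-based half-open (BED convention) internally.  The
integer center of an interval ``[s, e)`` is ``(s + e - 1) // 2`` so that
width-1 summit intervals are their own center and centers are deterministic
for even widths.  Distance ties between equidistant neighbors break toward
the negative (upstream) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeSequence",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_genome_table",
    "write_genome_table",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED lines; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Deterministic integer center: ``(start + end - 1) // 2``."""
        return (self.start + self.end - 1) // 2


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


class IntervalSet:
    """A sorted collection of :class:`GenomicInterval` with optional genome sizes.

    Intervals are kept sorted by ``(chrom, start, end)``.  ``genome`` maps
    chromosome name to length in bp and is required by operations that clip
    or normalize against genome size.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals, key=_sort_key)
        self.genome: dict[str, int] = dict(genome) if genome else {}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals and self.genome == other.genome

    def chroms(self) -> list[str]:
        out: list[str] = []
        for iv in self.intervals:
            if not out or out[-1] != iv.chrom:
                out.append(iv.chrom)
        return out

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def centers_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted arrays of interval centers keyed by chromosome."""
        out: dict[str, list[int]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv.center)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}

    def starts_ends_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            s, e = out.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    # ------------------------------------------------------------------
    # region arithmetic
    # ------------------------------------------------------------------
    def extend(self, w: int) -> "IntervalSet":
        """Extend every interval by ``w`` bp on each side, clipping to the
        chromosome.  Overlapping results are NOT merged."""
        if w < 0:
            raise ValueError(f"extension width must be >= 0, got {w}")
        out = []
        for iv in self.intervals:
            start = max(0, iv.start - w)
            end = iv.end + w
            limit = self.genome.get(iv.chrom)
            if limit is not None:
                end = min(end, limit)
                start = min(start, limit - 1)
            out.append(replace(iv, start=start, end=end))
        return IntervalSet(out, self.genome)

    def merge(self) -> "IntervalSet":
        """Coalesce overlapping or bookended intervals per chromosome.

        Merged intervals carry strand '.', no name/score; total covered
        length is invariant.
        """
        out: list[GenomicInterval] = []
        cur: GenomicInterval | None = None
        for iv in self.intervals:
            if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
                if iv.end > cur.end:
                    cur = replace(cur, end=iv.end)
            else:
                if cur is not None:
                    out.append(cur)
                cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        if cur is not None:
            out.append(cur)
        return IntervalSet(out, self.genome)

    def covered_length(self) -> int:
        """Total bp covered by the union of the intervals."""
        return sum(iv.width for iv in self.merge())

    def intersect_length(self, other: "IntervalSet") -> int:
        """Length in bp of the intersection of the two unions."""
        total = 0
        mine = self.merge().starts_ends_by_chrom()
        theirs = other.merge().starts_ends_by_chrom()
        for chrom, (s1, e1) in mine.items():
            if chrom not in theirs:
                continue
            s2, e2 = theirs[chrom]
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if hi > lo:
                    total += int(hi - lo)
                if e1[i] <= e2[j]:
                    i += 1
                else:
                    j += 1
        return total

    def overlap_count(self, other: "IntervalSet", w: int = 0) -> int:
        """Number of intervals in ``self`` whose ``w``-extension intersects at
        least one interval of ``other``; each interval counted once."""
        merged = other.merge().starts_ends_by_chrom()
        n = 0
        for iv in self.intervals:
            if iv.chrom not in merged:
                continue
            starts, ends = merged[iv.chrom]
            lo, hi = iv.start - w, iv.end + w
            # first merged block with end > lo
            j = int(np.searchsorted(ends, lo, side="right"))
            if j < len(starts) and starts[j] < hi:
                n += 1
        return n

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which 0-based positions fall inside the union."""
        merged = self.merge().starts_ends_by_chrom()
        if chrom not in merged:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = merged[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    def nearest_distance(self, anchor: GenomicInterval) -> int | None:
        """Signed, orientation-aware center-to-center distance from ``anchor``
        to its nearest interval in this set.

        The raw distance is ``center(b) - center(anchor)``; for a '-' strand
        anchor the sign is flipped.  Equidistant neighbors break toward the
        negative side.  Returns None when the chromosome is absent.
        """
        centers = self.centers_by_chrom().get(anchor.chrom)
        if centers is None or len(centers) == 0:
            return None
        a = anchor.center
        flip = -1 if anchor.strand == "-" else 1
        j = int(np.searchsorted(centers, a))
        best: int | None = None
        for k in (j - 1, j):
            if 0 <= k < len(centers):
                d = flip * (int(centers[k]) - a)  # oriented distance
                if best is None or (abs(d), d) < (abs(best), best):
                    best = d
        assert best is not None
        return best


# ----------------------------------------------------------------------
# genome sequence
# ----------------------------------------------------------------------

_ALPHABET = set("ACGTN")


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings over {A,C,G,T,N}, upper-cased."""

    seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, seq in self.seqs.items():
            s = seq.upper()
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(f"chromosome {chrom} contains invalid bases: {sorted(bad)}")
            clean[chrom] = s
        self.seqs = clean

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def chroms(self) -> list[str]:
        return list(self.seqs)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------


def read_bed(path: str | Path, genome: Mapping[str, int] | None = None) -> IntervalSet:
    """Read a 3-6 column BED file into a sorted :class:`IntervalSet`.

    Strand defaults to '.' when absent.  Malformed lines raise
    :class:`BedParseError` naming the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _VALID_STRANDS:
                raise BedParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(intervals, genome)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED6 when any interval has strand/name/score, else BED3."""
    bed6 = any(
        iv.strand != "." or iv.name is not None or iv.score is not None
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                score = "0" if iv.score is None else f"{iv.score:.2f}"
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (possibly line-wrapped, multi-record) FASTA file."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_genome_table(path: str | Path) -> dict[str, int]:
    """Read a two-column 'chrom<TAB>length' table."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            genome[parts[0]] = int(parts[1])
    return genome


def write_genome_table(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
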