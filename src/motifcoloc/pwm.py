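"""JASPAR count matrices, log-odds scoring, and two-stranded genome scanning.

A count matrix with counts ``c[i][b]`` over bases b in A,C,G,T at position i
is turned into a log-odds scorer (in bits)

    log_odds[i][b] = log2( (c[i][b] + k * q[b]) / (sum_b' c[i][b'] + k) / q[b] )

where q is the background distribution (default uniform) and k the total
pseudocount (default 0.8, distributed by background frequency).  Scanning
reports every window on either strand scoring at or above a threshold; the
built-in "high"/"low" stringency levels place the threshold at a fixed
fraction f of the dynamic score range, threshold = min + f*(max - min),
with f = 0.90 (high) and 0.80 (low).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomeSequence, GenomicInterval, IntervalSet

__all__ = [
    "MotifMatrix",
    "STRINGENCY_FRACTIONS",
    "read_jaspar",
    "write_jaspar",
    "scan_sequence",
    "score_threshold_for_pvalue",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: relative position of the score cutoff in [min_score, max_score]
STRINGENCY_FRACTIONS = {"high": 0.90, "low": 0.80}


@dataclass
class MotifMatrix:
    """A motif count matrix with a derived log-odds scorer.

    ``counts`` is an L x 4 array in A,C,G,T column order.
    """

    matrix_id: str
    name: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 array (A,C,G,T columns)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("each position needs at least one positive count")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds matrix (bits)."""
        totals = self.counts.sum(axis=1, keepdims=True) + self.pseudocount
        probs = (self.counts + self.pseudocount * self.background) / totals
        return np.log2(probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def threshold(self, stringency: str | float) -> float:
        """Absolute score cutoff for a stringency token or explicit value."""
        if isinstance(stringency, str):
            try:
                f = STRINGENCY_FRACTIONS[stringency]
            except KeyError:
                raise ValueError(
                    f"stringency must be one of {sorted(STRINGENCY_FRACTIONS)} "
                    f"or a numeric threshold, got {stringency!r}"
                ) from None
            lo, hi = self.min_score(), self.max_score()
            return lo + f * (hi - lo)
        return float(stringency)

    def reverse_complement(self) -> "MotifMatrix":
        """Matrix scoring the reverse-complement motif (reversed positions,
        complemented columns)."""
        rc = self.counts[::-1, ::-1].copy()
        return MotifMatrix(
            self.matrix_id, self.name, rc, self.background[::-1].copy(), self.pseudocount
        )


def read_jaspar(path: str | Path, pseudocount: float = 0.8) -> list[MotifMatrix]:
    """Parse a JASPAR PFM text file (possibly multi-record) into matrices."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    records = bio_motifs.parse(io.StringIO(text), "jaspar")
    out = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        out.append(
            MotifMatrix(m.matrix_id or m.name, m.name or "", counts, pseudocount=pseudocount)
        )
    return out


def write_jaspar(matrices: Iterable[MotifMatrix], path: str | Path) -> None:
    """Write matrices in JASPAR PFM text format, preserving counts."""

    def fmt(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else f"{x:.2f}"

    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.matrix_id} {m.name}\n")
            for j, base in enumerate(BASES):
                row = " ".join(fmt(v) for v in m.counts[:, j])
                fh.write(f"{base} [ {row} ]\n")


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all length-L windows plus a validity mask (no N)."""
    L = lom.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for i in range(L):
        window_codes = safe[i : i + n_win]
        scores += lom[i, window_codes]
        valid &= codes[i : i + n_win] >= 0
    return scores, valid


def scan_sequence(
    genome: GenomeSequence,
    matrix: MotifMatrix,
    stringency: str | float = "high",
) -> IntervalSet:
    """Scan every chromosome on both strands for windows scoring at or above
    the threshold.

    Reverse-strand hits are reported on forward coordinates with strand '-'.
    Windows containing N are skipped.  Hits carry the matrix id as name and
    the log-odds score in bits.
    """
    thr = matrix.threshold(stringency)
    lom_fwd = matrix.log_odds
    lom_rev = matrix.reverse_complement().log_odds
    hits: list[GenomicInterval] = []
    L = len(matrix)
    for chrom, seq in genome.seqs.items():
        if len(seq) < L:
            continue
        codes = _encode(seq)
        for lom, strand in ((lom_fwd, "+"), (lom_rev, "-")):
            scores, valid = _window_scores(codes, lom)
            take = np.flatnonzero(valid & (scores >= thr))
            for pos in take:
                hits.append(
                    GenomicInterval(
                        chrom,
                        int(pos),
                        int(pos) + L,
                        strand,
                        name=matrix.matrix_id,
                        score=float(scores[pos]),
                    )
                )
    return IntervalSet(hits, genome.lengths())


def score_threshold_for_pvalue(
    matrix: MotifMatrix, pvalue: float, precision: float = 1e-3
) -> float:
    """Score cutoff whose exceedance probability under the background model
    is at most ``pvalue``.

    The exact null score distribution is built by convolving the per-position
    score distributions (positions independent under the background), with
    scores discretized to ``precision`` bits.  Practical for motif lengths
    up to ~20.
    """
    if not (0 < pvalue < 1):
        raise ValueError("pvalue must be in (0, 1)")
    lom = matrix.log_odds
    dist: dict[int, float] = {0: 1.0}
    for i in range(len(matrix)):
        new: dict[int, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = s + round(lom[i, b] / precision)
                new[key] = new.get(key, 0.0) + prob * float(matrix.background[b])
        dist = new
    scores = sorted(dist)
    tail = 0.0
    for s in reversed(scores):
        tail += dist[s]
        if tail > pvalue:
            # the previous (higher) score was the last one meeting the bound
            return (s + 1) * precision
    return scores[0] * precision
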