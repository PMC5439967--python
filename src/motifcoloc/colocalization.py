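"""Spatial co-localization statistics for genomic site sets.

Three views of co-localization are provided:

* nearest-distance histograms — for each anchor, the signed oriented
  distance to its closest site, binned over a symmetric window;
* globally normalized density profiles — ALL site centers falling in each
  bin relative to each anchor center, divided by the genome-wide uniform
  expectation so that 1.0 is the null level;
* Fisher-exact overlap enrichment of two site sets against a background
  region universe (e.g. open chromatin).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import IntervalSet

__all__ = [
    "DistanceHistogram",
    "DensityProfile",
    "ContingencyTable2x2",
    "FisherResult",
    "distance_histogram",
    "density_profile",
    "fisher_overlap",
    "chip_peak_intersection",
]


@dataclass
class DistanceHistogram:
    half_window: int
    bin_width: int
    bin_edges: np.ndarray  # signed bp, length n_bins + 1
    counts: np.ndarray  # integer per bin
    n_anchors: int

    def to_rows(self) -> list[tuple[int, int, int]]:
        return [
            (int(self.bin_edges[i]), int(self.bin_edges[i + 1]), int(self.counts[i]))
            for i in range(len(self.counts))
        ]


@dataclass
class DensityProfile:
    half_window: int
    bin_width: int
    bin_edges: np.ndarray
    raw_counts: np.ndarray
    global_mean: float  # expected count per bin under genome-wide uniformity
    n_anchors: int

    @property
    def density(self) -> np.ndarray:
        return self.raw_counts / self.global_mean

    def to_rows(self) -> list[tuple[int, int, int, float]]:
        dens = self.density
        return [
            (
                int(self.bin_edges[i]),
                int(self.bin_edges[i + 1]),
                int(self.raw_counts[i]),
                float(dens[i]),
            )
            for i in range(len(self.raw_counts))
        ]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: foreground overlaps, b: foreground non-overlaps,
    c: background overlaps, d: background non-overlaps."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table cells must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both rows must have positive totals")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # nan when undefined (zero margin)
    ci_low: float
    ci_high: float
    p_value: float


def _bin_edges(half_window: int, bin_width: int) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if (2 * half_window) % bin_width != 0:
        raise ValueError("bin_width must divide 2 * half_window")
    return np.arange(-half_window, half_window + bin_width, bin_width)


def distance_histogram(
    anchors: IntervalSet,
    sites: IntervalSet,
    half_window: int,
    bin_width: int,
) -> DistanceHistogram:
    """Histogram of oriented nearest-site distances, one count per anchor.

    Anchors whose nearest site lies at or beyond ``half_window`` (or with no
    site on their chromosome) contribute nothing.
    """
    edges = _bin_edges(half_window, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for anchor in anchors:
        d = sites.nearest_distance(anchor)
        if d is None or not (-half_window <= d < half_window):
            continue
        counts[(d + half_window) // bin_width] += 1
    return DistanceHistogram(half_window, bin_width, edges, counts, len(anchors))


def density_profile(
    anchors: IntervalSet,
    sites: IntervalSet,
    half_window: int,
    bin_width: int,
    oriented: bool = False,
    effective_genome_length: int | None = None,
) -> DensityProfile:
    """Count all site centers around each anchor center and normalize to the
    genome-wide average site density.

    The normalizer is ``n_anchors * n_sites * bin_width / G`` where G is the
    total genome length (or ``effective_genome_length``, e.g. the mappable
    length, when given): the expected per-bin count if sites were uniform,
    so a uniform site set has density ~1 in every bin.
    """
    if len(sites) == 0:
        raise ValueError("density normalizer undefined for an empty site set")
    G = effective_genome_length
    if G is None:
        if not sites.genome:
            raise ValueError("genome lengths required for the global normalizer")
        G = sum(sites.genome.values())
    edges = _bin_edges(half_window, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    centers = sites.centers_by_chrom()
    for anchor in anchors:
        chrom_centers = centers.get(anchor.chrom)
        if chrom_centers is None:
            continue
        a = anchor.center
        lo = np.searchsorted(chrom_centers, a - half_window, side="left")
        hi = np.searchsorted(chrom_centers, a + half_window - 1, side="right")
        offsets = chrom_centers[lo:hi] - a
        if oriented and anchor.strand == "-":
            offsets = -offsets
            offsets = offsets[(offsets >= -half_window) & (offsets < half_window)]
        counts += np.bincount(
            (offsets + half_window) // bin_width, minlength=len(edges) - 1
        ).astype(np.int64)
    global_mean = len(anchors) * len(sites) * bin_width / G
    return DensityProfile(half_window, bin_width, edges, counts, global_mean, len(anchors))


def fisher_exact_from_table(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact test with Woolf 95% CI for the odds ratio."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a + b, c + d, a + c, b + d):
        return FisherResult(math.nan, math.nan, math.nan, 1.0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        return FisherResult(math.nan, math.nan, math.nan, float(p))
    odds = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(odds) - 1.96 * se)
    hi = math.exp(math.log(odds) + 1.96 * se)
    return FisherResult(odds, lo, hi, float(p))


def _restrict_to_background(sites: IntervalSet, background: IntervalSet) -> IntervalSet:
    """Keep the sites whose centers fall inside the background union."""
    kept = []
    merged = background.merge()
    by_chrom = merged.starts_ends_by_chrom()
    for iv in sites:
        if iv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[iv.chrom]
        j = int(np.searchsorted(starts, iv.center, side="right")) - 1
        if j >= 0 and iv.center < ends[j]:
            kept.append(iv)
    return IntervalSet(kept, sites.genome)


def fisher_overlap(
    a_sites: IntervalSet,
    b_sites: IntervalSet,
    background: IntervalSet,
    w: int = 0,
) -> tuple[ContingencyTable2x2, FisherResult]:
    """Overlap enrichment of two site sets relative to a background universe.

    Foreground row: a-sites genome-wide, split into those whose w-extension
    hits a b-site vs. not.  Background row: the same split after restricting
    both site sets to intervals centered inside the background union (the
    open-chromatin universe in the intended application).
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    a = a_sites.overlap_count(b_sites, w)
    b = len(a_sites) - a
    a_bg = _restrict_to_background(a_sites, background)
    b_bg = _restrict_to_background(b_sites, background)
    c = a_bg.overlap_count(b_bg, w)
    d = len(a_bg) - c
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact_from_table(table)


def chip_peak_intersection(
    sets: dict[str, IntervalSet], w: int = 0
) -> dict[str, dict[str, float | int]]:
    """Pairwise and higher-order co-occupancy counts for 2-3 named peak sets.

    An interval is co-occupied within a group when its w-extension intersects
    at least one interval of every other member set.  For each group the
    count and the percentage relative to each parent set are reported,
    keyed by 'name1&name2[&name3]'.
    """
    names = list(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("expected 2 or 3 named interval sets")
    out: dict[str, dict[str, float | int]] = {}
    for r in range(2, len(names) + 1):
        for group in itertools.combinations(names, r):
            entry: dict[str, float | int] = {}
            counts = {}
            for name in group:
                others = [sets[o] for o in group if o != name]
                n = sum(
                    1
                    for iv in sets[name]
                    if all(
                        IntervalSet([iv], sets[name].genome).overlap_count(o, w) == 1
                        for o in others
                    )
                )
                counts[name] = n
            entry["counts"] = counts  # type: ignore[assignment]
            entry["percent"] = {
                name: (100.0 * counts[name] / len(sets[name]) if len(sets[name]) else 0.0)
                for name in group
            }  # type: ignore[assignment]
            out["&".join(group)] = entry
    return out
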