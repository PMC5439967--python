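"""Rotational-phasing classification of co-localized motif site pairs.

Two protein binding sites separated along the DNA by a multiple of the
~10 bp helical pitch sit on the same face of the double helix ("phased",
compatible with direct protein-protein contact); sites offset by ~5 bp
modulo the pitch sit on opposite faces ("unphased").  Classification uses
the unsigned center-to-center distance d:

    r = d mod 10
    phased      if min(r, 10 - r) <= tolerance
    unphased    if |r - 5|        <= tolerance
    unclassified otherwise

so tolerance 0 reproduces the literal multiples-of-10 vs 5+10n rule and the
two classes stay disjoint for any tolerance < 2.5 (capped at 2 here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "PHASED",
    "UNPHASED",
    "UNCLASSIFIED",
    "PhasedPair",
    "classify_pair",
    "partition_pairs",
    "assign_nearest_gene",
]

PHASED = "phased"
UNPHASED = "unphased"
UNCLASSIFIED = "unclassified"

HELICAL_PITCH = 10  # bp per turn of B-form DNA


@dataclass(frozen=True)
class PhasedPair:
    site_a: GenomicInterval
    site_b: GenomicInterval
    d: int  # unsigned center-to-center distance, bp
    phase_class: str

    @property
    def region(self) -> GenomicInterval:
        """Union span of the two sites."""
        return GenomicInterval(
            self.site_a.chrom,
            min(self.site_a.start, self.site_b.start),
            max(self.site_a.end, self.site_b.end),
        )


def classify_pair(d: int, tolerance: int = 1) -> str:
    """Rotational-phase class of a center distance d (bp)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if not (0 <= tolerance <= 2):
        raise ValueError("tolerance must be in [0, 2]; classes overlap beyond 2.5")
    r = d % HELICAL_PITCH
    if min(r, HELICAL_PITCH - r) <= tolerance:
        return PHASED
    if abs(r - HELICAL_PITCH // 2) <= tolerance:
        return UNPHASED
    return UNCLASSIFIED


def partition_pairs(
    a_sites: IntervalSet,
    b_sites: IntervalSet,
    max_d: int = 45,
    tolerance: int = 1,
) -> tuple[IntervalSet, IntervalSet, list[PhasedPair]]:
    """Pair every a-site with its nearest b-site within ``max_d`` and split
    the pair regions by rotational-phase class.

    Each a-site pairs at most once; b-sites may pair multiply.  Unclassified
    pairs are kept in the returned pair list but excluded from both region
    sets.
    """
    centers = b_sites.centers_by_chrom()
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_sites:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)

    pairs: list[PhasedPair] = []
    phased_regions: list[GenomicInterval] = []
    unphased_regions: list[GenomicInterval] = []
    for a in a_sites:
        if a.chrom not in centers:
            continue
        # nearest by |center distance|, unsigned; ties resolved upstream-first
        d_signed = IntervalSet(b_by_chrom[a.chrom]).nearest_distance(
            GenomicInterval(a.chrom, a.start, a.end)  # strand-neutral anchor
        )
        if d_signed is None or abs(d_signed) > max_d:
            continue
        target_center = a.center + d_signed
        b = next(iv for iv in b_by_chrom[a.chrom] if iv.center == target_center)
        d = abs(d_signed)
        cls = classify_pair(d, tolerance)
        pair = PhasedPair(a, b, d, cls)
        pairs.append(pair)
        if cls == PHASED:
            phased_regions.append(pair.region)
        elif cls == UNPHASED:
            unphased_regions.append(pair.region)
    genome = a_sites.genome or b_sites.genome
    return (
        IntervalSet(phased_regions, genome),
        IntervalSet(unphased_regions, genome),
        pairs,
    )


def assign_nearest_gene(
    regions: IntervalSet, tss: IntervalSet
) -> dict[GenomicInterval, str]:
    """Map each region to the gene name of the nearest TSS center.

    Ties between equidistant TSS break to the lexicographically smallest
    gene name.
    """
    if len(tss) == 0:
        raise ValueError("TSS set must be non-empty")
    tss_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in tss:
        if iv.name is None:
            raise ValueError("TSS intervals must carry gene names")
        tss_by_chrom.setdefault(iv.chrom, []).append(iv)

    mapping: dict[GenomicInterval, str] = {}
    for region in regions:
        candidates = tss_by_chrom.get(region.chrom)
        if not candidates:
            continue
        c = region.center
        best = min(candidates, key=lambda t: (abs(t.center - c), t.name))
        mapping[region] = best.name  # type: ignore[assignment]
    return mapping
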