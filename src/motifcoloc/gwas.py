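"""Binomial enrichment of GWAS SNPs in genomic region sets.

The statistic: for a trait with n lead SNPs, of which x fall inside the
(window-extended, merged) region set, and with p the fraction of the
uniquely mappable genome covered by those regions, the enrichment p-value is
the upper binomial tail

    P(X >= x),  X ~ Binomial(n, p)

and the fold change is x / (n * p).  LD expansion augments each trait with
SNPs linked to its leads above an r-squared threshold; a two-proportion
z-score test compares overlap rates between two site families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "Snp",
    "GwasCatalog",
    "LDTable",
    "MappabilityTrack",
    "BinomialEnrichmentResult",
    "read_gwas_catalog",
    "read_ld_table",
    "ld_expand",
    "mappable_fraction",
    "binomial_enrichment",
    "window_sweep",
    "ztest_proportions",
    "DEFAULT_WINDOWS",
]

logger = logging.getLogger(__name__)

#: window half-widths (bp) swept by default when extending regions
DEFAULT_WINDOWS = (1000, 2000, 5000, 10000)


@dataclass(frozen=True)
class Snp:
    chrom: str
    pos: int  # 0-based position
    rsid: str

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, name=self.rsid)


@dataclass
class GwasCatalog:
    """Trait label -> deduplicated SNP list."""

    records: dict[str, list[Snp]] = field(default_factory=dict)

    def traits(self) -> list[str]:
        return list(self.records)

    def n_snps(self, trait: str) -> int:
        return len(self.records[trait])

    def trait_positions(self, trait: str) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for snp in self.records[trait]:
            out.setdefault(snp.chrom, []).append(snp.pos)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class LDTable:
    """Lead rsid -> linked SNPs with their r-squared to the lead."""

    links: dict[str, list[tuple[Snp, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lead, linked in self.links.items():
            for _, r2 in linked:
                if not (0.0 <= r2 <= 1.0):
                    raise ValueError(f"r2 out of [0,1] for lead {lead}: {r2}")


@dataclass
class MappabilityTrack:
    """Uniquely mappable intervals; the denominator universe for p."""

    mappable: IntervalSet

    @property
    def total_mappable(self) -> int:
        return self.mappable.covered_length()

    @classmethod
    def all_mappable(cls, genome: Mapping[str, int]) -> "MappabilityTrack":
        ivs = [GenomicInterval(c, 0, length) for c, length in genome.items() if length > 0]
        return cls(IntervalSet(ivs, genome))


@dataclass(frozen=True)
class BinomialEnrichmentResult:
    trait: str
    window: int
    x: int
    n: int
    p: float
    p_value: float
    fold: float
    q_value: float = math.nan


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

_REQUIRED_COLUMNS = ("CHR_ID", "CHR_POS", "SNPS", "DISEASE/TRAIT")


def read_gwas_catalog(path: str | Path) -> GwasCatalog:
    """Read a GWAS-Catalog-dialect TSV (CHR_ID, CHR_POS, SNPS, DISEASE/TRAIT).

    Rows with missing coordinates are skipped (count logged); duplicate
    (trait, rsid) entries collapse to one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: dict[str, dict[str, Snp]] = {}
    skipped = 0
    for chrom, pos, rsid, trait in zip(
        df["CHR_ID"], df["CHR_POS"], df["SNPS"], df["DISEASE/TRAIT"]
    ):
        if pd.isna(chrom) or pd.isna(pos) or str(pos).strip() == "":
            skipped += 1
            continue
        try:
            position = int(float(pos))
        except ValueError:
            skipped += 1
            continue
        trait_records = records.setdefault(str(trait), {})
        trait_records.setdefault(str(rsid), Snp(str(chrom), position, str(rsid)))
    if skipped:
        logger.warning("skipped %d catalog rows with missing coordinates", skipped)
    return GwasCatalog({t: list(snps.values()) for t, snps in records.items()})


def read_ld_table(path: str | Path) -> LDTable:
    """Read an LD TSV with columns lead_rsid, chrom, pos, rsid, r2."""
    df = pd.read_csv(path, sep="\t", dtype={"lead_rsid": str, "chrom": str, "rsid": str})
    links: dict[str, list[tuple[Snp, float]]] = {}
    for row in df.itertuples(index=False):
        links.setdefault(row.lead_rsid, []).append(
            (Snp(row.chrom, int(row.pos), row.rsid), float(row.r2))
        )
    return LDTable(links)


# ----------------------------------------------------------------------
# the statistic
# ----------------------------------------------------------------------


def ld_expand(catalog: GwasCatalog, ld: LDTable, r2_min: float = 0.8) -> GwasCatalog:
    """Augment each trait with SNPs linked to its leads at r2 > ``r2_min``,
    deduplicating by position and rsid."""
    if not (0.0 <= r2_min <= 1.0):
        raise ValueError("r2_min must be in [0, 1]")
    out: dict[str, list[Snp]] = {}
    for trait, snps in catalog.records.items():
        seen_ids = {s.rsid for s in snps}
        seen_pos = {(s.chrom, s.pos) for s in snps}
        expanded = list(snps)
        for lead in snps:
            for linked, r2 in ld.links.get(lead.rsid, []):
                if r2 <= r2_min:
                    continue
                if linked.rsid in seen_ids or (linked.chrom, linked.pos) in seen_pos:
                    continue
                expanded.append(linked)
                seen_ids.add(linked.rsid)
                seen_pos.add((linked.chrom, linked.pos))
        out[trait] = expanded
    return GwasCatalog(out)


def mappable_fraction(regions: IntervalSet, track: MappabilityTrack) -> float:
    """Fraction of the mappable genome covered by the region union."""
    total = track.total_mappable
    if total == 0:
        raise ValueError("mappability track covers zero bp")
    return regions.intersect_length(track.mappable) / total


def binomial_p_value(x: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= x) for X ~ Binomial(n, p)."""
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def binomial_enrichment(
    regions: IntervalSet,
    catalog: GwasCatalog,
    track: MappabilityTrack | None = None,
    w: int = 0,
    adjust: bool = True,
) -> list[BinomialEnrichmentResult]:
    """Per-trait binomial enrichment of SNPs in the w-extended region union.

    Regions are extended by ``w`` and merged before measuring, so
    overlapping windows are never double counted.  Without an explicit
    mappability track the whole genome is treated as mappable.  Results are
    sorted by p-value; Benjamini-Hochberg q-values are attached when
    ``adjust`` is set (the raw binomial p-value is the primary statistic).
    """
    if track is None:
        if not regions.genome:
            raise ValueError("genome lengths required to build a default mappability track")
        track = MappabilityTrack.all_mappable(regions.genome)
    extended = regions.extend(w).merge()
    p = mappable_fraction(extended, track)
    results = []
    for trait in catalog.traits():
        n = catalog.n_snps(trait)
        if n == 0:
            logger.warning("trait %r has no SNPs; skipped", trait)
            continue
        x = 0
        for chrom, positions in catalog.trait_positions(trait).items():
            x += int(extended.contains_points(chrom, positions).sum())
        p_value = binomial_p_value(x, n, p)
        fold = x / (n * p) if n * p > 0 else math.nan
        results.append(BinomialEnrichmentResult(trait, w, x, n, p, p_value, fold))
    results.sort(key=lambda r: (r.p_value, r.trait))
    if adjust and results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            BinomialEnrichmentResult(
                r.trait, r.window, r.x, r.n, r.p, r.p_value, r.fold, float(qv)
            )
            for r, qv in zip(results, q)
        ]
    return results


def window_sweep(
    regions: IntervalSet,
    catalog: GwasCatalog,
    track: MappabilityTrack | None = None,
    windows: Iterable[int] = DEFAULT_WINDOWS,
) -> list[BinomialEnrichmentResult]:
    """Run the enrichment at each window half-width and concatenate results."""
    out: list[BinomialEnrichmentResult] = []
    for w in windows:
        out.extend(binomial_enrichment(regions, catalog, track, w))
    return out


def ztest_proportions(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided z-score test comparing two proportions x1/n1 vs x2/n2.

    Uses the pooled estimate p = (x1+x2)/(n1+n2); a degenerate pooled
    proportion (0 or 1) returns z = 0, p-value = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= x_i <= n_i")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def results_to_frame(results: Iterable[BinomialEnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per trait x window)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "window": r.window,
                "x": r.x,
                "n": r.n,
                "p": r.p,
                "fold": r.fold,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
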