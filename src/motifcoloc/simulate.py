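"""Synthetic data with planted structure for every pipeline input.

The generators emulate the statistical structure the pipeline is meant to
detect: a random genome carrying exact-consensus motif pairs planted at
rotationally phased (multiples of 10 bp) or un-phased (5 + 10n bp) center
spacings, ChIP-style summits jittered around planted sites, oriented TSS
with motif placement downstream of the start site and at the +1-nucleosome
boundary, trait-labelled SNP sets with a controlled fraction planted inside
target regions, striped mappability masks, and block-correlated expression
matrices.  Every generator is deterministic under the config seed and
returns a truth table alongside its artifact.

The two bundled motif matrices are synthetic stand-ins for the bHLH/PAS
dimer and E-box motifs of the intended application: 14-bp sharp count
matrices whose consensus embeds the GCGTG core (motif A) and the CAGCTG
E-box (motif B).  The length and sharpness are chosen so that, at the
high-stringency relative threshold, chance decoy hits in a megabase-scale
random genome are rare enough not to perturb planted-pair recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas import GwasCatalog, LDTable, MappabilityTrack, Snp
from .intervals import GenomeSequence, GenomicInterval, IntervalSet
from .pwm import BASES, MotifMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "default_motifs",
    "make_genome",
    "plant_motif_pairs",
    "phasing_recovery_accuracy",
    "make_summits",
    "make_tss",
    "plant_tss_proximal_sites",
    "make_mappability",
    "make_gwas",
    "make_expression",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Planted center spacings: the subsets of the 10n (phased) and 5+10n
# (un-phased) families that let two 14-bp exact-consensus sites coexist
# without overwriting each other (d >= motif length) and stay inside the
# default 45-bp pairing radius even after +/-1 bp jitter.
PHASED_SPACINGS = (20, 30, 40)
UNPHASED_SPACINGS = (15, 25, 35)


@dataclass(frozen=True)
class TraitSpec:
    name: str
    n_snps: int = 100
    planted_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")


def _default_traits() -> list[TraitSpec]:
    return [TraitSpec("planted trait", 100, 0.5)] + [
        TraitSpec(f"null trait {i}", 100, 0.0) for i in range(1, 10)
    ]


@dataclass
class SimConfig:
    """Parameters of the planted-structure simulation.

    Defaults describe the standard benchmark: a 1 Mb two-chromosome genome
    at human-like 41% GC carrying 200 phased and 200 un-phased consensus
    pairs with no spacing jitter, 200 oriented TSS, summits jittered by a
    20 bp standard deviation, ten 100-SNP traits of which one has half its
    SNPs planted in target regions, a fully mappable genome, and a 3-block
    expression matrix of 10 rows/block over 20 samples at within-block
    |r| = 0.9.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_chroms: int = 2
    gc: float = 0.41
    n_pairs_phased: int = 200
    n_pairs_unphased: int = 200
    pair_jitter: int = 0
    n_tss: int = 200
    summit_jitter: float = 20.0
    n_decoy_summits: int = 0
    traits: list[TraitSpec] = field(default_factory=_default_traits)
    mappable_fraction_sim: float = 1.0
    expr_n_blocks: int = 3
    expr_rows_per_block: int = 10
    expr_n_samples: int = 20
    expr_within_r: float = 0.9
    expr_noise_sd: float | None = None  # default derived from expr_within_r

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")
        if not (0.0 < self.mappable_fraction_sim <= 1.0):
            raise ValueError("mappable_fraction_sim must be in (0, 1]")
        if self.pair_jitter < 0 or min(self.n_pairs_phased, self.n_pairs_unphased) < 0:
            raise ValueError("counts and jitter must be >= 0")
        if not (0.0 <= self.expr_within_r <= 1.0):
            raise ValueError("expr_within_r must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def _sharp_counts(consensus: str, hit: int = 97, miss: int = 1) -> np.ndarray:
    counts = np.full((len(consensus), 4), miss, dtype=float)
    for i, base in enumerate(consensus):
        counts[i, BASES.index(base)] = hit
    return counts


def default_motifs() -> tuple[MotifMatrix, MotifMatrix]:
    """The two bundled synthetic motif matrices (see module docstring)."""
    motif_a = MotifMatrix("SYNA0001.1", "synPasDimer", _sharp_counts("TTAGCGTGCTGACA"))
    motif_b = MotifMatrix("SYNB0002.1", "synEbox", _sharp_counts("GACCAGCTGTTCAT"))
    return motif_a, motif_b


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def make_genome(cfg: SimConfig) -> GenomeSequence:
    """I.i.d. random genome at the configured GC content, split evenly over
    ``n_chroms`` chromosomes."""
    rng = cfg.rng(1)
    gc = cfg.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names = _chrom_names(cfg.n_chroms)
    per = cfg.genome_length // cfg.n_chroms
    lengths = [per] * cfg.n_chroms
    lengths[-1] += cfg.genome_length - per * cfg.n_chroms
    seqs = {}
    base_array = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for name, length in zip(names, lengths):
        draws = rng.choice(4, size=length, p=probs)
        seqs[name] = base_array[draws].tobytes().decode()
    return GenomeSequence(seqs)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _write_site(buf: bytearray, start: int, consensus: str, strand: str) -> None:
    written = consensus if strand == "+" else _revcomp(consensus)
    buf[start : start + len(consensus)] = written.encode()


def plant_motif_pairs(
    genome: GenomeSequence,
    cfg: SimConfig,
    motif_a: MotifMatrix | None = None,
    motif_b: MotifMatrix | None = None,
) -> tuple[pd.DataFrame, GenomeSequence]:
    """Write exact-consensus site pairs into a copy of the genome.

    Each pair holds one motif-A site and one motif-B site at an unsigned
    center spacing drawn from :data:`PHASED_SPACINGS` or
    :data:`UNPHASED_SPACINGS` plus uniform jitter in [-pair_jitter,
    +pair_jitter]; the B site falls on a random side of the A site and site
    strands alternate deterministically to exercise strand handling.  The
    returned truth table records positions, spacing, and class.
    """
    if motif_a is None or motif_b is None:
        motif_a, motif_b = default_motifs()
    rng = cfg.rng(2)
    cons_a, cons_b = motif_a.consensus, motif_b.consensus
    La, Lb = len(cons_a), len(cons_b)
    buffers = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    chroms = list(genome.seqs)
    lengths = np.array([len(genome.seqs[c]) for c in chroms], dtype=float)
    chrom_probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    # keep pairs > 45 bp apart so sites of one pair can never capture the
    # nearest-neighbor pairing of another
    guard = 60
    margin = La + Lb + max(PHASED_SPACINGS + UNPHASED_SPACINGS) + cfg.pair_jitter + guard

    jobs = [("phased", PHASED_SPACINGS)] * cfg.n_pairs_phased + [
        ("unphased", UNPHASED_SPACINGS)
    ] * cfg.n_pairs_unphased
    rows = []
    for idx, (cls, menu) in enumerate(jobs):
        d0 = int(rng.choice(menu))
        jitter = int(rng.integers(-cfg.pair_jitter, cfg.pair_jitter + 1)) if cfg.pair_jitter else 0
        d = max(0, d0 + jitter)
        side = 1 if rng.random() < 0.5 else -1
        for attempt in range(100):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_probs))]
            limit = len(genome.seqs[chrom])
            a_start = int(rng.integers(margin, limit - margin))
            a_center = a_start + (La - 1) // 2
            b_center = a_center + side * d
            b_start = b_center - (Lb - 1) // 2
            lo = min(a_start, b_start) - guard
            hi = max(a_start + La, b_start + Lb) + guard
            if all(hi <= s or lo >= e for s, e in occupied[chrom]):
                occupied[chrom].append((lo, hi))
                break
        else:
            raise RuntimeError("could not place a motif pair after 100 resamples")
        a_strand = "+" if idx % 2 == 0 else "-"
        b_strand = "+" if (idx // 2) % 2 == 0 else "-"
        _write_site(buffers[chrom], a_start, cons_a, a_strand)
        _write_site(buffers[chrom], b_start, cons_b, b_strand)
        rows.append(
            {
                "chrom": chrom,
                "a_start": a_start,
                "a_center": a_center,
                "a_strand": a_strand,
                "b_start": b_start,
                "b_center": b_center,
                "b_strand": b_strand,
                "d": d,
                "d_menu": d0,
                "phase_class": cls,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "a_start",
            "a_center",
            "a_strand",
            "b_start",
            "b_center",
            "b_strand",
            "d",
            "d_menu",
            "phase_class",
        ],
    )
    mutated = GenomeSequence({c: b.decode() for c, b in buffers.items()})
    return truth, mutated


def phasing_recovery_accuracy(truth: pd.DataFrame, pairs) -> float:
    """Fraction of planted pairs whose recovered pair (matched by the
    A-site center) carries the planted phase class.

    A planted pair with no recovered counterpart counts as a miss.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    recovered = {
        (p.site_a.chrom, p.site_a.center): p.phase_class for p in pairs
    }
    hits = 0
    for chrom, center, cls in zip(truth["chrom"], truth["a_center"], truth["phase_class"]):
        if recovered.get((chrom, int(center))) == cls:
            hits += 1
    return hits / len(truth)


def make_summits(
    truth: pd.DataFrame, cfg: SimConfig, genome: GenomeSequence
) -> IntervalSet:
    """Width-1 summits at planted A-site centers plus Gaussian positional
    jitter, with optional uniform decoy summits."""
    if truth.empty and cfg.n_decoy_summits == 0:
        raise ValueError("no planted sites and no decoys requested")
    rng = cfg.rng(3)
    lengths = genome.lengths()
    out = []
    for chrom, center in zip(truth["chrom"], truth["a_center"]):
        pos = int(round(center + rng.normal(0.0, cfg.summit_jitter)))
        pos = min(max(pos, 0), lengths[chrom] - 1)
        out.append(GenomicInterval(chrom, pos, pos + 1, name="summit"))
    chroms = list(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(cfg.n_decoy_summits):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        pos = int(rng.integers(0, lengths[chrom]))
        out.append(GenomicInterval(chrom, pos, pos + 1, name="decoy"))
    return IntervalSet(out, lengths)


def make_tss(cfg: SimConfig, genome: GenomeSequence) -> IntervalSet:
    """Oriented width-1 TSS with synthetic gene names and mixed strands."""
    rng = cfg.rng(4)
    lengths = genome.lengths()
    chroms = list(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for i in range(cfg.n_tss):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        pos = int(rng.integers(500, lengths[chrom] - 500))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(GenomicInterval(chrom, pos, pos + 1, strand, name=f"gene{i + 1:04d}"))
    return IntervalSet(out, lengths)


def plant_tss_proximal_sites(
    genome: GenomeSequence,
    tss: IntervalSet,
    motif: MotifMatrix,
    offsets: Sequence[int] = (30, 200),
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GenomeSequence]:
    """Plant motif consensus downstream of a fraction of oriented TSS at the
    given offsets (default: just past the start site and at the
    +1-nucleosome boundary), reproducing a double-peak promoter profile."""
    rng = np.random.default_rng([seed % (2**31), 5])
    cons = motif.consensus
    L = len(cons)
    buffers = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    lengths = genome.lengths()
    rows = []
    for iv in tss:
        if rng.random() > fraction:
            continue
        sign = 1 if iv.strand != "-" else -1
        for off in offsets:
            center = iv.center + sign * off
            start = center - (L - 1) // 2
            if start < 0 or start + L > lengths[iv.chrom]:
                continue
            _write_site(buffers[iv.chrom], start, cons, iv.strand if iv.strand != "." else "+")
            rows.append(
                {"chrom": iv.chrom, "tss": iv.center, "offset": off, "start": start}
            )
    truth = pd.DataFrame(rows, columns=["chrom", "tss", "offset", "start"])
    return truth, GenomeSequence({c: b.decode() for c, b in buffers.items()})


def make_mappability(cfg: SimConfig, genome: GenomeSequence) -> MappabilityTrack:
    """Striped mappability mask: within each 1 kb period the first
    ``mappable_fraction_sim`` of positions are uniquely mappable."""
    period = 1000
    block = int(round(period * cfg.mappable_fraction_sim))
    out = []
    for chrom, length in genome.lengths().items():
        for start in range(0, length, period):
            end = min(start + block, length)
            if end > start:
                out.append(GenomicInterval(chrom, start, end))
    return MappabilityTrack(IntervalSet(out, genome.lengths()))


def _sample_in_union(
    union: IntervalSet, size: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    merged = list(union.merge())
    widths = np.array([iv.width for iv in merged], dtype=np.int64)
    if widths.sum() == 0 or not merged:
        raise ValueError("cannot sample positions from an empty union")
    cum = np.concatenate([[0], np.cumsum(widths)])
    draws = rng.integers(0, cum[-1], size=size)
    idx = np.searchsorted(cum, draws, side="right") - 1
    return [
        (merged[i].chrom, int(merged[i].start + (d - cum[i]))) for i, d in zip(idx, draws)
    ]


def make_gwas(
    cfg: SimConfig,
    regions: IntervalSet,
    track: MappabilityTrack,
) -> tuple[GwasCatalog, LDTable]:
    """Trait-labelled SNP sets with a planted in-region fraction, plus a
    synthetic LD table.

    For each trait, ``round(f * n)`` SNPs are placed uniformly inside the
    intersection of the regions with the mappable mask and the remainder
    uniformly over the whole mappable genome.  Each lead gains 0-3 linked
    SNPs within +/-5 kb whose r2 is drawn from a half-high (0.8-1.0),
    half-low (0.0-0.8) mixture.
    """
    rng = cfg.rng(6)
    mappable_union = track.mappable.merge()
    region_map = IntervalSet(
        _intersect(regions.merge(), mappable_union), regions.genome or track.mappable.genome
    )
    records: dict[str, list[Snp]] = {}
    counter = 0
    lengths = track.mappable.genome or regions.genome
    links: dict[str, list[tuple[Snp, float]]] = {}
    for spec in cfg.traits:
        n_in = int(round(spec.planted_fraction * spec.n_snps))
        if n_in > 0 and len(region_map) == 0:
            raise ValueError(
                f"trait {spec.name!r} requests planted SNPs but regions do not "
                "intersect the mappable genome"
            )
        placements = []
        if n_in:
            placements.extend(_sample_in_union(region_map, n_in, rng))
        if spec.n_snps - n_in:
            placements.extend(_sample_in_union(mappable_union, spec.n_snps - n_in, rng))
        snps = []
        for chrom, pos in placements:
            counter += 1
            snp = Snp(chrom, pos, f"rs{counter:07d}")
            snps.append(snp)
            n_links = int(rng.integers(0, 4))
            for _ in range(n_links):
                counter += 1
                shift = int(rng.integers(-5000, 5001))
                linked_pos = min(max(pos + shift, 0), lengths[chrom] - 1)
                r2 = (
                    float(rng.uniform(0.8, 1.0))
                    if rng.random() < 0.5
                    else float(rng.uniform(0.0, 0.8))
                )
                links.setdefault(snp.rsid, []).append(
                    (Snp(chrom, linked_pos, f"rs{counter:07d}"), r2)
                )
        records[spec.name] = snps
    return GwasCatalog(records), LDTable(links)


def _intersect(a: IntervalSet, b: IntervalSet) -> list[GenomicInterval]:
    out = []
    bb = b.starts_ends_by_chrom()
    for iv in a:
        if iv.chrom not in bb:
            continue
        starts, ends = bb[iv.chrom]
        j = int(np.searchsorted(ends, iv.start, side="right"))
        while j < len(starts) and starts[j] < iv.end:
            lo, hi = max(iv.start, int(starts[j])), min(iv.end, int(ends[j]))
            if hi > lo:
                out.append(GenomicInterval(iv.chrom, lo, hi))
            j += 1
    return out


def make_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Block-correlated expression matrix plus true block labels.

    Rows in the same block share a latent per-sample factor; loadings
    alternate in sign so within-block correlations are +/-within_r but
    |r| is constant, and independent Gaussian noise sets the correlation
    level: sd = sqrt((1 - r) / r) for within-block expected |r| = r (zero
    noise when r = 1), unless ``expr_noise_sd`` overrides it.
    """
    rng = cfg.rng(7)
    r = cfg.expr_within_r
    if cfg.expr_noise_sd is not None:
        sd = cfg.expr_noise_sd
    elif r <= 0:
        sd = 1.0
    else:
        sd = float(np.sqrt((1 - r) / r))
    rows = []
    labels = []
    names = []
    for b in range(cfg.expr_n_blocks):
        factor = rng.normal(size=cfg.expr_n_samples)
        for j in range(cfg.expr_rows_per_block):
            loading = 1.0 if j % 2 == 0 else -1.0
            noise = rng.normal(scale=sd, size=cfg.expr_n_samples) if sd > 0 else 0.0
            rows.append(loading * factor + noise)
            labels.append(b + 1)
            names.append(f"P{b + 1:02d}_{j + 1:02d}")
    matrix = pd.DataFrame(
        np.asarray(rows),
        index=names,
        columns=[f"sample{s + 1:02d}" for s in range(cfg.expr_n_samples)],
    )
    return matrix, pd.Series(labels, index=names, name="block")
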