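"""Scan a synthetic genome with two motif matrices and profile their
spatial co-localization.

Builds a 200 kb genome carrying planted motif pairs, scans it at high
stringency on both strands, and asks two questions: how far is the nearest
partner site from each anchor site (distance histogram), and how strongly
do partner sites pile up around anchors relative to a uniform genome
(density profile, 1.0 = no co-localization)?  Finally, a Fisher exact test
checks whether direct overlap of the two site sets is enriched against an
open-chromatin-style background universe.
"""

import numpy as np

from motifcoloc import (
    IntervalSet,
    GenomicInterval,
    density_profile,
    distance_histogram,
    fisher_overlap,
    scan_sequence,
)
from motifcoloc.simulate import SimConfig, default_motifs, make_genome, plant_motif_pairs

cfg = SimConfig(seed=11, genome_length=200_000, n_pairs_phased=60, n_pairs_unphased=60)
motif_a, motif_b = default_motifs()
truth, genome = plant_motif_pairs(make_genome(cfg), cfg)

hits_a = scan_sequence(genome, motif_a, "high")
hits_b = scan_sequence(genome, motif_b, "high")
print(f"high-stringency hits: {len(hits_a)} for {motif_a.name}, "
      f"{len(hits_b)} for {motif_b.name}")

hist = distance_histogram(hits_a, hits_b, half_window=100, bin_width=10)
in_window = int(hist.counts.sum())
print(f"{in_window}/{hist.n_anchors} anchor sites have a partner within 100 bp")

prof = density_profile(hits_a, hits_b, half_window=50, bin_width=10)
print("density profile (fold over uniform expectation, bins of 10 bp):")
for (lo, hi, count, dens) in prof.to_rows():
    print(f"  [{lo:+4d},{hi:+4d})  count={count:3d}  density={dens:7.1f}")

# Overlap enrichment against an open-chromatin-style background.  Decoy
# sites (uniform random, mimicking background motif matches) dilute both
# hit sets genome-wide; open chromatin covers the planted co-binding loci,
# so background-restricted sites overlap far more often.
rng = np.random.default_rng(11)
lengths = genome.lengths()


def with_decoys(hits, n=300):
    decoys = [
        GenomicInterval("chr1", int(p), int(p) + 14)
        for p in rng.integers(0, lengths["chr1"] - 14, n)
    ]
    return IntervalSet(list(hits) + decoys, lengths)


background = IntervalSet(
    [
        GenomicInterval(c, max(0, s - 500), s + 500)
        for c, s in zip(truth.chrom, truth.a_start)
    ],
    lengths,
)
table, fisher = fisher_overlap(with_decoys(hits_a), with_decoys(hits_b), background, w=50)
print(f"overlap within 50 bp, genome-wide: {table.a}/{table.a + table.b}; "
      f"within open chromatin: {table.c}/{table.c + table.d}")
print(f"odds ratio {fisher.odds_ratio:.2f} "
      f"(95% CI {fisher.ci_low:.2f}-{fisher.ci_high:.2f}), Fisher p = {fisher.p_value:.3g}")
print("Density far above 1 near offset 0 is the signature of genuine "
      "co-binding; the Fisher test (odds ratio below 1 in this orientation) "
      "shows overlap concentrates inside the open-chromatin universe.")
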