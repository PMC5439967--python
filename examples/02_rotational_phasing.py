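"""Classify co-localized site pairs by DNA helical-pitch rotational phasing.

Two binding sites spaced by a multiple of the ~10 bp helical pitch face the
same side of the double helix (compatible with direct protein contact);
spacings of 5 bp modulo the pitch put them on opposite faces.  The script
plants pairs of both kinds, recovers them by scanning, partitions them by
phase class, and assigns each pair region to its nearest gene.
"""

from collections import Counter

from motifcoloc import partition_pairs, scan_sequence
from motifcoloc.phasing import assign_nearest_gene
from motifcoloc.simulate import (
    SimConfig,
    default_motifs,
    make_genome,
    make_tss,
    phasing_recovery_accuracy,
    plant_motif_pairs,
)

cfg = SimConfig(seed=7, genome_length=500_000, n_pairs_phased=100, n_pairs_unphased=100)
motif_a, motif_b = default_motifs()
truth, genome = plant_motif_pairs(make_genome(cfg), cfg)

hits_a = scan_sequence(genome, motif_a, "high")
hits_b = scan_sequence(genome, motif_b, "high")
phased, unphased, pairs = partition_pairs(hits_a, hits_b, max_d=45, tolerance=0)

classes = Counter(p.phase_class for p in pairs)
print(f"recovered {len(pairs)} co-localized pairs: "
      f"{classes['phased']} phased, {classes['unphased']} un-phased")
spacings = Counter(p.d for p in pairs)
print("spacing distribution:", dict(sorted(spacings.items())))
print(f"planted-class recovery accuracy: {phasing_recovery_accuracy(truth, pairs):.3f}")

tss = make_tss(cfg, genome)
genes = assign_nearest_gene(unphased, tss)
some = list(genes.items())[:3]
for region, gene in some:
    print(f"un-phased pair region {region.chrom}:{region.start}-{region.end} -> {gene}")
print("Phased pairs mark candidate direct protein-protein contacts; un-phased "
      "pairs suggest interaction through an intermediary, and each region is "
      "tied to its nearest gene for downstream annotation.")
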