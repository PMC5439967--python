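"""Mappability-corrected binomial enrichment of GWAS SNPs in region sets.

For a trait with n SNPs of which x fall inside the (window-extended,
merged) regions, and p the fraction of the uniquely mappable genome those
regions cover, the enrichment p-value is the upper binomial tail P(X >= x).
One simulated trait has half its SNPs planted inside the regions; nine are
null.  LD expansion (r^2 > 0.8) grows each trait before testing.
"""

from motifcoloc import binomial_enrichment, ld_expand
from motifcoloc.gwas import results_to_frame
from motifcoloc.intervals import GenomicInterval, IntervalSet
from motifcoloc.simulate import SimConfig, make_genome, make_gwas, make_mappability

cfg = SimConfig(seed=3, genome_length=1_000_000, n_chroms=1, mappable_fraction_sim=0.8)
genome = make_genome(cfg)
track = make_mappability(cfg, genome)
regions = IntervalSet(
    [GenomicInterval("chr1", s, s + 1000) for s in range(0, 1_000_000, 10_000)],
    genome.lengths(),
)
catalog, ld = make_gwas(cfg, regions, track)
expanded = ld_expand(catalog, ld, r2_min=0.8)
print(f"LD expansion: planted trait {catalog.n_snps('planted trait')} lead SNPs "
      f"-> {expanded.n_snps('planted trait')} lead+linked")

results = binomial_enrichment(regions, catalog, track, w=1000)
table = results_to_frame(results)
print(table.head(4).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
top = results[0]
print(f"top trait: {top.trait!r}, x={top.x}/{top.n} SNPs in regions covering "
      f"p={top.p:.3f} of the mappable genome, fold={top.fold:.1f}, "
      f"binomial p={top.p_value:.3g}")
print("Only the planted trait has far more in-region SNPs than the mappable "
      "fraction predicts; null traits sit near fold 1 with large p-values.")
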